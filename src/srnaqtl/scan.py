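"""Genome scans for expression QTLs on bin genotypes.

Because IMF2 genotypes are fully observed at every bin, composite interval
mapping reduces to marker regression with an additive + dominance coding:
at a test bin, LOD = (n/2) * log10(RSS_reduced / RSS_full), where the
reduced model holds the intercept and selected cofactor markers and the full
model adds the test bin's additive code x in {-1, 0, +1} and dominance code
z = 1[Aa]. Cofactors are chosen by forward stepwise BIC on additive codes
and dropped within a window around the test bin. Genome-wide significance
is by permutation of trait values; trait-level discovery is controlled by
Benjamini-Hochberg across traits.

The public surface follows the statsmodels pattern: build a
:class:`QTLScanModel` from a trait matrix and a bin map, call ``fit()`` and
read estimates, intervals and classifications off the returned
:class:`QTLScanResults`.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import orth
from statsmodels.stats.multitest import multipletests

from . import effects as eff
from .genome import BinMap

_PERM_CHUNK = 128  # permutations per einsum block, keeps memory modest


@dataclass
class ScanConfig:
    """Scan settings; defaults replicate the mapped study design."""

    n_perm: int = 1000
    alpha: float = 0.05
    q: float = 0.05
    max_cofactors: int = 3
    window_bp: int = 10_000_000
    lod_drop: float = 1.5
    local_max_dist: int = 250_000
    peak_min_separation: int = 5
    valley_drop: float = 1.5
    n_perm_dominance: int = 1000
    dominance_alpha: float = 0.05
    seed: int = 0


class GenotypeDesign:
    """Additive/dominance codes per individual per bin, plus bin geometry."""

    def __init__(self, binmap: BinMap):
        self.binmap = binmap
        g = binmap.genotypes
        self.x = (g.astype(float) - 1.0)  # n x nb
        self.z = (g == 1).astype(float)
        self.n, self.n_bins = self.x.shape
        bins = binmap.bins
        self.chroms = bins["chrom"].to_numpy()
        self.mid = binmap.midpoints
        self.starts = bins["start"].to_numpy()
        self.ends = bins["end"].to_numpy()
        self.n_classes = np.array(
            [len(np.unique(g[:, j])) for j in range(self.n_bins)]
        )
        # contiguous index range per chromosome (bins are ordered)
        self.chrom_ranges: dict[str, tuple[int, int]] = {}
        for c in pd.unique(bins["chrom"]):
            idx = np.flatnonzero(self.chroms == c)
            self.chrom_ranges[str(c)] = (int(idx[0]), int(idx[-1]))


def _padded_orth(X: np.ndarray, p_max: int, n: int) -> np.ndarray:
    """Orthonormal column basis of X, zero-padded to p_max columns."""
    Q = orth(X)
    out = np.zeros((n, p_max))
    out[:, : Q.shape[1]] = Q
    return out


def build_bases(
    design: GenotypeDesign,
    cofactors: tuple[int, ...] = (),
    window_bp: int = 10_000_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin orthonormal bases of the full and reduced scan models.

    Cofactor markers lying within ``window_bp`` of the test bin (same
    chromosome) are dropped from both models at that bin. Bins with fewer
    than two genotype classes get identical bases, so their LOD is 0.
    """
    n, nb = design.n, design.n_bins
    ones = np.ones((n, 1))
    p_red = 1 + len(cofactors)
    p_full = p_red + 2
    Qred = np.zeros((nb, n, p_red))
    Qfull = np.zeros((nb, n, p_full))
    for j in range(nb):
        active = [
            c
            for c in cofactors
            if c != j
            and not (
                design.chroms[c] == design.chroms[j]
                and abs(int(design.mid[c]) - int(design.mid[j])) <= window_bp
            )
        ]
        Xr = (
            np.hstack([ones, design.x[:, active]]) if active else ones
        )
        Qr = _padded_orth(Xr, p_red, n)
        Qred[j] = Qr
        if design.n_classes[j] >= 2:
            Xf = np.hstack([Xr, design.x[:, [j]], design.z[:, [j]]])
            Qfull[j] = _padded_orth(Xf, p_full, n)
        else:
            Qfull[j, :, :p_red] = Qr
    return Qfull, Qred


def _lod_profiles(
    Y: np.ndarray, Qfull: np.ndarray, Qred: np.ndarray, n: int
) -> np.ndarray:
    """LOD profiles for each column of Y; returns (n_bins, m)."""
    Y = np.atleast_2d(Y.T).T  # (n, m)
    yty = np.einsum("nm,nm->m", Y, Y)
    pf = np.einsum("bnp,nm->bpm", Qfull, Y)
    pr = np.einsum("bnp,nm->bpm", Qred, Y)
    rss_f = np.maximum(yty[None, :] - np.einsum("bpm,bpm->bm", pf, pf), 1e-300)
    rss_r = np.maximum(yty[None, :] - np.einsum("bpm,bpm->bm", pr, pr), 1e-300)
    lod = np.maximum((n / 2.0) * np.log10(rss_r / rss_f), 0.0)
    # a reduced model that already fits perfectly leaves nothing to map;
    # the RSS ratio there is numerical noise
    degenerate = rss_r <= 1e-9 * (yty[None, :] + 1.0)
    lod[degenerate] = 0.0
    return lod


def scan_trait(
    y: np.ndarray,
    design: GenotypeDesign,
    cofactors: tuple[int, ...] = (),
    window_bp: int = 10_000_000,
    bases: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """LOD profile over all bins for one trait."""
    if bases is None:
        bases = build_bases(design, cofactors, window_bp)
    Qfull, Qred = bases
    return _lod_profiles(np.asarray(y, float), Qfull, Qred, design.n)[:, 0]


def select_cofactors(
    y: np.ndarray,
    design: GenotypeDesign,
    max_cofactors: int = 3,
) -> tuple[int, ...]:
    """Forward stepwise marker selection on additive codes.

    Scored by the extended BIC (per-term penalty ln n + 2 ln n_bins), which
    accounts for choosing each cofactor out of all bins; a plain BIC admits
    a spurious marker for most null traits once hundreds of bins compete.
    """
    y = np.asarray(y, dtype=float)
    n = design.n
    if max_cofactors <= 0 or np.ptp(y) == 0:
        return ()
    penalty = np.log(n) + 2.0 * np.log(design.n_bins)
    Qc = np.ones((n, 1)) / np.sqrt(n)
    resid_y = y - Qc @ (Qc.T @ y)
    rss = float(resid_y @ resid_y)
    if rss <= 1e-12:
        return ()
    chosen: list[int] = []
    score = n * np.log(rss / n)
    X = design.x
    for _ in range(max_cofactors):
        R = X - Qc @ (Qc.T @ X)
        norms2 = np.einsum("nj,nj->j", R, R)
        ok = norms2 > 1e-10
        gain = np.zeros(design.n_bins)
        gain[ok] = (R[:, ok].T @ resid_y) ** 2 / norms2[ok]
        j = int(np.argmax(gain))
        new_rss = max(rss - float(gain[j]), 1e-12)
        new_score = n * np.log(new_rss / n) + len(chosen + [j]) * penalty
        if new_score >= score:
            break
        chosen.append(j)
        if new_rss <= 1e-10:
            break
        q = R[:, j] / np.sqrt(norms2[j])
        Qc = np.hstack([Qc, q[:, None]])
        resid_y = resid_y - q * (q @ resid_y)
        rss, score = new_rss, new_score
    return tuple(sorted(chosen))


def permutation_threshold(
    y: np.ndarray,
    bases: tuple[np.ndarray, np.ndarray],
    n: int,
    n_perm: int = 1000,
    alpha: float = 0.05,
    rng: np.random.Generator | int = 0,
    observed_max: float | None = None,
) -> tuple[float, float, np.ndarray]:
    """Permute trait values, rescan, take the genome-wide max LOD.

    Returns (threshold, p, perm_max) where threshold is the (1 - alpha)
    empirical quantile of the permuted maxima and
    p = (1 + #{perm max >= observed max}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    y = np.asarray(y, dtype=float)
    Qfull, Qred = bases
    if observed_max is None:
        observed_max = float(_lod_profiles(y, Qfull, Qred, n).max())
    perm_max = np.empty(n_perm)
    done = 0
    while done < n_perm:
        m = min(_PERM_CHUNK, n_perm - done)
        Yp = rng.permuted(np.broadcast_to(y, (m, len(y))), axis=1).T
        perm_max[done : done + m] = _lod_profiles(Yp, Qfull, Qred, n).max(axis=0)
        done += m
    threshold = float(np.quantile(perm_max, 1.0 - alpha, method="higher"))
    p = float((1 + np.sum(perm_max >= observed_max)) / (1 + n_perm))
    return threshold, p, perm_max


def fdr_across_traits(pvalues: pd.Series, q: float = 0.05) -> pd.Series:
    """Benjamini-Hochberg across all scanned traits."""
    rejected, *_ = multipletests(pvalues.to_numpy(), alpha=q, method="fdr_bh")
    return pd.Series(rejected, index=pvalues.index)


def call_peaks(
    profile: np.ndarray,
    threshold: float,
    design: GenotypeDesign,
    min_separation: int = 5,
    valley_drop: float = 1.5,
) -> list[int]:
    """Local maxima >= threshold, one peak per plateau (lowest coordinate).

    Two maxima on one chromosome are distinct peaks only when they are at
    least ``min_separation`` bins apart AND separated by a valley dropping
    ``valley_drop`` LOD below the lower maximum; otherwise they collapse to
    the higher one (ties to the lower coordinate). Under the tight linkage
    of a bin map, wiggles on one LOD hill are not separate QTLs.
    """
    peaks: list[int] = []
    for lo, hi in design.chrom_ranges.values():
        v = profile[lo : hi + 1]
        cands = []
        j = 0
        while j < len(v):
            k = j
            while k + 1 < len(v) and v[k + 1] == v[j]:
                k += 1
            left_ok = j == 0 or v[j - 1] < v[j]
            right_ok = k == len(v) - 1 or v[k + 1] < v[j]
            if left_ok and right_ok and v[j] >= threshold:
                cands.append(j)
            j = k + 1
        cands.sort(key=lambda i: (-v[i], i))
        accepted: list[int] = []
        for i in cands:
            keep = True
            for p in accepted:
                a, b = min(i, p), max(i, p)
                valley = v[a : b + 1].min()
                if (
                    abs(i - p) >= min_separation
                    and valley <= min(v[i], v[p]) - valley_drop
                ):
                    continue
                keep = False
                break
            if keep:
                accepted.append(i)
        peaks.extend(lo + i for i in accepted)
    return sorted(peaks)


def support_interval(
    profile: np.ndarray,
    peak: int,
    design: GenotypeDesign,
    drop: float = 1.5,
) -> tuple[int, int]:
    """Contiguous bins around the peak with LOD >= peak - drop, extended one
    bin beyond on each side and clipped at the chromosome ends.

    Returns inclusive bin indices (lo, hi)."""
    chrom = design.chroms[peak]
    c_lo, c_hi = design.chrom_ranges[str(chrom)]
    cut = profile[peak] - drop
    lo = peak
    while lo > c_lo and profile[lo - 1] >= cut:
        lo -= 1
    hi = peak
    while hi < c_hi and profile[hi + 1] >= cut:
        hi += 1
    return max(lo - 1, c_lo), min(hi + 1, c_hi)


def variance_explained(y: np.ndarray, dosage: np.ndarray) -> float:
    """R^2 of the single-locus genotype-means model (mu + a*x + d*z)."""
    y = np.asarray(y, dtype=float)
    g = np.asarray(dosage)
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        return float("nan")
    classes = np.unique(g)
    if len(classes) < 2:
        raise ValueError("need at least 2 genotype classes")
    rss = 0.0
    for k in classes:
        sub = y[g == k]
        rss += float(((sub - sub.mean()) ** 2).sum())
    return 1.0 - rss / tss


def classify_local_distant(
    peak: int,
    interval: tuple[int, int],
    anchor_chrom: str,
    anchor_pos: int,
    design: GenotypeDesign,
    max_marker_dist: int = 250_000,
) -> str:
    """Local iff the trait anchor falls inside the support interval's bp
    span, or lies within ``max_marker_dist`` of the peak bin; a trait on a
    different chromosome from its peak is always distant."""
    if anchor_chrom != design.chroms[peak]:
        return "distant"
    lo, hi = interval
    if design.starts[lo] <= anchor_pos < design.ends[hi]:
        return "local"
    gap = max(
        design.starts[peak] - anchor_pos, anchor_pos - (design.ends[peak] - 1), 0
    )
    return "local" if gap <= max_marker_dist else "distant"


def _trait_rng(seed: int, trait_id: str) -> np.random.Generator:
    """Deterministic per-trait substream of the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(str(trait_id).encode())])
    )


class QTLScanModel:
    """Genome scan model for a matrix of expression traits.

    Parameters
    ----------
    traits
        An :class:`~srnaqtl.quantify.ExpressionTraitMatrix`, or a plain
        DataFrame (traits x samples) — in the latter case pass ``anchors``
        for local/distant classification.
    binmap
        Bin map whose individuals match the trait matrix columns.
    config
        :class:`ScanConfig`; defaults replicate the study design.
    """

    def __init__(self, traits, binmap: BinMap, config: ScanConfig | None = None,
                 anchors: pd.DataFrame | None = None):
        from .quantify import ExpressionTraitMatrix

        if isinstance(traits, ExpressionTraitMatrix):
            self.values = traits.values
            self.anchors = traits.anchors if anchors is None else anchors
            self.kind = traits.kind
        else:
            self.values = traits
            self.anchors = anchors
            self.kind = "custom"
        if list(self.values.columns) != list(binmap.individuals):
            raise ValueError("trait matrix columns must match bin-map individuals")
        self.binmap = binmap
        self.design = GenotypeDesign(binmap)
        self.config = config or ScanConfig()
        self._bases_cache: dict[tuple[int, ...], tuple[np.ndarray, np.ndarray]] = {}

    @classmethod
    def from_dataframe(cls, values: pd.DataFrame, binmap: BinMap,
                       anchors: pd.DataFrame | None = None,
                       config: ScanConfig | None = None) -> "QTLScanModel":
        return cls(values, binmap, config=config, anchors=anchors)

    def _bases(self, cofactors: tuple[int, ...]):
        if cofactors not in self._bases_cache:
            self._bases_cache[cofactors] = build_bases(
                self.design, cofactors, self.config.window_bp
            )
        return self._bases_cache[cofactors]

    def fit(self, seed: int | None = None, n_perm: int | None = None,
            keep_profiles: bool = True) -> "QTLScanResults":
        """Run the scan for every trait and assemble QTL records."""
        cfg = self.config
        if seed is None:
            seed = cfg.seed
        if n_perm is None:
            n_perm = cfg.n_perm
        design = self.design
        trait_ids = list(self.values.index)
        n = design.n
        profiles = np.zeros((len(trait_ids), design.n_bins))
        thresholds = np.zeros(len(trait_ids))
        pvals = np.ones(len(trait_ids))
        cofactor_sets: list[tuple[int, ...]] = []
        for t, tid in enumerate(trait_ids):
            y = self.values.loc[tid].to_numpy(dtype=float)
            rng = _trait_rng(seed, tid)
            cof = select_cofactors(y, design, cfg.max_cofactors)
            cofactor_sets.append(cof)
            bases = self._bases(cof)
            prof = scan_trait(y, design, bases=bases)
            profiles[t] = prof
            thr, p, _ = permutation_threshold(
                y, bases, n, n_perm=n_perm, alpha=cfg.alpha, rng=rng,
                observed_max=float(prof.max()),
            )
            thresholds[t] = thr
            pvals[t] = p
        pv = pd.Series(pvals, index=trait_ids, name="p_value")
        significant = fdr_across_traits(pv, cfg.q)
        records = []
        for t, tid in enumerate(trait_ids):
            if not significant.loc[tid]:
                continue
            y = self.values.loc[tid].to_numpy(dtype=float)
            rng = _trait_rng(seed ^ 0x5EED, tid)
            for peak in call_peaks(
                profiles[t], thresholds[t], design,
                cfg.peak_min_separation, cfg.valley_drop,
            ):
                records.append(
                    self._qtl_record(tid, y, profiles[t], peak, thresholds[t], rng)
                )
        columns = [
            "trait_id", "trait_chrom", "trait_pos", "chrom", "peak_bin",
            "peak_pos", "lod", "threshold", "ci_lo_bin", "ci_hi_bin",
            "ci_lo_bp", "ci_hi_bp", "r2", "a", "d", "p_dominance",
            "dominance_class", "qtl_class",
        ]
        qtl_table = pd.DataFrame(records, columns=columns)
        return QTLScanResults(
            model=self,
            lod=pd.DataFrame(profiles, index=trait_ids) if keep_profiles else None,
            thresholds=pd.Series(thresholds, index=trait_ids, name="threshold"),
            pvalues=pv,
            significant=significant,
            qtl_table=qtl_table,
            cofactors={tid: c for tid, c in zip(trait_ids, cofactor_sets)},
            seed=seed,
        )

    def _qtl_record(self, tid, y, profile, peak, threshold, rng) -> dict:
        cfg = self.config
        design = self.design
        interval = support_interval(profile, peak, design, cfg.lod_drop)
        dosage = self.binmap.genotypes[:, peak]
        r2 = variance_explained(y, dosage)
        try:
            est = eff.estimate_effects(y, dosage)
        except ValueError:  # a homozygote class absent at this bin
            est = None
        if est is not None and est.d_defined and est.n_Aa > 0:
            p_dom = eff.h_test(y, dosage, cfg.n_perm_dominance, rng)
            dom_class = eff.classify_dominance(est, p_dom < cfg.dominance_alpha)
        else:
            p_dom, dom_class = float("nan"), "none"
        if self.anchors is not None and tid in self.anchors.index:
            a_chrom = self.anchors.loc[tid, "chrom"]
            a_pos = int(self.anchors.loc[tid, "position"])
            qtl_class = classify_local_distant(
                peak, interval, a_chrom, a_pos, design, cfg.local_max_dist
            )
        else:
            a_chrom, a_pos, qtl_class = "", -1, ""
        return {
            "trait_id": tid,
            "trait_chrom": a_chrom,
            "trait_pos": a_pos,
            "chrom": design.chroms[peak],
            "peak_bin": peak,
            "peak_pos": int(design.mid[peak]),
            "lod": float(profile[peak]),
            "threshold": float(threshold),
            "ci_lo_bin": interval[0],
            "ci_hi_bin": interval[1],
            "ci_lo_bp": int(design.starts[interval[0]]),
            "ci_hi_bp": int(design.ends[interval[1]]),
            "r2": r2,
            "a": est.a if est is not None else float("nan"),
            "d": est.d if est is not None else float("nan"),
            "p_dominance": p_dom,
            "dominance_class": dom_class,
            "qtl_class": qtl_class,
        }


@dataclass
class QTLScanResults:
    """Fitted genome-scan results.

    Attributes
    ----------
    lod : DataFrame or None
        Traits x bins LOD profiles.
    thresholds, pvalues, significant : Series per trait.
    qtl_table : DataFrame
        One row per mapped QTL with peak, support interval, R^2, additive and
        dominance effects, dominance class and local/distant class.
    """

    model: QTLScanModel
    lod: pd.DataFrame | None
    thresholds: pd.Series
    pvalues: pd.Series
    significant: pd.Series
    qtl_table: pd.DataFrame
    cofactors: dict = field(default_factory=dict)
    seed: int = 0

    @property
    def n_significant_traits(self) -> int:
        return int(self.significant.sum())

    def class_counts(self) -> pd.Series:
        return self.qtl_table["qtl_class"].value_counts()

    def summary(self) -> str:
        lines = [
            "QTL genome scan results",
            "=" * 46,
            f"traits scanned:        {len(self.pvalues)}",
            f"significant traits:    {self.n_significant_traits}"
            f" (BH q = {self.model.config.q})",
            f"QTLs mapped:           {len(self.qtl_table)}",
        ]
        if len(self.qtl_table):
            counts = self.class_counts()
            for cls in ("local", "distant"):
                if cls in counts:
                    lines.append(f"  {cls + ':':<20} {counts[cls]}")
            dom = self.qtl_table["dominance_class"].value_counts()
            lines.append("dominance classes:")
            for cls, cnt in dom.items():
                lines.append(f"  {cls + ':':<20} {cnt}")
            med = self.qtl_table["lod"].median()
            lines.append(f"median peak LOD:       {med:.2f}")
        return "\n".join(lines)

    def plot_lod(self, trait_id, ax=None):
        """LOD profile along the genome for one trait."""
        import matplotlib.pyplot as plt

        if self.lod is None:
            raise ValueError("profiles were not kept")
        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        prof = self.lod.loc[trait_id].to_numpy()
        ax.plot(np.arange(len(prof)), prof, lw=1)
        ax.axhline(self.thresholds.loc[trait_id], color="r", ls="--", lw=0.8)
        ax.set_xlabel("bin index")
        ax.set_ylabel("LOD")
        ax.set_title(str(trait_id))
        return ax

    def write_qtl_table(self, path) -> None:
        self.qtl_table.to_csv(path, sep="\t", index=False, float_format="%.6g")
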