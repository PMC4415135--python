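"""Simulation studies that validate the method on the scaled study design.

Each function builds its own synthetic inputs from a seed, runs the package
end to end for one question — null calibration of the permutation scan,
planted local/distant QTL recovery, dominance testing, cluster geometry
against brute-force oracles, the correlation significance threshold — and
returns the measured quantities. The problem sizes (98 hybrids, ~190 bins,
200 permutations) mirror the scaled study design described in the docs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import clusters as cl
from . import correlate as corr
from . import effects as eff
from . import simulate as sim
from .scan import QTLScanModel, ScanConfig


def _study_scan_config(n_perm: int = 200) -> ScanConfig:
    return ScanConfig(n_perm=n_perm, n_perm_dominance=n_perm)


def null_calibration(
    seed: int, n_traits: int = 200, n_perm: int = 200
) -> dict:
    """Null traits against their own genome-wide permutation thresholds.

    Returns the fraction of traits whose max LOD exceeds their own 5%
    threshold (expected ~0.05) and the number of Benjamini-Hochberg
    discoveries at q=0.05 (expected ~0).
    """
    _, binmap = sim.scaled_imf2_population(seed=seed)
    rng = np.random.default_rng(seed + 1)
    values = pd.DataFrame(
        rng.normal(10.0, 1.0, size=(n_traits, binmap.n_individuals)),
        index=[f"null{k}" for k in range(n_traits)],
        columns=binmap.individuals,
    )
    res = QTLScanModel(values, binmap, _study_scan_config(n_perm)).fit(
        seed=seed + 2
    )
    exceed = float(
        (res.lod.max(axis=1).to_numpy() > res.thresholds.to_numpy()).mean()
    )
    return {
        "exceed_rate": exceed,
        "bh_discoveries": int(res.significant.sum()),
        "n_traits": n_traits,
        "n_bins": binmap.n_bins,
    }


def _planted_traits(binmap, rng, n_traits, local: bool, a=1.0, d=0.0):
    bins = binmap.bins
    chroms = list(pd.unique(bins["chrom"]))
    traits = []
    for k in range(n_traits):
        b = int(rng.integers(binmap.n_bins))
        if local:
            chrom = bins["chrom"].iloc[b]
            pos = int((bins["start"].iloc[b] + bins["end"].iloc[b]) // 2)
        else:
            others = [c for c in chroms if c != bins["chrom"].iloc[b]]
            chrom = others[int(rng.integers(len(others)))]
            sub = bins[bins["chrom"] == chrom]
            j = int(rng.integers(len(sub)))
            pos = int((sub["start"].iloc[j] + sub["end"].iloc[j]) // 2)
        traits.append(
            sim.TraitSpec(
                f"t{k}", chrom, pos, effects=[(b, a, d)], baseline=10.0
            )
        )
    return traits


def _fit_planted(binmap, traits, rng, seed, n_perm=200):
    arch = sim.QTLArchitecture(traits, noise="normal", residual_sd=1.0)
    values = sim.simulate_trait_matrix(arch, binmap, rng)
    anchors = pd.DataFrame(
        {
            "chrom": [t.chrom for t in traits],
            "position": [t.position for t in traits],
            "length": 24,
        },
        index=values.index,
    )
    model = QTLScanModel(
        values, binmap, _study_scan_config(n_perm), anchors=anchors
    )
    return values, model.fit(seed=seed)


def local_recovery(seed: int, n_traits: int = 100) -> dict:
    """Planted local QTLs at one residual-sd additive effect.

    Measures detection, peak placement within one bin of the planted locus
    with a local classification, and whether the additive estimate falls
    within three standard errors of the planted value.
    """
    _, binmap = sim.scaled_imf2_population(seed=seed)
    rng = np.random.default_rng(seed + 3)
    traits = _planted_traits(binmap, rng, n_traits, local=True, a=1.0)
    values, res = _fit_planted(binmap, traits, rng, seed + 4)
    planted = {t.trait_id: t.effects[0][0] for t in traits}
    qtab = res.qtl_table
    detected = 0
    within1_local = 0
    a_ok = 0
    for tid in values.index:
        sub = qtab[qtab["trait_id"] == tid]
        if not len(sub):
            continue
        detected += 1
        best = sub.sort_values("lod", ascending=False).iloc[0]
        if (
            abs(int(best["peak_bin"]) - planted[tid]) <= 1
            and best["qtl_class"] == "local"
        ):
            within1_local += 1
        g = binmap.genotypes[:, int(best["peak_bin"])]
        y = values.loc[tid].to_numpy()
        est = eff.estimate_effects(y, g)
        resid = np.concatenate(
            [y[g == k] - y[g == k].mean() for k in np.unique(g)]
        )
        s2 = resid @ resid / max(len(y) - 3, 1)
        se_a = np.sqrt(s2 * (1.0 / est.n_AA + 1.0 / est.n_aa) / 4.0)
        if abs(est.a - 1.0) <= 3.0 * se_a:
            a_ok += 1
    return {
        "detection_rate": detected / n_traits,
        "within1_local_rate": within1_local / n_traits,
        "a_within_3se_rate": a_ok / max(detected, 1),
        "n_traits": n_traits,
    }


def distant_classification(seed: int, n_traits: int = 100) -> dict:
    """Effects planted on a different chromosome from the trait anchor are
    classified distant."""
    _, binmap = sim.scaled_imf2_population(seed=seed)
    rng = np.random.default_rng(seed + 5)
    traits = _planted_traits(binmap, rng, n_traits, local=False, a=1.0)
    values, res = _fit_planted(binmap, traits, rng, seed + 6)
    qtab = res.qtl_table
    distant = 0
    detected = 0
    for tid in values.index:
        sub = qtab[qtab["trait_id"] == tid]
        if not len(sub):
            continue
        detected += 1
        best = sub.sort_values("lod", ascending=False).iloc[0]
        if best["qtl_class"] == "distant":
            distant += 1
    return {
        "distant_rate": distant / max(detected, 1),
        "detection_rate": detected / n_traits,
        "n_traits": n_traits,
    }


def dominance_study(
    seed: int,
    n_type1: int = 500,
    n_power: int = 200,
    n_perm: int = 400,
) -> dict:
    """h-test calibration and power, plus overdominance classification.

    Type-I error with planted d=0; power with d = -a at one residual-sd;
    negative-overdominance recall with the heterozygote planted below both
    homozygotes (d = -2a).
    """
    _, binmap = sim.scaled_imf2_population(seed=seed)
    rng = np.random.default_rng(seed + 7)
    g = binmap.genotypes[:, binmap.n_bins // 2]
    x = g.astype(float) - 1.0
    z = (g == 1).astype(float)

    def run_case(a, d, n_reps, classify=False):
        hits = 0
        for _ in range(n_reps):
            y = 10.0 + a * x + d * z + rng.normal(0, 1.0, len(x))
            p = eff.h_test(y, g, n_perm=n_perm,
                           seed=int(rng.integers(2**31)))
            if classify:
                est = eff.estimate_effects(y, g)
                cls = eff.classify_dominance(est, p < 0.05)
                hits += cls == "negative-overdominant"
            else:
                hits += p < 0.05
        return hits / n_reps

    return {
        "type1_rate": run_case(2.0, 0.0, n_type1),
        "power_d_minus_a": run_case(1.0, -1.0, n_power),
        "overdominant_recall": run_case(1.0, -2.0, n_power, classify=True),
        "n_type1": n_type1,
        "n_power": n_power,
    }


def _brute_islands(track, min_cov):
    out, start = [], None
    for i, v in enumerate(track):
        if v >= min_cov and start is None:
            start = i
        elif v < min_cov and start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, len(track)))
    return out


def _brute_merge(spans, max_gap):
    merged = []
    for s, e in spans:
        if merged and s - merged[-1][1] <= max_gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def cluster_oracle_study(seed: int, n_tracks: int = 100) -> dict:
    """Island and merge outputs against per-position brute-force scans on
    random coverage tracks, plus the hand-computed 2x2 size factors."""
    rng = np.random.default_rng(seed + 8)
    agree = 0
    for _ in range(n_tracks):
        track = rng.integers(0, 60, size=int(rng.integers(50, 400)))
        islands = cl.find_islands({"c": track}, 30).islands
        got = list(map(tuple, islands[["start", "end"]].to_numpy()))
        expect = _brute_islands(track, 30)
        gap = int(rng.integers(1, 50))
        merged = cl.merge_islands(
            cl.IslandSet(
                pd.DataFrame(
                    [("c", s, e) for s, e in expect],
                    columns=["chrom", "start", "end"],
                ),
                30,
            ),
            gap,
        )
        got_m = list(
            map(tuple, merged.clusters[["start", "end"]].to_numpy())
        )
        agree += (got == expect) and (got_m == _brute_merge(expect, gap))
    factors = cl.size_factors_median_of_ratios([[100, 200], [50, 100]])
    return {
        "oracle_agreement": agree / n_tracks,
        "size_factor_lib1": float(factors[0]),
        "size_factor_lib2": float(factors[1]),
        "n_tracks": n_tracks,
    }


def correlation_threshold_study(seed: int, n_sims: int = 60_000) -> dict:
    """Simulated r* against the analytic critical Pearson r."""
    r98 = corr.simulation_threshold(98, n_sims=n_sims, seed=seed + 9)
    grid = {
        n: corr.simulation_threshold(n, n_sims=n_sims // 3, seed=seed + n)
        for n in (26, 50, 98)
    }
    return {
        "r_star_n98": r98,
        "analytic_n98": corr.analytic_critical_r(98),
        "monotone": float(grid[26] > grid[50] > grid[98]),
        "n_sims": n_sims,
    }


def determinism_study(seed: int, workdir) -> dict:
    """Run the full pipeline twice with one seed; artifacts must be
    byte-identical."""
    from pathlib import Path

    from . import pipeline as pl

    dirs = []
    for name in ("run1", "run2"):
        out = Path(workdir) / name
        cfg = pl.PipelineConfig(
            outdir=str(out), seed=seed, n_chrom=2, chrom_length=8_000_000,
            genes_per_chrom=12, n_rils=12, n_imf2=30,
            recomb_rate_cm_per_mb=8.0, n_traits=25, effect_size=4.0,
            scan=_study_scan_config(100),
        )
        pl.run(cfg)
        dirs.append(out)
    files = sorted(
        p.relative_to(dirs[0])
        for p in dirs[0].rglob("*")
        if p.is_file() and not p.name.startswith(".")
    )
    identical = all(
        (dirs[0] / rel).read_bytes() == (dirs[1] / rel).read_bytes()
        for rel in files
    )
    return {"byte_identical": float(identical), "n_files": len(files)}
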