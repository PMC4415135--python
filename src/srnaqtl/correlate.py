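"""Pairwise expression correlations, simulation-based significance
thresholds, and co-regulation classification by QTL distance.

Correlation classes follow the study's dividing points: |r| >= 0.3 is a
strong (positive or negative) correlation; the p < 0.05 significance
threshold r* is the (1 - alpha) quantile of |r| between independent
standard-normal vectors of the shared sample length.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

CORRELATION_CLASSES = ("strong negative", "none", "strong positive")
COREG_CLASSES = ("shared-local", "nearby-distant", "far-distant", "mixed")


def pairwise_correlations(
    values: pd.DataFrame, grouping: pd.Series, min_samples: int = 3
) -> pd.DataFrame:
    """Pearson r for every within-group pair of traits.

    ``grouping`` maps trait id to a group key (mother gene or cluster id);
    traits with no group (NaN) are skipped, as are zero-variance vectors.
    Returns columns trait_i, trait_j, group, n, r.
    """
    rows = []
    for group, members in grouping.dropna().groupby(grouping.dropna()):
        ids = [t for t in members.index if t in values.index]
        if len(ids) < 2:
            continue
        sub = values.loc[ids].to_numpy(dtype=float)
        sd = sub.std(axis=1)
        for (i, ti), (j, tj) in combinations(enumerate(ids), 2):
            if sd[i] == 0 or sd[j] == 0:
                log.info("skipping zero-variance pair (%s, %s)", ti, tj)
                continue
            n = sub.shape[1]
            if n < min_samples:
                continue
            r = float(np.corrcoef(sub[i], sub[j])[0, 1])
            rows.append((ti, tj, group, n, r))
    return pd.DataFrame(rows, columns=["trait_i", "trait_j", "group", "n", "r"])


def cross_correlations(
    values_a: pd.DataFrame, values_b: pd.DataFrame, pairing: pd.Series
) -> pd.DataFrame:
    """Pearson r between each trait in A and its paired trait in B
    (e.g. an sRNA trait against its mother gene's e-trait)."""
    rows = []
    for tid, other in pairing.dropna().items():
        if tid not in values_a.index or other not in values_b.index:
            continue
        x = values_a.loc[tid].to_numpy(dtype=float)
        y = values_b.loc[other].to_numpy(dtype=float)
        if x.std() == 0 or y.std() == 0:
            log.info("skipping zero-variance pair (%s, %s)", tid, other)
            continue
        rows.append((tid, other, len(x), float(np.corrcoef(x, y)[0, 1])))
    return pd.DataFrame(rows, columns=["trait_i", "trait_j", "n", "r"])


def simulation_threshold(
    n_samples: int,
    n_sims: int = 100_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """r* = (1 - alpha) empirical quantile of |r| over pairs of independent
    standard-normal vectors of length ``n_samples``."""
    if n_samples < 4:
        raise ValueError("n_samples must be >= 4")
    rng = np.random.default_rng(seed)
    out = np.empty(n_sims)
    done = 0
    chunk = max(1, min(20_000, n_sims))
    while done < n_sims:
        m = min(chunk, n_sims - done)
        x = rng.standard_normal((m, n_samples))
        y = rng.standard_normal((m, n_samples))
        x = x - x.mean(axis=1, keepdims=True)
        y = y - y.mean(axis=1, keepdims=True)
        r = np.einsum("ij,ij->i", x, y) / (
            np.linalg.norm(x, axis=1) * np.linalg.norm(y, axis=1)
        )
        out[done : done + m] = np.abs(r)
        done += m
    return float(np.quantile(out, 1.0 - alpha))


def analytic_critical_r(n_samples: int, alpha: float = 0.05) -> float:
    """Closed-form two-sided critical Pearson r: t / sqrt(t^2 + df)."""
    df = n_samples - 2
    t = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(t / np.sqrt(t * t + df))


def classify_correlations(r, strong_cut: float = 0.3):
    """r >= cut -> strong positive; r <= -cut -> strong negative; else none.
    The boundary itself counts as strong."""
    r = np.asarray(r, dtype=float)
    out = np.where(
        r >= strong_cut,
        "strong positive",
        np.where(r <= -strong_cut, "strong negative", "none"),
    )
    return out if out.ndim else str(out)


def coregulation_classify(
    class_i: str,
    class_j: str,
    peak_pos_i: tuple[str, int],
    peak_pos_j: tuple[str, int],
    max_dist: int = 2_000_000,
) -> str:
    """Joint regulation pattern of two mapped traits.

    Both local -> shared-local; both distant with peaks within ``max_dist``
    on one chromosome -> nearby-distant; both distant otherwise ->
    far-distant; one of each -> mixed. Peak positions are bin midpoints.
    """
    if class_i == "local" and class_j == "local":
        return "shared-local"
    if class_i == "distant" and class_j == "distant":
        (c1, p1), (c2, p2) = peak_pos_i, peak_pos_j
        if c1 == c2 and abs(p1 - p2) <= max_dist:
            return "nearby-distant"
        return "far-distant"
    return "mixed"


def coregulation_table(
    qtl_table: pd.DataFrame,
    grouping: pd.Series,
    values: pd.DataFrame,
    max_dist: int = 2_000_000,
) -> pd.DataFrame:
    """Within-group pairs of mapped traits with correlation and joint
    regulation class. Traits with several QTLs use their highest-LOD one."""
    best = (
        qtl_table.sort_values("lod", ascending=False)
        .drop_duplicates("trait_id")
        .set_index("trait_id")
    )
    rows = []
    for group, members in grouping.dropna().groupby(grouping.dropna()):
        ids = [t for t in members.index if t in best.index and t in values.index]
        for ti, tj in combinations(ids, 2):
            qi, qj = best.loc[ti], best.loc[tj]
            cls = coregulation_classify(
                qi["qtl_class"], qj["qtl_class"],
                (qi["chrom"], qi["peak_pos"]), (qj["chrom"], qj["peak_pos"]),
                max_dist,
            )
            x = values.loc[ti].to_numpy(dtype=float)
            y = values.loc[tj].to_numpy(dtype=float)
            r = (
                float(np.corrcoef(x, y)[0, 1])
                if x.std() > 0 and y.std() > 0
                else np.nan
            )
            rows.append((ti, tj, group, cls, r))
    return pd.DataFrame(
        rows, columns=["trait_i", "trait_j", "group", "coregulation", "r"]
    )
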