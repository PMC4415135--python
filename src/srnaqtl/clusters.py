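"""sRNA island and cluster construction from pooled read coverage.

An island is a maximal run of genomic positions with pooled (all-library)
coverage of at least 30x; islands within 1000 nt of each other merge into a
cluster. Cluster counts are normalized with median-of-ratios size factors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import SRNATable


def pooled_coverage(table: SRNATable) -> dict[str, np.ndarray]:
    """Per-position coverage, read counts summed over all libraries.

    coverage(p) = sum over records overlapping p of the record's total count.
    Arrays run from position 0 to the last covered position per chromosome.
    """
    totals = table.total_per_record
    recs = table.records
    tracks: dict[str, np.ndarray] = {}
    for chrom, idx in recs.groupby("chrom", sort=True).groups.items():
        starts = recs.loc[idx, "start"].to_numpy(dtype=np.int64)
        ends = starts + recs.loc[idx, "length"].to_numpy(dtype=np.int64)
        w = totals[np.asarray(idx, dtype=np.intp)]
        diff = np.zeros(int(ends.max()) + 1, dtype=np.int64)
        np.add.at(diff, starts, w)
        np.add.at(diff, ends, -w)
        tracks[str(chrom)] = np.cumsum(diff)[:-1]
    return tracks


@dataclass
class IslandSet:
    """Disjoint, sorted islands: columns chrom, start, end (half-open)."""

    islands: pd.DataFrame
    min_coverage: int

    def __len__(self) -> int:
        return len(self.islands)


def find_islands(
    coverage: dict[str, np.ndarray], min_cov: int = 30
) -> IslandSet:
    """Maximal runs of positions with coverage >= min_cov."""
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    rows = []
    for chrom in sorted(coverage):
        track = np.asarray(coverage[chrom])
        hot = np.concatenate([[False], track >= min_cov, [False]])
        edges = np.flatnonzero(np.diff(hot.astype(np.int8)))
        for s, e in zip(edges[::2], edges[1::2]):
            rows.append((chrom, int(s), int(e)))
    return IslandSet(
        pd.DataFrame(rows, columns=["chrom", "start", "end"]), min_cov
    )


@dataclass
class ClusterSet:
    """Merged islands with ids in the ``chr03-261504-273325`` style.

    ``clusters`` columns: cluster_id, chrom, start, end, n_islands.
    ``counts``/``size_factors``/``normalized`` are attached by
    :func:`quantify_clusters` and :func:`normalize`.
    """

    clusters: pd.DataFrame
    counts: np.ndarray | None = None
    libraries: list[str] | None = None
    size_factors: np.ndarray | None = None
    normalized: pd.DataFrame | None = None

    def __len__(self) -> int:
        return len(self.clusters)


def merge_islands(islands: IslandSet, max_gap: int = 1000) -> ClusterSet:
    """Transitively join islands whose gap (next.start - prev.end) is
    <= max_gap; a cluster spans min start to max end of its members."""
    rows = []
    df = islands.islands
    for chrom, sub in df.groupby("chrom", sort=True):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if len(starts) and ((np.diff(starts) < 0).any() or (starts[1:] < ends[:-1]).any()):
            raise ValueError("islands must be sorted and disjoint")
        cur_start = cur_end = None
        n_members = 0
        for s, e in zip(starts, ends):
            if cur_start is None:
                cur_start, cur_end, n_members = s, e, 1
            elif s - cur_end <= max_gap:
                cur_end, n_members = e, n_members + 1
            else:
                rows.append((chrom, int(cur_start), int(cur_end), n_members))
                cur_start, cur_end, n_members = s, e, 1
        if cur_start is not None:
            rows.append((chrom, int(cur_start), int(cur_end), n_members))
    clusters = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_islands"])
    clusters.insert(
        0,
        "cluster_id",
        [f"{r.chrom}-{r.start}-{r.end}" for r in clusters.itertuples()],
    )
    return ClusterSet(clusters)


def quantify_clusters(table: SRNATable, clusters: ClusterSet) -> ClusterSet:
    """count(c, lib) = sum of counts of records whose 5' anchor lies in c.

    Membership is by record start (records are <= 26 nt, so the anchor
    choice is immaterial at cluster scale); records outside all clusters
    contribute nothing.
    """
    n_c = len(clusters.clusters)
    counts = np.zeros((n_c, len(table.libraries)), dtype=np.int64)
    recs = table.records
    cl = clusters.clusters
    for chrom, sub in cl.groupby("chrom", sort=False):
        mask = (recs["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        anchors = recs.loc[mask, "start"].to_numpy()
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        idx = np.searchsorted(starts, anchors, side="right") - 1
        ok = (idx >= 0) & (anchors < ends[np.clip(idx, 0, len(ends) - 1)])
        rows = sub.index.to_numpy()[idx[ok]]
        np.add.at(counts, rows, table.counts[np.flatnonzero(mask)[ok]])
    return ClusterSet(
        clusters.clusters.copy(), counts, list(table.libraries)
    )


def size_factors_median_of_ratios(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors.

    factor_j = median over rows i (with all-positive counts) of
    count(i, j) / geometric-mean over libraries of row i.
    """
    counts = np.asarray(counts, dtype=float)
    eligible = (counts > 0).all(axis=1)
    if not eligible.any():
        raise ValueError(
            "no cluster has positive counts in every library; "
            "size factors need at least one such cluster"
        )
    sub = counts[eligible]
    log_gm = np.mean(np.log(sub), axis=1)
    ratios = np.log(sub) - log_gm[:, None]
    return np.exp(np.median(ratios, axis=0))


def normalize(clusters: ClusterSet, factors: np.ndarray | None = None) -> ClusterSet:
    """Divide each library's column by its size factor."""
    if clusters.counts is None:
        raise ValueError("quantify clusters before normalizing")
    if factors is None:
        factors = size_factors_median_of_ratios(clusters.counts)
    factors = np.asarray(factors, dtype=float)
    if (factors <= 0).any():
        raise ValueError("size factors must be positive")
    normalized = pd.DataFrame(
        clusters.counts / factors[None, :],
        index=pd.Index(clusters.clusters["cluster_id"], name="trait_id"),
        columns=clusters.libraries,
    )
    return ClusterSet(
        clusters.clusters.copy(), clusters.counts, clusters.libraries,
        factors, normalized,
    )


def cluster_trait_matrix(clusters: ClusterSet):
    """Normalized cluster counts as an ExpressionTraitMatrix
    (kind ``cluster-normalized``), anchored at the cluster midpoint."""
    from .quantify import ExpressionTraitMatrix

    if clusters.normalized is None:
        raise ValueError("normalize clusters first")
    cl = clusters.clusters
    anchors = pd.DataFrame(
        {
            "chrom": cl["chrom"].to_numpy(),
            "position": ((cl["start"] + cl["end"]) // 2).to_numpy(),
            "length": (cl["end"] - cl["start"]).to_numpy(),
        },
        index=clusters.normalized.index,
    )
    return ExpressionTraitMatrix(
        "cluster-normalized", clusters.normalized, anchors
    )


def write_cluster_bed(clusters: ClusterSet, path) -> None:
    cl = clusters.clusters
    cl[["chrom", "start", "end", "cluster_id"]].to_csv(
        path, sep="\t", index=False, header=False
    )
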