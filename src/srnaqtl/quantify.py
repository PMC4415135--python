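"""Abundance normalization and expression-trait calling.

sRNA abundance is expressed in reads per million genome-mapped reads (RPM);
clusters use median-of-ratios-normalized counts; mRNA FPKM is consumed as-is.
An entity is *expressed* when its value meets the kind-specific threshold
(RPM >= 0.6, normalized >= 6, FPKM >= 1, all inclusive), and becomes an
expression trait when expressed in more than 25 of the 98 hybrids (>= 26).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeLayout
from .io import SRNATable

log = logging.getLogger(__name__)

REGION_CLASSES = (
    "exon", "intron", "UTR", "upstream-2kb", "downstream-500bp", "intergenic",
)


@dataclass
class ThresholdBundle:
    """All calling thresholds in one place (defaults are the study's)."""

    rpm_expressed: float = 0.6
    cluster_expressed: float = 6.0
    fpkm_expressed: float = 1.0
    min_expressing_samples: int = 26  # "more than 25 of the 98 IMF2s"
    island_min_coverage: int = 30
    island_merge_gap: int = 1000
    upstream_window: int = 2000
    downstream_window: int = 500

    def expressed_threshold(self, kind: str) -> float:
        return {
            "sRNA-RPM": self.rpm_expressed,
            "cluster-normalized": self.cluster_expressed,
            "mRNA-FPKM": self.fpkm_expressed,
        }[kind]


@dataclass
class ExpressionTraitMatrix:
    """Traits x samples of normalized non-negative values with genomic anchors.

    ``anchors`` (indexed by trait id) carries ``chrom``, ``position`` and
    ``length``; optional columns ``strand``, ``mother_gene`` and ``region``
    are added by annotation steps.
    """

    kind: str
    values: pd.DataFrame
    anchors: pd.DataFrame

    KINDS = ("sRNA-RPM", "cluster-normalized", "mRNA-FPKM")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown matrix kind {self.kind!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        if not self.values.index.equals(self.anchors.index):
            raise ValueError("anchors must be indexed by the trait ids")

    @property
    def n_traits(self) -> int:
        return len(self.values)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset(self, trait_ids) -> "ExpressionTraitMatrix":
        return ExpressionTraitMatrix(
            self.kind, self.values.loc[trait_ids], self.anchors.loc[trait_ids]
        )


def rpm_normalize(table: SRNATable) -> ExpressionTraitMatrix:
    """RPM(t, lib) = count(t, lib) / (library total / 1e6)."""
    totals = np.asarray(table.library_totals, dtype=float)
    zero = totals <= 0
    if zero.any():
        bad = [table.libraries[i] for i in np.flatnonzero(zero)]
        raise ValueError(f"zero genome-mapped total for libraries {bad}")
    values = pd.DataFrame(
        table.counts / (totals[None, :] / 1e6),
        index=pd.Index(table.records["srna_id"], name="trait_id"),
        columns=table.libraries,
    )
    anchors = pd.DataFrame(
        {
            "chrom": table.records["chrom"].to_numpy(),
            "position": table.records["start"].to_numpy(),
            "length": table.records["length"].to_numpy(),
            "strand": table.records["strand"].to_numpy(),
        },
        index=values.index,
    )
    return ExpressionTraitMatrix("sRNA-RPM", values, anchors)


def call_expressed(values, threshold: float) -> np.ndarray:
    """Expressed iff value >= threshold (inclusive boundary)."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    return np.asarray(values) >= threshold


def call_traits(
    matrix: ExpressionTraitMatrix,
    thresholds: ThresholdBundle | None = None,
    min_samples: int | None = None,
) -> ExpressionTraitMatrix:
    """Retain entities expressed in at least ``min_samples`` samples
    (default 26, the strict reading of "more than 25 of the 98").

    The same rule generates s-traits, sc-traits and e-traits from their
    respective matrix kinds.
    """
    thresholds = thresholds or ThresholdBundle()
    if min_samples is None:
        min_samples = thresholds.min_expressing_samples
    expressed = call_expressed(
        matrix.values.to_numpy(), thresholds.expressed_threshold(matrix.kind)
    )
    keep = expressed.sum(axis=1) >= min_samples
    out = ExpressionTraitMatrix(
        matrix.kind, matrix.values[keep], matrix.anchors[keep]
    )
    log.info(
        "call_traits(%s): %d of %d retained", matrix.kind, out.n_traits,
        matrix.n_traits,
    )
    return out


def annotate_trait_regions(
    anchors: pd.DataFrame,
    layout: GenomeLayout,
    thresholds: ThresholdBundle | None = None,
) -> pd.DataFrame:
    """Assign each anchor exactly one region class, strand-aware.

    Precedence when several genes compete: genic > upstream > downstream >
    intergenic; ties within a level break to the nearest TSS. Genic anchors
    are refined to exon / intron / UTR (exonic but outside every CDS when the
    gene has CDS annotation). Returns columns ``region`` and ``te`` (the
    TE flag of the assigned gene; False for intergenic).
    """
    thresholds = thresholds or ThresholdBundle()
    up, down = thresholds.upstream_window, thresholds.downstream_window
    chrom_lengths = dict(layout.chromosomes)
    regions: list[str] = []
    te_flags: list[bool] = []
    genes_by_chrom = {c: layout.genes_on(c) for c in layout.chrom_names}
    for trait_id, row in anchors.iterrows():
        chrom, pos = row["chrom"], int(row["position"])
        if chrom not in chrom_lengths:
            raise ValueError(f"{trait_id}: unknown chromosome {chrom}")
        if not 0 <= pos < chrom_lengths[chrom]:
            raise ValueError(f"{trait_id}: anchor beyond chromosome end")
        best: tuple[int, int, str, bool] | None = None  # (level, tss_dist, ...)
        for g in genes_by_chrom[chrom]:
            if g.start <= pos < g.end:
                level, label = 0, _genic_subclass(g, pos)
            elif _in_upstream(g, pos, up):
                level, label = 1, "upstream-2kb"
            elif _in_downstream(g, pos, down):
                level, label = 2, "downstream-500bp"
            else:
                continue
            cand = (level, abs(pos - g.tss), label, g.is_te)
            if best is None or cand[:2] < best[:2]:
                best = cand
        if best is None:
            regions.append("intergenic")
            te_flags.append(False)
        else:
            regions.append(best[2])
            te_flags.append(best[3])
    return pd.DataFrame({"region": regions, "te": te_flags}, index=anchors.index)


def _genic_subclass(g, pos: int) -> str:
    in_exon = any(s <= pos < e for s, e in g.exons)
    if not in_exon:
        return "intron"
    if g.cds and not any(s <= pos < e for s, e in g.cds):
        return "UTR"
    return "exon"


def _in_upstream(g, pos: int, window: int) -> bool:
    """Upstream = 5' of the TSS, within the window."""
    if g.strand == "+":
        return g.start - window <= pos < g.start
    return g.end <= pos < g.end + window


def _in_downstream(g, pos: int, window: int) -> bool:
    if g.strand == "+":
        return g.end <= pos < g.end + window
    return g.start - window <= pos < g.start


def assign_mother_genes(
    anchors: pd.DataFrame, layout: GenomeLayout
) -> pd.Series:
    """Mother gene of each anchor: the gene (exons + introns) whose span
    contains it, nearest TSS on ties; NaN for intergenic anchors."""
    genes_by_chrom = {c: layout.genes_on(c) for c in layout.chrom_names}
    out = []
    for _, row in anchors.iterrows():
        pos = int(row["position"])
        best = None
        for g in genes_by_chrom.get(row["chrom"], []):
            if g.start <= pos < g.end:
                cand = (abs(pos - g.tss), g.gene_id)
                if best is None or cand < best:
                    best = cand
        out.append(best[1] if best else np.nan)
    return pd.Series(out, index=anchors.index, name="mother_gene")


def size_class_summary(matrix: ExpressionTraitMatrix) -> pd.DataFrame:
    """Per-length trait counts and fractions (fractions sum to 1)."""
    lengths = matrix.anchors["length"]
    counts = lengths.value_counts().sort_index()
    return pd.DataFrame(
        {"count": counts, "fraction": counts / counts.sum()}
    ).rename_axis("length")
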