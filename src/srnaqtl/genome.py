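"""Genome layout and bin-map containers shared across the package.

Internal coordinates are 0-based half-open throughout; GFF3 (1-based closed)
is converted at the I/O boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Founder labels. The A allele is, by convention, the Zhenshan 97 allele.
FOUNDER_ZS = 0
FOUNDER_MH = 1
FOUNDER_NAMES = ("ZS", "MH")

#: Genotype string codes, indexed by A-allele dosage (0, 1, 2).
GENOTYPE_CODES = ("aa", "Aa", "AA")


@dataclass(frozen=True)
class Gene:
    """An annotated gene model.

    ``start``/``end`` delimit the transcript (0-based half-open); ``exons``
    and ``cds`` are ordered, non-overlapping interval lists within it.
    ``is_te`` marks transposable-element genes.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...] = ()
    cds: tuple[tuple[int, int], ...] = ()
    is_te: bool = False

    @property
    def tss(self) -> int:
        """Transcription start site (strand-aware)."""
        return self.start if self.strand == "+" else self.end - 1

    def validate(self, chrom_length: int) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if not (0 <= self.start < self.end <= chrom_length):
            raise ValueError(f"{self.gene_id}: interval outside chromosome")
        prev_end = -1
        for s, e in self.exons:
            if s < self.start or e > self.end or s >= e:
                raise ValueError(f"{self.gene_id}: exon outside transcript")
            if s < prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or unordered")
            prev_end = e


@dataclass
class GenomeLayout:
    """Chromosome sizes plus gene annotation."""

    chromosomes: list[tuple[str, int]]
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        lengths = dict(self.chromosomes)
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        for g in self.genes:
            if g.chrom not in lengths:
                raise ValueError(f"{g.gene_id}: unknown chromosome {g.chrom}")
            g.validate(lengths[g.chrom])

    @property
    def chrom_names(self) -> list[str]:
        return [c for c, _ in self.chromosomes]

    def chrom_length(self, name: str) -> int:
        for c, length in self.chromosomes:
            if c == name:
                return length
        raise KeyError(name)

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)

    def genes_on(self, chrom: str) -> list[Gene]:
        return [g for g in self.genes if g.chrom == chrom]


@dataclass
class BinMap:
    """Ordered genome bins with per-individual genotype dosages.

    ``bins`` has columns ``chrom``, ``start``, ``end`` (0-based half-open),
    ordered by chromosome then position. ``genotypes`` is an
    (individuals x bins) int8 array of A-allele dosages (0=aa, 1=Aa, 2=AA);
    RIL populations carry only {0, 2}.
    """

    bins: pd.DataFrame
    genotypes: np.ndarray
    individuals: list[str]

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.individuals), len(self.bins)):
            raise ValueError("genotype matrix shape mismatch")
        if not np.isin(self.genotypes, [0, 1, 2]).all():
            raise ValueError("genotype dosages must be 0, 1 or 2")

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def midpoints(self) -> np.ndarray:
        return ((self.bins["start"] + self.bins["end"]) // 2).to_numpy()

    def bin_of(self, chrom: str, pos: int) -> int:
        """Index of the bin containing ``pos`` on ``chrom``."""
        sel = self.bins["chrom"] == chrom
        if not sel.any():
            raise KeyError(f"unknown chromosome {chrom}")
        sub = self.bins[sel]
        idx = np.searchsorted(sub["start"].to_numpy(), pos, side="right") - 1
        if idx < 0 or pos >= sub["end"].iloc[idx]:
            raise ValueError(f"position {chrom}:{pos} outside all bins")
        return int(sub.index[idx])

    def genotype_strings(self) -> pd.DataFrame:
        """Genotypes as AA/Aa/aa strings (individuals x bins)."""
        codes = np.array(GENOTYPE_CODES, dtype=object)[self.genotypes]
        cols = [
            f"{r.chrom}:{r.start}-{r.end}" for r in self.bins.itertuples()
        ]
        return pd.DataFrame(codes, index=self.individuals, columns=cols)
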