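"""Synthetic immortalized-F2 (IMF2) population generator.

Simulates recombinant inbred lines (RILs) by single-seed descent from a
Zhenshan 97 x Minghui 63 cross (Haldane map function, i.e. crossovers as a
Poisson process with no interference), pairs RILs into IMF2 hybrids, derives
the bin map from the union of RIL breakpoints, and simulates sRNA counts and
mother-gene mRNA levels with planted additive/dominance QTL effects so every
downstream stage can be tested against known ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as sio
from .genome import (
    FOUNDER_MH,
    FOUNDER_ZS,
    BinMap,
    Gene,
    GenomeLayout,
)

log = logging.getLogger(__name__)

# Rice-like chromosome lengths (Mb), totalling ~373 Mb.
_RICE_CHROM_MB = (43.3, 35.9, 36.4, 35.5, 29.9, 31.2, 29.7, 28.4,
                  23.0, 23.2, 29.0, 27.5)


@dataclass
class SimConfig:
    """Study-design parameters for the simulated population.

    Defaults emulate the mapped study design: 196 RILs paired into 98
    hybrids, a ~373-Mb genome and a recombination rate calibrated so the
    RIL set carries about 1556 breakpoints, yielding about 1568 bins;
    library sizes span 14.52-27.73 million genome-mapped reads.
    """

    seed: int = 0
    n_rils: int = 196
    n_imf2: int = 98
    recomb_rate_cm_per_mb: float = 1.06
    selfing_generations: int = 8
    library_size_range: tuple[int, int] = (14_520_000, 27_730_000)
    dispersion: float = 0.2

    def __post_init__(self) -> None:
        if self.n_imf2 > self.n_rils * (self.n_rils - 1) // 2:
            raise ValueError("n_imf2 exceeds the number of distinct RIL pairs")
        if self.recomb_rate_cm_per_mb < 0:
            raise ValueError("recombination rate must be >= 0")


@dataclass
class RILGenome:
    """A fully homozygous founder mosaic.

    ``segments`` maps chromosome name to ``(boundaries, labels)``:
    boundaries is an increasing array [0, b1, ..., L] and labels gives the
    founder (FOUNDER_ZS / FOUNDER_MH) of each of the len(boundaries)-1
    segments.
    """

    segments: dict[str, tuple[np.ndarray, np.ndarray]]

    def founder_at(self, chrom: str, pos: int) -> int:
        bounds, labels = self.segments[chrom]
        i = int(np.searchsorted(bounds, pos, side="right")) - 1
        if i < 0 or i >= len(labels):
            raise ValueError(f"position {chrom}:{pos} outside chromosome")
        return int(labels[i])

    def breakpoints(self, chrom: str) -> np.ndarray:
        bounds, _ = self.segments[chrom]
        return bounds[1:-1]


def _compress(bounds: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge adjacent segments with equal labels."""
    if len(labels) == 0:
        return bounds, labels
    keep = np.ones(len(labels), dtype=bool)
    keep[1:] = labels[1:] != labels[:-1]
    new_labels = labels[keep]
    new_bounds = np.concatenate([bounds[:-1][keep], bounds[-1:]])
    return new_bounds, new_labels


def _label_at(hap: tuple[np.ndarray, np.ndarray], pos: np.ndarray) -> np.ndarray:
    bounds, labels = hap
    idx = np.searchsorted(bounds, pos, side="right") - 1
    return labels[np.clip(idx, 0, len(labels) - 1)]


def _gamete(
    hap_a: tuple[np.ndarray, np.ndarray],
    hap_b: tuple[np.ndarray, np.ndarray],
    length: int,
    rate_per_bp: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One meiotic product: crossovers are Poisson (Haldane, no interference),
    starting haplotype drawn at random."""
    n_x = rng.poisson(rate_per_bp * length)
    xovers = np.sort(rng.uniform(0, length, size=n_x)).astype(np.int64)
    xovers = np.unique(xovers[(xovers > 0) & (xovers < length)])
    start_hap = int(rng.integers(2))
    cuts = np.unique(
        np.concatenate([[0], hap_a[0], hap_b[0], xovers, [length]])
    )
    mids = (cuts[:-1] + cuts[1:]) // 2
    # Parity of crossovers left of each elementary segment picks the haplotype.
    parity = np.searchsorted(xovers, mids, side="right") % 2
    which = (start_hap + parity) % 2
    lab_a = _label_at(hap_a, mids)
    lab_b = _label_at(hap_b, mids)
    labels = np.where(which == 0, lab_a, lab_b).astype(np.int8)
    return _compress(cuts, labels)


def simulate_ril_genomes(
    layout: GenomeLayout,
    n: int,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[RILGenome]:
    """Simulate ``n`` RILs by selfing an F1 for ``config.selfing_generations``
    generations and fixing any residual heterozygous segment to a random
    founder allele (RILs are treated as fully homozygous).
    """
    if n < 2:
        raise ValueError("need at least 2 RILs")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rate_per_bp = config.recomb_rate_cm_per_mb / 100 / 1_000_000
    rils: list[RILGenome] = []
    for _ in range(n):
        segments: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, length in layout.chromosomes:
            zs = (np.array([0, length]), np.array([FOUNDER_ZS], dtype=np.int8))
            mh = (np.array([0, length]), np.array([FOUNDER_MH], dtype=np.int8))
            hap1, hap2 = zs, mh  # the F1
            for _ in range(config.selfing_generations):
                new1 = _gamete(hap1, hap2, length, rate_per_bp, rng)
                new2 = _gamete(hap1, hap2, length, rate_per_bp, rng)
                hap1, hap2 = new1, new2
            # Resolve residual heterozygosity segment-wise.
            cuts = np.unique(np.concatenate([hap1[0], hap2[0]]))
            mids = (cuts[:-1] + cuts[1:]) // 2
            l1 = _label_at(hap1, mids)
            l2 = _label_at(hap2, mids)
            labels = np.where(
                l1 == l2, l1, rng.integers(0, 2, size=len(mids))
            ).astype(np.int8)
            segments[chrom] = _compress(cuts, labels)
        rils.append(RILGenome(segments))
    return rils


@dataclass
class IMF2Population:
    """IMF2 hybrids from paired RIL crosses; A is the Zhenshan 97 allele."""

    rils: list[RILGenome]
    pairing: list[tuple[int, int]]
    layout: GenomeLayout

    def __post_init__(self) -> None:
        for i, j in self.pairing:
            if i == j:
                raise ValueError("a pair must reference two distinct RILs")
            if not (0 <= i < len(self.rils) and 0 <= j < len(self.rils)):
                raise IndexError("pair references a missing RIL")

    @property
    def individuals(self) -> list[str]:
        return [f"IMF2_{k:03d}" for k in range(len(self.pairing))]

    def genotype(self, individual: int, chrom: str, pos: int) -> str:
        """Genotype code AA/Aa/aa at a genomic position."""
        i, j = self.pairing[individual]
        dosage = int(self.rils[i].founder_at(chrom, pos) == FOUNDER_ZS) + int(
            self.rils[j].founder_at(chrom, pos) == FOUNDER_ZS
        )
        return ("aa", "Aa", "AA")[dosage]


def pair_rils_to_imf2(
    rils: list[RILGenome],
    pairing: list[tuple[int, int]],
    layout: GenomeLayout,
) -> IMF2Population:
    return IMF2Population(rils, pairing, layout)


def random_pairing(
    n_rils: int, n_imf2: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Draw crosses without replacement.

    With enough RILs each line enters at most one cross (the real study's
    paired-cross design); smaller panels reuse RILs but never repeat a pair.
    """
    if 2 * n_imf2 <= n_rils:
        order = rng.permutation(n_rils)
        return [(int(order[2 * k]), int(order[2 * k + 1])) for k in range(n_imf2)]
    from itertools import combinations

    all_pairs = list(combinations(range(n_rils), 2))
    if n_imf2 > len(all_pairs):
        raise ValueError("n_imf2 exceeds the number of distinct RIL pairs")
    idx = rng.choice(len(all_pairs), size=n_imf2, replace=False)
    return [all_pairs[i] for i in idx]


def derive_bin_map(rils: list[RILGenome], layout: GenomeLayout) -> BinMap:
    """Bins are the intervals between the union of all RIL breakpoints;
    within a bin every RIL (hence every IMF2) has a constant genotype.

    Returns a BinMap over the RILs themselves with dosages in {0, 2}.
    """
    if not rils:
        raise ValueError("need at least one RIL")
    rows = []
    dosage_cols = []
    for chrom, length in layout.chromosomes:
        cuts = np.unique(
            np.concatenate(
                [[0], [length]] + [r.breakpoints(chrom) for r in rils]
            )
        )
        starts, ends = cuts[:-1], cuts[1:]
        mids = (starts + ends) // 2
        for s, e in zip(starts, ends):
            rows.append((chrom, int(s), int(e)))
        chrom_dosages = np.stack(
            [
                2 * (_label_at(r.segments[chrom], mids) == FOUNDER_ZS)
                for r in rils
            ]
        ).astype(np.int8)
        dosage_cols.append(chrom_dosages)
    bins = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    genotypes = np.concatenate(dosage_cols, axis=1)
    individuals = [f"RIL_{k:03d}" for k in range(len(rils))]
    return BinMap(bins, genotypes, individuals)


def imf2_bin_genotypes(ril_map: BinMap, population: IMF2Population) -> BinMap:
    """IMF2 dosages per bin from the parental RIL dosages."""
    alleles = (ril_map.genotypes // 2).astype(np.int8)  # {0,1} A alleles
    geno = np.stack(
        [alleles[i] + alleles[j] for i, j in population.pairing]
    ).astype(np.int8)
    return BinMap(ril_map.bins.copy(), geno, population.individuals)


# ---------------------------------------------------------------------------
# Expression simulation


@dataclass
class TraitSpec:
    """One planted expression trait.

    ``effects`` lists (bin_index, additive a, dominance d); the expected
    value for individual i is ``baseline + sum(a*x_i + d*z_i)`` with
    x in {-1, 0, +1} for {aa, Aa, AA} and z = 1 iff Aa, on the RPM scale.
    """

    trait_id: str
    chrom: str
    position: int
    effects: list[tuple[int, float, float]] = field(default_factory=list)
    baseline: float = 10.0
    length: int = 24
    strand: str = "+"
    mother_gene: str | None = None
    coupling: float = 0.0


@dataclass
class QTLArchitecture:
    """Ground truth for the simulator: planted traits plus the noise model.

    ``noise`` is ``"negbin"`` (counts with variance m + dispersion*m^2),
    ``"normal"`` (Gaussian on the expression scale, sd ``residual_sd``) or
    ``"none"`` (deterministic expected counts).
    """

    traits: list[TraitSpec]
    noise: str = "negbin"
    dispersion: float = 0.2
    residual_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.noise not in ("negbin", "normal", "none"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if self.noise == "negbin" and self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")

    def validate_against(self, binmap: BinMap) -> None:
        for t in self.traits:
            for b, _, _ in t.effects:
                if not 0 <= b < binmap.n_bins:
                    raise ValueError(
                        f"{t.trait_id}: effect locus {b} not in bin map"
                    )


def genetic_values(arch: QTLArchitecture, binmap: BinMap) -> pd.DataFrame:
    """Expected trait values (traits x individuals) before noise."""
    x = binmap.genotypes.astype(float) - 1.0
    z = (binmap.genotypes == 1).astype(float)
    rows = {}
    for t in arch.traits:
        mu = np.full(binmap.n_individuals, t.baseline)
        for b, a, d in t.effects:
            mu = mu + a * x[:, b] + d * z[:, b]
        rows[t.trait_id] = mu
    df = pd.DataFrame.from_dict(rows, orient="index", columns=binmap.individuals)
    if (df.to_numpy() < 0).any():
        log.warning("negative expected expression clipped at 0")
        df = df.clip(lower=0.0)
    return df


def simulate_trait_matrix(
    arch: QTLArchitecture,
    binmap: BinMap,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Continuous trait values (genetic value + Gaussian residual), the
    direct input for scan calibration studies."""
    mu = genetic_values(arch, binmap)
    if arch.noise == "normal":
        mu = mu + rng.normal(0.0, arch.residual_sd, size=mu.shape)
    return mu


def simulate_expression(
    arch: QTLArchitecture,
    binmap: BinMap,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[sio.SRNATable, pd.DataFrame, np.ndarray]:
    """Simulate the full observable bundle: an sRNA count table, a
    mother-gene FPKM matrix and library totals.

    Expected counts are the genetic value (RPM scale) times library depth;
    the count noise model is set by ``arch.noise``. Mother-gene FPKM tracks
    its sRNAs' genetic value through each trait's ``coupling`` coefficient.
    """
    arch.validate_against(binmap)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_lib = binmap.n_individuals
    lo, hi = config.library_size_range
    totals = rng.integers(lo, hi + 1, size=n_lib)
    mu = genetic_values(arch, binmap)  # traits x individuals, RPM scale
    depth = totals / 1e6
    expected = mu.to_numpy() * depth[None, :]
    if arch.noise == "negbin":
        alpha = arch.dispersion
        m = np.maximum(expected, 1e-12)
        counts = rng.negative_binomial(1.0 / alpha, 1.0 / (1.0 + alpha * m))
    elif arch.noise == "normal":
        vals = expected + rng.normal(
            0.0, arch.residual_sd, size=expected.shape
        ) * depth[None, :]
        counts = np.rint(np.clip(vals, 0, None)).astype(np.int64)
    else:  # "none"
        counts = np.rint(expected).astype(np.int64)
    records = pd.DataFrame(
        {
            "srna_id": [t.trait_id for t in arch.traits],
            "chrom": [t.chrom for t in arch.traits],
            "start": [t.position for t in arch.traits],
            "strand": [t.strand for t in arch.traits],
            "length": [t.length for t in arch.traits],
            "category": "shared",
        }
    )
    table = sio.SRNATable(
        records, counts.astype(np.int64), list(binmap.individuals), totals
    )
    # Mother-gene mRNA levels with configurable coupling to their sRNAs.
    gene_rows: dict[str, np.ndarray] = {}
    for t in arch.traits:
        if t.mother_gene is None:
            continue
        base = gene_rows.get(t.mother_gene)
        signal = t.coupling * (mu.loc[t.trait_id].to_numpy() - t.baseline)
        if base is None:
            gene_rows[t.mother_gene] = 20.0 + signal
        else:
            gene_rows[t.mother_gene] = base + signal
    if gene_rows:
        fpkm = pd.DataFrame.from_dict(
            gene_rows, orient="index", columns=binmap.individuals
        )
        fpkm = (fpkm + rng.normal(0.0, 1.0, size=fpkm.shape)).clip(lower=0.0)
    else:
        fpkm = pd.DataFrame(columns=binmap.individuals, dtype=float)
    return table, fpkm, totals


# ---------------------------------------------------------------------------
# Layout helpers and fixture bundle


def rice_like_layout(genes_per_chrom: int = 40, seed: int = 0) -> GenomeLayout:
    """A 12-chromosome, ~373-Mb layout with randomly placed gene models."""
    chroms = [
        (f"chr{i + 1:02d}", int(mb * 1e6)) for i, mb in enumerate(_RICE_CHROM_MB)
    ]
    return _with_random_genes(GenomeLayout(chroms), genes_per_chrom, seed)


def toy_layout(
    n_chrom: int = 3,
    chrom_length: int = 20_000_000,
    genes_per_chrom: int = 25,
    seed: int = 0,
) -> GenomeLayout:
    """A scaled-down layout for tests and demonstrations."""
    chroms = [(f"chr{i + 1:02d}", chrom_length) for i in range(n_chrom)]
    return _with_random_genes(GenomeLayout(chroms), genes_per_chrom, seed)


def _with_random_genes(
    layout: GenomeLayout, genes_per_chrom: int, seed: int
) -> GenomeLayout:
    rng = np.random.default_rng(seed)
    genes = []
    for chrom, length in layout.chromosomes:
        starts = np.sort(
            rng.choice(length - 30_000, size=genes_per_chrom, replace=False)
        )
        for k, s in enumerate(starts):
            s = int(s)
            glen = int(rng.integers(2_000, 8_000))
            e = min(s + glen, length)
            mid = s + (e - s) // 2
            exons = ((s, mid - 200), (mid + 200, e)) if e - s > 1_000 else ((s, e),)
            cds = tuple((max(a, s + 100), min(b, e - 100)) for a, b in exons)
            cds = tuple((a, b) for a, b in cds if a < b)
            genes.append(
                Gene(
                    gene_id=f"{chrom}g{k:04d}",
                    chrom=chrom,
                    strand="+" if rng.integers(2) == 0 else "-",
                    start=s,
                    end=e,
                    exons=exons,
                    cds=cds,
                    is_te=bool(rng.random() < 0.2),
                )
            )
    return GenomeLayout(layout.chromosomes, genes)


def scaled_imf2_population(
    seed: int,
    n_rils: int = 16,
    n_imf2: int = 98,
    n_chrom: int = 3,
    chrom_length: int = 20_000_000,
    recomb_rate_cm_per_mb: float = 10.4,
    genes_per_chrom: int = 25,
) -> tuple[GenomeLayout, BinMap]:
    """The package's scaled-down IMF2 study design: ~200 bins over a 60-Mb
    genome, 98 hybrids as distinct pairs drawn from a compact RIL panel.

    A small panel reuses each RIL in ~12 crosses, so every bin boundary is
    informative in ~12 hybrids — the resolution the planted-QTL recovery
    studies need (with 196 RILs each used once, a boundary recombines in
    only one hybrid and peak positions diffuse).
    """
    layout = toy_layout(n_chrom, chrom_length, genes_per_chrom, seed=seed)
    cfg = SimConfig(
        seed=seed, n_rils=n_rils, n_imf2=n_imf2,
        recomb_rate_cm_per_mb=recomb_rate_cm_per_mb,
    )
    rng = np.random.default_rng(seed)
    rils = simulate_ril_genomes(layout, n_rils, cfg, rng)
    pop = pair_rils_to_imf2(
        rils, random_pairing(n_rils, n_imf2, rng), layout
    )
    binmap = imf2_bin_genotypes(derive_bin_map(rils, layout), pop)
    return layout, binmap


def architecture_to_dict(arch: QTLArchitecture) -> dict:
    return {
        "noise": arch.noise,
        "dispersion": arch.dispersion,
        "residual_sd": arch.residual_sd,
        "traits": [
            {
                "trait_id": t.trait_id,
                "chrom": t.chrom,
                "position": t.position,
                "length": t.length,
                "strand": t.strand,
                "baseline": t.baseline,
                "mother_gene": t.mother_gene,
                "coupling": t.coupling,
                "effects": [list(e) for e in t.effects],
            }
            for t in arch.traits
        ],
    }


def architecture_from_dict(d: dict) -> QTLArchitecture:
    traits = [
        TraitSpec(
            trait_id=t["trait_id"],
            chrom=t["chrom"],
            position=t["position"],
            effects=[tuple(e) for e in t["effects"]],
            baseline=t["baseline"],
            length=t["length"],
            strand=t["strand"],
            mother_gene=t["mother_gene"],
            coupling=t["coupling"],
        )
        for t in d["traits"]
    ]
    return QTLArchitecture(
        traits, noise=d["noise"], dispersion=d["dispersion"],
        residual_sd=d["residual_sd"],
    )


def write_fixture_bundle(
    directory,
    layout: GenomeLayout,
    binmap: BinMap,
    table: sio.SRNATable,
    fpkm: pd.DataFrame,
    arch: QTLArchitecture,
) -> dict[str, str]:
    """Emit the complete simulated data set; every file round-trips through
    the io module."""
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": d / "genotypes.tsv",
        "srna_table": d / "srna_table.tsv",
        "library_totals": d / "library_totals.tsv",
        "fpkm": d / "fpkm.tsv",
        "annotation": d / "annotation.gff3",
        "ground_truth": d / "ground_truth.json",
    }
    sio.write_genotype_matrix(binmap, paths["genotypes"])
    sio.write_srna_table(table, paths["srna_table"], paths["library_totals"])
    sio.write_matrix(fpkm, paths["fpkm"])
    sio.write_gff3(layout, paths["annotation"])
    sio.write_json(architecture_to_dict(arch), paths["ground_truth"])
    return {k: str(v) for k, v in paths.items()}
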