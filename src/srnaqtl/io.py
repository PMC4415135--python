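"""Readers and writers for the on-disk formats, SNP-replaced genome
construction, and allelic read-count bookkeeping.

Formats: genotype TSV (individuals x bins, AA/Aa/aa), sRNA table TSV with a
library-totals sidecar, BED (0-based half-open) for sRNA positions, GFF3
(converted to/from 1-based closed at this boundary), FASTA via Biopython,
FPKM TSV, JSON ground truth, YAML configs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import BinMap, Gene, GenomeLayout

log = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")

#: Read-origin categories: identical between parents, SNP-bearing,
#: or mapped to only one parental genome.
CATEGORIES = ("shared", "snp", "zs_only", "mh_only")


# ---------------------------------------------------------------------------
# SNP table and SNP-replaced genomes


@dataclass
class SNPTable:
    """Parental SNPs: (chrom, 1-based pos, reference base, ZS base, MH base)."""

    records: pd.DataFrame

    COLUMNS = ("chrom", "pos", "ref", "zs", "mh")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.records.columns)
        if missing:
            raise ValueError(f"SNP table missing columns {sorted(missing)}")
        for col in ("ref", "zs", "mh"):
            bad = ~self.records[col].isin(VALID_BASES)
            if bad.any():
                raise ValueError(f"invalid base in column {col!r}")
        if self.records.duplicated(["chrom", "pos"]).any():
            raise ValueError("duplicate (chrom, pos) in SNP table")

    def __len__(self) -> int:
        return len(self.records)


def read_snp_table(path: str | Path) -> SNPTable:
    return SNPTable(pd.read_csv(path, sep="\t"))


def write_snp_table(table: SNPTable, path: str | Path) -> None:
    table.records.to_csv(path, sep="\t", index=False)


def build_snp_replaced_genome(
    reference: dict[str, str], snps: SNPTable, parent: str
) -> dict[str, str]:
    """Substitute parental bases into the reference at every SNP site.

    ``parent`` is ``"ZS"`` or ``"MH"``. The reference base at each site must
    match the table (hard error naming the site otherwise); output sequences
    have the same lengths as the reference.
    """
    col = {"ZS": "zs", "MH": "mh"}.get(parent.upper())
    if col is None:
        raise ValueError(f"parent must be ZS or MH, got {parent!r}")
    out = {name: list(seq) for name, seq in reference.items()}
    for rec in snps.records.itertuples():
        if rec.chrom not in out:
            raise ValueError(f"SNP on unknown chromosome {rec.chrom}")
        seq = out[rec.chrom]
        i = rec.pos - 1  # 1-based -> 0-based
        if not 0 <= i < len(seq):
            raise ValueError(f"SNP position out of range: {rec.chrom}:{rec.pos}")
        if seq[i].upper() != rec.ref:
            raise ValueError(
                f"reference mismatch at {rec.chrom}:{rec.pos}: "
                f"expected {rec.ref}, found {seq[i]}"
            )
        seq[i] = getattr(rec, col)
    return {name: "".join(seq) for name, seq in out.items()}


def read_fasta(path: str | Path) -> dict[str, str]:
    return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# sRNA table


@dataclass
class SRNATable:
    """Position-resolved sRNA records with per-library counts.

    ``records`` columns: ``srna_id``, ``chrom``, ``start`` (0-based),
    ``strand``, ``length`` (nt), ``category`` (one of :data:`CATEGORIES`) and
    optionally ``sequence``. ``counts`` is (records x libraries) of
    non-negative integers; ``library_totals`` holds total genome-mapped reads
    per library (may exceed the column sums of retained records).
    """

    records: pd.DataFrame
    counts: np.ndarray
    libraries: list[str]
    library_totals: np.ndarray

    REQUIRED = ("srna_id", "chrom", "start", "strand", "length", "category")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.records.columns)
        if missing:
            raise ValueError(f"sRNA table missing columns {sorted(missing)}")
        self.counts = np.asarray(self.counts)
        self.library_totals = np.asarray(self.library_totals, dtype=np.int64)
        if self.counts.shape != (len(self.records), len(self.libraries)):
            raise ValueError("count matrix shape mismatch")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be integers")
        bad = ~self.records["category"].isin(CATEGORIES)
        if bad.any():
            raise ValueError("unknown sRNA origin category")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def total_per_record(self) -> np.ndarray:
        """Counts summed over all libraries, one value per record."""
        return self.counts.sum(axis=1)

    def subset(self, mask: np.ndarray) -> "SRNATable":
        return SRNATable(
            self.records[mask].reset_index(drop=True),
            self.counts[np.asarray(mask)],
            list(self.libraries),
            self.library_totals.copy(),
        )


def filter_srna_records(
    table: SRNATable,
    min_len: int = 18,
    max_len: int = 26,
    blocklist: set[str] | frozenset[str] = frozenset(),
) -> SRNATable:
    """Keep records with min_len <= length <= max_len whose sequence is not
    on the blocklist (a stand-in for tRNA/rRNA/snRNA/snoRNA removal).

    Record order is preserved; counts are untouched.
    """
    if min_len > max_len:
        raise ValueError("min_len > max_len")
    lengths = table.records["length"].to_numpy()
    keep = (lengths >= min_len) & (lengths <= max_len)
    if blocklist and "sequence" in table.records.columns:
        keep &= ~table.records["sequence"].isin(blocklist).to_numpy()
    elif blocklist:
        raise ValueError("blocklist filtering requires a 'sequence' column")
    out = table.subset(keep)
    log.info("filter_srna_records: %d -> %d records", len(table), len(out))
    if len(out) == 0:
        log.warning("all sRNA records removed by filtering")
    return out


def merge_allelic_counts(zs_count, mh_count, category: str):
    """Combine allele-specific counts into one abundance per locus.

    SNP-bearing loci sum the two allele counts ("put together"); shared loci
    carry a single indistinguishable count (passed as ``zs_count``, with
    ``mh_count`` ignored unless contradictory); parent-specific loci take
    that parent's count only.
    """
    zs = np.asarray(zs_count)
    mh = np.asarray(mh_count)
    if (zs < 0).any() or (mh < 0).any():
        raise ValueError("negative count")
    if category == "snp":
        return zs + mh
    if category == "shared":
        return zs
    if category == "zs_only":
        if (mh > 0).any():
            raise ValueError("ZS-only locus has Minghui 63 counts")
        return zs
    if category == "mh_only":
        if (zs > 0).any():
            raise ValueError("MH-only locus has Zhenshan 97 counts")
        return mh
    raise ValueError(f"unknown category {category!r}")


def write_srna_table(table: SRNATable, path: str | Path, totals_path: str | Path) -> None:
    counts = pd.DataFrame(table.counts, columns=table.libraries)
    pd.concat([table.records.reset_index(drop=True), counts], axis=1).to_csv(
        path, sep="\t", index=False
    )
    pd.DataFrame(
        {"library": table.libraries, "total_reads": table.library_totals}
    ).to_csv(totals_path, sep="\t", index=False)


def read_srna_table(path: str | Path, totals_path: str | Path) -> SRNATable:
    df = pd.read_csv(path, sep="\t")
    totals = pd.read_csv(totals_path, sep="\t")
    meta_cols = [c for c in df.columns if c in SRNATable.REQUIRED + ("sequence",)]
    libraries = [c for c in df.columns if c not in meta_cols]
    if list(totals["library"]) != libraries:
        raise ValueError("library totals do not match count columns")
    return SRNATable(
        df[meta_cols],
        df[libraries].to_numpy(dtype=np.int64),
        libraries,
        totals["total_reads"].to_numpy(),
    )


def write_srna_bed(table: SRNATable, path: str | Path) -> None:
    """Emit sRNA positions as BED4 (0-based half-open)."""
    recs = table.records
    bed = pd.DataFrame(
        {
            "chrom": recs["chrom"],
            "start": recs["start"],
            "end": recs["start"] + recs["length"],
            "name": recs["srna_id"],
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# Genotype matrix


def write_genotype_matrix(binmap: BinMap, path: str | Path) -> None:
    df = binmap.genotype_strings()
    df.index.name = "individual"
    df.to_csv(path, sep="\t")


def read_genotype_matrix(path: str | Path) -> BinMap:
    df = pd.read_csv(path, sep="\t", index_col=0)
    bins = []
    for col in df.columns:
        chrom, span = col.rsplit(":", 1)
        start, end = span.split("-")
        bins.append((chrom, int(start), int(end)))
    bins_df = pd.DataFrame(bins, columns=["chrom", "start", "end"])
    code = {"aa": 0, "Aa": 1, "AA": 2}
    try:
        geno = df.apply(lambda col: col.map(code)).to_numpy(dtype=np.int8)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid genotype code in {path}") from exc
    if np.isnan(geno.astype(float)).any():
        raise ValueError(f"invalid genotype code in {path}")
    return BinMap(bins_df, geno, list(df.index))


# ---------------------------------------------------------------------------
# Expression matrices (FPKM and normalized values)


def write_matrix(values: pd.DataFrame, path: str | Path) -> None:
    values.to_csv(path, sep="\t", index_label="trait_id")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="trait_id")


# ---------------------------------------------------------------------------
# GFF3 for gene annotation

_GFF_COLS = (
    "seqid source type start end score strand phase attributes".split()
)


def write_gff3(layout: GenomeLayout, path: str | Path) -> None:
    """Write the layout's gene models as GFF3 (1-based closed)."""
    lines = ["##gff-version 3"]
    for chrom, length in layout.chromosomes:
        lines.append(f"##sequence-region {chrom} 1 {length}")
    for g in layout.genes:
        attrs = f"ID={g.gene_id};is_te={'true' if g.is_te else 'false'}"
        lines.append(
            "\t".join(
                [g.chrom, "srnaqtl", "gene", str(g.start + 1), str(g.end),
                 ".", g.strand, ".", attrs]
            )
        )
        for kind, ivals in (("exon", g.exons), ("CDS", g.cds)):
            for i, (s, e) in enumerate(ivals, 1):
                lines.append(
                    "\t".join(
                        [g.chrom, "srnaqtl", kind, str(s + 1), str(e), ".",
                         g.strand, "." if kind == "exon" else "0",
                         f"ID={g.gene_id}.{kind}{i};Parent={g.gene_id}"]
                    )
                )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path) -> GenomeLayout:
    chromosomes: list[tuple[str, int]] = []
    genes: dict[str, dict] = {}
    for raw in Path(path).read_text().splitlines():
        if raw.startswith("##sequence-region"):
            _, chrom, _start, end = raw.split()
            chromosomes.append((chrom, int(end)))
            continue
        if not raw or raw.startswith("#"):
            continue
        fields = raw.split("\t")
        if len(fields) != 9:
            raise ValueError(f"malformed GFF3 line: {raw!r}")
        rec = dict(zip(_GFF_COLS, fields))
        attrs = dict(
            kv.split("=", 1) for kv in rec["attributes"].split(";") if "=" in kv
        )
        start, end = int(rec["start"]) - 1, int(rec["end"])  # to half-open
        if rec["type"] == "gene":
            genes[attrs["ID"]] = {
                "chrom": rec["seqid"], "strand": rec["strand"],
                "start": start, "end": end,
                "is_te": attrs.get("is_te", "false") == "true",
                "exons": [], "cds": [],
            }
        elif rec["type"] in ("exon", "CDS"):
            parent = attrs["Parent"]
            key = "exons" if rec["type"] == "exon" else "cds"
            genes[parent][key].append((start, end))
    gene_objs = [
        Gene(
            gene_id=gid, chrom=g["chrom"], strand=g["strand"],
            start=g["start"], end=g["end"],
            exons=tuple(sorted(g["exons"])), cds=tuple(sorted(g["cds"])),
            is_te=g["is_te"],
        )
        for gid, g in genes.items()
    ]
    return GenomeLayout(chromosomes, gene_objs)


# ---------------------------------------------------------------------------
# JSON / YAML helpers


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def read_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def write_yaml(obj: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))
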