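"""End-to-end orchestration: simulate (or ingest) -> quantify -> cluster ->
scan (with genetic effects) -> hotspots -> correlations -> report.

All randomness flows from a single master seed; rerunning with the same
configuration produces byte-identical artifacts. The simulate stage caches
its fixture bundle keyed by a configuration hash; downstream stages are
cheap at the sizes used and always recompute.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clusters as cl
from . import correlate as corr
from . import hotspots as hs
from . import io as sio
from . import quantify as qt
from . import simulate as sim
from .scan import QTLScanModel, ScanConfig

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one run needs; loadable from YAML via :meth:`from_yaml`."""

    outdir: str = "srnaqtl_out"
    seed: int = 0
    # simulate stage (ignored when input paths are given)
    n_chrom: int = 3
    chrom_length: int = 20_000_000
    genes_per_chrom: int = 25
    n_rils: int = 16
    n_imf2: int = 98
    recomb_rate_cm_per_mb: float = 10.4
    n_traits: int = 60
    frac_with_qtl: float = 0.5
    effect_size: float = 8.0
    dominance_effect: float = -2.0
    baseline: float = 10.0
    dispersion: float = 0.2
    # input paths (enable ingest instead of simulation)
    genotypes: str | None = None
    srna_table: str | None = None
    library_totals: str | None = None
    fpkm: str | None = None
    annotation: str | None = None
    # thresholds and scan settings
    thresholds: qt.ThresholdBundle = field(default_factory=qt.ThresholdBundle)
    scan: ScanConfig = field(default_factory=ScanConfig)
    # stage toggles
    run_cluster: bool = True
    run_scan: bool = True
    run_hotspots: bool = True
    run_correlate: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = sio.read_yaml(path) or {}
        thr = qt.ThresholdBundle(**raw.pop("thresholds", {}))
        scan_raw = raw.pop("scan", {})
        scan = ScanConfig(**scan_raw)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(thresholds=thr, scan=scan, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def content_hash(self) -> str:
        d = self.to_dict()
        d.pop("outdir", None)  # content is path-independent
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _build_architecture(
    cfg: PipelineConfig, layout, binmap, rng: np.random.Generator
) -> sim.QTLArchitecture:
    """Plant a mix of local and distant QTL effects on random traits."""
    bins = binmap.bins
    traits = []
    gene_pool = layout.genes
    for k in range(cfg.n_traits):
        b = int(rng.integers(binmap.n_bins))
        chrom = bins["chrom"].iloc[b]
        pos = int(rng.integers(bins["start"].iloc[b], bins["end"].iloc[b]))
        effects = []
        if rng.random() < cfg.frac_with_qtl:
            if rng.random() < 0.5:  # local: effect at the trait's own bin
                eb = b
            else:  # distant: anywhere else
                eb = int(rng.integers(binmap.n_bins - 1))
                if eb >= b:
                    eb += 1
            effects = [(eb, cfg.effect_size, cfg.dominance_effect)]
        gene = None
        for g in layout.genes_on(chrom):
            if g.start <= pos < g.end:
                gene = g.gene_id
                break
        if gene is None and gene_pool:
            gene = gene_pool[int(rng.integers(len(gene_pool)))].gene_id
        traits.append(
            sim.TraitSpec(
                trait_id=f"srna_{k:04d}",
                chrom=chrom,
                position=pos,
                effects=effects,
                baseline=cfg.baseline,
                mother_gene=gene,
                coupling=float(rng.random() < 0.5),
            )
        )
    return sim.QTLArchitecture(traits, noise="negbin", dispersion=cfg.dispersion)


def _simulate_stage(cfg: PipelineConfig, outdir: Path):
    fixture_dir = outdir / "fixture"
    hash_file = fixture_dir / ".config_hash"
    want = cfg.content_hash()
    if hash_file.exists() and hash_file.read_text() == want:
        log.info("simulate: reusing cached fixture bundle")
        layout = sio.read_gff3(fixture_dir / "annotation.gff3")
        binmap = sio.read_genotype_matrix(fixture_dir / "genotypes.tsv")
        table = sio.read_srna_table(
            fixture_dir / "srna_table.tsv", fixture_dir / "library_totals.tsv"
        )
        fpkm = sio.read_matrix(fixture_dir / "fpkm.tsv")
        arch = sim.architecture_from_dict(
            sio.read_json(fixture_dir / "ground_truth.json")
        )
        return layout, binmap, table, fpkm, arch
    rng = np.random.default_rng(cfg.seed)
    layout = sim.toy_layout(
        cfg.n_chrom, cfg.chrom_length, cfg.genes_per_chrom, seed=cfg.seed
    )
    simcfg = sim.SimConfig(
        seed=cfg.seed,
        n_rils=cfg.n_rils,
        n_imf2=cfg.n_imf2,
        recomb_rate_cm_per_mb=cfg.recomb_rate_cm_per_mb,
        dispersion=cfg.dispersion,
    )
    rils = sim.simulate_ril_genomes(layout, cfg.n_rils, simcfg, rng)
    pairing = sim.random_pairing(cfg.n_rils, cfg.n_imf2, rng)
    pop = sim.pair_rils_to_imf2(rils, pairing, layout)
    ril_map = sim.derive_bin_map(rils, layout)
    binmap = sim.imf2_bin_genotypes(ril_map, pop)
    arch = _build_architecture(cfg, layout, binmap, rng)
    table, fpkm, _ = sim.simulate_expression(arch, binmap, simcfg, rng)
    sim.write_fixture_bundle(fixture_dir, layout, binmap, table, fpkm, arch)
    hash_file.write_text(want)
    log.info(
        "simulate: %d RILs, %d IMF2s, %d bins, %d sRNA records",
        cfg.n_rils, cfg.n_imf2, binmap.n_bins, len(table),
    )
    return layout, binmap, table, fpkm, arch


def _ingest_stage(cfg: PipelineConfig):
    layout = sio.read_gff3(cfg.annotation)
    binmap = sio.read_genotype_matrix(cfg.genotypes)
    table = sio.read_srna_table(cfg.srna_table, cfg.library_totals)
    fpkm = sio.read_matrix(cfg.fpkm) if cfg.fpkm else pd.DataFrame()
    return layout, binmap, table, fpkm, None


def run(cfg: PipelineConfig) -> dict:
    """Run all enabled stages; returns a dict of result objects and writes
    TSV artifacts under ``cfg.outdir``."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    ingest = cfg.genotypes is not None
    layout, binmap, table, fpkm, arch = (
        _ingest_stage(cfg) if ingest else _simulate_stage(cfg, outdir)
    )
    results.update(layout=layout, binmap=binmap, srna_table=table, arch=arch)

    # quantify: s-traits and e-traits
    table = sio.filter_srna_records(table)
    rpm = qt.rpm_normalize(table)
    straits = qt.call_traits(rpm, cfg.thresholds)
    region = qt.annotate_trait_regions(straits.anchors, layout, cfg.thresholds)
    straits.anchors = straits.anchors.join(region)
    straits.anchors["mother_gene"] = qt.assign_mother_genes(
        straits.anchors, layout
    )
    sio.write_matrix(straits.values, outdir / "s_traits.tsv")
    straits.anchors.to_csv(outdir / "s_trait_anchors.tsv", sep="\t")
    log.info("quantify: %d sRNA records -> %d s-traits", len(table),
             straits.n_traits)
    results["straits"] = straits

    etraits = None
    if len(fpkm):
        gene_pos = {
            g.gene_id: (g.chrom, (g.start + g.end) // 2, g.end - g.start)
            for g in layout.genes
        }
        keep = [g for g in fpkm.index if g in gene_pos]
        anchors = pd.DataFrame(
            [gene_pos[g] for g in keep],
            index=pd.Index(keep, name="trait_id"),
            columns=["chrom", "position", "length"],
        )
        emat = qt.ExpressionTraitMatrix(
            "mRNA-FPKM", fpkm.loc[keep].clip(lower=0.0), anchors
        )
        etraits = qt.call_traits(emat, cfg.thresholds)
        sio.write_matrix(etraits.values, outdir / "e_traits.tsv")
        log.info("quantify: %d mRNAs -> %d e-traits", len(fpkm),
                 etraits.n_traits)
        results["etraits"] = etraits

    # clusters -> sc-traits
    sctraits = None
    if cfg.run_cluster:
        coverage = cl.pooled_coverage(table)
        islands = cl.find_islands(coverage, cfg.thresholds.island_min_coverage)
        clusters = cl.merge_islands(islands, cfg.thresholds.island_merge_gap)
        clusters = cl.quantify_clusters(table, clusters)
        log.info("cluster: %d islands -> %d clusters", len(islands),
                 len(clusters))
        if len(clusters):
            try:
                clusters = cl.normalize(clusters)
                scmat = cl.cluster_trait_matrix(clusters)
                sctraits = qt.call_traits(scmat, cfg.thresholds)
                sio.write_matrix(sctraits.values, outdir / "sc_traits.tsv")
                log.info("cluster: %d sc-traits", sctraits.n_traits)
            except ValueError as exc:
                log.warning("cluster normalization skipped: %s", exc)
        cl.write_cluster_bed(clusters, outdir / "clusters.bed")
        results["clusters"] = clusters
        results["sctraits"] = sctraits

    # genome scans (effects and dominance are part of the fit)
    if cfg.run_scan:
        for name, mat in (
            ("s", straits), ("sc", sctraits), ("e", etraits)
        ):
            if mat is None or mat.n_traits == 0:
                continue
            model = QTLScanModel(mat, binmap, cfg.scan)
            res = model.fit(seed=cfg.seed)
            res.write_qtl_table(outdir / f"{name}_qtl_table.tsv")
            log.info(
                "scan(%s-traits): %d traits, %d significant, %d QTLs",
                name, mat.n_traits, res.n_significant_traits,
                len(res.qtl_table),
            )
            results[f"{name}_scan"] = res

    # hotspots
    if cfg.run_hotspots and cfg.run_scan and "s_scan" in results:
        trait_track = hs.call_hotspots(
            hs.density_per_bin(straits.anchors, binmap),
            hs.MULTIPLIERS["trait"],
        )
        hs.hotspot_report(trait_track).to_csv(
            outdir / "s_trait_hotspots.tsv", sep="\t", index=False
        )
        results["trait_hotspots"] = trait_track
        qtab = results["s_scan"].qtl_table
        if len(qtab):
            qtl_anchors = pd.DataFrame(
                {"chrom": qtab["chrom"], "position": qtab["peak_pos"]}
            )
            qtl_track = hs.call_hotspots(
                hs.density_per_bin(qtl_anchors, binmap), hs.MULTIPLIERS["qtl"]
            )
            hs.hotspot_report(qtl_track).to_csv(
                outdir / "sqtl_hotspots.tsv", sep="\t", index=False
            )
            results["qtl_hotspots"] = qtl_track

    # correlations
    if cfg.run_correlate:
        pairs = corr.pairwise_correlations(
            straits.values, straits.anchors["mother_gene"]
        )
        rstar = corr.simulation_threshold(
            straits.n_samples, n_sims=20_000, seed=cfg.seed
        )
        if len(pairs):
            pairs["class"] = corr.classify_correlations(pairs["r"].to_numpy())
        pairs.to_csv(outdir / "same_gene_correlations.tsv", sep="\t",
                     index=False, float_format="%.6g")
        sio.write_json({"r_star": rstar, "n": straits.n_samples},
                       outdir / "correlation_threshold.json")
        results["correlations"] = pairs
        results["r_star"] = rstar

    report(results, outdir)
    return results


def report(results: dict, outdir: Path) -> pd.DataFrame:
    """Machine-readable run summary (counts of traits, QTLs by class,
    hotspot tallies)."""
    rows = []

    def add(k, v):
        rows.append({"quantity": k, "value": v})

    straits = results.get("straits")
    if straits is not None:
        add("s_traits", straits.n_traits)
    if results.get("sctraits") is not None:
        add("sc_traits", results["sctraits"].n_traits)
    if results.get("etraits") is not None:
        add("e_traits", results["etraits"].n_traits)
    for name in ("s", "sc", "e"):
        res = results.get(f"{name}_scan")
        if res is None:
            continue
        add(f"{name}_qtls", len(res.qtl_table))
        counts = res.class_counts()
        add(f"local_{name}_qtls", int(counts.get("local", 0)))
        add(f"distant_{name}_qtls", int(counts.get("distant", 0)))
    for key in ("trait_hotspots", "qtl_hotspots"):
        if key in results:
            add(key, int(results[key].flags.sum()))
    if "correlations" in results and len(results["correlations"]):
        add("strong_correlations",
            int((results["correlations"]["r"].abs() >= 0.3).sum()))
    df = pd.DataFrame(rows, columns=["quantity", "value"])
    df.to_csv(Path(outdir) / "summary.tsv", sep="\t", index=False)
    return df
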