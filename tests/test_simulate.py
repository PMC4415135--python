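"""The synthetic population: homozygosity, Mendelian frequencies, bin
constancy and ground-truth effect recovery."""

import numpy as np
import pandas as pd
import pytest

from srnaqtl import simulate as sim
from srnaqtl.genome import FOUNDER_ZS, GenomeLayout


def test_zero_length_chromosome_rejected():
    with pytest.raises(ValueError, match="non-positive length"):
        GenomeLayout([("chr01", 0)])


def test_rils_fully_homozygous_and_tile_chromosomes(small_population,
                                                    small_layout):
    for ril in small_population["rils"]:
        for chrom, length in small_layout.chromosomes:
            bounds, labels = ril.segments[chrom]
            assert bounds[0] == 0 and bounds[-1] == length
            assert np.all(np.diff(bounds) > 0)
            # one founder label per segment, adjacent labels alternate
            assert set(np.unique(labels)) <= {0, 1}
            assert np.all(labels[1:] != labels[:-1])


def test_zero_recombination_gives_single_founder_per_chromosome():
    layout = sim.toy_layout(n_chrom=2, chrom_length=1_000_000,
                            genes_per_chrom=0, seed=0)
    cfg = sim.SimConfig(seed=3, n_rils=10, n_imf2=5,
                        recomb_rate_cm_per_mb=0.0)
    rils = sim.simulate_ril_genomes(layout, 10, cfg)
    for ril in rils:
        for chrom, _ in layout.chromosomes:
            _, labels = ril.segments[chrom]
            assert len(labels) == 1


def test_founder_allele_frequency_half():
    """Mendelian expectation: ZS fraction 0.50 +/- 0.05 over 1000 RILs."""
    layout = sim.toy_layout(n_chrom=1, chrom_length=5_000_000,
                            genes_per_chrom=0, seed=0)
    cfg = sim.SimConfig(seed=17, n_rils=1000, n_imf2=2,
                        recomb_rate_cm_per_mb=4.0)
    rils = sim.simulate_ril_genomes(layout, 1000, cfg)
    for pos in (0, 2_500_000, 4_999_999):
        frac = np.mean(
            [r.founder_at("chr01", pos) == FOUNDER_ZS for r in rils]
        )
        assert abs(frac - 0.5) <= 0.05


def test_determinism_same_seed_same_breakpoints(small_layout):
    cfg = sim.SimConfig(seed=9, n_rils=6, n_imf2=3,
                        recomb_rate_cm_per_mb=6.0)
    a = sim.simulate_ril_genomes(small_layout, 6, cfg)
    b = sim.simulate_ril_genomes(small_layout, 6, cfg)
    for ra, rb in zip(a, b):
        for chrom in ra.segments:
            assert np.array_equal(ra.segments[chrom][0], rb.segments[chrom][0])
            assert np.array_equal(ra.segments[chrom][1], rb.segments[chrom][1])


def test_imf2_genotype_definition(small_population):
    """AA iff both parental RILs carry ZS; aa iff both MH; Aa otherwise."""
    pop = small_population["pop"]
    rils = small_population["rils"]
    for ind in (0, 7, 23):
        i, j = pop.pairing[ind]
        for chrom, pos in (("chr01", 123_456), ("chr02", 6_543_210)):
            zs_count = int(rils[i].founder_at(chrom, pos) == FOUNDER_ZS) + int(
                rils[j].founder_at(chrom, pos) == FOUNDER_ZS
            )
            assert pop.genotype(ind, chrom, pos) == ("aa", "Aa", "AA")[zs_count]


def test_pairing_validation(small_population, small_layout):
    rils = small_population["rils"]
    with pytest.raises(ValueError):
        sim.pair_rils_to_imf2(rils, [(3, 3)], small_layout)
    with pytest.raises(IndexError):
        sim.pair_rils_to_imf2(rils, [(0, 99)], small_layout)


def test_imf2_genotype_frequencies_quarter_half_quarter():
    """Independent RIL allele draws give (0.25, 0.50, 0.25) +/- 0.07."""
    layout = sim.toy_layout(n_chrom=1, chrom_length=4_000_000,
                            genes_per_chrom=0, seed=0)
    cfg = sim.SimConfig(seed=23, n_rils=196, n_imf2=98,
                        recomb_rate_cm_per_mb=4.0)
    rng = np.random.default_rng(23)
    rils = sim.simulate_ril_genomes(layout, 196, cfg, rng)
    pop = sim.pair_rils_to_imf2(rils, sim.random_pairing(196, 98, rng), layout)
    binmap = sim.imf2_bin_genotypes(sim.derive_bin_map(rils, layout), pop)
    freqs = np.stack(
        [(binmap.genotypes == k).mean(axis=0) for k in (2, 1, 0)]
    ).mean(axis=1)
    assert np.allclose(freqs, [0.25, 0.5, 0.25], atol=0.07)


def test_bin_map_tiles_and_single_breakpoint_case(small_population,
                                                  small_layout):
    bins = small_population["ril_map"].bins
    for chrom, length in small_layout.chromosomes:
        sub = bins[bins["chrom"] == chrom]
        assert sub["start"].iloc[0] == 0
        assert sub["end"].iloc[-1] == length
        assert (sub["start"].iloc[1:].to_numpy()
                == sub["end"].iloc[:-1].to_numpy()).all()


def test_no_ril_label_change_inside_any_bin(small_population):
    """Brute-force: RIL founder labels are constant within every bin."""
    rils = small_population["rils"]
    ril_map = small_population["ril_map"]
    rng = np.random.default_rng(0)
    for _, row in ril_map.bins.iterrows():
        probes = rng.integers(row["start"], row["end"], size=5)
        for r in rils[::3]:
            labels = {r.founder_at(row["chrom"], int(p)) for p in probes}
            assert len(labels) == 1


def test_planted_effects_reproduced_exactly_without_noise(small_population):
    """a=3, d=0 gives means (13, 10, 7); d=-4 puts Aa below both."""
    binmap = small_population["binmap"]
    b = binmap.n_bins // 2
    arch = sim.QTLArchitecture(
        [
            sim.TraitSpec("t_add", "chr01", 1000, effects=[(b, 3.0, 0.0)]),
            sim.TraitSpec("t_od", "chr01", 2000, effects=[(b, 3.0, -4.0)]),
        ],
        noise="none",
    )
    mu = sim.genetic_values(arch, binmap)
    g = binmap.genotypes[:, b]
    row = mu.loc["t_add"].to_numpy()
    for k, expect in ((2, 13.0), (1, 10.0), (0, 7.0)):
        assert np.allclose(row[g == k], expect)
    row = mu.loc["t_od"].to_numpy()
    assert np.allclose(row[g == 1], 6.0)
    assert row[g == 1].mean() < min(row[g == 2].mean(), row[g == 0].mean())


def test_null_architecture_is_null(small_population):
    """With no effects, genotype explains nothing (ANOVA n.s. for >=95%)."""
    from scipy import stats

    binmap = small_population["binmap"]
    rng = np.random.default_rng(31)
    arch = sim.QTLArchitecture(
        [sim.TraitSpec(f"n{k}", "chr01", 1000) for k in range(100)],
        noise="normal", residual_sd=1.0,
    )
    Y = sim.simulate_trait_matrix(arch, binmap, rng)
    b = binmap.n_bins // 3
    g = binmap.genotypes[:, b]
    n_sig = 0
    for k in range(100):
        y = Y.iloc[k].to_numpy()
        groups = [y[g == c] for c in np.unique(g)]
        _, p = stats.f_oneway(*groups)
        n_sig += p < 0.01
    assert n_sig <= 5


def test_simulated_counts_regress_back_to_planted_effects(study_population):
    """Regressing traits on true genotype codes recovers (a, d) within
    3 standard errors for 95% of traits."""
    _, binmap = study_population
    rng = np.random.default_rng(41)
    n_traits = 200
    b = int(binmap.n_bins * 0.6)
    arch = sim.QTLArchitecture(
        [
            sim.TraitSpec(f"t{k}", "chr01", 1000, effects=[(b, 1.0, -0.5)])
            for k in range(n_traits)
        ],
        noise="normal", residual_sd=1.0,
    )
    Y = sim.simulate_trait_matrix(arch, binmap, rng)
    g = binmap.genotypes[:, b]
    x = g.astype(float) - 1.0
    z = (g == 1).astype(float)
    X = np.column_stack([np.ones_like(x), x, z])
    XtX_inv = np.linalg.inv(X.T @ X)
    ok = 0
    for k in range(n_traits):
        y = Y.iloc[k].to_numpy()
        beta = XtX_inv @ (X.T @ y)
        resid = y - X @ beta
        s2 = resid @ resid / (len(y) - 3)
        se = np.sqrt(np.diag(XtX_inv) * s2)
        ok += (abs(beta[1] - 1.0) <= 3 * se[1]) and (
            abs(beta[2] + 0.5) <= 3 * se[2]
        )
    assert ok / n_traits >= 0.95


def test_library_totals_match_column_sums_in_none_mode(small_population):
    binmap = small_population["binmap"]
    cfg = small_population["config"]
    arch = sim.QTLArchitecture(
        [sim.TraitSpec("t0", "chr01", 500)], noise="none"
    )
    table, _, totals = sim.simulate_expression(arch, binmap, cfg)
    assert np.array_equal(table.library_totals, totals)
    assert (table.counts.sum(axis=0) <= totals).all()


def test_fixture_bundle_round_trip(tmp_path, small_population, small_layout):
    from srnaqtl import io as sio

    binmap = small_population["binmap"]
    cfg = small_population["config"]
    arch = sim.QTLArchitecture(
        [sim.TraitSpec("t0", "chr01", 500, effects=[(1, 2.0, -1.0)],
                       mother_gene="chr01g0001", coupling=0.5)],
        noise="negbin", dispersion=0.2,
    )
    table, fpkm, _ = sim.simulate_expression(arch, binmap, cfg)
    paths = sim.write_fixture_bundle(
        tmp_path / "fx", small_layout, binmap, table, fpkm, arch
    )
    binmap2 = sio.read_genotype_matrix(paths["genotypes"])
    assert np.array_equal(binmap2.genotypes, binmap.genotypes)
    pd.testing.assert_frame_equal(binmap2.bins, binmap.bins)
    table2 = sio.read_srna_table(paths["srna_table"], paths["library_totals"])
    assert np.array_equal(table2.counts, table.counts)
    layout2 = sio.read_gff3(paths["annotation"])
    assert layout2.chromosomes == small_layout.chromosomes
    assert len(layout2.genes) == len(small_layout.genes)
    arch2 = sim.architecture_from_dict(sio.read_json(paths["ground_truth"]))
    assert [t.trait_id for t in arch2.traits] == ["t0"]
    assert arch2.traits[0].effects == [(1, 2.0, -1.0)]


def test_fixture_bundle_byte_identical_across_runs(tmp_path, small_population,
                                                   small_layout):
    binmap = small_population["binmap"]
    cfg = small_population["config"]
    arch = sim.QTLArchitecture([sim.TraitSpec("t0", "chr01", 500)])
    outs = []
    for name in ("a", "b"):
        rng = np.random.default_rng(77)
        table, fpkm, _ = sim.simulate_expression(arch, binmap, cfg, rng)
        paths = sim.write_fixture_bundle(
            tmp_path / name, small_layout, binmap, table, fpkm, arch
        )
        outs.append(paths)
    for key in outs[0]:
        a = open(outs[0][key], "rb").read()
        b = open(outs[1][key], "rb").read()
        assert a == b, key
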