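import numpy as np
import pandas as pd
import pytest

from srnaqtl import simulate as sim
from srnaqtl.io import SRNATable


@pytest.fixture(scope="session")
def small_layout():
    return sim.toy_layout(n_chrom=2, chrom_length=8_000_000,
                          genes_per_chrom=10, seed=5)


@pytest.fixture(scope="session")
def small_population(small_layout):
    """A compact IMF2 population: 12 RILs, 40 hybrids, ~40 bins."""
    cfg = sim.SimConfig(seed=5, n_rils=12, n_imf2=40,
                        recomb_rate_cm_per_mb=8.0)
    rng = np.random.default_rng(5)
    rils = sim.simulate_ril_genomes(small_layout, 12, cfg, rng)
    pairing = sim.random_pairing(12, 40, rng)
    pop = sim.pair_rils_to_imf2(rils, pairing, small_layout)
    ril_map = sim.derive_bin_map(rils, small_layout)
    binmap = sim.imf2_bin_genotypes(ril_map, pop)
    return {"rils": rils, "pop": pop, "ril_map": ril_map, "binmap": binmap,
            "config": cfg}


@pytest.fixture(scope="session")
def study_population():
    """The scaled study design used by the recovery and calibration tests."""
    layout, binmap = sim.scaled_imf2_population(seed=11)
    return layout, binmap


def make_srna_table(records, counts, libraries=None, totals=None):
    counts = np.asarray(counts, dtype=np.int64)
    if libraries is None:
        libraries = [f"lib{j}" for j in range(counts.shape[1])]
    if totals is None:
        totals = np.maximum(counts.sum(axis=0), 1) * 10
    df = pd.DataFrame(records)
    if "srna_id" not in df:
        df["srna_id"] = [f"s{i}" for i in range(len(df))]
    for col, default in (("strand", "+"), ("category", "shared")):
        if col not in df:
            df[col] = default
    return SRNATable(df, counts, list(libraries), np.asarray(totals))


@pytest.fixture
def tiny_table():
    """Four sRNA records on two chromosomes, two libraries."""
    records = {
        "chrom": ["chr01", "chr01", "chr01", "chr02"],
        "start": [100, 110, 5000, 200],
        "length": [21, 24, 24, 22],
    }
    counts = [[5, 3], [2, 0], [7, 7], [1, 4]]
    return make_srna_table(records, counts)
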