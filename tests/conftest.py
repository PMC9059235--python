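import numpy as np
import pytest

from amprep import (
    AbundanceTable,
    MetadataTable,
    SampleRecord,
    SimulationConfig,
    simulate_study,
)


def make_meta(records):
    return MetadataTable(records)


def milk_record(sample_id, protocol="P3", prototype="SCC-cfu-", erep=1, srep=1,
                run="V1V2", phase="main"):
    return SampleRecord(
        sample_id=sample_id,
        material="milk",
        protocol=protocol,
        prototype=prototype,
        extraction_rep=erep,
        sequencing_rep=srep,
        primer_run=run,
        phase=phase,
    )


def water_record(sample_id, protocol="P3", erep=1, srep=1, run="V1V2", phase="main"):
    return SampleRecord(
        sample_id=sample_id,
        material="water",
        protocol=protocol,
        extraction_rep=erep,
        sequencing_rep=srep,
        primer_run=run,
        phase=phase,
    )


@pytest.fixture
def mixed_table():
    """3 milk + 2 water columns with one water-only ASV and one single hit."""
    asvs = ["A1", "A2", "A3", "A4", "A5"]
    samples = ["m1", "m2", "m3", "w1", "w2"]
    counts = np.array(
        [
            [600, 550, 700, 0, 0],    # milk-only, everywhere
            [100, 200, 150, 10, 0],   # milk + water
            [0, 0, 0, 50, 30],        # water-only
            [0, 7, 0, 0, 0],          # single hit (milk)
            [300, 250, 260, 0, 5],    # milk + water
        ]
    )
    table = AbundanceTable(asvs, samples, counts)
    meta = make_meta(
        [milk_record("m1", erep=1), milk_record("m2", erep=2), milk_record("m3", erep=3)]
        + [water_record("w1", erep=1), water_record("w2", erep=2)]
    )
    return table, meta


@pytest.fixture(scope="session")
def sim_pretrial():
    return simulate_study(SimulationConfig(phase="pretrial", seed=7))


@pytest.fixture(scope="session")
def sim_main():
    return simulate_study(SimulationConfig(phase="main", seed=7))


@pytest.fixture(scope="session")
def recovery_config():
    """Config for which chance singletons/water-only ASVs are (near-)impossible,
    so planted-contaminant and planted-singleton recovery is exact."""
    return SimulationConfig(
        phase="main",
        seed=11,
        n_asvs=30,
        base_alpha=5.0,
        depth_median={"P3": 5000, "P4": 5000, "P6": 5000},
        depth_sigma=0.2,
        sigma_ext=0.1,
        epsilon=0.0,
        n_foreign=0,
        n_singletons=5,
        include_controls=False,
    )


@pytest.fixture(scope="session")
def recovery_sim(recovery_config):
    return simulate_study(recovery_config)
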