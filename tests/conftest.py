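import pandas as pd
import pytest

from methylome.io_formats import CX_COLUMNS, GenomeSequence, SampleMethylome
from methylome.synthetic_data import (
    SimulationConfig,
    plant_dmrs,
    simulate_counts,
    simulate_genome,
    simulate_true_methylome,
)


def make_methylome(rows, sample_id="S"):
    """Build a SampleMethylome from (chrom, pos, strand, meth, unmeth, context, tri) tuples."""
    df = pd.DataFrame(rows, columns=CX_COLUMNS)
    return SampleMethylome(sample_id, df)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        seed=11, chrom_lengths=(60_000,), lambda_length=12_000,
        n_dmrs=4, dmr_length=1500,
    )


@pytest.fixture(scope="session")
def small_genome(small_config):
    return simulate_genome(small_config)


@pytest.fixture(scope="session")
def small_truth(small_genome, small_config):
    return simulate_true_methylome(small_genome, small_config)


@pytest.fixture(scope="session")
def small_planted(small_truth, small_config, small_genome):
    return plant_dmrs(small_truth, small_config, genome=small_genome)


@pytest.fixture(scope="session")
def small_samples(small_truth, small_planted, small_config):
    ctrl = simulate_counts(small_truth, small_config, "DMSO")
    treat = simulate_counts(small_planted, small_config, "AZD")
    return {"DMSO": ctrl, "AZD": treat}
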