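import pytest

from svarbiter.regions import sample_random_regions_loguniform
from svarbiter.simulate import (
    LongReadModel,
    PairedReadModel,
    SimulationConfig,
    make_fixture_suite,
)

SUITE_SEED = 7

SUITE_CONFIG = SimulationConfig(
    seed=SUITE_SEED,
    genome_length=80_000,
    n_hom_del=4,
    n_het_del=4,
    n_insertion=2,
)

SUITE_MODELS = (
    PairedReadModel(name="ill100", read_length=100, insert_mean=300, insert_sd=30, depth=30),
    PairedReadModel(name="ill250", read_length=250, insert_mean=800, insert_sd=80, depth=20),
    LongReadModel(name="pac", read_min=1000, read_max=4000, depth=12),
)


@pytest.fixture(scope="session")
def suite(tmp_path_factory):
    """One small simulated input bundle shared across the whole run."""
    out = tmp_path_factory.mktemp("fixture_suite")
    return make_fixture_suite(SUITE_SEED, str(out), SUITE_CONFIG, SUITE_MODELS)


@pytest.fixture(scope="session")
def random_calls(suite):
    """Random non-SV regions sampled away from the planted truth."""
    layout = suite.genome.layout(exclude_truth_pad=1000)
    return sample_random_regions_loguniform(layout, 60, 50, 2000, seed=11)
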