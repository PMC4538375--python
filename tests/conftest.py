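import pytest

from dsxscan.pipeline import RunConfig, analyze
from dsxscan.synthetic_data import (
    default_config,
    generate_dataset,
    load_od1_seed,
    load_od2_seed,
)

DATASET_SEED = 1


@pytest.fixture(scope="session")
def od1_seed():
    return load_od1_seed()


@pytest.fixture(scope="session")
def od2_seed():
    return load_od2_seed()


@pytest.fixture(scope="session")
def dataset():
    """The default twelve-taxon synthetic dataset with its truth manifest."""
    return generate_dataset(default_config(DATASET_SEED))


@pytest.fixture(scope="session")
def analysis(dataset, od1_seed, od2_seed):
    """Full pipeline run (scan + classify + aggregate) over the default dataset."""
    return analyze(dataset.contigs, od1_seed, od2_seed, RunConfig())
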