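import numpy as np
import pytest

from chimeraseq.synthetic_data import FixtureConfig, generate_fixture

DEFAULT_SEED = 1234


@pytest.fixture(scope="session")
def default_fixture():
    """Full-conditions fixture: 30x, 0.5% error, 30% fusion fraction."""
    return generate_fixture(FixtureConfig(seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def clean_fixture():
    """Noiseless, lighter-coverage fixture for exact truth-table oracles."""
    cfg = FixtureConfig(
        seed=77, coverage=8.0, error_rate=0.0, contaminant_fraction=0.0
    )
    return generate_fixture(cfg)


@pytest.fixture(scope="session")
def junction_library_552(default_fixture):
    """All exon-boundary junctions of the fixture genes, both orientations."""
    from chimeraseq.annotation import enumerate_junction_library

    bundle, _ = default_fixture
    return enumerate_junction_library(
        bundle.donor_model,
        bundle.acceptor_model,
        bundle.reference_sequences,
        flank=bundle.config.read_length - 1,
    )
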