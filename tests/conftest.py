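import numpy as np
import pytest

from calvesig import BinnedSeries, SyntheticSpec, generate, generate_components
from calvesig.synthetic import bin_grid


@pytest.fixture(scope="session")
def default_spec():
    return SyntheticSpec()


@pytest.fixture(scope="session")
def noiseless_spec():
    return SyntheticSpec(noise_sd=0.0, beat_jitter_sd=0.0, artifact_fraction=0.0)


@pytest.fixture(scope="session")
def default_record(default_spec):
    """One full synthetic recording at the shipped defaults (reused: ~1 s)."""
    return generate(default_spec)


@pytest.fixture(scope="session")
def noiseless_binned(noiseless_spec):
    trend, seasonal, remainder = generate_components(noiseless_spec)
    return BinnedSeries(bin_grid(noiseless_spec), trend + seasonal + remainder)


def make_binned(values, bin_width=0.5):
    values = np.asarray(values, dtype=float)
    return BinnedSeries(np.arange(values.size) * bin_width, values, bin_width)
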