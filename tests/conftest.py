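import numpy as np
import pytest

from dcfba.strainmodel import builtin_network
from dcfba.synthetic import GeneratorConfig, default_envelope, generate_timeseries


@pytest.fixture(scope="session")
def pe():
    """Calibrated fixture production envelope."""
    return default_envelope()


@pytest.fixture(scope="session")
def net():
    """Built-in minimal strain network."""
    return builtin_network()


@pytest.fixture(scope="session")
def clean_series(pe):
    """Noise-free synthetic time series with the default stage schedule."""
    return generate_timeseries(pe, GeneratorConfig(noise_cv=0.0))


@pytest.fixture(scope="session")
def noisy_series(pe):
    """2% multiplicative-noise series, fixed seed, half-hour sampling."""
    cfg = GeneratorConfig(noise_cv=0.02, seed=7)
    return generate_timeseries(pe, cfg)


def assert_close(a, b, rel=0.0, abs_=0.0, msg=""):
    a, b = float(a), float(b)
    tol = abs_ + rel * max(abs(a), abs(b))
    assert abs(a - b) <= tol, f"{msg}: {a} vs {b} (tol {tol})"
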