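"""Shared fixtures: the calibrated baseline and fast solver settings."""

import numpy as np
import pytest

from ampkmtor import baseline_parameters


@pytest.fixture(scope="session")
def baseline():
    return baseline_parameters()


@pytest.fixture(scope="session")
def fast_solve():
    """Reduced-precision solver settings for tests that only need structure."""
    return dict(rtol=1e-6, atol=1e-8, conservation_check=False)
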