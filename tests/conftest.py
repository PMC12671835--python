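import numpy as np
import pytest

from fpfdist import FPFParams, Sample, SupportBounds, rvs_inverse


@pytest.fixture
def unit_params():
    """lam = 1 on the unit interval."""
    return FPFParams(1.0, 1.0, SupportBounds(0.0, 1.0))


@pytest.fixture
def ten_params():
    """lam = 0.5 on (0, 10)."""
    return FPFParams(0.5, 1.0, SupportBounds(0.0, 10.0))


def make_sample(lam: float, n: int, seed: int, bounds: SupportBounds | None = None) -> Sample:
    bd = bounds or SupportBounds(0.0, 1.0)
    draw = rvs_inverse(n, FPFParams.from_lam(lam, bd), seed)
    return Sample(draw.values, bd, "explicit")


@pytest.fixture
def sample_lam1():
    return make_sample(1.0, 500, seed=42)
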