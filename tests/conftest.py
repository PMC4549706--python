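import numpy as np
import pytest

from inhibkit.models import ProgressCurve
from inhibkit.simulate import (
    AZ_DBH2_DESIGN,
    AZ_DBH2_TRUTH,
    HIT_CYTC_DESIGN,
    HIT_CYTC_TRUTH,
    LEAD_CYTC_SLOW_DESIGN,
    LEAD_CYTC_SLOW_TRUTH,
    LEAD_DBH2_SLOW_DESIGN,
    LEAD_DBH2_SLOW_TRUTH,
    GeneratorSpec,
    generate_progress_curves,
    generate_rate_table,
)


@pytest.fixture
def az_competitive_table():
    """Noiseless competitive initial-rate grid at the DBH2/azoxystrobin design."""
    spec = GeneratorSpec("fast-competitive", AZ_DBH2_TRUTH, AZ_DBH2_DESIGN,
                         "proportional", 0.0, 0)
    return generate_rate_table(spec)[0]


@pytest.fixture
def hit_noncompetitive_table():
    """Noiseless noncompetitive grid at the cytochrome c/hit-compound design."""
    spec = GeneratorSpec("fast-noncompetitive", HIT_CYTC_TRUTH, HIT_CYTC_DESIGN,
                         "proportional", 0.0, 0)
    return generate_rate_table(spec)[0]


def make_noisy_curve(v0, vs, kobs, sigma=0.02, duration=600.0, n=60, seed=0,
                     S=6e-5, I=2e-8):
    """One synthetic slow-binding trace with additive noise (sigma x final signal)."""
    from inhibkit.models import slow_binding_progress

    t = np.linspace(0.0, duration, n)
    y = slow_binding_progress(t, v0, vs, kobs)
    rng = np.random.default_rng(seed)
    y = y + rng.normal(0.0, sigma * abs(y[-1]), size=n)
    return ProgressCurve(times=t, signal=y, S=S, I=I)
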