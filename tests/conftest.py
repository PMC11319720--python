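import math

import numpy as np
import pytest

from peristalsis_mhd import DimensionlessParams

# The documented default configuration used across examples and studies.
DEFAULTS = DimensionlessParams()
F_DEFAULT = -0.4
F_TRAP = -0.1  # trapping-window flow rate used by the bolus studies


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


def draw_params(rng, fd_safe: bool = False) -> DimensionlessParams:
    """One random valid parameter set.

    ``fd_safe`` restricts to moderate Hartmann/Jeffrey numbers so that the
    solution's fourth derivative stays small enough for second-order finite
    differences at n ~ 4000 to resolve it to ~1e-7; the wide ranges exercise
    the overflow-safe closed-form evaluation instead.
    """
    if fd_safe:
        p = dict(
            eps=rng.uniform(0.1, 0.6),
            M=rng.uniform(0.3, 1.8),
            beta=rng.uniform(-1.2, 1.2),
            alpha=rng.uniform(0.0, math.pi / 2),
            lambda1=rng.uniform(0.0, 1.0),
            Br=rng.uniform(0.5, 2.5),
            eta=rng.uniform(0.05, 0.8),
            c1=rng.uniform(0.0, 2.0),
            c2=rng.uniform(0.0, 2.0),
        )
        margin = 2.5
    else:
        p = dict(
            eps=rng.uniform(0.0, 0.85),
            M=rng.uniform(0.05, 12.0),
            beta=rng.uniform(-1.4, 1.4),
            alpha=rng.uniform(0.0, math.pi / 2),
            lambda1=rng.uniform(0.0, 3.0),
            Br=rng.uniform(0.2, 3.0),
            eta=rng.uniform(1e-6, 1.0),
            c1=rng.uniform(0.0, 3.0),
            c2=rng.uniform(0.0, 3.0),
        )
        margin = 2.9
    # Keep clear of the temperature resonance Br*(1+eps)*sqrt(eta) = pi.
    cap = (margin / (p["Br"] * (1.0 + p["eps"]))) ** 2
    p["eta"] = min(p["eta"], cap)
    return DimensionlessParams(**p)
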