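import numpy as np
import pytest

from repliptr.distributions import DistributionSpec, ParameterSet
from repliptr.model import CoverageTrack
from repliptr.simulate import generate_coverage

#: one representative in-bounds concentration per family
FAMILY_CONC = {
    "von_mises": 0.7,
    "cardioid": 0.3,
    "wrapped_cauchy": 0.4,
    "jones_pewsey": 0.7,
    "linear_cardioid": 0.2,
    "exp_linear_cardioid": 0.2,
}

ALL_FAMILIES = list(FAMILY_CONC)


def random_params(family: str, rng: np.random.Generator,
                  max_pptr: float | None = None) -> ParameterSet:
    """Draw an in-bounds parameter set for property tests.

    With ``max_pptr`` the concentration is drawn inside the working range
    [1, max_pptr] of the growth model (QC caps accepted fits at pPTR 3).
    """
    from repliptr.distributions import (
        KAPPA_FAMILIES,
        RHO_BOUND,
        DistributionSpec,
        concentration_for_pptr,
    )

    mu = rng.uniform(0, 2 * np.pi)
    if max_pptr is not None:
        conc = concentration_for_pptr(
            DistributionSpec(family), rng.uniform(1.0, max_pptr)
        )
    elif family in KAPPA_FAMILIES:
        conc = rng.uniform(0.05, 2.0)
    else:
        conc = rng.uniform(0.0, 0.9 * RHO_BOUND[family])
    psi = rng.uniform(-1.0, 1.0)
    return ParameterSet(mu=mu, concentration=conc, psi=psi)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def toy_track():
    """Five-bin track with small integer depths."""
    return CoverageTrack(np.array([3, 1, 0, 2, 4]), sample_id="toy")


@pytest.fixture
def vm_track():
    """Moderate-size simulated von Mises track (shared to keep tests fast)."""
    return generate_coverage(
        DistributionSpec("von_mises"),
        ParameterSet(mu=1.0, concentration=0.7),
        1000, 16.0, seed=11,
    )
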