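import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", database=None, deadline=None)
settings.load_profile("suite")

from vicurve.profiles import DISTANCES_9, VAProfile
from vicurve.simulate import SimParams


@pytest.fixture
def rng():
    return np.random.default_rng(20250901)


@pytest.fixture
def fast_params():
    """Generator parameters with a fixed QoL slope (no calibration run)."""
    return SimParams(n_patients=30, seed=5, qol_slope=6.0)


def make_random_profiles(rng, n, smooth=True):
    """Random nine-distance VA profiles.

    ``smooth=True`` draws plausible visual curves (log-linear trend plus
    noise); otherwise VA is uniform in [5, 95], exercising the fitters on
    arbitrary data.
    """
    d = np.asarray(DISTANCES_9)
    profiles = []
    for i in range(n):
        if smooth:
            base = rng.uniform(55, 90)
            slope = rng.uniform(0, 15)
            va = base + slope * (np.log10(d) - np.log10(d[0])) + rng.normal(0, 2, len(d))
        else:
            va = rng.uniform(5, 95, len(d))
        va = np.clip(va, 0, 100)
        profiles.append(VAProfile(f"R{i:04d}", tuple(d), tuple(va)))
    return profiles


@pytest.fixture
def random_profiles(rng):
    return make_random_profiles(rng, 50)
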