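"""Shared fixtures: one small synthetic world reused across test modules.

The world is 4 x 6 pixels over 31 years with the package's default
parameter ranges; phenology extraction on it is the slowest shared step,
so everything is session-scoped.
"""

import numpy as np
import pytest

from frostphen import frost, phenology, synthetic

YEARS = np.arange(1982, 2013)


@pytest.fixture(scope="session")
def truth():
    return synthetic.gen_truth(4, 6, seed=1)


@pytest.fixture(scope="session")
def ndvi_noiseless(truth):
    return synthetic.gen_ndvi(truth, YEARS, noise_sd=0.0, seed=2)


@pytest.fixture(scope="session")
def tmin_cube(truth):
    return synthetic.gen_tmin(truth, YEARS, timestep_hours=3, seed=3)


@pytest.fixture(scope="session")
def daily(tmin_cube):
    return frost.daily_min(tmin_cube)


@pytest.fixture(scope="session")
def phen_grids(ndvi_noiseless):
    return phenology.extract_phenology(ndvi_noiseless)


@pytest.fixture(scope="session")
def ensemble(phen_grids):
    return phen_grids["ensemble"]
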