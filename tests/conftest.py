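import warnings

import numpy as np
import pytest

from trabeflow.geometry import GeometryParams, build_idealized_chamber
from trabeflow.ib_solver import grid_for_tier

warnings.filterwarnings("ignore", message="pulsatile run not periodic")


@pytest.fixture(scope="session")
def coarse_grid():
    return grid_for_tier("coarse")


@pytest.fixture(scope="session")
def default_params():
    return GeometryParams()


@pytest.fixture(scope="session")
def smooth_chamber(coarse_grid, default_params):
    """Idealized chamber without trabeculae, coarse tier."""
    return build_idealized_chamber(default_params, coarse_grid.h)


@pytest.fixture(scope="session")
def trabeculated_chamber(coarse_grid, default_params):
    """Idealized chamber at the biologically relevant height hT/bV = 0.08."""
    return build_idealized_chamber(
        default_params.with_ht_rel(0.08), coarse_grid.h
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)
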