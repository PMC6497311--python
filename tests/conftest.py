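import numpy as np
import pytest

from lalimap import LALIType, LinearTuringParams, PhenotypeCloud


# reduced-scale linear model used throughout: same kinetics as the full-size
# default, smaller lattice and fewer steps so patterns form in milliseconds
SMALL_LINEAR = dict(grid_n=48, n_steps=5000)


@pytest.fixture
def small_linear_params():
    return LinearTuringParams(seed=0, **SMALL_LINEAR)


@pytest.fixture
def small_linear_type():
    return LALIType("linear", coords={"f_u": 0.811, "T_rel": 1.2}, fixed=SMALL_LINEAR)


def synthetic_cloud(points) -> PhenotypeCloud:
    """A cloud built directly from phenotype rows (no simulation)."""
    return PhenotypeCloud(lali_type=None, phenotypes=np.asarray(points, dtype=float))
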