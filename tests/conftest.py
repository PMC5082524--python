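import numpy as np
import pytest

from scenesel.design_matrix import build_block_schedule, build_design_matrix, double_gamma_hrf
from scenesel.grid import TemplateSpace
from scenesel.synthetic_cohort import make_template_rois


@pytest.fixture(scope="session")
def space_small():
    return TemplateSpace.default((30, 36, 30))


@pytest.fixture(scope="session")
def space_default():
    return TemplateSpace.default()


@pytest.fixture(scope="session")
def rois_small(space_small):
    return make_template_rois(space_small)


@pytest.fixture(scope="session")
def schedule():
    return build_block_schedule()


@pytest.fixture(scope="session")
def hrf():
    return double_gamma_hrf()


@pytest.fixture(scope="session")
def design(schedule):
    return build_design_matrix(schedule, n_volumes=214)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
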