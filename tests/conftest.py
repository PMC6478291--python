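import numpy as np
import pytest
from hypothesis import settings

from faceprint.synth import (
    Acquisition,
    NoiseParams,
    ROISpec,
    build_schedule,
    make_atlas,
    make_subject_template,
)

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")

TINY_GRID = (16, 16, 12)
TINY_SPECS = [
    ROISpec("FFA_L", (-12.0, -9.0, -6.0), 6.0, "task_positive", "L"),
    ROISpec("FFA_R", (12.0, -9.0, -6.0), 6.0, "task_positive", "R"),
    ROISpec("pSTS_TPJ_R", (12.0, 9.0, 3.0), 6.0, "hybrid", "R"),
    ROISpec("Precuneus_M", (0.0, 12.0, 6.0), 5.0, "task_negative", "M"),
]


@pytest.fixture(scope="session")
def tiny_atlas():
    return make_atlas(TINY_GRID, 3.0, TINY_SPECS)


@pytest.fixture(scope="session")
def tiny_schedule():
    # 4 conditions x 2 blocks x 5 stimuli x 0.8 s = 4 s blocks, 8 s rest
    return build_schedule(4, 2, 5, 0.8, 8.0, order_seed=11)


@pytest.fixture(scope="session")
def tiny_acquisition():
    return Acquisition(tr_s=1.7, n_volumes=30, discard_initial=0)


@pytest.fixture(scope="session")
def tiny_template(tiny_atlas):
    return make_subject_template(tiny_atlas, subject_seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def tiny_cohort_kwargs(**overrides):
    """Shared settings for fast multi-run simulations."""
    kw = dict(
        layout="custom",
        n_subjects=3,
        sessions_per_subject=3,
        atlas=make_atlas(TINY_GRID, 3.0, TINY_SPECS),
        schedule_kwargs=dict(
            n_conditions=4, blocks_per_condition=2, stimuli_per_block=5,
            stimulus_period_s=0.8, rest_duration_s=8.0,
        ),
        acquisition=Acquisition(1.7, 30, 0),
        noise_params=NoiseParams(0.2, 1.0, 0.1),
        master_seed=5,
    )
    kw.update(overrides)
    return kw
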