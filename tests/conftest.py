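import dataclasses

import numpy as np
import pytest

from fdgquant.core import FrameSchedule, ScanMeta
from fdgquant.simulate import (
    InputFunctionModel,
    StudyDesign,
    aif_on_grid,
    simulation_grid,
)


@pytest.fixture(scope="session")
def grid():
    return simulation_grid()


@pytest.fixture(scope="session")
def default_model():
    return InputFunctionModel()


@pytest.fixture(scope="session")
def default_schedule():
    return FrameSchedule.default()


@pytest.fixture(scope="session")
def meta():
    return ScanMeta(subject_id="m01", session="test", injected_dose_mbq=169.2,
                    body_weight_kg=5.8, glycemia_arterial_mmol_l=4.5,
                    glycemia_venous_mmol_l=4.4)


@pytest.fixture(scope="session")
def dense_cp(default_model, grid):
    """Default input function (kBq/mL) on the dense grid, nominal dose/weight."""
    return aif_on_grid(default_model, grid, dose_mbq=169.2, weight_kg=5.8)


@pytest.fixture(scope="session")
def variance_free_design():
    """Design with every variance component switched off (deterministic truth)."""
    return StudyDesign(sigma_inter=0.0, sigma_intra=0.0, sigma_region=0.0,
                       global_scale_cv=0.0, noise_cv=0.0, glycemia_sd=0.0,
                       dose_sd_mbq=0.0, weight_sd_kg=0.0, venous_resid_sd=0.0,
                       rng_seed=7)


@pytest.fixture
def small_design():
    """Small, fast study: 2 subjects, 3 regions."""
    return StudyDesign(
        n_subjects=2,
        region_ki_map={"pons": 0.0119, "cerebellum": 0.0159, "thalamus": 0.0156},
        rng_seed=11,
    )


def make_design(**overrides) -> StudyDesign:
    base = StudyDesign()
    return dataclasses.replace(base, **overrides)
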