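import numpy as np
import pytest

from cario import synth


@pytest.fixture()
def small_config():
    """A small, fast cohort configuration with default noise levels."""
    return synth.CohortConfig(n_lesions=6, seed=7, image_shape=(64, 64), frame_count=30)


@pytest.fixture()
def noise_free_config():
    return synth.CohortConfig(
        n_lesions=6,
        seed=7,
        noise_sd_swir=0.0,
        noise_sd_thermal=0.0,
        noise_sd_oct=0.0,
        noise_sd_microct=0.0,
    )


@pytest.fixture()
def mid_lesion():
    """An unambiguous partially-arrested lesion used across modality tests."""
    return synth.LesionTruth(
        lesion_depth_um=200.0,
        tsl_thickness_um=50.0,
        mineral_loss_frac=0.25,
        permeability=synth.permeability_from_tsl(50.0),
        surface_type="smooth",
        has_composite=False,
        water_pool_frac=0.0,
        sl_thickness_um=70.0,
        lesion_id=0,
    )


@pytest.fixture()
def sound_truth():
    """Zero-mineral-loss truth: no lesion, no pooling."""
    return synth.LesionTruth(
        lesion_depth_um=0.0,
        tsl_thickness_um=0.0,
        mineral_loss_frac=0.0,
        permeability=1.0,
        surface_type="smooth",
        has_composite=False,
        water_pool_frac=0.0,
        lesion_id=0,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
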