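import numpy as np
import pytest

import navregsim as nv


@pytest.fixture(scope="session")
def zero_noise():
    """Noise-free, event-free configuration."""
    return nv.NoiseConfig(
        fle_image_sigma=0.0,
        fle_tracker_sigma=0.0,
        pointer_sigma=0.0,
        surface_offset_sigma=0.0,
        screw_plan_sigma=0.0,
        fusion_noise_sigma_mm_deg=(0.0, 0.0),
        p_wrong_level=0.0,
        p_drf_displacement=0.0,
        p_missing_data=0.0,
        p_image_quality=0.0,
        drf_displacement_mm=0.0,
    )


@pytest.fixture(scope="session")
def coarse_geometry():
    """Coarser mesh for Monte-Carlo-heavy tests."""
    return nv.GeometryParams(grid_n=12)


@pytest.fixture(scope="session")
def scene():
    return nv.make_vertebra_scene(1)


@pytest.fixture(scope="session")
def clean_record(scene, zero_noise):
    return nv.simulate_measurements(scene, zero_noise, 7)


def rng_of(seed):
    return np.random.default_rng(seed)
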