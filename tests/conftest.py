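import numpy as np
import pytest

from axoquant import (
    Calibration,
    GROWTH_CONE_CALIBRATION,
    GrowthConeSceneConfig,
    IFSceneConfig,
    OrganelleSceneConfig,
    generate_growth_cone_movie,
    generate_if_image,
    generate_organelle_movie,
)


@pytest.fixture(scope="session")
def organelle_calib() -> Calibration:
    """Organelle-movie acquisition: 229.55 nm/px, 3.3 frames/s per channel."""
    return Calibration()


@pytest.fixture(scope="session")
def cone_calib() -> Calibration:
    return GROWTH_CONE_CALIBRATION


@pytest.fixture(scope="session")
def small_lyso_movie(organelle_calib):
    """A small mixed-motility lysosome movie with ground truth."""
    cfg = OrganelleSceneConfig(
        n_processive=4, n_stationary=3, n_jitter=3,
        n_frames=40, width=256, height=128, seed=11,
    )
    return generate_organelle_movie(cfg, organelle_calib)


@pytest.fixture(scope="session")
def small_cone_movie(cone_calib):
    cfg = GrowthConeSceneConfig(
        drift_speed_mean_um_s=0.0666, drift_speed_sd_um_s=0.0, n_frames=60, seed=5
    )
    return generate_growth_cone_movie(cfg, cone_calib)


@pytest.fixture(scope="session")
def if_scene():
    cfg = IFSceneConfig(
        n_cells=60, width=640, height=640,
        markers=("MAP2", "SMI32"),
        positive_fraction={"MAP2": 0.7, "SMI32": 0.8},
        conditional_on={"SMI32": "MAP2"},
        seed=3,
    )
    return generate_if_image(cfg)


def gaussian_frame(centers, amp=100.0, sigma=1.5, shape=(128, 256), background=10.0):
    """Noise-free frame with isotropic Gaussian spots at (x, y) centers."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    img = np.full(shape, background, dtype=float)
    for cx, cy in centers:
        img += amp * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2))
    return img
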