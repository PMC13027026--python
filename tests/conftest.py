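import numpy as np
import pytest

from semmorph import (
    Calibration,
    MicrographPair,
    SceneParams,
    generate_scene,
    measure_pair,
)


def scene_pair(scene):
    """Wrap a synthetic scene as a MicrographPair without re-normalization."""
    return MicrographPair(
        image=scene.image.astype(float),
        label_mask=scene.label_mask,
        calibration=Calibration(pixel_size_um=scene.params.pixel_size_um),
    )


def ellipse_mask(shape, xc, yc, a, b, phi_deg):
    """Analytic filled-ellipse rasterization, independent of the generator."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    phi = np.deg2rad(phi_deg)
    dx, dy = xx - xc, yy - yc
    u = dx * np.cos(phi) + dy * np.sin(phi)
    v = -dx * np.sin(phi) + dy * np.cos(phi)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


@pytest.fixture(scope="session")
def default_scene():
    """A mixed scene: chains, isolated cells, and planted occlusions."""
    return generate_scene(SceneParams(n_cells=40, seed=11))


@pytest.fixture(scope="session")
def default_measurement(default_scene):
    cells, counts = measure_pair(scene_pair(default_scene), image_id="fixture")
    return cells, counts


@pytest.fixture(scope="session")
def clean_scene():
    """No occlusion, no chains: every cell isolated and fully visible."""
    return generate_scene(
        SceneParams(n_cells=30, occluded_fraction=0.0, chain_probability=0.0, seed=7)
    )
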