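import numpy as np
import pytest

from citrus3d import FruitSpec, SceneConfig, render_scene, sample_scene_config


def disc_mask(shape, center, radius):
    """Rasterized disc: pixel centers within `radius` of `center` (u, v)."""
    h, w = shape
    vv, uu = np.mgrid[0:h, 0:w]
    return (uu - center[0]) ** 2 + (vv - center[1]) ** 2 <= radius**2


@pytest.fixture(scope="session")
def on_axis_sphere_scene():
    """80 mm sphere centred on the optical axis at 1000 mm."""
    config = SceneConfig(
        fruits=(FruitSpec(center=(0.0, 0.0, 1000.0), diameters=(80.0, 80.0, 80.0)),),
        seed=11,
    )
    rgb, depth, truth = render_scene(config)
    return config, rgb, depth, truth


@pytest.fixture(scope="session")
def illumination_scenes():
    """One randomly drawn occluded scene per illumination mode."""
    out = {}
    for i, mode in enumerate(("well", "weak", "non_uniform")):
        config = sample_scene_config(100 + i, illumination=mode)
        out[mode] = (config, *render_scene(config))
    return out
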