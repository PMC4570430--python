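import numpy as np
import pytest

import leafseg3d as L

# Small-format scenes keep the suite fast; the camera-format benchmark
# lives in the acceptance tests.
SMALL = dict(height=240, width=320)


@pytest.fixture(scope="session")
def default_config():
    return L.PipelineConfig()


@pytest.fixture(scope="session")
def scene4():
    """Four leaves (one occlusion chain + one single), default noise."""
    return L.generate_scene(L.SceneParams(n_leaves=4, seed=0, **SMALL))


@pytest.fixture(scope="session")
def two_leaf_scene():
    """One occluding pair at the default 30 mm depth offset."""
    params = L.SceneParams(n_leaves=2, occluded_fraction=1.0, seed=0, **SMALL)
    return L.generate_scene(params)


@pytest.fixture(scope="session")
def clean_two_leaf_scene():
    params = L.SceneParams(n_leaves=2, occluded_fraction=1.0, seed=0,
                           depth_noise_sd_mm=0.0, dropout_rate_edge=0.0,
                           **SMALL)
    return L.generate_scene(params)


@pytest.fixture(scope="session")
def single_clean_scene():
    params = L.SceneParams(n_leaves=1, seed=0, depth_noise_sd_mm=0.0,
                           dropout_rate_edge=0.0, **SMALL)
    return L.generate_scene(params)


@pytest.fixture(scope="session")
def segmented_two_leaf(two_leaf_scene, default_config):
    frame, gt = two_leaf_scene
    segments, debug = L.segment_leaves(frame, default_config,
                                       return_debug=True)
    return frame, gt, segments, debug


@pytest.fixture(scope="session")
def circle_field():
    """GVF of a circular Gaussian ridge of radius 20 centred in 64x64."""
    yy, xx = np.mgrid[0:64, 0:64]
    r = np.hypot(xx - 32, yy - 32)
    edge = L.EdgeMap(np.exp(-0.5 * ((r - 20) / 1.5) ** 2))
    field = L.compute_gvf(edge, L.GVFParams(mu=0.2, n_iter=80))
    return edge, field


def iou(a, b):
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    union = np.count_nonzero(a | b)
    return np.count_nonzero(a & b) / union if union else 0.0
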