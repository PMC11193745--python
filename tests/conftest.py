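import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import croplandsyn as cs

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_scene():
    """A 128x128, K=6 scene with moderate independent errors."""
    params = cs.SceneParams(n_rows=128, n_cols=128, k_maps=6,
                            cropland_fraction=0.3, omission=0.2,
                            commission=0.1, n_zones=4, seed=11)
    return cs.generate_scene(params)


@pytest.fixture(scope="session")
def labeled_pool(small_scene):
    """Stratified sample on the scene's vote map, labeled from truth."""
    vote = cs.vote_map(small_scene.products)
    pool = cs.stratified_sample(vote, 1200, restrict_to_extent=False, seed=5)
    return cs.label_from_truth(pool, small_scene.truth)


def make_grid(labels, pixel_size=30.0, origin=(0.0, None), crs="equal-area",
              nodata=255):
    """LabelGrid from a 2-D array; origin_y defaults to the grid height."""
    labels = np.asarray(labels)
    oy = origin[1] if origin[1] is not None else labels.shape[0] * pixel_size
    spec = cs.GridSpec(origin[0], oy, pixel_size,
                       labels.shape[0], labels.shape[1], crs)
    return cs.LabelGrid(spec, labels.astype(np.uint8), nodata)


@pytest.fixture
def grid_factory():
    return make_grid
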