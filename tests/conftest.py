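import numpy as np
import pytest

from ricemap import (ErrorMatrix, Grid2D, SceneConfig, Transform, Unit,
                     generate_scene)


@pytest.fixture
def grid_factory():
    def make(values, unit=Unit.DB, pixel_size=30.0, nodata_mask=None):
        return Grid2D(np.asarray(values, dtype=float), unit,
                      Transform(0.0, 0.0, pixel_size), nodata_mask=nodata_mask)
    return make


@pytest.fixture(scope="session")
def small_scene():
    """120x120 synthetic scene shared by the stage-contrast tests."""
    return generate_scene(SceneConfig(shape=(120, 120), seed=7))


@pytest.fixture
def toy_error_matrix():
    """Two-category worked example: 100 samples, 60/40 km2 mapped, 100 km2 total."""
    return ErrorMatrix(
        counts=np.array([[45, 5], [10, 40]]),
        categories=["A", "B"],
        mapped_areas=np.array([60.0, 40.0]),
        total_area=100.0,
    )
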