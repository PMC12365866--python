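import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from firesev.grid import LandscapeGrid  # noqa: E402
from firesev.synthetic import StemMap, generate_stem_map  # noqa: E402


@pytest.fixture
def small_grid() -> LandscapeGrid:
    """20 x 20 pixels of 30 m (600 x 600 m)."""
    return LandscapeGrid(0.0, 0.0, 20, 20, 30.0)


@pytest.fixture
def random_stems(small_grid) -> StemMap:
    return generate_stem_map(small_grid, "random", 30.0, seed=42)


def stem_map_from_points(points, grid, height=10.0, crown_radius=3.0) -> StemMap:
    """Build a StemMap with constant heights/crowns from raw coordinates."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    return StemMap(
        x=pts[:, 0],
        y=pts[:, 1],
        height=np.full(n, float(height)),
        crown_radius=np.full(n, float(crown_radius)),
        grid=grid,
    )
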