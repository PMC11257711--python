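import numpy as np
import pytest
from hypothesis import settings

from spot import PointPattern, Window

settings.register_profile("ci", derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def unit_window():
    return Window(0.0, 1000.0, 0.0, 1000.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def two_point_pattern(unit_window):
    """Two interior points at distance 10; no edge effects within t <= 20."""
    return PointPattern(np.array([[495.0, 500.0], [505.0, 500.0]]), unit_window)


def naive_K_oracle(points, area, radii, normalization="unbiased"):
    """Double-loop counting oracle for univariate K without edge correction."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    radii = np.asarray(radii, dtype=float)
    counts = np.zeros(radii.size)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = np.hypot(*(points[i] - points[j]))
            counts += (d < radii).astype(float)
    denom = n * (n - 1) if normalization == "unbiased" else n * n
    return area * counts / denom


def naive_K_biv_oracle(points_a, points_b, area, radii):
    """Double-loop oracle for bivariate K without edge correction."""
    radii = np.asarray(radii, dtype=float)
    counts = np.zeros(radii.size)
    for pa in np.asarray(points_a, dtype=float):
        for pb in np.asarray(points_b, dtype=float):
            d = np.hypot(*(pa - pb))
            counts += (d < radii).astype(float)
    return area * counts / (len(points_a) * len(points_b))
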