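import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pleograde as pg

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table5_matrix() -> pg.ConfusionMatrix:
    """Published validation cross-tabulation (modified rows vs original columns)."""
    return pg.ConfusionMatrix(((0, 3, 0), (3, 22, 5), (1, 6, 13)))


@pytest.fixture(scope="session")
def phase1_cohort() -> list[pg.CaseRecord]:
    """Synthetic development-style cohort: 13/80/27 cases for grades 1/2/3."""
    config = pg.CohortConfig(distributions=pg.phase1_distributions(), seed=7)
    return pg.generate_cohort(config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_simple_polygon(rng: np.random.Generator, n_vertices: int) -> np.ndarray:
    """Star-shaped (hence simple) polygon: jittered angles with random radii.

    Angles are evenly spaced with sub-spacing jitter, so they stay strictly
    increasing and wind once around the origin; any radial polygon around an
    interior point is simple.
    """
    jitter = rng.uniform(0.0, 0.8, n_vertices)
    angles = 2 * np.pi * (np.arange(n_vertices) + jitter) / n_vertices
    radii = rng.uniform(1.0, 30.0, n_vertices)
    return np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])
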