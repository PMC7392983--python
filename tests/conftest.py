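import numpy as np
import pandas as pd
import pytest
from hypothesis import settings
from shapely.geometry import box

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

from streetcover.simulate import SyntheticCityConfig, simulate_city, simulate_study
from streetcover.spatial import CityBoundary, RoadNetwork


@pytest.fixture
def unit_square_city() -> CityBoundary:
    return CityBoundary(city_id="sq", country="AR", polygon=box(0, 0, 1000, 1000))


@pytest.fixture
def small_city():
    return simulate_city(
        SyntheticCityConfig(city_size_m=2500.0, n_subcities=3), seed=11, city_id="T000"
    )


@pytest.fixture(scope="session")
def small_study():
    return simulate_study(6, seed=23, size_range_m=(2000.0, 3500.0), n_subcities_range=(2, 4))


@pytest.fixture(scope="session")
def small_pipeline(small_study):
    from streetcover.pipeline import run_study_pipeline

    return run_study_pipeline(small_study)


def random_polygon(rng: np.random.Generator, scale: float = 1000.0):
    """A random simple polygon: star-shaped around the origin."""
    n = int(rng.integers(4, 12))
    angles = np.sort(rng.uniform(0, 2 * np.pi, size=n))
    radii = rng.uniform(0.2 * scale, scale, size=n)
    pts = np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])
    from shapely.geometry import Polygon

    return Polygon(pts)


def random_network(rng: np.random.Generator, n_lines: int = 5, scale: float = 400.0):
    lines = []
    for _ in range(n_lines):
        n_v = int(rng.integers(2, 5))
        lines.append(rng.uniform(-scale, scale, size=(n_v, 2)))
    return RoadNetwork(lines)


def audited_frame_from_counts(n_ok: int, n_zero: int, n_error: int) -> pd.DataFrame:
    status = (["OK"] * n_ok) + (["ZERO_RESULTS"] * n_zero) + (["ERROR"] * n_error)
    return pd.DataFrame(
        {
            "status": status,
            "available": [s == "OK" for s in status],
            "analysis_ok": [s != "ERROR" for s in status],
        }
    )
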