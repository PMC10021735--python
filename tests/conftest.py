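import numpy as np
import pytest

from archaccess import AccessibilityModel, GeneratorConfig, generate_region, toy_fixture


@pytest.fixture(scope="session")
def toy():
    return toy_fixture()


@pytest.fixture(scope="session")
def toy_results(toy):
    return AccessibilityModel(toy).fit()


@pytest.fixture(scope="session")
def small_config():
    # compact region: quick to route, still multi-island with naval routes
    return GeneratorConfig(
        n_districts=2,
        islands_per_district=(2, 3),
        residences_per_district=(25, 35),
        puskesmas_per_district=(1, 2),
        hospitals_per_district=(1, 1),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_region(small_config):
    return generate_region(small_config)


@pytest.fixture(scope="session")
def small_results(small_region):
    return AccessibilityModel(small_region).fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_star_polygon(rng, n_vertices=8, radius=5.0, irregularity=0.6, center=(0.0, 0.0)):
    """Random simple polygon: star-shaped around its center by construction."""
    from shapely.geometry import Polygon

    angles = np.sort(rng.uniform(0, 2 * np.pi, size=n_vertices))
    radii = radius * (1 - irregularity + irregularity * rng.uniform(0, 2, size=n_vertices))
    xs = center[0] + radii * np.cos(angles)
    ys = center[1] + radii * np.sin(angles)
    return Polygon(zip(xs, ys))
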