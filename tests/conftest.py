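import numpy as np
import pytest

import ablazone as az

CANONICAL_SPACING = (1.0, 1.0, 0.5)


@pytest.fixture(scope="session")
def ellipsoid():
    """Axis-aligned ellipsoid, semi-axes 20/15/8 mm, anisotropic spacing."""
    grid, truth = az.make_ellipsoid((20.0, 15.0, 8.0), spacing=CANONICAL_SPACING)
    return grid, truth


@pytest.fixture(scope="session")
def rotated_ellipsoid():
    grid, truth = az.make_ellipsoid(
        (20.0, 15.0, 8.0), rotation=30.0, spacing=CANONICAL_SPACING
    )
    return grid, truth


@pytest.fixture(scope="session")
def sphere20():
    grid, truth = az.make_sphere(20.0, spacing=(1.0, 1.0, 1.0))
    return grid, truth


@pytest.fixture(scope="session")
def notched_sphere():
    """Sphere r=20 with an infinite 6 mm notch through the center."""
    grid, truth = az.make_notched_sphere(20.0, 6.0, spacing=(1.0, 1.0, 1.0))
    return grid, truth


@pytest.fixture(scope="session")
def half_notched_sphere():
    """Sphere r=20 notched from the +x surface down to the center only."""
    grid, truth = az.make_notched_sphere(
        20.0, 6.0, through=False, spacing=(1.0, 1.0, 1.0)
    )
    return grid, truth


def random_small_phantom(seed: int):
    """A random phantom on a grid of at most 64^3 voxels, for oracle checks."""
    rng = np.random.default_rng(seed)
    kind = rng.choice(["sphere", "ellipsoid", "notched_sphere", "dumbbell", "multi"])
    spacing = tuple(rng.choice([0.8, 1.0, 1.25], size=3))
    if kind == "sphere":
        g, _ = az.make_sphere(float(rng.uniform(6, 14)), spacing=spacing)
    elif kind == "ellipsoid":
        semi = np.sort(rng.uniform(5, 14, size=3))[::-1]
        g, _ = az.make_ellipsoid(semi, rotation=float(rng.uniform(0, 90)), spacing=spacing)
    elif kind == "notched_sphere":
        r = float(rng.uniform(8, 14))
        g, _ = az.make_notched_sphere(
            r, float(rng.uniform(1, 0.6 * r)), through=bool(rng.random() < 0.5),
            spacing=spacing,
        )
    elif kind == "dumbbell":
        g, _ = az.make_dumbbell(
            float(rng.uniform(4, 7)), float(rng.uniform(8, 14)), float(rng.uniform(1.5, 3)),
            spacing=spacing,
        )
    else:
        pos = rng.uniform(-8, 8, size=(3, 2))
        g, _ = az.make_multi_applicator(
            pos, tip_exposure_mm=float(rng.uniform(8, 14)),
            lobe_radius_mm=float(rng.uniform(4, 7)),
            radius_jitter=0.3, seed=int(rng.integers(1 << 16)), spacing=spacing,
        )
    assert max(g.shape) <= 64, f"random phantom too large: {g.shape}"
    return g
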