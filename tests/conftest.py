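import numpy as np
import pytest

from corneamorph.fitting import FitConfig, FittedSurface, _uniform_clamped_knots, fit_surface
from corneamorph.io import polar_to_cartesian
from corneamorph.solid import build_solid
from corneamorph.synthetic import CorneaParams, generate_cornea


def constant_surface(z0: float, label: str, spans: int = 8) -> FittedSurface:
    """Exact plane z = z0 as a spline surface (partition of unity)."""
    t = _uniform_clamped_knots(spans, 3, 4.0)
    n = len(t) - 4
    return FittedSurface(label, t, t, np.full((n, n), float(z0)))


@pytest.fixture(scope="session")
def pillbox_surfaces():
    return constant_surface(0.0, "anterior"), constant_surface(0.55, "posterior")


@pytest.fixture(scope="session")
def pillbox_solid(pillbox_surfaces):
    return build_solid(*pillbox_surfaces)


@pytest.fixture(scope="session")
def two_sphere_params():
    # spherical limit (Q = 0) of the conicoid model: closed forms available
    return CorneaParams(R_ant=7.8, Q_ant=0.0, R_post=6.5, Q_post=0.0, t0=0.55)


@pytest.fixture(scope="session")
def two_sphere_grids(two_sphere_params):
    ant, post, truth = generate_cornea(two_sphere_params)
    return ant, post, truth


@pytest.fixture(scope="session")
def two_sphere_surfaces(two_sphere_grids):
    ant, post, _ = two_sphere_grids
    cfg = FitConfig()
    return fit_surface(polar_to_cartesian(ant), cfg), fit_surface(polar_to_cartesian(post), cfg)


@pytest.fixture(scope="session")
def two_sphere_solid(two_sphere_surfaces):
    return build_solid(*two_sphere_surfaces)


@pytest.fixture(scope="session")
def kc_params():
    """A decentered stage-II-like ectatic eye, noise-free."""
    return CorneaParams(
        R_ant=6.8, Q_ant=-0.45, R_post=5.7, Q_post=-0.50, t0=0.49,
        bump_amplitude=0.12, bump_center=(0.9, 1.2), bump_sigma=0.8,
        thinning_fraction=0.6, noise_sd=0.0,
    )


@pytest.fixture(scope="session")
def kc_eye(kc_params):
    return generate_cornea(kc_params)


@pytest.fixture(scope="session")
def kc_surfaces(kc_eye):
    ant, post, _ = kc_eye
    cfg = FitConfig()
    return fit_surface(polar_to_cartesian(ant), cfg), fit_surface(polar_to_cartesian(post), cfg)
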