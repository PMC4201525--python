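"""Geometric variables of the reconstructed cornea.

From the fitted anterior/posterior height fields and the closed solid,
this module extracts the morphometric record used for keratoconus
diagnosis: total volume, per-surface areas, diametral (sagittal) section
areas through the apex and through the minimum-thickness point, apex and
minimum-thickness decentrations, center of mass, and the volumes of the
solid inside cylinders of radius 0.5/1/1.5/2 mm about the axis through
the minimum-thickness points.

Conventions (Z positive posterior, into the eye):

* the "apex" of a surface is its most anterior point, i.e. the global
  minimizer of the height field over the closed 4 mm disc; its deviation
  is the XY distance to the instrument axis.  On a flat or rotationally
  symmetric surface ties are broken toward the axis.
* thickness is axial (along Z) by default, so the two minimum-thickness
  contact points share (x, y) and the cylinder axis is parallel to Z; a
  ``normal`` mode measuring along the anterior surface normal is
  available for the thickness report itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Callable

import numpy as np
from scipy import optimize

from .io import APERTURE_MM
from .fitting import FittedSurface
from .solid import SolidModel, SolidModelError, build_solid

DEFAULT_CYLINDER_RADII = (0.5, 1.0, 1.5, 2.0)


class MorphometryError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# extremum search over the disc
# ---------------------------------------------------------------------------

def _polar_grid(r_max: float, nr: int = 81, nth: int = 256):
    r = np.linspace(0.0, r_max, nr)
    th = np.arange(nth) * (2.0 * math.pi / nth)
    rr, tt = np.meshgrid(r, th, indexing="ij")
    return rr * np.cos(tt), rr * np.sin(tt), rr, tt


def _minimize_on_disc(fun: Callable, r_max: float = APERTURE_MM,
                      tie_tol: float = 1e-12) -> tuple[float, float, float]:
    """Global minimum of a scalar field over the closed disc.

    Dense polar-grid seeding followed by Nelder-Mead refinement; grid
    ties (flat extrema) are broken toward smaller radius, then smaller
    azimuth.  Returns (x, y, value).
    """
    X, Y, rr, tt = _polar_grid(r_max)
    vals = np.asarray(fun(X, Y), dtype=float)
    flat = vals.ravel()
    vmin = flat.min()
    near = np.nonzero(flat <= vmin + tie_tol)[0]
    order = np.lexsort((tt.ravel()[near], rr.ravel()[near]))
    k = near[order[0]]
    seed = (X.ravel()[k], Y.ravel()[k])

    def penalized(p):
        r = math.hypot(p[0], p[1])
        if r > r_max:
            x, y = r_max * p[0] / r, r_max * p[1] / r
            return float(fun(x, y)) + (r - r_max)
        return float(fun(p[0], p[1]))

    res = optimize.minimize(
        penalized, seed, method="Nelder-Mead",
        options={"xatol": 1e-9, "fatol": 1e-15, "maxiter": 4000},
    )
    if not res.success and res.status != 2:  # status 2 = maxiter, still usable
        raise MorphometryError(f"extremum search failed: {res.message}")
    x, y = res.x
    r = math.hypot(x, y)
    if r > r_max:
        x, y = r_max * x / r, r_max * y / r
    v = float(fun(x, y))
    v_seed = float(fun(*seed))
    # keep the tie-broken grid seed unless refinement strictly improved on it
    # (on flat extrema the simplex drifts without descending)
    if v >= v_seed - tie_tol:
        x, y, v = seed[0], seed[1], v_seed
    return float(x), float(y), v


@dataclass
class ApexInfo:
    """Most anterior point of one surface and its decentration."""

    surface_label: str
    position: tuple[float, float, float]
    deviation: float


def find_apex(surface: FittedSurface) -> ApexInfo:
    """Locate the apex (global minimum of the height field) of a surface."""
    x, y, z = _minimize_on_disc(surface.evaluate, surface.aperture)
    return ApexInfo(
        surface_label=surface.surface_label,
        position=(x, y, z),
        deviation=math.hypot(x, y),
    )


# ---------------------------------------------------------------------------
# thickness
# ---------------------------------------------------------------------------

@dataclass
class ThicknessInfo:
    minimum: float
    anterior_point: tuple[float, float, float]
    posterior_point: tuple[float, float, float]
    anterior_deviation: float
    posterior_deviation: float
    mode: str = "axial"
    map_values: np.ndarray | None = None


def _normal_thickness_at(anterior: FittedSurface, posterior: FittedSurface,
                         x: float, y: float) -> tuple[float, tuple[float, float, float]]:
    h = 1e-5
    gx = (anterior.evaluate(x + h, y) - anterior.evaluate(x - h, y)) / (2 * h)
    gy = (anterior.evaluate(x, y + h) - anterior.evaluate(x, y - h)) / (2 * h)
    n = np.array([-gx, -gy, 1.0])
    n /= np.linalg.norm(n)
    za = float(anterior.evaluate(x, y))

    def gap(s):
        p = np.array([x, y, za]) + s * n
        return float(posterior.evaluate(p[0], p[1])) - p[2]

    s = optimize.brentq(gap, 0.0, 2.0, xtol=1e-12)
    p = np.array([x, y, za]) + s * n
    return float(s), (float(p[0]), float(p[1]), float(p[2]))


def min_thickness(anterior: FittedSurface, posterior: FittedSurface,
                  mode: str = "axial") -> ThicknessInfo:
    """Locate the thinnest point between the two surfaces.

    Axial mode minimizes T(x, y) = z_post - z_ant (contact points share
    (x, y)); normal mode minimizes the distance along the anterior
    surface normal.  Raises if the model has non-positive thickness.
    """
    if mode not in ("axial", "normal"):
        raise ValueError(f"unknown thickness mode {mode!r}")
    axial = lambda x, y: posterior.evaluate(x, y) - anterior.evaluate(x, y)
    X, Y, _, _ = _polar_grid(APERTURE_MM)
    tmap = np.asarray(axial(X, Y))
    if tmap.min() <= 0:
        raise MorphometryError("non-positive thickness: invalid corneal model")

    if mode == "axial":
        x, y, t = _minimize_on_disc(axial)
        if t <= 0:
            raise MorphometryError("non-positive thickness: invalid corneal model")
        pa = (x, y, float(anterior.evaluate(x, y)))
        pp = (x, y, float(posterior.evaluate(x, y)))
    else:
        inner = APERTURE_MM - 0.2  # keep the normal ray inside the evaluable disc

        def t_normal(x, y):
            return _normal_thickness_at(anterior, posterior, x, y)[0]

        x, y, t = _minimize_on_disc(np.vectorize(t_normal), inner)
        t, pp = _normal_thickness_at(anterior, posterior, x, y)
        pa = (x, y, float(anterior.evaluate(x, y)))
    return ThicknessInfo(
        minimum=float(t),
        anterior_point=pa, posterior_point=pp,
        anterior_deviation=math.hypot(pa[0], pa[1]),
        posterior_deviation=math.hypot(pp[0], pp[1]),
        mode=mode, map_values=tmap,
    )


# ---------------------------------------------------------------------------
# integral quantities
# ---------------------------------------------------------------------------

def total_volume(solid: SolidModel) -> float:
    """Divergence-theorem volume of the watertight solid, mm^3."""
    if not solid.is_watertight():
        raise SolidModelError("volume requires a watertight solid")
    return float(solid.mesh.volume)


def surface_areas(solid: SolidModel) -> tuple[float, float, float, float]:
    """(anterior, posterior, perimetric, total) label areas, mm^2."""
    parts = [solid.label_area(name) for name in ("anterior", "posterior", "perimetric")]
    if any(a == 0.0 for a in parts):
        raise SolidModelError("solid is missing a face-label class")
    return (*parts, sum(parts))


def center_of_mass(solid: SolidModel) -> tuple[tuple[float, float, float], float]:
    """Uniform-density centroid (x, y, z) and its XY modulus."""
    if not solid.is_watertight():
        raise SolidModelError("center of mass requires a watertight solid")
    c = solid.mesh.center_mass
    return (float(c[0]), float(c[1]), float(c[2])), float(math.hypot(c[0], c[1]))


def sagittal_section_area(solid: SolidModel, azimuth: float) -> float:
    """Area of the full diametral cross-section at the given azimuth (rad).

    The plane contains the Z axis and the direction (cos azimuth,
    sin azimuth).  Computed from the mesh-plane intersection polygon;
    azimuths that coincide with mesh edges are nudged by a negligible
    jitter to keep the intersection transversal.
    """
    for jitter in (0.0, 2.3e-7, -3.1e-7, 1.7e-6):
        a = azimuth + jitter
        normal = np.array([-math.sin(a), math.cos(a), 0.0])
        try:
            path3 = solid.mesh.section(plane_origin=np.zeros(3), plane_normal=normal)
        except Exception:
            continue
        if path3 is None:
            continue
        try:
            path2 = path3.to_2D()[0]
        except AttributeError:
            path2 = path3.to_planar()[0]
        except Exception:
            continue
        area = float(abs(path2.area))
        if area > 0.0:
            return area
    raise MorphometryError(f"degenerate mesh-plane intersection at azimuth {azimuth}")


def cylinder_intersection_volume(
    anterior: FittedSurface,
    posterior: FittedSurface,
    axis_xy: tuple[float, float],
    radius: float,
    *,
    r_max: float = APERTURE_MM,
    n_radial: int = 64,
    n_angular: int = 256,
) -> float:
    """Volume of the solid inside the Z-parallel cylinder about ``axis_xy``.

    Quadrature of the axial thickness field over the cylinder's disc
    footprint (Gauss-Legendre radially, trapezoidal azimuthally); the
    footprint is clipped to the reconstruction aperture, outside which
    the solid does not exist.
    """
    if radius <= 0:
        raise ValueError("cylinder radius must be positive")
    x0, y0 = axis_xy
    gr, gw = np.polynomial.legendre.leggauss(n_radial)
    rho = 0.5 * radius * (gr + 1.0)
    wr = 0.5 * radius * gw * rho
    phi = np.arange(n_angular) * (2.0 * math.pi / n_angular)
    wphi = 2.0 * math.pi / n_angular
    X = x0 + rho[:, None] * np.cos(phi)[None, :]
    Y = y0 + rho[:, None] * np.sin(phi)[None, :]
    inside = X**2 + Y**2 <= r_max**2 + 1e-12
    T = np.where(
        inside,
        posterior.evaluate(X, Y) - anterior.evaluate(X, Y),
        0.0,
    )
    return float((T * wr[:, None]).sum() * wphi)


# ---------------------------------------------------------------------------
# the full record
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MorphometryConfig:
    density: tuple[int, int] = (128, 256)
    cylinder_radii: tuple[float, ...] = DEFAULT_CYLINDER_RADII
    thickness_mode: str = "axial"
    r_max: float = APERTURE_MM


@dataclass
class MorphometryRecord:
    """The 18 per-eye geometric variables (lengths mm, areas mm^2, volumes mm^3)."""

    total_volume: float
    anterior_area: float
    posterior_area: float
    total_area: float
    sagittal_apex_area: float
    sagittal_min_thickness_area: float
    anterior_apex_deviation: float
    posterior_apex_deviation: float
    anterior_min_thickness_deviation: float
    posterior_min_thickness_deviation: float
    com_x: float
    com_y: float
    com_z: float
    com_xy_deviation: float
    cyl_volume_r05: float
    cyl_volume_r10: float
    cyl_volume_r15: float
    cyl_volume_r20: float

    @classmethod
    def field_names(cls) -> list[str]:
        return [f.name for f in fields(cls)]

    def to_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in self.field_names()}


def compute_morphometry(
    anterior: FittedSurface,
    posterior: FittedSurface,
    config: MorphometryConfig | None = None,
) -> MorphometryRecord:
    """Build the solid and extract the complete morphometric record."""
    config = config or MorphometryConfig()
    if tuple(config.cylinder_radii) != DEFAULT_CYLINDER_RADII:
        raise ValueError(
            "MorphometryRecord carries the four standard cylinder radii; "
            "use cylinder_intersection_volume directly for other radii"
        )
    solid = build_solid(anterior, posterior, config.r_max, config.density)
    vol = total_volume(solid)
    area_a, area_p, _, area_total = surface_areas(solid)
    apex_a = find_apex(anterior)
    apex_p = find_apex(posterior)
    thick = min_thickness(anterior, posterior, config.thickness_mode)

    apex_az = (
        math.atan2(apex_a.position[1], apex_a.position[0])
        if apex_a.deviation > 1e-9 else 0.0
    )
    tmin_az = (
        math.atan2(thick.anterior_point[1], thick.anterior_point[0])
        if thick.anterior_deviation > 1e-9 else 0.0
    )
    sag_apex = sagittal_section_area(solid, apex_az)
    sag_tmin = sagittal_section_area(solid, tmin_az)
    (cx, cy, cz), com_dev = center_of_mass(solid)

    axis_xy = thick.anterior_point[:2]
    cyl = [
        cylinder_intersection_volume(anterior, posterior, axis_xy, r, r_max=config.r_max)
        for r in config.cylinder_radii
    ]
    return MorphometryRecord(
        total_volume=vol,
        anterior_area=area_a, posterior_area=area_p, total_area=area_total,
        sagittal_apex_area=sag_apex, sagittal_min_thickness_area=sag_tmin,
        anterior_apex_deviation=apex_a.deviation,
        posterior_apex_deviation=apex_p.deviation,
        anterior_min_thickness_deviation=thick.anterior_deviation,
        posterior_min_thickness_deviation=thick.posterior_deviation,
        com_x=cx, com_y=cy, com_z=cz, com_xy_deviation=com_dev,
        cyl_volume_r05=cyl[0], cyl_volume_r10=cyl[1],
        cyl_volume_r15=cyl[2], cyl_volume_r20=cyl[3],
    )
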