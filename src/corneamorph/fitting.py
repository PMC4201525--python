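"""Penalized least-squares tensor-product B-spline fitting of corneal surfaces.

Over a 4 mm aperture each corneal surface is a graph ``z(x, y)`` over the
XY plane, so the commercial patch-surface step is reimplemented as a
height-field smoother: the fitted surface minimizes

    sum_k (z_k - z(x_k, y_k))^2  +  lambda^2 * J[z],
    J[z] = integral over the disc of (z_xx^2 + 2 z_xy^2 + z_yy^2),

i.e. squared vertical point-surface residuals plus a thin-plate bending
penalty.  ``z`` lives in the tensor product of clamped cubic B-spline
spaces on a square knot lattice covering the disc.  The stiffness
``lambda`` is a length (mm, default 1e-3): with z in mm the data term
carries mm^2 while J is dimensionless, so weighting the penalty by
lambda^2 is the unique dimensionally homogeneous choice, and lambda sets
the deformation scale below which the fit stops following the data —
``lambda -> inf`` collapses the fit onto the best affine plane.

The solver is exposed both as the scikit-learn style estimator
:class:`SplineSurfaceSmoother` and as the functional wrapper
:func:`fit_surface` operating on point clouds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.interpolate import BSpline
from sklearn.base import BaseEstimator, RegressorMixin

from .io import APERTURE_MM, PointCloud

#: residual classification thresholds (mm): good below, bad above
DEFAULT_THRESHOLDS = (1e-4, 1e-3)


class FitError(RuntimeError):
    pass


@dataclass(frozen=True)
class FitConfig:
    """Configuration of the spline smoother.

    ``spans_u``/``spans_v`` count knot spans per direction (the exported
    tool's maximum is 255; the default 64 is ample for a 4 mm aperture
    and much faster).  ``stiffness`` is the bending-penalty weight.
    ``sample_spacing`` is the number of points per ring used (256 keeps
    every export sample; smaller values subsample azimuthally).
    """

    spans_u: int = 64
    spans_v: int = 64
    degree: int = 3
    stiffness: float = 1e-3
    sample_spacing: int = 256

    def __post_init__(self) -> None:
        if min(self.spans_u, self.spans_v) < self.degree + 1:
            raise ValueError("span count must be at least degree + 1")
        if self.stiffness < 0:
            raise ValueError("stiffness must be >= 0")


def _uniform_clamped_knots(spans: int, degree: int, half: float) -> np.ndarray:
    interior = np.linspace(-half, half, spans + 1)
    return np.concatenate([
        np.full(degree, -half), interior, np.full(degree, half),
    ])


def _basis_values(t: np.ndarray, k: int, x: np.ndarray, nu: int = 0) -> np.ndarray:
    """Dense (len(x), n_basis) matrix of nu-th basis derivatives."""
    n = len(t) - k - 1
    b = BSpline(t, np.eye(n), k, extrapolate=False)
    if nu:
        b = b.derivative(nu)
    return np.nan_to_num(b(x))


def _gram(t: np.ndarray, k: int, nu: int) -> np.ndarray:
    """Gram matrix of nu-th derivatives, integrated exactly by Gauss quadrature."""
    n = len(t) - k - 1
    spans = np.unique(t)
    # products of two degree-(k - nu) pieces: degree <= 6, 4-point Gauss exact
    gx, gw = np.polynomial.legendre.leggauss(k + 1)
    G = np.zeros((n, n))
    for a, b in zip(spans[:-1], spans[1:]):
        mid, halfw = 0.5 * (a + b), 0.5 * (b - a)
        xs = mid + halfw * gx
        B = _basis_values(t, k, xs, nu)
        G += halfw * (B * gw[:, None]).T @ B
    return G


def _sparse_rows(t: np.ndarray, k: int, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-point nonzero basis values and their column indices, shape (npts, k+1)."""
    D = BSpline.design_matrix(x, t, k, extrapolate=False).tocsr()
    npts = len(x)
    return D.data.reshape(npts, k + 1), D.indices.reshape(npts, k + 1)


def _deriv_rows(t: np.ndarray, k: int, x: np.ndarray, nu: int,
                ix: np.ndarray) -> np.ndarray:
    """Values of the nu-th derivative of the k+1 active basis functions per point."""
    dense = _basis_values(t, k, x, nu)
    return dense[np.arange(len(x))[:, None], ix]


_PENALTY_CACHE: dict[tuple, sp.csr_matrix] = {}


def _penalty_matrix(tx: np.ndarray, ty: np.ndarray, k: int, aperture: float) -> sp.csr_matrix:
    """Bending-penalty matrix, integrated over the disc of the given aperture.

    The integration domain is the disc (the surface's actual domain), not
    the bounding square: integrating over the square's data-free corners
    would drag the fit flat near the aperture edge.  Quadrature is
    Gauss-Legendre radially and trapezoidal azimuthally, resolving the
    knot cells.
    """
    key = (tx.tobytes(), ty.tobytes(), k, float(aperture))
    if key in _PENALTY_CACHE:
        return _PENALTY_CACHE[key]
    nx, ny = len(tx) - k - 1, len(ty) - k - 1
    spans = max(len(np.unique(tx)), len(np.unique(ty))) - 1
    nr = max(96, 2 * spans + 32)
    ntheta = max(256, 4 * spans)
    gr, gw = np.polynomial.legendre.leggauss(nr)
    r = 0.5 * aperture * (gr + 1.0)
    wr = 0.5 * aperture * gw * r  # polar Jacobian
    th = np.arange(ntheta) * (2.0 * np.pi / ntheta)
    wth = 2.0 * np.pi / ntheta
    X = (r[:, None] * np.cos(th)[None, :]).ravel()
    Y = (r[:, None] * np.sin(th)[None, :]).ravel()
    W = (wr[:, None] * np.full(ntheta, wth)[None, :]).ravel()
    X = np.clip(X, -aperture, aperture)
    Y = np.clip(Y, -aperture, aperture)
    _, ix = _sparse_rows(tx, k, X)
    _, iy = _sparse_rows(ty, k, Y)
    npts, m = len(X), (k + 1) ** 2
    cols = (ix[:, :, None] * ny + iy[:, None, :]).reshape(npts, m)
    indptr = np.arange(npts + 1) * m

    def tensor_rows(nux: int, nuy: int) -> sp.csr_matrix:
        bx = _deriv_rows(tx, k, X, nux, ix)
        by = _deriv_rows(ty, k, Y, nuy, iy)
        data = (bx[:, :, None] * by[:, None, :]).reshape(npts, m)
        return sp.csr_matrix((data.ravel(), cols.ravel(), indptr), shape=(npts, nx * ny))

    Wd = sp.diags(W)
    P = sp.csr_matrix((nx * ny, nx * ny))
    Bxx = tensor_rows(2, 0)
    P = P + Bxx.T @ Wd @ Bxx
    Bxy = tensor_rows(1, 1)
    P = P + 2.0 * (Bxy.T @ Wd @ Bxy)
    Byy = tensor_rows(0, 2)
    P = P + Byy.T @ Wd @ Byy
    P = P.tocsr()
    _PENALTY_CACHE[key] = P
    return P


@dataclass
class FittedSurface:
    """Smooth tensor-product spline height field over the 4 mm disc."""

    surface_label: str
    knots_x: np.ndarray
    knots_y: np.ndarray
    coeffs: np.ndarray  # (n_basis_x, n_basis_y)
    degree: int = 3
    aperture: float = APERTURE_MM

    def __call__(self, x, y):
        return self.evaluate(x, y)

    def evaluate(self, x, y) -> np.ndarray:
        """Evaluate z(x, y) at scattered points (clamped to the bounding square)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        shape = np.broadcast_shapes(x.shape, y.shape)
        xf = np.clip(np.broadcast_to(x, shape).ravel(), -self.aperture, self.aperture)
        yf = np.clip(np.broadcast_to(y, shape).ravel(), -self.aperture, self.aperture)
        dx, ix = _sparse_rows(self.knots_x, self.degree, xf)
        dy, iy = _sparse_rows(self.knots_y, self.degree, yf)
        # z_i = sum_{a,b} dx[i,a] * C[ix[i,a], iy[i,b]] * dy[i,b]
        z = np.einsum("pa,pab,pb->p", dx, self.coeffs[ix[:, :, None], iy[:, None, :]], dy)
        out = z.reshape(shape)
        return out if shape else float(out)

    def bending_energy(self) -> float:
        """Integrated squared second derivatives of the field over the disc."""
        P = _penalty_matrix(self.knots_x, self.knots_y, self.degree, self.aperture)
        c = self.coeffs.ravel()
        return float(c @ (P @ c))

    def to_dict(self) -> dict:
        return {
            "surface_label": self.surface_label,
            "degree": int(self.degree),
            "aperture": float(self.aperture),
            "knots_x": self.knots_x.tolist(),
            "knots_y": self.knots_y.tolist(),
            "coeffs": self.coeffs.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedSurface":
        return cls(
            surface_label=d["surface_label"],
            knots_x=np.asarray(d["knots_x"], float),
            knots_y=np.asarray(d["knots_y"], float),
            coeffs=np.asarray(d["coeffs"], float),
            degree=int(d["degree"]),
            aperture=float(d.get("aperture", APERTURE_MM)),
        )

    def save(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict()))
        return path

    @classmethod
    def load(cls, path) -> "FittedSurface":
        return cls.from_dict(json.loads(Path(path).read_text()))


class SplineSurfaceSmoother(RegressorMixin, BaseEstimator):
    """Scikit-learn estimator form of the penalized spline height-field fit.

    Parameters mirror :class:`FitConfig`.  ``fit(X, z)`` takes ``X`` of
    shape (n, 2) holding (x, y) in mm and the elevations ``z``; the
    fitted field is available as ``surface_`` and through ``predict``.
    """

    def __init__(self, spans_u: int = 64, spans_v: int = 64, degree: int = 3,
                 stiffness: float = 1e-3, aperture: float = APERTURE_MM):
        self.spans_u = spans_u
        self.spans_v = spans_v
        self.degree = degree
        self.stiffness = stiffness
        self.aperture = aperture

    def fit(self, X, z, surface_label: str = "anterior"):
        X = np.asarray(X, dtype=float)
        z = np.asarray(z, dtype=float).ravel()
        if X.ndim != 2 or X.shape[1] != 2 or X.shape[0] != z.size:
            raise ValueError("X must be (n, 2) with matching z")
        if not (np.isfinite(X).all() and np.isfinite(z).all()):
            raise FitError("non-finite input")
        r = np.hypot(X[:, 0], X[:, 1])
        if np.any(r > self.aperture + 1e-9):
            raise FitError("input point outside the fitting aperture")
        k = self.degree
        tx = _uniform_clamped_knots(self.spans_u, k, self.aperture)
        ty = _uniform_clamped_knots(self.spans_v, k, self.aperture)
        nx, ny = len(tx) - k - 1, len(ty) - k - 1

        xs = np.clip(X[:, 0], -self.aperture, self.aperture)
        ys = np.clip(X[:, 1], -self.aperture, self.aperture)
        dx, ix = _sparse_rows(tx, k, xs)
        dy, iy = _sparse_rows(ty, k, ys)
        npts, m = X.shape[0], (k + 1) ** 2
        data = (dx[:, :, None] * dy[:, None, :]).reshape(npts, m)
        cols = (ix[:, :, None] * ny + iy[:, None, :]).reshape(npts, m)
        indptr = np.arange(npts + 1) * m
        A = sp.csr_matrix((data.ravel(), cols.ravel(), indptr), shape=(npts, nx * ny))

        AtA = (A.T @ A).tocsr()
        Atz = A.T @ z
        P = _penalty_matrix(tx, ty, k, self.aperture)
        system = (AtA + self.stiffness**2 * P).tocsc()
        # basis functions with neither data nor disc support (corner patches
        # fully outside the aperture) are excluded exactly and pinned to zero
        supported = (AtA.diagonal() > 0) | (P.diagonal() > 0)
        reduced = system[supported][:, supported]
        rhs = Atz[supported]
        try:
            lu = spla.splu(reduced)
        except RuntimeError as exc:
            raise FitError(
                "rank-deficient system at the requested span counts; "
                "reduce spans_u/spans_v or use stiffness > 0"
            ) from exc
        c = lu.solve(rhs)
        c += lu.solve(rhs - reduced @ c)  # one step of iterative refinement
        if not np.all(np.isfinite(c)):
            raise FitError(
                "rank-deficient system at the requested span counts; "
                "reduce spans_u/spans_v or use stiffness > 0"
            )
        coef = np.zeros(nx * ny)
        coef[supported] = c
        self.coef_ = coef.reshape(nx, ny)
        self.surface_ = FittedSurface(
            surface_label=surface_label, knots_x=tx, knots_y=ty,
            coeffs=self.coef_, degree=k, aperture=self.aperture,
        )
        self.n_features_in_ = 2
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "surface_"):
            raise FitError("estimator is not fitted")
        X = np.asarray(X, dtype=float)
        return self.surface_.evaluate(X[:, 0], X[:, 1])


def fit_surface(cloud: PointCloud, config: FitConfig | None = None) -> FittedSurface:
    """Fit the smoothing spline to one surface's point cloud.

    Coincident apex samples are collapsed (averaged) first; azimuthal
    subsampling is applied when ``config.sample_spacing`` < 256.
    """
    config = config or FitConfig()
    cloud = cloud.deduplicated()
    pts = cloud.points
    if config.sample_spacing < 256:
        stride = max(1, 256 // config.sample_spacing)
        pts = pts[::stride]
    est = SplineSurfaceSmoother(
        spans_u=config.spans_u, spans_v=config.spans_v,
        degree=config.degree, stiffness=config.stiffness,
    )
    est.fit(pts[:, :2], pts[:, 2], surface_label=cloud.surface_label)
    return est.surface_


@dataclass
class ResidualReport:
    """Vertical point-surface residuals with good/intermediate/bad counts."""

    mean: float
    sd: float
    residuals: np.ndarray
    n_good: int
    n_intermediate: int
    n_bad: int
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS

    @property
    def counts(self) -> tuple[int, int, int]:
        return (self.n_good, self.n_intermediate, self.n_bad)


def point_surface_residuals(
    surface: FittedSurface,
    cloud: PointCloud,
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
) -> ResidualReport:
    """Distance-error report: residual = |z_k - z(x_k, y_k)| per point.

    Points with residual below ``thresholds[0]`` are "good", above
    ``thresholds[1]`` "bad", the rest intermediate.
    """
    lo, hi = thresholds
    if not lo < hi:
        raise ValueError("thresholds must be increasing")
    pts = cloud.points
    r = np.hypot(pts[:, 0], pts[:, 1])
    if np.any(r > surface.aperture + 1e-9):
        raise ValueError("point outside the fitted disc")
    res = np.abs(pts[:, 2] - surface.evaluate(pts[:, 0], pts[:, 1]))
    n_good = int((res < lo).sum())
    n_bad = int((res > hi).sum())
    sd = float(res.std(ddof=1)) if len(res) > 1 else 0.0
    return ResidualReport(
        mean=float(res.mean()), sd=sd, residuals=res,
        n_good=n_good, n_bad=n_bad,
        n_intermediate=len(res) - n_good - n_bad,
        thresholds=(lo, hi),
    )
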