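"""Synthetic anterior/posterior corneal surfaces with known ground truth.

No deposited topographer exports exist, so every downstream stage is
exercised on corneas generated from a standard ophthalmic model: each
surface is a conicoid (apical radius R, asphericity Q) whose sagitta is

    s(r; R, Q) = r^2 / (R + sqrt(R^2 - (1 + Q) r^2)),

with the instrument axis as Z, positive pointing posteriorly (into the
eye).  Keratoconus is emulated as a decentered Gaussian ectasia: the
anterior surface protrudes anteriorly by ``A * exp(-d^2 / (2 sigma^2))``
(d = in-plane distance to the cone center), the posterior surface follows
the bump with amplitude ``(1 + f) * A`` so the stroma thins locally by the
fraction ``f`` of the bump.  Severity presets additionally steepen both
surfaces and reduce central thickness, following the magnitudes clinicians
report for Amsler-Krumeich stages I to IV.

Ground-truth apex and minimum-thickness locations are computed from the
closed forms by 2D optimization, so recovery by the reconstruction
pipeline can be checked exactly.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import optimize

from .io import (
    APERTURE_MM,
    N_AZIMUTH,
    N_RINGS,
    RING_STEP_MM,
    PolarGrid,
    write_polar_csv,
)

STAGES = ("I", "II", "III-IV")
#: severity mix of the modeled cohort: stage I / II / III-IV shares
DEFAULT_SEVERITY_MIX = (0.512, 0.366, 0.122)


class GenerationError(RuntimeError):
    """Raised when requested parameters produce a non-physical cornea."""


@dataclass(frozen=True)
class CorneaParams:
    """Generative parameters for one synthetic eye (all lengths in mm)."""

    R_ant: float = 7.8          # anterior apical radius
    Q_ant: float = -0.26        # anterior asphericity
    R_post: float = 6.5         # posterior apical radius
    Q_post: float = -0.30       # posterior asphericity
    t0: float = 0.55            # central thickness
    bump_amplitude: float = 0.0  # ectasia amplitude A; 0 = healthy
    bump_center: tuple[float, float] = (0.0, 0.0)
    bump_sigma: float = 0.8     # ectasia Gaussian width
    thinning_fraction: float = 0.0  # local stromal thinning fraction f
    noise_sd: float = 0.0       # cell-wise measurement noise
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("R_ant", "R_post"):
            R = getattr(self, name)
            if R <= APERTURE_MM:
                raise ValueError(f"{name} must exceed the 4 mm aperture, got {R}")
        if self.t0 <= 0:
            raise ValueError("central thickness must be positive")
        if self.bump_amplitude < 0:
            raise ValueError("bump amplitude must be >= 0")
        if self.bump_amplitude > 0 and self.bump_sigma <= 0:
            raise ValueError("bump sigma must be positive when amplitude > 0")
        if not 0.0 <= self.thinning_fraction < 1.0:
            raise ValueError("thinning fraction must lie in [0, 1)")


@dataclass
class GroundTruth:
    """Analytic reference quantities for a generated eye."""

    params: CorneaParams
    anterior_apex_xy: tuple[float, float]
    posterior_apex_xy: tuple[float, float]
    min_thickness_xy: tuple[float, float]
    min_thickness_mm: float

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=1)


def conicoid_sagitta(r, R: float, Q: float):
    """Sagitta of a conicoid of apical radius R and asphericity Q at radius r."""
    r = np.asarray(r, dtype=float)
    disc = R * R - (1.0 + Q) * r * r
    if np.any(disc < 0):
        raise ValueError("conicoid undefined at requested radius")
    return r * r / (R + np.sqrt(disc))


def _bump(x, y, params: CorneaParams):
    if params.bump_amplitude == 0.0:
        return np.zeros_like(np.asarray(x, dtype=float))
    x0, y0 = params.bump_center
    d2 = (np.asarray(x) - x0) ** 2 + (np.asarray(y) - y0) ** 2
    return params.bump_amplitude * np.exp(-d2 / (2.0 * params.bump_sigma**2))


def anterior_height(x, y, params: CorneaParams):
    """Closed-form anterior elevation z_a(x, y); the bump subtracts (protrudes anteriorly)."""
    r = np.hypot(x, y)
    return conicoid_sagitta(r, params.R_ant, params.Q_ant) - _bump(x, y, params)


def posterior_height(x, y, params: CorneaParams):
    """Closed-form posterior elevation z_p(x, y)."""
    r = np.hypot(x, y)
    s = conicoid_sagitta(r, params.R_post, params.Q_post)
    return params.t0 + s - (1.0 + params.thinning_fraction) * _bump(x, y, params)


def thickness(x, y, params: CorneaParams):
    """Axial thickness z_p - z_a of the closed-form model."""
    return posterior_height(x, y, params) - anterior_height(x, y, params)


def _minimize_on_disc(fun, seed_xy: tuple[float, float]) -> tuple[float, float]:
    """Nelder-Mead refinement of a closed form, constrained to the 4 mm disc."""

    def penalized(p):
        r = math.hypot(p[0], p[1])
        if r > APERTURE_MM:
            return fun(APERTURE_MM * p[0] / r, APERTURE_MM * p[1] / r) + (r - APERTURE_MM)
        return fun(p[0], p[1])

    res = optimize.minimize(
        penalized, seed_xy, method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 2000},
    )
    return float(res.x[0]), float(res.x[1])


def _grid_seed(fun) -> tuple[float, float]:
    r = np.linspace(0, APERTURE_MM, 81)
    th = np.linspace(0, 2 * math.pi, 128, endpoint=False)
    rr, tt = np.meshgrid(r, th, indexing="ij")
    x, y = rr * np.cos(tt), rr * np.sin(tt)
    vals = fun(x, y)
    # ties broken toward the center, then smaller azimuth
    flat = np.argsort(vals.ravel(), kind="stable")
    best = flat[0]
    vmin = vals.ravel()[best]
    near = np.nonzero(vals.ravel() <= vmin + 1e-13)[0]
    order = np.lexsort((tt.ravel()[near], rr.ravel()[near]))
    k = near[order[0]]
    return float(x.ravel()[k]), float(y.ravel()[k])


def ground_truth(params: CorneaParams) -> GroundTruth:
    """Analytic apex and minimum-thickness locations of the noise-free model."""
    ant = lambda x, y: anterior_height(x, y, params)
    post = lambda x, y: posterior_height(x, y, params)
    thick = lambda x, y: thickness(x, y, params)
    if params.bump_amplitude == 0.0:
        apex_a = apex_p = tmin_xy = (0.0, 0.0)
    else:
        apex_a = _minimize_on_disc(ant, _grid_seed(np.vectorize(ant)))
        apex_p = _minimize_on_disc(post, _grid_seed(np.vectorize(post)))
        tmin_xy = _minimize_on_disc(thick, _grid_seed(np.vectorize(thick)))
    return GroundTruth(
        params=params,
        anterior_apex_xy=apex_a,
        posterior_apex_xy=apex_p,
        min_thickness_xy=tmin_xy,
        min_thickness_mm=float(thickness(*tmin_xy, params)),
    )


def generate_cornea(params: CorneaParams) -> tuple[PolarGrid, PolarGrid, GroundTruth]:
    """Sample the closed-form eye on the 21 x 256 export lattice.

    Gaussian measurement noise of sd ``noise_sd`` is added cell-wise
    (reproducibly from ``seed``).  Raises :class:`GenerationError` if the
    noise-free surfaces intersect anywhere on the disc.
    """
    r = np.arange(N_RINGS)[:, None] * RING_STEP_MM
    th = np.arange(N_AZIMUTH)[None, :] * (2.0 * math.pi / N_AZIMUTH)
    x = r * np.cos(th)
    y = r * np.sin(th)

    # thickness positivity on a fine grid plus the analytic minimum
    gt = ground_truth(params)
    rf = np.linspace(0, APERTURE_MM, 161)[:, None]
    tf = np.linspace(0, 2 * math.pi, 256, endpoint=False)[None, :]
    tmap = thickness(rf * np.cos(tf), rf * np.sin(tf), params)
    if tmap.min() <= 0 or gt.min_thickness_mm <= 0:
        raise GenerationError("anterior and posterior surfaces intersect on the disc")

    za = anterior_height(x, y, params)
    zp = posterior_height(x, y, params)
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        za = za + rng.normal(0.0, params.noise_sd, za.shape)
        zp = zp + rng.normal(0.0, params.noise_sd, zp.shape)
    return PolarGrid("anterior", za), PolarGrid("posterior", zp), gt


# ---------------------------------------------------------------------------
# cohort presets
# ---------------------------------------------------------------------------

#: per-stage parameter distributions.  Healthy values are conventional
#: ophthalmic magnitudes; keratoconic stages steepen both surfaces
#: (Amsler-Krumeich keratometry bands), reduce central thickness, and
#: escalate the ectasia bump and its local thinning.
PRESETS: dict[str, dict] = {
    "healthy": dict(R_ant=(7.8, 0.25), Q_ant=(-0.26, 0.08), R_post=(6.5, 0.20),
                    Q_post=(-0.30, 0.08), t0=(0.55, 0.03),
                    A=(0.0, 0.0), f=(0.0, 0.0), sigma=(0.8, 0.8), r0=(0.0, 0.0)),
    "I": dict(R_ant=(7.3, 0.15), Q_ant=(-0.35, 0.08), R_post=(6.1, 0.15),
              Q_post=(-0.40, 0.08), t0=(0.52, 0.02),
              A=(0.06, 0.10), f=(0.55, 0.65), sigma=(0.7, 1.0), r0=(0.5, 1.5)),
    "II": dict(R_ant=(6.8, 0.15), Q_ant=(-0.45, 0.08), R_post=(5.7, 0.15),
               Q_post=(-0.50, 0.08), t0=(0.49, 0.02),
               A=(0.10, 0.16), f=(0.60, 0.70), sigma=(0.7, 1.0), r0=(0.5, 1.5)),
    "III-IV": dict(R_ant=(6.3, 0.15), Q_ant=(-0.55, 0.08), R_post=(5.2, 0.15),
                   Q_post=(-0.60, 0.08), t0=(0.45, 0.02),
                   A=(0.16, 0.26), f=(0.65, 0.75), sigma=(0.7, 1.0), r0=(0.5, 1.5)),
}

#: default measurement-noise sd, mm (a couple of microns, Scheimpflug-like)
DEFAULT_NOISE_SD = 0.002


def expected_bump_amplitude(stage: str) -> float:
    lo, hi = PRESETS[stage]["A"]
    return 0.5 * (lo + hi)


def draw_params(stage: str, rng: np.random.Generator, *, noise_sd: float = DEFAULT_NOISE_SD) -> CorneaParams:
    """Draw one eye's parameters from the stage preset distributions."""
    p = PRESETS[stage]
    normal = lambda key: float(rng.normal(*p[key]))
    unif = lambda key: float(rng.uniform(*p[key]))
    if stage == "healthy":
        A, f, sigma, center = 0.0, 0.0, 0.8, (0.0, 0.0)
    else:
        A, f, sigma = unif("A"), unif("f"), unif("sigma")
        r0 = unif("r0")
        ang = float(rng.uniform(0.0, 2.0 * math.pi))
        center = (r0 * math.cos(ang), r0 * math.sin(ang))
    return CorneaParams(
        R_ant=max(normal("R_ant"), 5.0), Q_ant=normal("Q_ant"),
        R_post=max(normal("R_post"), 4.5), Q_post=normal("Q_post"),
        t0=max(normal("t0"), 0.35),
        bump_amplitude=A, bump_center=center, bump_sigma=sigma,
        thinning_fraction=f, noise_sd=noise_sd,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def largest_remainder_allocation(n: int, shares: tuple[float, ...]) -> list[int]:
    """Allocate n items to shares by the largest-remainder rule."""
    if not math.isclose(sum(shares), 1.0, abs_tol=1e-9):
        raise ValueError("severity mix must sum to 1")
    quotas = [n * s for s in shares]
    counts = [int(math.floor(q)) for q in quotas]
    remainder = n - sum(counts)
    order = sorted(range(len(shares)), key=lambda k: quotas[k] - counts[k], reverse=True)
    for k in order[:remainder]:
        counts[k] += 1
    return counts


@dataclass
class SyntheticEye:
    """One labeled cohort member."""

    eye_id: str
    label: int           # 0 healthy, 1 keratoconus
    stage: str           # "healthy" or an Amsler-Krumeich stratum
    params: CorneaParams
    anterior: PolarGrid
    posterior: PolarGrid
    truth: GroundTruth


def generate_cohort(
    n_healthy: int,
    n_kc: int,
    severity_mix: tuple[float, float, float] = DEFAULT_SEVERITY_MIX,
    seed: int = 0,
    *,
    noise_sd: float = DEFAULT_NOISE_SD,
) -> list[SyntheticEye]:
    """Generate a labeled cohort, fully reproducible from ``seed``."""
    rng = np.random.default_rng(seed)
    counts = largest_remainder_allocation(n_kc, tuple(severity_mix))
    plan = [("healthy", 0)] * n_healthy + [
        (stage, 1) for stage, c in zip(STAGES, counts) for _ in range(c)
    ]
    eyes = []
    for k, (stage, label) in enumerate(plan):
        params = draw_params(stage, rng, noise_sd=noise_sd)
        ant, post, gt = generate_cornea(params)
        eyes.append(SyntheticEye(f"eye{k:03d}", label, stage, params, ant, post, gt))
    return eyes


def write_cohort(eyes: list[SyntheticEye], out_dir) -> Path:
    """Write per-eye polar CSVs, ground-truth sidecars, and a manifest CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = ["eye_id,label,stage,anterior_csv,posterior_csv,truth_json"]
    for eye in eyes:
        a = out_dir / f"{eye.eye_id}_anterior.csv"
        p = out_dir / f"{eye.eye_id}_posterior.csv"
        t = out_dir / f"{eye.eye_id}_truth.json"
        write_polar_csv(eye.anterior, a)
        write_polar_csv(eye.posterior, p)
        t.write_text(eye.truth.to_json())
        rows.append(f"{eye.eye_id},{eye.label},{eye.stage},{a.name},{p.name},{t.name}")
    manifest = out_dir / "cohort.csv"
    manifest.write_text("\n".join(rows) + "\n")
    return manifest
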