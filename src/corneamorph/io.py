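"""Reading and writing the topographer polar-export dialect.

The Scheimpflug/Placido topographer exports each corneal surface (anterior,
posterior) as a CSV matrix of elevations in mm sampled on a fixed polar
lattice: row ``i`` is the ring of radius ``i * 0.2`` mm and column ``j`` the
semi-meridian at azimuth ``j * 360 / 256`` degrees.  The reconstruction
region is the central disc of radius 4 mm, i.e. the first 21 rings; rings
beyond that are trimmed on read.  A complete surface therefore carries
``21 * 256 = 5376`` samples (the 256 cells of ring 0 all describe the apex
point and are deduplicated only when a surface is fitted).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: number of semi-meridians per ring in the export
N_AZIMUTH = 256
#: radial step between consecutive rings, mm
RING_STEP_MM = 0.2
#: aperture radius of the reconstruction region, mm
APERTURE_MM = 4.0
#: rings with r <= 4 mm (i = 0 .. 20)
N_RINGS = int(round(APERTURE_MM / RING_STEP_MM)) + 1
#: plausibility window for elevations, mm
MAX_ABS_ELEVATION_MM = 10.0

SURFACE_LABELS = ("anterior", "posterior")


class PolarFormatError(ValueError):
    """Raised when a polar-export file violates the lattice dialect."""


@dataclass
class PolarGrid:
    """Per-surface elevation matrix on the ring x semi-meridian lattice.

    ``elevations`` has shape (21, 256); missing cells are NaN.
    """

    surface_label: str
    elevations: np.ndarray

    def __post_init__(self) -> None:
        if self.surface_label not in SURFACE_LABELS:
            raise ValueError(f"unknown surface label {self.surface_label!r}")
        self.elevations = np.asarray(self.elevations, dtype=float)
        if self.elevations.shape != (N_RINGS, N_AZIMUTH):
            raise PolarFormatError(
                f"elevation matrix must be {N_RINGS}x{N_AZIMUTH}, "
                f"got {self.elevations.shape}"
            )
        finite = self.elevations[np.isfinite(self.elevations)]
        if finite.size and np.abs(finite).max() >= MAX_ABS_ELEVATION_MM:
            raise PolarFormatError(
                f"elevations outside plausibility window |z| < {MAX_ABS_ELEVATION_MM} mm"
            )

    @property
    def ring_radii(self) -> np.ndarray:
        """Radii r_i = i * 0.2 mm of the 21 retained rings."""
        return np.arange(N_RINGS) * RING_STEP_MM

    @property
    def azimuths_rad(self) -> np.ndarray:
        """Azimuths theta_j = j * 2 pi / 256, counter-clockwise from +X."""
        return np.arange(N_AZIMUTH) * (2.0 * math.pi / N_AZIMUTH)

    def n_finite(self) -> int:
        return int(np.isfinite(self.elevations).sum())

    def missing_cells(self) -> list[tuple[int, int]]:
        ii, jj = np.nonzero(~np.isfinite(self.elevations))
        return list(zip(ii.tolist(), jj.tolist()))


@dataclass
class PointCloud:
    """Cartesian (x, y, z) samples in mm for one corneal surface."""

    surface_label: str
    points: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[1] != 3:
            raise ValueError("points must be (n, 3)")

    def __len__(self) -> int:
        return self.points.shape[0]

    def deduplicated(self) -> "PointCloud":
        """Collapse coincident apex samples (ring 0) to one point.

        The 256 cells of the degenerate center ring all describe the same
        spatial point; their z values (which may differ under measurement
        noise) are averaged.
        """
        r = np.hypot(self.points[:, 0], self.points[:, 1])
        central = r < 1e-12
        if central.sum() <= 1:
            return PointCloud(self.surface_label, self.points.copy())
        z0 = self.points[central, 2].mean()
        kept = self.points[~central]
        pts = np.vstack([[0.0, 0.0, z0], kept])
        return PointCloud(self.surface_label, pts)


@dataclass
class ValidationReport:
    """Aperture-completeness verdict for one polar grid."""

    complete_within_4mm: bool
    missing_cells: list[tuple[int, int]] = field(default_factory=list)

    @property
    def verdict(self) -> str:
        return "accept" if self.complete_within_4mm else "discard"


def _parse_cell(token: str, missing_sentinels: tuple[str, ...]) -> float:
    tok = token.strip()
    if tok in missing_sentinels:
        return math.nan
    try:
        return float(tok)
    except ValueError as exc:
        raise PolarFormatError(f"unparsable cell {token!r}") from exc


def _looks_like_header(tokens: list[str], missing_sentinels: tuple[str, ...]) -> bool:
    for tok in tokens:
        tok = tok.strip()
        if tok in missing_sentinels:
            continue
        try:
            float(tok)
        except ValueError:
            return True
    return False


def _read_blocks(path: Path) -> list[list[str]]:
    """Split a polar CSV into blank-line-separated blocks of raw lines."""
    blocks: list[list[str]] = []
    current: list[str] = []
    for line in path.read_text().splitlines():
        if line.strip() == "":
            if current:
                blocks.append(current)
                current = []
        else:
            current.append(line)
    if current:
        blocks.append(current)
    return blocks


def read_polar_grid(
    path,
    surface_label: str,
    *,
    missing_sentinels: tuple[str, ...] = ("", "nan", "NaN", "-1000"),
) -> PolarGrid:
    """Read one surface's elevation matrix from a polar-export CSV.

    Accepts a one-surface file or a two-block file (anterior block first,
    posterior second, separated by a blank line).  Rings beyond the 4 mm
    aperture are dropped; rings absent from the file are recorded as
    missing.  Raises :class:`PolarFormatError` on a row with the wrong
    column count or an unparsable cell, naming its location.
    """
    path = Path(path)
    if surface_label not in SURFACE_LABELS:
        raise ValueError(f"unknown surface label {surface_label!r}")
    blocks = _read_blocks(path)
    if not blocks:
        raise PolarFormatError(f"{path}: empty file")
    if len(blocks) == 1:
        lines = blocks[0]
    elif len(blocks) == 2:
        lines = blocks[SURFACE_LABELS.index(surface_label)]
    else:
        raise PolarFormatError(f"{path}: expected 1 or 2 surface blocks, got {len(blocks)}")

    rows = [line.split(",") for line in lines]
    if rows and _looks_like_header(rows[0], missing_sentinels):
        rows = rows[1:]

    mat = np.full((N_RINGS, N_AZIMUTH), np.nan)
    for i, tokens in enumerate(rows):
        if i >= N_RINGS:
            break  # rings beyond the 4 mm aperture are ignored
        if len(tokens) != N_AZIMUTH:
            raise PolarFormatError(
                f"{path}: row {i} has {len(tokens)} columns, expected {N_AZIMUTH}"
            )
        for j, tok in enumerate(tokens):
            try:
                mat[i, j] = _parse_cell(tok, missing_sentinels)
            except PolarFormatError as exc:
                raise PolarFormatError(f"{path}: row {i}, column {j}: {exc}") from None
    return PolarGrid(surface_label, mat)


def write_polar_csv(grid: PolarGrid, path, *, missing_token: str = "") -> Path:
    """Write a grid in the export dialect; round-trips bit-exactly."""
    path = Path(path)
    lines = []
    for i in range(N_RINGS):
        cells = []
        for j in range(N_AZIMUTH):
            z = grid.elevations[i, j]
            cells.append(missing_token if not np.isfinite(z) else np.format_float_positional(z, unique=True))
        lines.append(",".join(cells))
    path.write_text("\n".join(lines) + "\n")
    return path


def write_eye_csv(anterior: PolarGrid, posterior: PolarGrid, path) -> Path:
    """Write both surfaces of one eye as a two-block polar CSV."""
    path = Path(path)
    blocks = []
    for grid in (anterior, posterior):
        rows = []
        for i in range(N_RINGS):
            rows.append(
                ",".join(
                    "" if not np.isfinite(z) else np.format_float_positional(z, unique=True)
                    for z in grid.elevations[i]
                )
            )
        blocks.append("\n".join(rows))
    path.write_text("\n\n".join(blocks) + "\n")
    return path


def polar_to_cartesian(grid: PolarGrid) -> PointCloud:
    """Map every finite lattice cell (i, j) to (r_i cos theta_j, r_i sin theta_j, z_ij)."""
    r = grid.ring_radii[:, None]
    th = grid.azimuths_rad[None, :]
    x = r * np.cos(th)
    y = r * np.sin(th)
    z = grid.elevations
    finite = np.isfinite(z)
    pts = np.column_stack([x[finite], y[finite], z[finite]])
    return PointCloud(grid.surface_label, pts)


def validate_aperture(grid: PolarGrid) -> ValidationReport:
    """Apply the completeness rule: any missing cell within r <= 4 mm discards the eye."""
    missing = grid.missing_cells()
    return ValidationReport(complete_within_4mm=not missing, missing_cells=missing)


def write_xyz(cloud: PointCloud, path) -> Path:
    """Write the point cloud as whitespace-separated XYZ text."""
    path = Path(path)
    np.savetxt(path, cloud.points, fmt="%.12g")
    return path


def write_ply_points(cloud: PointCloud, path) -> Path:
    """Write the point cloud as an ascii PLY vertex list."""
    path = Path(path)
    n = len(cloud)
    header = (
        "ply\nformat ascii 1.0\n"
        f"comment corneamorph {cloud.surface_label} surface point cloud\n"
        f"element vertex {n}\n"
        "property double x\nproperty double y\nproperty double z\n"
        "end_header\n"
    )
    body = "\n".join(" ".join(f"{v:.12g}" for v in p) for p in cloud.points)
    path.write_text(header + body + "\n")
    return path
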