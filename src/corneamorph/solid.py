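"""Closed solid assembly of the two fitted corneal surfaces.

The anterior and posterior height fields are sampled on a shared polar
mesh (rings x sectors, triangle fan at the pole), and the two caps are
closed by a ruled perimetric band between the boundary circles at the
aperture radius.  The result is a watertight, consistently outward-
oriented triangle mesh with per-face labels, suitable for exact
divergence-theorem volume and first-moment integration.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh

from .io import APERTURE_MM
from .fitting import FittedSurface

FACE_LABELS = ("anterior", "posterior", "perimetric")
#: minimum admissible corneal thickness, mm (1 micron)
MIN_THICKNESS_MM = 1e-3


class SolidModelError(RuntimeError):
    pass


@dataclass
class SolidModel:
    """Watertight labeled triangle mesh of one cornea."""

    mesh: trimesh.Trimesh
    face_labels: np.ndarray  # int codes indexing FACE_LABELS
    n_rings: int
    n_sectors: int

    def faces_with_label(self, label: str) -> np.ndarray:
        code = FACE_LABELS.index(label)
        return np.nonzero(self.face_labels == code)[0]

    def label_area(self, label: str) -> float:
        return float(self.mesh.area_faces[self.faces_with_label(label)].sum())

    @property
    def euler_characteristic(self) -> int:
        return int(self.mesh.euler_number)

    def is_watertight(self) -> bool:
        return bool(self.mesh.is_watertight)


def _cap_vertices(surface: FittedSurface, r_max: float, n_rings: int, n_sectors: int) -> np.ndarray:
    """Pole vertex followed by ring-major (ring, sector) grid vertices."""
    radii = np.arange(1, n_rings + 1) * (r_max / n_rings)
    th = np.arange(n_sectors) * (2.0 * np.pi / n_sectors)
    x = (radii[:, None] * np.cos(th)[None, :]).ravel()
    y = (radii[:, None] * np.sin(th)[None, :]).ravel()
    z = surface.evaluate(x, y)
    pole = np.array([[0.0, 0.0, float(surface.evaluate(0.0, 0.0))]])
    return np.vstack([pole, np.column_stack([x, y, z])])


def _cap_faces(n_rings: int, n_sectors: int, offset: int, flip: bool) -> np.ndarray:
    """Fan + quad-strip triangulation of one cap; `flip` reverses winding."""
    faces = []
    ring0 = offset + 1  # first ring starts after the pole vertex
    for j in range(n_sectors):
        jn = (j + 1) % n_sectors
        faces.append([offset, ring0 + j, ring0 + jn])
    for i in range(n_rings - 1):
        a = ring0 + i * n_sectors
        b = ring0 + (i + 1) * n_sectors
        for j in range(n_sectors):
            jn = (j + 1) % n_sectors
            faces.append([a + j, b + j, b + jn])
            faces.append([a + j, b + jn, a + jn])
    faces = np.asarray(faces, dtype=np.int64)
    if flip:
        faces = faces[:, ::-1]
    return faces


def build_solid(
    anterior: FittedSurface,
    posterior: FittedSurface,
    r_max: float = APERTURE_MM,
    density: tuple[int, int] = (128, 256),
    *,
    min_thickness: float = MIN_THICKNESS_MM,
) -> SolidModel:
    """Assemble the closed corneal solid from the two fitted surfaces.

    ``density`` is (radial rings, angular sectors).  With Z positive
    posterior, the posterior cap faces +Z (outward), the anterior cap -Z.
    Raises :class:`SolidModelError` if the surfaces come closer than
    ``min_thickness`` anywhere (reporting the offending location), or if
    the assembled mesh is not watertight.
    """
    n_rings, n_sectors = density
    if n_rings < 1 or n_sectors < 3:
        raise ValueError("density must be at least (1, 3)")

    # intersection guard on the sampling lattice
    radii = np.concatenate([[0.0], np.arange(1, n_rings + 1) * (r_max / n_rings)])
    th = np.arange(n_sectors) * (2.0 * np.pi / n_sectors)
    xg = radii[:, None] * np.cos(th)[None, :]
    yg = radii[:, None] * np.sin(th)[None, :]
    thick = posterior.evaluate(xg, yg) - anterior.evaluate(xg, yg)
    if thick.min() < min_thickness:
        i, j = np.unravel_index(int(thick.argmin()), thick.shape)
        raise SolidModelError(
            f"surfaces intersect (thickness {thick.min():.3g} mm) at "
            f"r = {radii[i]:.3f} mm, theta = {np.degrees(th[j]):.1f} deg"
        )

    va = _cap_vertices(anterior, r_max, n_rings, n_sectors)
    vp = _cap_vertices(posterior, r_max, n_rings, n_sectors)
    na = va.shape[0]
    vertices = np.vstack([va, vp])

    # anterior cap: outward normal points -Z, needs flipped winding
    fa = _cap_faces(n_rings, n_sectors, 0, flip=True)
    fp = _cap_faces(n_rings, n_sectors, na, flip=False)

    # ruled band between the boundary rings at equal theta, outward radial
    a0 = 1 + (n_rings - 1) * n_sectors           # anterior boundary ring start
    p0 = na + 1 + (n_rings - 1) * n_sectors      # posterior boundary ring start
    band = []
    for j in range(n_sectors):
        jn = (j + 1) % n_sectors
        band.append([a0 + j, p0 + jn, p0 + j])
        band.append([a0 + j, a0 + jn, p0 + jn])
    fb = np.asarray(band, dtype=np.int64)

    faces = np.vstack([fa, fp, fb])
    labels = np.concatenate([
        np.full(len(fa), FACE_LABELS.index("anterior")),
        np.full(len(fp), FACE_LABELS.index("posterior")),
        np.full(len(fb), FACE_LABELS.index("perimetric")),
    ])
    mesh = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    if not mesh.is_watertight:
        raise SolidModelError("internal error: assembled mesh is not watertight")
    if mesh.volume <= 0:
        raise SolidModelError("internal error: assembled mesh is not outward-oriented")
    return SolidModel(mesh=mesh, face_labels=labels, n_rings=n_rings, n_sectors=n_sectors)


def export_mesh(solid: SolidModel, path, fmt: str | None = None) -> Path:
    """Export as binary STL or ascii PLY (PLY keeps the face ``label`` property)."""
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "stl":
        path.write_bytes(trimesh.exchange.stl.export_stl(solid.mesh))
    elif fmt == "ply":
        _write_labeled_ply(solid, path)
    else:
        raise ValueError(f"unknown mesh format {fmt!r}")
    return path


def _write_labeled_ply(solid: SolidModel, path: Path) -> None:
    v, f = solid.mesh.vertices, solid.mesh.faces
    lines = [
        "ply", "format ascii 1.0",
        "comment corneamorph corneal solid; face label codes: "
        + ", ".join(f"{i}={name}" for i, name in enumerate(FACE_LABELS)),
        f"element vertex {len(v)}",
        "property double x", "property double y", "property double z",
        f"element face {len(f)}",
        "property list uchar int vertex_indices",
        "property uchar label",
        "end_header",
    ]
    lines += [" ".join(f"{c:.17g}" for c in p) for p in v]
    lines += [
        f"3 {a} {b} {c} {lab}"
        for (a, b, c), lab in zip(f, solid.face_labels)
    ]
    path.write_text("\n".join(lines) + "\n")


def load_labeled_ply(path) -> SolidModel:
    """Re-import a labeled ascii PLY written by :func:`export_mesh`."""
    lines = Path(path).read_text().splitlines()
    try:
        end = lines.index("end_header")
    except ValueError:
        raise SolidModelError(f"{path}: missing PLY header")
    nv = nf = 0
    for line in lines[:end]:
        parts = line.split()
        if parts[:2] == ["element", "vertex"]:
            nv = int(parts[2])
        elif parts[:2] == ["element", "face"]:
            nf = int(parts[2])
    verts = np.array([[float(t) for t in lines[end + 1 + i].split()] for i in range(nv)])
    faces, labels = [], []
    for i in range(nf):
        parts = lines[end + 1 + nv + i].split()
        faces.append([int(parts[1]), int(parts[2]), int(parts[3])])
        labels.append(int(parts[4]))
    mesh = trimesh.Trimesh(vertices=verts, faces=np.asarray(faces), process=False)
    return SolidModel(
        mesh=mesh, face_labels=np.asarray(labels), n_rings=0, n_sectors=0,
    )


def mesh_stats(solid: SolidModel) -> dict:
    """Summary statistics of the solid (for JSON manifests)."""
    m = solid.mesh
    return {
        "n_vertices": int(len(m.vertices)),
        "n_faces": int(len(m.faces)),
        "watertight": solid.is_watertight(),
        "euler_characteristic": solid.euler_characteristic,
        "volume_mm3": float(m.volume),
        "total_area_mm2": float(m.area),
        "area_anterior_mm2": solid.label_area("anterior"),
        "area_posterior_mm2": solid.label_area("posterior"),
        "area_perimetric_mm2": solid.label_area("perimetric"),
    }
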