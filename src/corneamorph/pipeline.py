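"""End-to-end orchestration: polar CSVs -> surfaces -> solid -> record -> tables.

Functions here are shared by the command-line interface and by batch
analyses.  Per-eye reconstruction applies the aperture-completeness rule
(an eye with any missing sample inside the 4 mm radius is discarded, not
fatal for the cohort) and the cohort analysis emits the four table
shapes of the diagnostic battery.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .fitting import FitConfig, FittedSurface, ResidualReport, fit_surface, point_surface_residuals
from .morphometry import MorphometryConfig, MorphometryRecord, compute_morphometry
from .solid import SolidModel, build_solid
from .stats import cohort_report


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration (desk-scale defaults).

    Fitting spans and mesh density are set for cohort throughput; raise
    them (e.g. spans 64+, density (128, 256)) for single-eye precision
    work.
    """

    spans: int = 32
    degree: int = 3
    stiffness: float = 1e-3
    density: tuple[int, int] = (64, 256)
    cylinder_radii: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0)
    thickness_mode: str = "axial"
    seed: int = 0

    def __post_init__(self) -> None:
        radii = tuple(self.cylinder_radii)
        if any(r <= 0 for r in radii) or list(radii) != sorted(radii):
            raise ValueError("cylinder radii must be positive and sorted")
        if max(radii) > cio.APERTURE_MM:
            raise ValueError("cylinder radii cannot exceed the aperture")

    def fit_config(self) -> FitConfig:
        return FitConfig(spans_u=self.spans, spans_v=self.spans,
                         degree=self.degree, stiffness=self.stiffness)

    def morphometry_config(self) -> MorphometryConfig:
        return MorphometryConfig(density=self.density,
                                 cylinder_radii=self.cylinder_radii,
                                 thickness_mode=self.thickness_mode)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class EyeReconstruction:
    eye_id: str
    discarded: bool
    discard_reason: str | None = None
    anterior: FittedSurface | None = None
    posterior: FittedSurface | None = None
    residuals: dict[str, ResidualReport] = field(default_factory=dict)
    solid: SolidModel | None = None


def reconstruct_eye(
    anterior_csv,
    posterior_csv,
    config: RunConfig | None = None,
    eye_id: str = "eye",
    *,
    build_mesh: bool = True,
) -> EyeReconstruction:
    """Reconstruct one eye from its two polar CSVs.

    Returns a discarded reconstruction (with the reason) if either
    surface fails the aperture-completeness rule.
    """
    config = config or RunConfig()
    grids = {
        "anterior": cio.read_polar_grid(anterior_csv, "anterior"),
        "posterior": cio.read_polar_grid(posterior_csv, "posterior"),
    }
    for label, grid in grids.items():
        report = cio.validate_aperture(grid)
        if report.verdict == "discard":
            return EyeReconstruction(
                eye_id=eye_id, discarded=True,
                discard_reason=(
                    f"{label} surface incomplete within 4 mm: "
                    f"{len(report.missing_cells)} missing cells"
                ),
            )
    rec = EyeReconstruction(eye_id=eye_id, discarded=False)
    fc = config.fit_config()
    for label, grid in grids.items():
        cloud = cio.polar_to_cartesian(grid)
        surface = fit_surface(cloud, fc)
        setattr(rec, label, surface)
        rec.residuals[label] = point_surface_residuals(surface, cloud)
    if build_mesh:
        rec.solid = build_solid(rec.anterior, rec.posterior, density=config.density)
    return rec


def analyze_eye(rec: EyeReconstruction, config: RunConfig | None = None) -> MorphometryRecord:
    config = config or RunConfig()
    return compute_morphometry(rec.anterior, rec.posterior, config.morphometry_config())


def load_manifest(cohort_dir) -> pd.DataFrame:
    cohort_dir = Path(cohort_dir)
    manifest = cohort_dir / "cohort.csv"
    if not manifest.exists():
        raise FileNotFoundError(f"no cohort manifest at {manifest}")
    return pd.read_csv(manifest)


def analyze_cohort(
    cohort_dir,
    config: RunConfig | None = None,
    *,
    progress: bool = False,
) -> tuple[pd.DataFrame, dict, list[dict]]:
    """Reconstruct and measure every eye listed in a cohort manifest.

    Returns (records table indexed by eye id with label/stage columns,
    statistics report, list of discarded eyes with reasons).  The
    statistical battery is skipped (empty report) when only one class
    survives.
    """
    config = config or RunConfig()
    cohort_dir = Path(cohort_dir)
    manifest = load_manifest(cohort_dir)
    rows, discarded = [], []
    for _, entry in manifest.iterrows():
        rec = reconstruct_eye(
            cohort_dir / entry["anterior_csv"],
            cohort_dir / entry["posterior_csv"],
            config, eye_id=entry["eye_id"], build_mesh=False,
        )
        if rec.discarded:
            discarded.append({"eye_id": rec.eye_id, "reason": rec.discard_reason})
            continue
        record = analyze_eye(rec, config)
        row = {"eye_id": rec.eye_id, "label": int(entry["label"]), "stage": entry["stage"]}
        row.update(record.to_dict())
        rows.append(row)
    records = pd.DataFrame(rows).set_index("eye_id")
    variables = MorphometryRecord.field_names()
    if records.empty or records["label"].nunique() < 2 or records["label"].value_counts().min() < 2:
        report: dict = {}
    else:
        stages = np.where(records["label"] == 0, "normal", records["stage"])
        report = cohort_report(records[variables], records["label"], stages)
    return records, report, discarded


def write_report(records: pd.DataFrame, report: dict, discarded: list[dict],
                 out_dir, config: RunConfig) -> None:
    """Write the morphometry table, the four table-shaped CSVs and a JSON report."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records.to_csv(out_dir / "morphometry.csv")
    if report:
        report["group"].to_csv(out_dir / "table_group_comparison.csv", index=False)
        report["roc"].to_csv(out_dir / "table_roc.csv", index=False)
        if "staged" in report:
            report["staged"].to_csv(out_dir / "table_staged_comparison.csv", index=False)
        cyl_vars = [v for v in records.columns if v.startswith("cyl_volume")]
        cyl = report["group"][report["group"]["variable"].isin(cyl_vars)]
        cyl.to_csv(out_dir / "table_cylinder_volumes.csv", index=False)
    payload = {
        "config": dataclasses.asdict(config),
        "config_digest": config.digest(),
        "seed": config.seed,
        "n_eyes": int(len(records)),
        "n_discarded": len(discarded),
        "discarded": discarded,
    }
    if report:
        payload["roc"] = report["roc"].to_dict(orient="records")
        payload["group"] = report["group"].to_dict(orient="records")
    (out_dir / "report.json").write_text(json.dumps(payload, indent=1, default=str))


def write_manifest(out_dir, config: RunConfig, extra: dict | None = None) -> Path:
    """Record config hash, seed and package version next to any output."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "config_digest": config.digest(),
    }
    payload.update(extra or {})
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(payload, indent=1))
    return path
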