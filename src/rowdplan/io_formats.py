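"""On-disk artifacts: NIfTI grids, CSV spot lists and tables, JSON configs.

Grids round-trip through NIfTI (RAS, mm, origin at the first-voxel centre,
float32). Spot lists are CSV with columns ``field_id, range_mm, x_mm, y_mm,
weight`` plus a plan-level JSON carrying fields, prescription and fractions.
Every writer stamps a schema version; every run directory gets a manifest
(resolved config echo, seed, checksums) sufficient to reproduce the run.
"""

from __future__ import annotations

import hashlib
import json
import subprocess
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import nibabel as nib
import numpy as np
import pandas as pd

from .beam import AXIS_DIRECTIONS, BeamConfig, Field, Plan, Spot
from .errors import (
    ConfigurationError,
    UnsupportedFormatError,
    ValidationError,
)
from .grids import VoxelGrid
from .optimizer import OptimizerConfig

__all__ = [
    "SCHEMA_VERSION",
    "read_grid",
    "write_grid",
    "read_plan",
    "write_plan",
    "read_calibration",
    "read_config",
    "RunConfig",
    "write_manifest",
    "write_convergence_log",
]

SCHEMA_VERSION = "1.0"
SPOT_COLUMNS = ["field_id", "range_mm", "x_mm", "y_mm", "weight"]
MODEL_CHOICES = ("rbe11", "rbe11_oer", "mcn_oer", "ror_oer")


def write_grid(grid: VoxelGrid, path: str | Path) -> Path:
    """Write a grid as single-volume float32 NIfTI (RAS, mm)."""
    path = Path(path)
    affine = np.diag([grid.spacing[0], grid.spacing[1], grid.spacing[2], 1.0])
    affine[:3, 3] = grid.origin
    img = nib.Nifti1Image(np.asarray(grid.values, dtype=np.float32), affine)
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))
    return path


def read_grid(path: str | Path) -> VoxelGrid:
    """Read a 3-D single-component NIfTI volume back into a VoxelGrid."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise UnsupportedFormatError(
            f"{path}: expected a 3-D volume, got shape {data.shape}"
        )
    affine = img.affine
    rot = affine[:3, :3]
    if not np.allclose(rot - np.diag(np.diag(rot)), 0.0, atol=1e-6):
        raise UnsupportedFormatError(f"{path}: only axis-aligned (RAS diagonal) grids supported")
    spacing = np.diag(rot)
    if np.any(spacing <= 0):
        raise UnsupportedFormatError(f"{path}: non-positive voxel spacing in affine")
    return VoxelGrid(data.astype(np.float32), tuple(spacing), tuple(affine[:3, 3]))


def write_plan(plan: Plan, directory: str | Path, stem: str = "plan") -> tuple[Path, Path]:
    """Write a plan as <stem>.json + <stem>_spots.csv; returns both paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    csv_path = directory / f"{stem}_spots.csv"
    json_path = directory / f"{stem}.json"
    rows = [
        {"field_id": s.field_id, "range_mm": s.range_mm, "x_mm": s.x_mm, "y_mm": s.y_mm, "weight": s.weight}
        for s in plan.spots
    ]
    pd.DataFrame(rows, columns=SPOT_COLUMNS).to_csv(csv_path, index=False)
    payload = {
        "schema_version": SCHEMA_VERSION,
        "prescription_gy_rbe": plan.prescription_gy_rbe,
        "fractions": plan.fractions,
        "spots_csv": csv_path.name,
        "fields": [
            {
                "field_id": f.field_id,
                "direction": f.direction,
                "spot_spacing_mm": f.spot_spacing_mm,
                "layer_spacing_mm": f.layer_spacing_mm,
            }
            for f in plan.fields
        ],
    }
    json_path.write_text(json.dumps(payload, indent=2))
    return json_path, csv_path


def read_plan(json_path: str | Path) -> Plan:
    """Read and validate a plan (JSON + referenced spot CSV)."""
    json_path = Path(json_path)
    try:
        payload = json.loads(json_path.read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"{json_path}: invalid JSON ({exc})") from exc
    for key in ("schema_version", "prescription_gy_rbe", "fields", "spots_csv"):
        if key not in payload:
            raise ValidationError(f"{json_path}: missing field {key!r}")
    fields = []
    for entry in payload["fields"]:
        for key in ("field_id", "direction"):
            if key not in entry:
                raise ValidationError(f"{json_path}: field entry missing {key!r}")
        if entry["direction"] not in AXIS_DIRECTIONS:
            raise ValidationError(f"{json_path}: bad direction {entry['direction']!r}")
        fields.append(
            Field(
                field_id=str(entry["field_id"]),
                direction=entry["direction"],
                spot_spacing_mm=float(entry.get("spot_spacing_mm", 5.0)),
                layer_spacing_mm=float(entry.get("layer_spacing_mm", 4.0)),
            )
        )
    csv_path = json_path.parent / payload["spots_csv"]
    df = pd.read_csv(csv_path)
    missing = [c for c in SPOT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{csv_path}: missing column(s) {missing}")
    if (df["weight"] < 0).any():
        raise ValidationError(f"{csv_path}: negative spot weight")
    spots = [
        Spot(str(r.field_id), float(r.range_mm), float(r.x_mm), float(r.y_mm), float(r.weight))
        for r in df.itertuples()
    ]
    return Plan(
        fields,
        spots,
        prescription_gy_rbe=float(payload["prescription_gy_rbe"]),
        fractions=int(payload.get("fractions", 1)),
    )


def read_calibration(path: str | Path) -> pd.DataFrame:
    """Read an uptake->pO2 calibration table (2-column CSV) with validation."""
    df = pd.read_csv(path)
    missing = [c for c in ("uptake", "pO2_mmHg") if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    x = df["uptake"].to_numpy(dtype=float)
    if np.any(np.diff(x) <= 0):
        raise ConfigurationError(f"{path}: uptake column must be strictly increasing")
    return df


_RUNCONFIG_KEYS = {
    "model",
    "prescription_gy_rbe",
    "fields",
    "oer",
    "tissues",
    "optimizer",
    "beam",
    "phantom",
    "seed",
    "paths",
}


@dataclass
class RunConfig:
    """Resolved run configuration (strict schema, unknown keys rejected)."""

    model: str = "rbe11"
    prescription_gy_rbe: float = 2.0
    fields: str = "single"  # single | opposing
    oer: dict[str, Any] = field(default_factory=dict)
    tissues: dict[str, dict[str, float]] = field(default_factory=dict)
    optimizer: dict[str, Any] = field(default_factory=dict)
    beam: dict[str, Any] = field(default_factory=dict)
    phantom: dict[str, Any] = field(default_factory=dict)
    seed: int = 0
    paths: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model not in MODEL_CHOICES:
            raise ConfigurationError(
                f"model must be one of {MODEL_CHOICES}, got {self.model!r}"
            )
        if self.fields not in ("single", "opposing"):
            raise ConfigurationError("fields must be 'single' or 'opposing'")

    @property
    def oer_enabled(self) -> bool:
        return self.model.endswith("_oer")

    @property
    def rbe_kind(self) -> str:
        return {"rbe11": "constant_1p1", "rbe11_oer": "constant_1p1", "mcn_oer": "MCN", "ror_oer": "ROR_approx"}[self.model]

    def optimizer_config(self) -> OptimizerConfig:
        return OptimizerConfig(**self.optimizer)

    def beam_config(self) -> BeamConfig:
        return BeamConfig(**self.beam)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


def read_config(path: str | Path) -> RunConfig:
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"{path}: invalid JSON ({exc})") from exc
    unknown = set(payload) - _RUNCONFIG_KEYS - {"schema_version"}
    if unknown:
        raise ValidationError(f"{path}: unknown config key(s) {sorted(unknown)}")
    payload.pop("schema_version", None)
    return RunConfig(**payload)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _git_describe() -> str:
    try:
        out = subprocess.run(
            ["git", "describe", "--always", "--dirty"],
            capture_output=True,
            text=True,
            timeout=5,
        )
        return out.stdout.strip() or "unknown"
    except Exception:
        return "unknown"


def write_manifest(
    directory: str | Path,
    config: RunConfig | dict[str, Any] | None,
    seed: int | None = None,
    extra: dict[str, Any] | None = None,
) -> Path:
    """Write manifest.json: schema version, config echo, seed, checksums."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = sorted(p for p in directory.iterdir() if p.is_file() and p.name != "manifest.json")
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "git_describe": _git_describe(),
        "seed": seed,
        "config": config.to_dict() if isinstance(config, RunConfig) else config,
        "checksums": {p.name: _sha256(p) for p in files},
    }
    if extra:
        manifest.update(extra)
    path = directory / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def write_convergence_log(log: list[dict], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(log, columns=["iteration", "cost", "d50_target", "max_violation"]).to_csv(
        path, index=False
    )
    return path
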