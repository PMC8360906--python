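"""File formats: CSV dialects, YAML configuration, input validation.

All angle columns are degrees; simulation coordinates are dimensionless
box units, Cartesian y-up.  Tracing tables from image analysis (y-down
pixel convention) can be flipped on load with ``flip_y=True``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .inference import OrientationDataset
from .params import MechanicalParams
from .shape import CATEGORIES
from .tracing import TRACING_COLUMNS, polygons_from_tracing

ANGLES_COLUMNS = ["embryo_id", "ring_category", "angle_deg"]
RECOIL_COLUMNS = ["trace_id", "group", "time_s", "distance"]
DIVISION_COLUMNS = ["time_min", "x", "y", "axis_x", "axis_y", "in_plane"]


# ------------------------------------------------------------------ run config
@dataclass
class RunConfig:
    """Merged pipeline configuration with reproducibility provenance."""

    params: MechanicalParams = field(default_factory=MechanicalParams)
    n_cells: int = 400
    cluster_size: int = 19
    cluster_increment: float = 0.09
    seeds: tuple = (0, 1, 2, 3, 4)
    grid_start: float = 0.0
    grid_stop: float = 0.20
    grid_step: float = 0.01
    relax_tol: float = 1e-6
    zero_stress_tol: float = 1e-4
    experiment_angles: str = None

    def grid(self) -> np.ndarray:
        n = int(round((self.grid_stop - self.grid_start) / self.grid_step)) + 1
        return np.round(np.linspace(self.grid_start, self.grid_stop, n), 10)

    def to_dict(self) -> dict:
        return {
            "lambda_coeff": self.params.lambda_coeff,
            "gamma_ref": self.params.gamma_ref,
            "cluster_increment": self.cluster_increment,
            "n_cells": self.n_cells,
            "cluster_size": self.cluster_size,
            "seeds": list(self.seeds),
            "grid": [self.grid_start, self.grid_stop, self.grid_step],
            "relax_tol": self.relax_tol,
            "zero_stress_tol": self.zero_stress_tol,
            "experiment_angles": self.experiment_angles,
        }

    def config_hash(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def load_run_config(path) -> RunConfig:
    """Read a YAML run configuration; keys mirror RunConfig fields."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    params = MechanicalParams(
        lambda_coeff=raw.get("lambda_coeff", 0.259),
        gamma_ref=raw.get("gamma_ref", 0.172),
        cluster_increment=raw.get("cluster_increment", 0.09),
    )
    grid = raw.get("grid", [0.0, 0.20, 0.01])
    return RunConfig(
        params=params,
        n_cells=int(raw.get("n_cells", 400)),
        cluster_size=int(raw.get("cluster_size", 19)),
        cluster_increment=float(raw.get("cluster_increment", 0.09)),
        seeds=tuple(raw.get("seeds", [0, 1, 2, 3, 4])),
        grid_start=float(grid[0]),
        grid_stop=float(grid[1]),
        grid_step=float(grid[2]),
        relax_tol=float(raw.get("relax_tol", 1e-6)),
        zero_stress_tol=float(raw.get("zero_stress_tol", 1e-4)),
        experiment_angles=raw.get("experiment_angles"),
    )


# ----------------------------------------------------------------- CSV loaders
def _require_columns(df: pd.DataFrame, columns, kind: str):
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{kind} table missing columns {missing}")


def load_tracings(path, flip_y: bool = False) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, TRACING_COLUMNS, "tracing")
    polygons_from_tracing(df, flip_y=flip_y)  # validates simplicity
    return df


def load_angles(path) -> OrientationDataset:
    """Experimental angles CSV -> pooled OrientationDataset."""
    df = pd.read_csv(path)
    _require_columns(df, ANGLES_COLUMNS, "angles")
    bad = df[(df["angle_deg"] < 0) | (df["angle_deg"] > 90)]
    if len(bad):
        raise ValidationError(
            f"angles outside [0, 90] at rows {bad.index.tolist()[:5]}"
        )
    return OrientationDataset(
        angles_by_category={
            cat: df.loc[df["ring_category"] == cat, "angle_deg"].to_numpy(float)
            for cat in CATEGORIES
        },
        source="experiment",
        metadata={"path": str(path), "n_embryos": df["embryo_id"].nunique()},
    )


def write_angles(measured: pd.DataFrame, path) -> None:
    """Write a per-cell orientation table in the angles CSV dialect."""
    ok = measured[
        measured["orientation_defined"]
        & ~measured["is_cluster"]
        & measured["orientation_to_cluster"].notna()
    ]
    out = pd.DataFrame(
        {
            "embryo_id": ok["embryo_id"],
            "ring_category": ok["ring_category"],
            "angle_deg": ok["orientation_to_cluster"],
        }
    )
    out.to_csv(path, index=False)


def load_recoil(path):
    from .synthetic import recoil_traces_from_frame

    df = pd.read_csv(path)
    _require_columns(df, RECOIL_COLUMNS, "recoil")
    return recoil_traces_from_frame(df)


def load_divisions(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, DIVISION_COLUMNS, "divisions")
    return df


# ------------------------------------------------------------------ validation
@dataclass
class ValidationReport:
    kind: str
    path: str
    errors: list

    @property
    def ok(self) -> bool:
        return not self.errors

    def __str__(self) -> str:
        head = f"{self.kind} file {self.path}: {len(self.errors)} errors"
        return "\n".join([head] + [f"  - {e}" for e in self.errors])


def validate_inputs(path, kind: str) -> ValidationReport:
    """Schema/range validation of an input table; returns a readable report."""
    errors = []
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        return ValidationReport(kind, str(path), [f"unreadable: {exc}"])

    if kind == "tracings":
        try:
            _require_columns(df, TRACING_COLUMNS, kind)
            polygons_from_tracing(df)
        except Exception as exc:
            errors.append(str(exc))
    elif kind == "angles":
        try:
            _require_columns(df, ANGLES_COLUMNS, kind)
        except Exception as exc:
            errors.append(str(exc))
        else:
            for idx, val in df["angle_deg"].items():
                if not 0 <= val <= 90:
                    errors.append(f"row {idx}: angle {val} outside [0, 90]")
            unknown = set(df["ring_category"]) - set(CATEGORIES)
            if unknown:
                errors.append(f"unknown ring categories {sorted(unknown)}")
    elif kind == "recoil":
        try:
            _require_columns(df, RECOIL_COLUMNS, kind)
        except Exception as exc:
            errors.append(str(exc))
        else:
            for tid, grp in df.groupby("trace_id"):
                t = grp["time_s"].to_numpy()
                dec = np.nonzero(np.diff(t) <= 0)[0]
                for d in dec:
                    errors.append(
                        f"trace {tid}: non-increasing time at row {grp.index[d + 1]}"
                    )
    elif kind == "divisions":
        try:
            _require_columns(df, DIVISION_COLUMNS, kind)
        except Exception as exc:
            errors.append(str(exc))
        else:
            norms = np.hypot(df["axis_x"], df["axis_y"])
            for idx in df.index[np.abs(norms - 1.0) > 1e-6]:
                errors.append(f"row {idx}: daughter axis not unit length")
    else:
        errors.append(f"unknown kind {kind!r}")
    return ValidationReport(kind, str(path), errors)
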