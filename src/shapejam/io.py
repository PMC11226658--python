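"""Plain-text readers/writers and run configuration.

Formats (all inspectable text):

* trajectory: CSV with header ``frame,cell_id,x,y`` plus a JSON sidecar
  ``<path>.json`` holding ``{dt, box_type, Lx, Ly | R, phi}``;
* polygon outlines: CSV with header ``frame,cell_id,vertex_index,x,y``;
* fit results and scalar summaries: JSON.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .dynamics import Box, Trajectory
from .exceptions import SchemaError
from .shape_stats import PolygonEnsemble

__all__ = [
    "read_trajectory",
    "write_trajectory",
    "read_polygons",
    "write_polygons",
    "write_json",
    "read_json",
    "write_fit",
    "RunConfig",
    "ShapeConditions",
    "HeterogeneitySettings",
    "config_hash",
    "write_manifest",
]

TRAJ_COLUMNS = ["frame", "cell_id", "x", "y"]
POLY_COLUMNS = ["frame", "cell_id", "vertex_index", "x", "y"]


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    path = Path(path)
    n_frames, n_cells, _ = traj.positions.shape
    frame = np.repeat(np.arange(n_frames), n_cells)
    cid = np.tile(np.arange(n_cells), n_frames)
    flat = traj.positions.reshape(-1, 2)
    df = pd.DataFrame({"frame": frame, "cell_id": cid, "x": flat[:, 0], "y": flat[:, 1]})
    df.to_csv(path, index=False, float_format="%.17g")
    meta: dict[str, Any] = {"dt": traj.dt, "box_type": traj.box.kind, "phi": traj.phi}
    if traj.box.kind == "periodic":
        meta.update(Lx=traj.box.Lx, Ly=traj.box.Ly)
    else:
        meta.update(R=traj.box.R)
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_trajectory(path: str | Path) -> Trajectory:
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise SchemaError(f"missing JSON sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in ("dt", "box_type"):
        if key not in meta:
            raise SchemaError(f"sidecar lacks required key '{key}'")
    if meta["box_type"] == "periodic":
        box = Box.periodic(meta["Lx"], meta["Ly"])
    elif meta["box_type"] == "circular":
        box = Box.circular(meta["R"])
    else:
        raise SchemaError(f"unknown box_type {meta['box_type']!r}")

    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != TRAJ_COLUMNS:
        raise SchemaError(f"expected columns {TRAJ_COLUMNS}, found {list(df.columns)}")
    bad = df.index[df[["x", "y"]].isna().any(axis=1)]
    if len(bad):
        raise SchemaError(f"NaN coordinate at row {int(bad[0])}")
    df = df.sort_values(["frame", "cell_id"], kind="stable").reset_index(drop=True)
    frames = df["frame"].unique()
    if not np.array_equal(frames, np.arange(len(frames))):
        raise SchemaError("frame indices are not contiguous from 0")
    counts = df.groupby("frame", sort=True)["cell_id"].agg(["count", "min", "max"])
    n_cells = int(counts["count"].iloc[0])
    if not ((counts["count"] == n_cells).all() and (counts["min"] == 0).all()
            and (counts["max"] == n_cells - 1).all()):
        raise SchemaError("cell ids must be contiguous 0..n-1 in every frame")
    pos = df[["x", "y"]].to_numpy().reshape(len(frames), n_cells, 2)
    return Trajectory(positions=pos, dt=float(meta["dt"]), box=box, phi=meta.get("phi"))


# ---------------------------------------------------------------------------
# polygons
# ---------------------------------------------------------------------------


def write_polygons(ensemble: PolygonEnsemble, path: str | Path) -> None:
    rows = []
    for f, cid, poly in ensemble.iter_polygons():
        for k, (x, y) in enumerate(poly):
            rows.append((f, cid, k, x, y))
    pd.DataFrame(rows, columns=POLY_COLUMNS).to_csv(Path(path), index=False, float_format="%.17g")


def read_polygons(path: str | Path) -> PolygonEnsemble:
    df = pd.read_csv(Path(path), float_precision="round_trip")
    if list(df.columns) != POLY_COLUMNS:
        raise SchemaError(f"expected columns {POLY_COLUMNS}, found {list(df.columns)}")
    bad = df.index[df[["x", "y"]].isna().any(axis=1)]
    if len(bad):
        raise SchemaError(f"NaN coordinate at row {int(bad[0])}")
    frames: list[dict[int, np.ndarray]] = []
    for f in sorted(df["frame"].unique()):
        sub = df[df["frame"] == f]
        frame: dict[int, np.ndarray] = {}
        for cid, grp in sub.groupby("cell_id"):
            grp = grp.sort_values("vertex_index")
            if not np.array_equal(grp["vertex_index"].to_numpy(), np.arange(len(grp))):
                raise SchemaError(f"non-contiguous vertex_index for frame {f}, cell {cid}")
            frame[int(cid)] = grp[["x", "y"]].to_numpy()
        frames.append(frame)
    return PolygonEnsemble(frames=frames)


# ---------------------------------------------------------------------------
# JSON results
# ---------------------------------------------------------------------------


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o: Any) -> Any:
        if isinstance(o, np.bool_):
            return bool(o)
        if isinstance(o, np.integer):
            return int(o)
        if isinstance(o, np.floating):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if is_dataclass(o) and not isinstance(o, type):
            return asdict(o)
        return super().default(o)


def write_json(obj: Any, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, cls=_NumpyEncoder, indent=1, sort_keys=True))


def read_json(path: str | Path) -> Any:
    return json.loads(Path(path).read_text())


def write_fit(fit: Any, path: str | Path, **diagnostics: Any) -> None:
    """Serialize a KGammaFit/MeanFieldFit as {parameter, loglik, n, diagnostics}."""
    payload = asdict(fit)
    payload["diagnostics"] = diagnostics
    write_json(payload, path)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


class ShapeConditions(BaseModel):
    """One synthetic shape-ensemble condition for the scaling pipeline."""

    model_config = ConfigDict(extra="forbid")

    dist: str = Field(pattern="^(kgamma|meanfield)$")
    param: float
    n: int = 20000
    seed: int


class HeterogeneitySettings(BaseModel):
    """Vertex-model settings for the dynamical-heterogeneity pipeline."""

    model_config = ConfigDict(extra="forbid")

    n_cells: int = 100
    p0: float = 3.85
    temperature: float = 0.015
    steps: int = 40000
    snapshot_stride: int = 50
    fraction: float = 0.10
    seed: int = 1
    quench_steps: int = 1500
    equil_steps: int = 6000
    frozen_n_values: list[int] = [1, 2, 4, 8, 12, 16]
    frozen_T_values: list[float] = [0.005, 0.02]
    frozen_seeds: list[int] = [1, 2, 3]
    frozen_p0: float = 3.72
    prod_steps: int = 6000


class RunConfig(BaseModel):
    """Schema-versioned pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    schema_version: int = 1
    shape_conditions: list[ShapeConditions] | None = None
    heterogeneity: HeterogeneitySettings | None = None
    fit_range: tuple[float, float] = (1.15, 2.5)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        try:
            return cls.model_validate(json.loads(Path(path).read_text()))
        except Exception as exc:  # pydantic ValidationError or JSON decode
            raise SchemaError(str(exc)) from exc

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=1))


def config_hash(config: RunConfig) -> str:
    return hashlib.sha256(config.model_dump_json().encode()).hexdigest()[:16]


def write_manifest(config: RunConfig, out_dir: str | Path, **extra: Any) -> None:
    from importlib.metadata import version

    try:
        pkg_version = version("shapejam")
    except Exception:  # pragma: no cover
        pkg_version = "unknown"
    payload = {
        "config_hash": config_hash(config),
        "config": json.loads(config.model_dump_json()),
        "shapejam_version": pkg_version,
        **extra,
    }
    write_json(payload, Path(out_dir) / "manifest.json")
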