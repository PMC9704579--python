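"""Readers and writers binding the pipeline stages together.

Formats: trajectory CSV with header ``time,x[,y,z]`` (seconds and length
units, metres by convention); camera matrices as 3x4 whitespace-separated
plain-text files; identified models as JSON; swarm metrics and stability
maps as CSV.  All CSV is UTF-8, '.' decimal, LF line endings, and float
values are written with 17 significant digits so write-then-read is an
identity up to float formatting.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .sysid.models import TransferFunctionModel
from .swarm.simulate import SwarmResult
from .trajectory import Trajectory

__all__ = [
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_camera_matrix",
    "read_camera_matrix",
    "write_model_json",
    "read_model_json",
    "write_swarm_metrics_csv",
    "write_swarm_trajectory_csv",
    "write_population_csv",
    "read_population_csv",
    "write_image_stacks",
    "read_image_stack",
    "file_checksum",
    "write_manifest",
]

_FLOAT_FMT = "%.17g"
_AXES = ("x", "y", "z")


def write_trajectory_csv(path: str | Path, traj: Trajectory) -> Path:
    """Write a trajectory as ``time,x[,y,z]``."""
    path = Path(path)
    vals = traj.values if traj.values.ndim == 2 else traj.values[:, None]
    cols = {"time": traj.times}
    for k in range(vals.shape[1]):
        cols[_AXES[k]] = vals[:, k]
    pd.DataFrame(cols).to_csv(
        path, index=False, float_format=_FLOAT_FMT, lineterminator="\n"
    )
    return path


def read_trajectory_csv(path: str | Path) -> Trajectory:
    """Read a ``time,x[,y,z]`` trajectory; rejects malformed headers."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    cols = list(df.columns)
    if not cols or cols[0] != "time":
        raise ValueError(f"{path}: first column must be 'time', got {cols[:1]}")
    axes = cols[1:]
    if not axes or axes != list(_AXES[: len(axes)]):
        raise ValueError(
            f"{path}: position columns must be {list(_AXES)} prefixes, got {axes}"
        )
    t = df["time"].to_numpy(float)
    if len(t) < 2:
        raise ValueError(f"{path}: need at least two samples")
    dts = np.diff(t)
    if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-12):
        raise ValueError(f"{path}: time column is not uniformly sampled")
    vals = df[axes].to_numpy(float)
    if vals.shape[1] == 1:
        vals = vals[:, 0]
    return Trajectory(vals, dt=float(dts[0]), t0=float(t[0]))


def write_camera_matrix(path: str | Path, P: np.ndarray) -> Path:
    path = Path(path)
    P = np.asarray(P, dtype=float)
    if P.shape != (3, 4):
        raise ValueError(f"camera matrix must be 3x4, got {P.shape}")
    np.savetxt(path, P, fmt=_FLOAT_FMT)
    return path


def read_camera_matrix(path: str | Path) -> np.ndarray:
    path = Path(path)
    values = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                values.extend(float(tok) for tok in line.split())
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    if len(values) != 12:
        raise ValueError(
            f"{path}: expected 12 numbers for a 3x4 camera matrix, got {len(values)}"
        )
    return np.asarray(values).reshape(3, 4)


def write_model_json(path: str | Path, model: TransferFunctionModel,
                     extra: dict | None = None) -> Path:
    path = Path(path)
    payload = model.to_dict()
    if extra:
        payload.update(extra)
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path


def read_model_json(path: str | Path) -> TransferFunctionModel:
    return TransferFunctionModel.from_dict(json.loads(Path(path).read_text()))


def write_swarm_metrics_csv(path: str | Path, result: SwarmResult) -> Path:
    path = Path(path)
    cols = {"t": result.times, "Xm": result.x_m, "Vm": result.v_m}
    for k in range(result.barycenter.shape[1]):
        cols[f"RC{_AXES[k]}"] = result.barycenter[:, k]
    cols["normRC"] = result.barycenter_norm
    pd.DataFrame(cols).to_csv(
        path, index=False, float_format=_FLOAT_FMT, lineterminator="\n"
    )
    return path


def write_swarm_trajectory_csv(path: str | Path, result: SwarmResult,
                               stride: int = 1) -> Path:
    path = Path(path)
    n_rec, n_agents, dim = result.positions.shape
    rows = []
    for k in range(0, n_rec, stride):
        for i in range(n_agents):
            row = {"t": result.times[k], "agent": i}
            for d in range(dim):
                row[_AXES[d]] = result.positions[k, i, d]
            rows.append(row)
    pd.DataFrame(rows).to_csv(
        path, index=False, float_format=_FLOAT_FMT, lineterminator="\n"
    )
    return path


def write_population_csv(path: str | Path, delays_ms: np.ndarray) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"individual_id": np.arange(len(delays_ms)), "delay_ms": delays_ms}
    ).to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")
    return path


def read_population_csv(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    if "delay_ms" not in df.columns:
        raise ValueError(f"{path}: missing 'delay_ms' column")
    return df["delay_ms"].to_numpy(float)


def write_image_stacks(
    out_dir: str | Path,
    frames: dict[str, np.ndarray],
    cameras: dict[str, np.ndarray] | None = None,
) -> Path:
    """Write per-camera image stacks as zero-padded-numbered 8-bit PNGs.

    Each camera gets a sub-directory ``<camera_id>/frame_000123.png``; with
    ``cameras`` given (camera id -> 3x4 matrix), a ``<camera_id>.txt``
    projection-matrix file is written alongside.
    """
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    for cid, stack in frames.items():
        cam_dir = out_dir / cid
        cam_dir.mkdir(parents=True, exist_ok=True)
        for k, frame in enumerate(stack):
            iio.imwrite(cam_dir / f"frame_{k:06d}.png",
                        np.asarray(frame, dtype=np.uint8))
        if cameras is not None:
            write_camera_matrix(out_dir / f"{cid}.txt", cameras[cid])
    return out_dir


def read_image_stack(directory: str | Path) -> np.ndarray:
    """Read a directory of numbered PNG/TIFF frames into (n, h, w)."""
    import imageio.v3 as iio

    directory = Path(directory)
    files = sorted(directory.glob("*.png")) + sorted(directory.glob("*.tif*"))
    if not files:
        raise ValueError(f"no image frames found in {directory}")
    return np.stack([iio.imread(f) for f in files])


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path,
    stages: list[str],
    seeds: dict[str, int],
    inputs: dict | None = None,
) -> Path:
    """Write a reproducibility manifest: stages, per-stage seeds, package
    version and checksums of every artifact in the output directory."""
    from . import __version__

    out_dir = Path(out_dir)
    artifacts = {
        p.name: file_checksum(p)
        for p in sorted(out_dir.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {
        "version": __version__,
        "stages": stages,
        "seeds": seeds,
        "inputs": inputs or {},
        "artifacts": artifacts,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path
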