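"""File formats: trajectory/label/feature CSVs and dataset manifests.

Trajectory CSV layout: one row per localisation with columns ``traj_id``,
``frame`` (0-based, consecutive within a trajectory), ``x``, ``y``
(positions in μm).  Metadata such as the time step lives in ``#``-prefixed
header comment lines or in a sidecar manifest.  All writes are atomic
(temp file + rename) so interrupted runs never leave truncated tables.
"""

from __future__ import annotations

import os
import tempfile
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import yaml

from .datasets import DatasetConfig
from .trajectory import Trajectory2D

__all__ = [
    "atomic_write_text",
    "read_trajectories",
    "write_trajectories",
    "write_manifest",
    "read_manifest",
    "write_labels",
    "write_features",
]

TRAJECTORY_COLUMNS = ("traj_id", "frame", "x", "y")


def atomic_write_text(path, text: str) -> None:
    """Write ``text`` to ``path`` via a temp file and atomic rename."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def atomic_write_frame(path, df: pd.DataFrame, header_comments: Sequence[str] = ()) -> None:
    """Atomically write a DataFrame as CSV with optional '#' header lines."""
    text = "".join(f"# {line}\n" for line in header_comments) + df.to_csv(index=False)
    atomic_write_text(path, text)


def read_trajectories(
    path,
    dt: float = 1.0,
    t0: float = 0.0,
    min_steps: int = 2,
) -> List[Tuple[str, Trajectory2D]]:
    """Read a trajectory CSV into (id, Trajectory2D) pairs.

    Frames must be consecutive within each id; ids shorter than
    ``min_steps`` steps are rejected by name.  ``dt`` comes from the
    caller's configuration (e.g. 0.0284 s for typical receptor data).
    """
    # round_trip parsing keeps write->read exact at full float precision
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory CSV {path} is missing columns {missing}")
    out: List[Tuple[str, Trajectory2D]] = []
    for tid, group in df.groupby("traj_id", sort=False):
        group = group.sort_values("frame")
        frames = group["frame"].to_numpy()
        gaps = (frames[1:] - frames[:-1]) != 1
        if gaps.any():
            where = int(frames[:-1][gaps][0])
            raise ValueError(
                f"trajectory {tid!r}: non-consecutive frames after frame {where}"
            )
        if frames.size - 1 < min_steps:
            raise ValueError(
                f"trajectory {tid!r} has {frames.size - 1} steps; "
                f"minimum is {min_steps}"
            )
        positions = group[["x", "y"]].to_numpy(dtype=float)
        out.append((str(tid), Trajectory2D(positions=positions, dt=dt, t0=t0)))
    return out


def write_trajectories(
    pairs: Sequence[Tuple[str, Trajectory2D]], path, dt: Optional[float] = None
) -> None:
    """Write (id, trajectory) pairs as a trajectory CSV.

    The time step is recorded in a header comment line; positions go to
    full float precision so read/write round-trips are exact up to float
    formatting.
    """
    frames = []
    for tid, traj in pairs:
        n = traj.positions.shape[0]
        frames.append(
            pd.DataFrame(
                {
                    "traj_id": [tid] * n,
                    "frame": range(n),
                    "x": traj.positions[:, 0],
                    "y": traj.positions[:, 1],
                }
            )
        )
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=list(TRAJECTORY_COLUMNS)
    )
    if dt is None and pairs:
        dt = pairs[0][1].dt
    comments = [f"dt = {dt} s", "positions in um; frame is 0-based"]
    text = "".join(f"# {line}\n" for line in comments) + df.to_csv(
        index=False, float_format="%.17g"
    )
    atomic_write_text(path, text)


def write_manifest(config: DatasetConfig, path) -> None:
    """Persist a dataset recipe as a YAML manifest."""
    atomic_write_text(path, yaml.safe_dump(config.to_dict(), sort_keys=False))


def read_manifest(path) -> DatasetConfig:
    with open(path) as fh:
        return DatasetConfig.from_dict(yaml.safe_load(fh))


def write_labels(tset, path) -> None:
    """Labels CSV: traj_id, generating model, mode and true parameters."""
    rows: List[Dict] = []
    for i, (spec, mode) in enumerate(zip(tset.specs, tset.modes)):
        rows.append(
            {
                "traj_id": i,
                "model": spec.model,
                "mode": mode,
                "sigma": spec.sigma,
                "hurst": spec.hurst if spec.hurst is not None else "",
                "v1": spec.drift[0] if spec.drift else "",
                "v2": spec.drift[1] if spec.drift else "",
                "lambda1": spec.reversion[0] if spec.reversion else "",
                "lambda2": spec.reversion[1] if spec.reversion else "",
            }
        )
    atomic_write_frame(path, pd.DataFrame(rows))


def write_features(df: pd.DataFrame, path) -> None:
    """Feature table CSV in the fixed column order."""
    atomic_write_frame(path, df)
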