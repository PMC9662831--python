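"""Readers and writers for trajectory tables.

The on-disk format is a delimited text table with mandatory header
``time_min, cell_id, plasmid_id, x_um, cell_length_um`` (tab-separated by
default): one row per focus per frame, long-axis position mid-cell relative
in μm, negative toward the designated old pole.  One trajectory per
(cell_id, plasmid_id) pair, strictly increasing uniformly spaced times.
Simulator exports add a ``tether_count`` column and a flat key=value
metadata sidecar (params, seed, counters) next to the table.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .simulate import Trajectory

__all__ = [
    "read_trajectories",
    "write_trajectories",
    "write_metadata",
    "read_metadata",
    "read_params_file",
]

REQUIRED_COLUMNS = ["time_min", "cell_id", "plasmid_id", "x_um", "cell_length_um"]

#: Allowed overshoot of |x_um| beyond cell_length_um/2 (μm), for rounding in
#: external tracking tables.
POSITION_TOLERANCE = 0.01


class TrajectoryTableError(ValueError):
    """A trajectory table violates the format contract."""


def read_trajectories(path: str | Path, delimiter: str = "\t") -> list[Trajectory]:
    """Read a trajectory table into one Trajectory per (cell_id, plasmid_id).

    Validates mandatory columns, numeric fields, uniform strictly-increasing
    time spacing per trajectory and |x| <= cell_length/2 + tolerance, with
    row-numbered diagnostics.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter, dtype={"cell_id": str, "plasmid_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TrajectoryTableError(f"{path}: missing column(s) {missing}")
    for col in ("time_min", "x_um", "cell_length_um"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 2  # 1-based incl. header
            raise TrajectoryTableError(
                f"{path}: non-numeric value in column {col!r} at line {row}"
            )
        df[col] = pd.to_numeric(df[col])
    over = df["x_um"].abs() > df["cell_length_um"] / 2.0 + POSITION_TOLERANCE
    if over.any():
        row = int(np.flatnonzero(over)[0]) + 2
        raise TrajectoryTableError(
            f"{path}: |x_um| exceeds cell_length_um/2 + {POSITION_TOLERANCE} "
            f"at line {row}"
        )

    out: list[Trajectory] = []
    for (cell, plasmid), g in df.groupby(["cell_id", "plasmid_id"], sort=True):
        g = g.sort_index()
        t = g["time_min"].to_numpy(dtype=float)
        if t.size >= 2:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise TrajectoryTableError(
                    f"{path}: non-increasing time for cell {cell!r} "
                    f"plasmid {plasmid!r}"
                )
            if np.max(np.abs(dt - dt[0])) > 1e-6:
                raise TrajectoryTableError(
                    f"{path}: non-uniform time spacing for cell {cell!r} "
                    f"plasmid {plasmid!r}"
                )
            interval_s = dt[0] * 60.0
        else:
            interval_s = 60.0
        x = g["x_um"].to_numpy(dtype=float)
        tc = (
            g["tether_count"].to_numpy(dtype=np.int64)
            if "tether_count" in g.columns
            else np.zeros(t.size, dtype=np.int64)
        )
        out.append(
            Trajectory(
                times=(t - t[0]) * 60.0,
                positions=x[:, None],
                tether_counts=tc[:, None],
                sampling_interval=interval_s,
                L=float(g["cell_length_um"].iloc[0]),
                seed=-1,
                duration=(t[-1] - t[0]) * 60.0,
                cell_id=str(cell),
                plasmid_ids=[str(plasmid)],
            )
        )
    return out


def write_trajectories(
    trajs: Sequence[Trajectory] | Trajectory,
    path: str | Path,
    delimiter: str = "\t",
    with_metadata: bool = True,
) -> Path:
    """Write trajectories as a delimited table; simulator runs also get a
    metadata sidecar ``<path>.meta``."""
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    rows = []
    for traj in trajs:
        for j in range(traj.n_plasmids):
            pid = traj.plasmid_ids[j] if j < len(traj.plasmid_ids) else str(j)
            x = traj.positions[:, j]
            for k in range(traj.times.size):
                if np.isnan(x[k]):
                    continue
                rows.append(
                    {
                        "time_min": traj.times[k] / 60.0,
                        "cell_id": traj.cell_id,
                        "plasmid_id": pid,
                        "x_um": x[k],
                        "cell_length_um": traj.L,
                        "tether_count": int(traj.tether_counts[k, j]),
                    }
                )
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False, float_format="%.6f")
    if with_metadata:
        write_metadata(trajs, Path(str(path) + ".meta"))
    return path


def write_metadata(trajs: Sequence[Trajectory], path: str | Path) -> Path:
    """Flat key=value metadata sidecar for a table of simulator runs."""
    lines = []
    for i, traj in enumerate(trajs):
        prefix = f"run{i}." if len(trajs) > 1 else ""
        lines.append(f"{prefix}cell_id={traj.cell_id}")
        lines.append(f"{prefix}seed={traj.seed}")
        lines.append(f"{prefix}L_um={traj.L}")
        lines.append(f"{prefix}sampling_interval_s={traj.sampling_interval}")
        lines.append(f"{prefix}duration_s={traj.duration}")
        for key, val in traj.counters.items():
            lines.append(f"{prefix}{key}={val}")
        if traj.params is not None:
            p = traj.params
            params_json = json.dumps(
                {f: getattr(p, f) for f in p.__dataclass_fields__}, sort_keys=True
            )
            lines.append(f"{prefix}params={params_json}")
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path


def read_params_file(path: str | Path):
    """Read a flat key=value parameter config (SI-μm units, keys are the
    model-parameter field names; '#' starts a comment) into a validated
    parameter record."""
    from .params import make_params

    kw: dict[str, float] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}: expected key=value, got {raw!r}")
        key, _, val = line.partition("=")
        key = key.strip()
        val = val.strip()
        kw[key] = int(val) if key in ("nA", "np") else float(val)
    return make_params(**kw)


def read_metadata(path: str | Path) -> dict[str, str]:
    """Parse a flat key=value sidecar into a dict of strings."""
    out = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or "=" not in line:
            continue
        key, _, val = line.partition("=")
        out[key] = val
    return out
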