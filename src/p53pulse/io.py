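"""Tidy-table input/output for experiments and derived results.

Trajectories travel as long-format delimited tables with columns
``experiment_id, cell_id, time_h, p53, area, marker``; experiment metadata
(protocol, dose, pre-equilibration, baseline index) and division times go to
sidecar tables. Reads are order-free and verify the uniform time grid; short
gaps can be interpolated up to a configurable run length.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CellTrajectory, Experiment, TemperatureProtocol

__all__ = [
    "experiment_to_frame",
    "write_tables",
    "read_trajectories",
    "DEFAULT_COLUMN_MAP",
]

# adapter for externally deposited tables whose column names differ
DEFAULT_COLUMN_MAP = {
    "experiment_id": "experiment_id",
    "cell_id": "cell_id",
    "time_h": "time_h",
    "p53": "p53",
    "area": "area",
    "marker": "marker",
}


def experiment_to_frame(experiment: Experiment) -> pd.DataFrame:
    """Long-format trajectory table of one experiment."""
    frames = []
    for traj in experiment.trajectories:
        frames.append(
            pd.DataFrame(
                {
                    "experiment_id": experiment.experiment_id,
                    "cell_id": traj.cell_id,
                    "time_h": traj.times,
                    "p53": traj.p53,
                    "area": traj.area,
                    "marker": traj.marker,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_tables(experiments: list[Experiment], out_dir: str | Path) -> dict[str, Path]:
    """Write trajectory, metadata and division tables; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    traj_path = out_dir / "trajectories.csv"
    meta_path = out_dir / "experiments.json"
    div_path = out_dir / "divisions.csv"

    pd.concat([experiment_to_frame(e) for e in experiments], ignore_index=True).to_csv(
        traj_path, index=False, float_format="%.17g"  # bit-exact round trips
    )
    meta = {
        e.experiment_id: {
            "protocol": list(map(list, e.protocol.segments)),
            "dose_gy": e.dose_gy,
            "pre_equilibrated": e.pre_equilibrated,
            "baseline_index": e.baseline_index,
        }
        for e in experiments
    }
    meta_path.write_text(json.dumps(meta, indent=1))
    div_rows = [
        {"experiment_id": e.experiment_id, "cell_id": t.cell_id, "time_h": d}
        for e in experiments
        for t in e.trajectories
        for d in t.divisions
    ]
    pd.DataFrame(div_rows, columns=["experiment_id", "cell_id", "time_h"]).to_csv(
        div_path, index=False
    )
    return {"trajectories": traj_path, "metadata": meta_path, "divisions": div_path}


def _fill_short_gaps(
    times: np.ndarray, values: np.ndarray, dt: float, max_gap: int
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Regrid onto the uniform grid, interpolating gaps of ≤ max_gap frames."""
    n = int(round((times[-1] - times[0]) / dt)) + 1
    grid = times[0] + np.arange(n) * dt
    idx = np.round((times - times[0]) / dt).astype(int)
    present = np.zeros(n, dtype=bool)
    present[idx] = True
    missing_runs = _runs(~present)
    if any(r[1] - r[0] + 1 > max_gap for r in missing_runs):
        return grid, values, False
    out = np.interp(grid, times, values)
    return grid, out, True


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    runs, start = [], None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, mask.size - 1))
    return runs


def read_trajectories(
    traj_path: str | Path,
    metadata_path: str | Path | None = None,
    divisions_path: str | Path | None = None,
    *,
    column_map: dict[str, str] | None = None,
    max_gap_frames: int = 0,
) -> list[Experiment]:
    """Read experiments back from tidy tables (order-free).

    Raises on a non-uniform grid unless the gaps are at most
    ``max_gap_frames`` long, in which case they are linearly interpolated.
    """
    cmap = {**DEFAULT_COLUMN_MAP, **(column_map or {})}
    df = pd.read_csv(traj_path, float_precision="round_trip").rename(
        columns={v: k for k, v in cmap.items()}
    )
    required = set(DEFAULT_COLUMN_MAP)
    if not required.issubset(df.columns):
        raise ValueError(f"missing columns: {sorted(required - set(df.columns))}")

    meta = {}
    if metadata_path is not None:
        meta = json.loads(Path(metadata_path).read_text())
    divisions: dict[tuple[str, str], list[float]] = {}
    if divisions_path is not None:
        ddf = pd.read_csv(divisions_path)
        for row in ddf.itertuples():
            divisions.setdefault((row.experiment_id, row.cell_id), []).append(
                float(row.time_h)
            )

    experiments = []
    for exp_id, edf in df.groupby("experiment_id", sort=True):
        trajectories = []
        bad_cells = []
        for cell_id, cdf in edf.groupby("cell_id", sort=True):
            cdf = cdf.sort_values("time_h")
            times = cdf["time_h"].to_numpy(dtype=float)
            steps = np.diff(times)
            dt = np.min(steps) if steps.size else 0.25
            if steps.size and not np.allclose(steps, dt, atol=1e-9):
                grid, p53, ok = _fill_short_gaps(
                    times, cdf["p53"].to_numpy(dtype=float), dt, max_gap_frames
                )
                if not ok:
                    bad_cells.append(str(cell_id))
                    continue
                _, area, _ = _fill_short_gaps(
                    times, cdf["area"].to_numpy(dtype=float), dt, max_gap_frames
                )
                _, marker, _ = _fill_short_gaps(
                    times, cdf["marker"].to_numpy(dtype=float), dt, max_gap_frames
                )
                times = grid
            else:
                p53 = cdf["p53"].to_numpy(dtype=float)
                area = cdf["area"].to_numpy(dtype=float)
                marker = cdf["marker"].to_numpy(dtype=float)
            trajectories.append(
                CellTrajectory(
                    str(cell_id),
                    times,
                    p53,
                    area,
                    marker,
                    divisions.get((str(exp_id), str(cell_id)), []),
                )
            )
        if bad_cells:
            raise ValueError(
                f"non-uniform sampling beyond gap tolerance in {exp_id}: {bad_cells}"
            )
        m = meta.get(str(exp_id), {})
        protocol = TemperatureProtocol(
            tuple((float(a), float(b)) for a, b in m.get("protocol", [[0.0, 37.0]]))
        )
        experiments.append(
            Experiment(
                experiment_id=str(exp_id),
                protocol=protocol,
                dose_gy=float(m.get("dose_gy", 0.0)),
                pre_equilibrated=bool(m.get("pre_equilibrated", True)),
                trajectories=trajectories,
                baseline_index=int(m.get("baseline_index", 0)),
            )
        )
    return experiments
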