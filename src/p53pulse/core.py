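"""Domain containers for single-cell p53 trajectory analysis.

The analysis operates on populations of single-cell time series sampled on a
uniform grid (default 15 min): the median nuclear p53 reporter intensity, the
nuclear area and the integrated nuclear-marker intensity per cell, grouped into
experiments that share a temperature protocol and radiation dose.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "TemperatureProtocol",
    "CellTrajectory",
    "Experiment",
    "PulseFeature",
    "PitchResult",
    "Q10Estimate",
    "QuantileWeights",
    "PopulationSummary",
    "PermutationCI",
    "CellTimeMatrix",
]


@dataclass(frozen=True)
class TemperatureProtocol:
    """Piecewise-constant temperature schedule.

    ``segments`` is an ordered list of ``(start_h, temp_c)`` pairs; the first
    entry must start at time 0 and start times must be strictly increasing.
    Transitions are treated as instantaneous (experimentally the ramp takes
    on the order of 30 min; an optional linear ramp is supported by the
    generator).
    """

    segments: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        starts = [s for s, _ in self.segments]
        if starts[0] != 0:
            raise ValueError("first protocol segment must start at time 0")
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("protocol start times must be strictly increasing")

    @classmethod
    def constant(cls, temp_c: float) -> "TemperatureProtocol":
        return cls(((0.0, float(temp_c)),))

    @classmethod
    def step(cls, temp0: float, temp1: float, t_shift_h: float) -> "TemperatureProtocol":
        return cls(((0.0, float(temp0)), (float(t_shift_h), float(temp1))))

    def temperature_at(self, t_h: float) -> float:
        temp = self.segments[0][1]
        for start, t in self.segments:
            if t_h >= start:
                temp = t
        return temp

    def spans(self, duration_h: float) -> list[tuple[float, float, float]]:
        """(start, end, temp) spans covering [0, duration_h]."""
        out = []
        for k, (start, temp) in enumerate(self.segments):
            if start >= duration_h:
                break
            end = self.segments[k + 1][0] if k + 1 < len(self.segments) else duration_h
            out.append((start, min(end, duration_h), temp))
        return out


@dataclass
class CellTrajectory:
    """One cell's sampled signals on a uniform time grid (hours)."""

    cell_id: str
    times: np.ndarray
    p53: np.ndarray
    area: np.ndarray
    marker: np.ndarray
    divisions: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.p53 = np.asarray(self.p53, dtype=float)
        self.area = np.asarray(self.area, dtype=float)
        self.marker = np.asarray(self.marker, dtype=float)
        n = self.times.size
        for name in ("p53", "area", "marker"):
            if getattr(self, name).size != n:
                raise ValueError(f"{name} length does not match time grid")
        if n >= 2:
            steps = np.diff(self.times)
            if not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
                raise ValueError("time grid is not uniform")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if self.times.size > 1 else 0.0

    def copy(self) -> "CellTrajectory":
        return CellTrajectory(
            self.cell_id,
            self.times.copy(),
            self.p53.copy(),
            self.area.copy(),
            self.marker.copy(),
            list(self.divisions),
        )


@dataclass
class Experiment:
    """A population of trajectories sharing one condition and time grid."""

    experiment_id: str
    protocol: TemperatureProtocol
    dose_gy: float
    pre_equilibrated: bool
    trajectories: list[CellTrajectory]
    baseline_index: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.trajectories:
            t0 = self.trajectories[0].times
            for traj in self.trajectories[1:]:
                if traj.times.size != t0.size or not np.allclose(traj.times, t0):
                    raise ValueError("trajectories do not share one time grid")
            if not 0 <= self.baseline_index < t0.size:
                raise ValueError("baseline_index outside time grid")

    @property
    def times(self) -> np.ndarray:
        return self.trajectories[0].times

    @property
    def n_cells(self) -> int:
        return len(self.trajectories)

    def p53_matrix(self) -> np.ndarray:
        """(n_cells, n_times) matrix of p53 levels."""
        return np.vstack([t.p53 for t in self.trajectories])

    def baseline_values(self) -> np.ndarray:
        return np.array([t.p53[self.baseline_index] for t in self.trajectories])

    def map_p53(self, fn: Callable[[CellTrajectory], np.ndarray]) -> "Experiment":
        """New experiment with per-cell p53 replaced by ``fn(traj)``."""
        new = []
        for traj in self.trajectories:
            c = traj.copy()
            c.p53 = np.asarray(fn(traj), dtype=float)
            new.append(c)
        return replace(self, trajectories=new)


@dataclass(frozen=True)
class PulseFeature:
    """One detected p53 pulse (times in hours, amplitude in raw units)."""

    cell_id: str
    start_h: float
    end_h: float
    amplitude: float
    cost: float
    index: int = 0

    @property
    def duration_h(self) -> float:
        return self.end_h - self.start_h


@dataclass
class PitchResult:
    """Per-cell AMDF pitch positions and inter-pitch intervals (hours)."""

    cell_id: str
    window_lengths_h: np.ndarray
    positions_by_window: list[np.ndarray]  # one array per window length
    positions_h: np.ndarray  # averaged over windows per pitch index
    intervals_h: np.ndarray
    n_requested: int

    @property
    def n_found(self) -> int:
        return int(self.positions_h.size)

    @property
    def truncated(self) -> bool:
        return self.n_found < self.n_requested


@dataclass(frozen=True)
class Q10Estimate:
    """Temperature coefficient of the pulse rate with bootstrap 95% CI."""

    q10: float
    ci_low: float
    ci_high: float
    temperatures: tuple[float, ...]
    pitch_index: int
    n_boot: int
    n_excluded: int = 0


@dataclass
class QuantileWeights:
    """Multiplicative per-rank weights fitting one experiment onto a reference."""

    reference_id: str
    query_id: str
    quantiles: np.ndarray
    weights: np.ndarray
    mode: str = "per-cell-rank"  # or "per-timepoint-quantile"

    def __post_init__(self) -> None:
        self.quantiles = np.asarray(self.quantiles, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights <= 0):
            raise ValueError("weights must be strictly positive")
        if np.any(np.diff(self.quantiles) < 0):
            raise ValueError("quantile grid must be increasing")


@dataclass
class PopulationSummary:
    """Median trajectory with an inter-quantile band."""

    times: np.ndarray
    median: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_cells: int
    q_lower: float = 0.25
    q_upper: float = 0.75


@dataclass(frozen=True)
class PermutationCI:
    """Group-difference estimate with a resampling 95% confidence interval."""

    statistic: str
    estimate: float
    ci_low: float
    ci_high: float
    n_resamples: int
    seed: int
    method: str = "permutation"
    p_value: float | None = None


@dataclass
class CellTimeMatrix:
    """Cells × time matrix with a recorded (invertible) row order."""

    values: np.ndarray
    cell_ids: list[str]
    times: np.ndarray

    def reorder(self, order: Sequence[int]) -> "CellTimeMatrix":
        order = list(order)
        return CellTimeMatrix(
            self.values[order], [self.cell_ids[i] for i in order], self.times
        )
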