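"""Artifact filtering and division handling for single-cell trajectories.

Segmentation and tracking errors appear in reporter traces as single-frame
spikes or sustained intensity shifts that return to the original level. Both
are detected from the trajectory's own increments — an excursion whose entry
and exit steps each exceed the standard deviation of the working trace — and
replaced by linear interpolation; the pass is iterated because removing large
artifacts shrinks the SD and exposes smaller ones. Genuine p53 pulses are much
slower (per-frame increments well below the trace SD) and are left intact.

Cell divisions are found on the nuclear geometry channels: area and integrated
marker intensity are normalized to their means, smoothed by the same artifact
pass, averaged, and run through a 1-D Prewitt derivative filter (75 min
support); divisions are the positions where the filter response magnitude
exceeds a threshold. Frames around each division are interpolated out of the
p53 trace, since nuclear-envelope breakdown makes those measurements
meaningless.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import CellTrajectory

__all__ = [
    "PreprocessConfig",
    "remove_spikes_and_shifts",
    "prewitt_kernel",
    "detect_divisions",
    "mask_division_frames",
    "preprocess_trajectory",
]


@dataclass
class PreprocessConfig:
    max_iterations: int = 10
    prewitt_length_min: float = 75.0     # filter support in minutes
    dt_h: float = 0.25                   # sampling interval, hours
    division_threshold: float = 0.5      # on the |Prewitt| response
    division_mask_halfwidth: int = 2     # samples interpolated on each side
    max_shift_samples: int = 16          # longest plateau treated as a shift
    strict_inequality: bool = True       # increments compared to SD strictly
    recompute_sd: bool = True            # SD re-estimated each iteration

    def __post_init__(self) -> None:
        taps = self.prewitt_length_min / (self.dt_h * 60.0)
        if taps <= 0 or abs(taps - round(taps)) > 1e-9:
            raise ValueError("prewitt_length_min must be a positive multiple of the sampling interval")
        if self.division_threshold <= 0:
            raise ValueError("division_threshold must be positive")


def _interpolate_range(x: np.ndarray, lo: int, hi: int) -> None:
    """Replace x[lo..hi] (inclusive) by the chord between flanking points.

    At the array boundary the nearest retained value is extended instead.
    """
    n = x.size
    left = lo - 1
    right = hi + 1
    if left < 0 and right >= n:
        return
    if left < 0:
        x[: hi + 1] = x[right]
    elif right >= n:
        x[lo:] = x[left]
    else:
        span = right - left
        frac = (np.arange(lo, hi + 1) - left) / span
        x[lo : hi + 1] = x[left] + frac * (x[right] - x[left])


def _find_artifact(x: np.ndarray, sd: float, max_plateau: int, strict: bool) -> tuple[int, int] | None:
    """First spike/shift in ``x``: returns the inclusive index range to replace.

    A feature is an increase followed by a decrease (or the reverse), both
    larger than ``sd``, separated by at most ``max_plateau`` samples; the
    samples between the two steps are the artifact. A multi-sample excursion
    must be a plateau — its interior peak-to-peak range no larger than the
    bounding steps — so that a slow pulse arch whose edges graze the
    threshold is not mistaken for a sustained shift. Endpoint excursions
    whose single flanking step exceeds ``sd`` are treated as artifacts too.
    """
    d = np.diff(x)
    exceeds = (np.abs(d) > sd) if strict else (np.abs(d) >= sd)
    idx = np.flatnonzero(exceeds)
    if idx.size == 0:
        return None
    for pos, i in enumerate(idx):
        s_i = np.sign(d[i])
        # look for an opposite-signed large step within the plateau window
        for j in idx[pos + 1 :]:
            if j - i > max_plateau:
                break
            if np.sign(d[j]) == -s_i:
                interior = x[i + 1 : j + 1]
                if j == i + 1 or np.ptp(interior) <= max(abs(d[i]), abs(d[j])):
                    return i + 1, j
                break
    # no paired step: handle boundary artifacts (one-sided excursions)
    if idx[0] == 0:
        return 0, 0
    if idx[-1] == d.size - 1:
        return d.size, d.size
    return None


def remove_spikes_and_shifts(
    signal: np.ndarray, config: PreprocessConfig | None = None
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Iteratively remove spikes and sustained shifts from a trace.

    Returns the cleaned signal (same length) and the list of replaced
    inclusive index ranges. The comparison threshold is the standard
    deviation of the current working copy, recomputed each iteration by
    default so the running estimate tightens as artifacts disappear.
    """
    config = config or PreprocessConfig()
    x = np.asarray(signal, dtype=float).copy()
    if x.size < 3:
        return x, []
    replaced: list[tuple[int, int]] = []
    sd = float(np.std(x, ddof=1))
    for _ in range(config.max_iterations):
        if config.recompute_sd:
            sd = float(np.std(x, ddof=1))
        if sd == 0:
            break
        found_any = False
        guard = 0
        while True:
            hit = _find_artifact(x, sd, config.max_shift_samples, config.strict_inequality)
            if hit is None:
                break
            lo, hi = hit
            _interpolate_range(x, lo, hi)
            replaced.append((lo, hi))
            found_any = True
            guard += 1
            if guard > x.size:
                break
        if not found_any:
            break
    return x, replaced


def prewitt_kernel(config: PreprocessConfig) -> np.ndarray:
    """1-D Prewitt derivative kernel of the configured support.

    75 min at 15-min sampling gives the canonical 5-tap [-1, -1, 0, 1, 1].
    """
    taps = int(round(config.prewitt_length_min / (config.dt_h * 60.0)))
    half = taps // 2
    k = np.zeros(2 * half + 1)
    k[:half] = -1.0
    k[half + 1 :] = 1.0
    return k


def detect_divisions(
    area: np.ndarray, marker: np.ndarray, config: PreprocessConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Division time indices from nuclear area and marker discontinuities.

    Both channels are normalized to their means, smoothed by the artifact
    pass, averaged, and filtered with the Prewitt kernel; runs of samples
    where |response| exceeds the threshold are merged into one event at the
    response extremum. Returns (indices, filtered trace).
    """
    config = config or PreprocessConfig()
    area = np.asarray(area, dtype=float)
    marker = np.asarray(marker, dtype=float)
    if area.size != marker.size:
        raise ValueError("area and marker must have the same length")
    a = area / np.mean(area)
    m = marker / np.mean(marker)
    a, _ = remove_spikes_and_shifts(a, config)
    m, _ = remove_spikes_and_shifts(m, config)
    combined = 0.5 * (a + m)

    k = prewitt_kernel(config)
    half = k.size // 2
    padded = np.pad(combined, half, mode="edge")
    response = np.convolve(padded, k[::-1], mode="valid")

    above = np.abs(response) > config.division_threshold
    indices = []
    i = 0
    n = above.size
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            run = np.abs(response[i : j + 1])
            indices.append(i + int(np.argmax(run)))
            i = j + 1
        else:
            i += 1
    return np.asarray(indices, dtype=int), response


def mask_division_frames(
    traj: CellTrajectory,
    divisions: np.ndarray | list[int],
    config: PreprocessConfig | None = None,
) -> CellTrajectory:
    """Interpolate p53 over a window around each division.

    Windows of ``division_mask_halfwidth`` samples on each side are merged
    when they overlap and replaced by the chord between flanking retained
    points (nearest-value extension at the grid boundary).
    """
    config = config or PreprocessConfig()
    out = traj.copy()
    n = out.p53.size
    hw = config.division_mask_halfwidth
    intervals: list[list[int]] = []
    for idx in sorted(int(i) for i in divisions):
        if not 0 <= idx < n:
            raise ValueError(f"division index {idx} outside grid")
        lo, hi = max(0, idx - hw), min(n - 1, idx + hw)
        if intervals and lo <= intervals[-1][1] + 1:
            intervals[-1][1] = max(intervals[-1][1], hi)
        else:
            intervals.append([lo, hi])
    for lo, hi in intervals:
        _interpolate_range(out.p53, lo, hi)
    return out


def preprocess_trajectory(
    traj: CellTrajectory, config: PreprocessConfig | None = None
) -> tuple[CellTrajectory, dict]:
    """Full preprocessing of one cell: divisions → masking → spike/shift pass.

    Returns the cleaned trajectory (divisions recorded in hours) and a QC
    dict with the number of divisions and replaced ranges.
    """
    config = config or PreprocessConfig()
    div_idx, _resp = detect_divisions(traj.area, traj.marker, config)
    masked = mask_division_frames(traj, div_idx, config)
    cleaned, ranges = remove_spikes_and_shifts(masked.p53, config)
    masked.p53 = cleaned
    masked.divisions = [float(traj.times[i]) for i in div_idx]
    qc = {
        "cell_id": traj.cell_id,
        "n_divisions": int(div_idx.size),
        "n_replaced_ranges": len(ranges),
        "replaced_ranges": ranges,
    }
    return masked, qc
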