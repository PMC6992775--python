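"""Pulse detection by band normalization and Smith-Waterman-style DTW.

Each trajectory is first rescaled into [0, 1] with a *band*: a lower envelope
(running local minimum, capped from above) and an upper envelope (running
local maximum, floored from below, kept at least a minimum width above the
lower bound). Band normalization emphasises slow pulse-scale fluctuations and
makes cells with different absolute levels comparable to one template.

A symmetric raised-cosine peak pattern (default 4 h, range 0–1) is then
aligned against the normalized trace with a local (subsequence) variant of
dynamic time warping: the accumulated cost is free to start at any signal
position (first pattern column carries only its local cost), a virtual +∞ row
prevents alignments before the signal starts, and occurrences end at local
minima of the last column below an acceptance threshold. Backtracking gives
each occurrence's start; overlapping occurrences are filtered greedily by
cost. Pulse amplitudes are measured on the raw (non-band-normalized) trace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import maximum_filter1d, minimum_filter1d

from .core import CellTrajectory, PulseFeature

__all__ = [
    "BandConstants",
    "BandEnvelope",
    "band_constants_for_population",
    "band_envelope",
    "band_normalize",
    "make_peak_pattern",
    "dtw_match",
    "filter_overlaps",
    "pulse_features",
    "detect_pulses",
    "pulse_state_probabilities",
]


@dataclass
class BandConstants:
    """Constants shaping the normalization band.

    ``lower_cap_pct`` / ``upper_floor_pct`` are percentiles of the cell's own
    signal used when the absolute cap/floor are not given. ``min_band_width``
    is an absolute width in the population's units (see
    :func:`band_constants_for_population`).
    """

    extremum_window_h: float = 6.0     # 1.5 × pattern length
    min_band_width: float | None = None
    lower_cap: float | None = None
    upper_floor: float | None = None
    lower_cap_pct: float = 60.0
    upper_floor_pct: float = 40.0
    anchor_length_h: float = 3.0       # edge extension, half the window

    def __post_init__(self) -> None:
        if self.min_band_width is not None and self.min_band_width <= 0:
            raise ValueError("min band width must be positive")
        if self.anchor_length_h < 0:
            raise ValueError("anchor length must be nonnegative")


@dataclass
class BandEnvelope:
    lower: np.ndarray
    upper: np.ndarray


def band_constants_for_population(
    signals: list[np.ndarray], **overrides
) -> BandConstants:
    """Derive band constants from a population of traces.

    The minimum band width defaults to 10% of the population's
    baseline-to-peak range (2nd to 98th percentile of all values).
    """
    allv = np.concatenate([np.asarray(s, dtype=float) for s in signals])
    lo, hi = np.percentile(allv, [2.0, 98.0])
    width = max(0.1 * (hi - lo), 1e-9)
    overrides.setdefault("min_band_width", width)
    return BandConstants(**overrides)


def band_envelope(
    signal: np.ndarray, constants: BandConstants, dt_h: float = 0.25
) -> BandEnvelope:
    """Running-extrema band around a trace.

    The signal is anchor-extended at both edges (constant extension of
    ``anchor_length_h``), the lower/upper bounds are running minima/maxima
    over ``extremum_window_h``, the lower bound is clamped from above by the
    cap, the upper from below by the floor, and the band is kept at least
    ``min_band_width`` wide.
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 2:
        raise ValueError("signal too short for a band")
    width = constants.min_band_width
    if width is None:
        lo_p, hi_p = np.percentile(x, [2.0, 98.0])
        width = max(0.1 * (hi_p - lo_p), 1e-9)
    cap = constants.lower_cap
    if cap is None:
        cap = float(np.percentile(x, constants.lower_cap_pct))
    floor = constants.upper_floor
    if floor is None:
        floor = float(np.percentile(x, constants.upper_floor_pct)) + width

    n_anchor = int(round(constants.anchor_length_h / dt_h))
    ext = np.pad(x, n_anchor, mode="edge") if n_anchor else x
    n_win = max(1, int(round(constants.extremum_window_h / dt_h)) | 1)  # odd
    lower = minimum_filter1d(ext, size=n_win, mode="nearest")
    upper = maximum_filter1d(ext, size=n_win, mode="nearest")
    if n_anchor:
        lower = lower[n_anchor:-n_anchor]
        upper = upper[n_anchor:-n_anchor]
    lower = np.minimum(lower, cap)
    upper = np.maximum(upper, floor)
    upper = np.maximum(upper, lower + width)
    return BandEnvelope(lower=lower, upper=upper)


def band_normalize(signal: np.ndarray, envelope: BandEnvelope) -> np.ndarray:
    """Rescale a trace into [0, 1] within its band (hard clip)."""
    x = np.asarray(signal, dtype=float)
    if x.size != envelope.lower.size:
        raise ValueError("envelope does not match signal length")
    return np.clip((x - envelope.lower) / (envelope.upper - envelope.lower), 0.0, 1.0)


def make_peak_pattern(length_h: float = 4.0, dt_h: float = 0.25) -> np.ndarray:
    """Symmetric raised-cosine peak template in [0, 1].

    p_j = sin²(π j / (M − 1)): endpoints 0, maximum 1 at the midpoint,
    mirror-symmetric. Length 4 h at 15-min sampling gives 17 samples.
    """
    m = int(round(length_h / dt_h)) + 1
    if m < 3:
        raise ValueError("pattern needs at least 3 samples")
    j = np.arange(m)
    return np.sin(np.pi * j / (m - 1)) ** 2


def dtw_match(
    signal: np.ndarray,
    pattern: np.ndarray,
    threshold: float | None = None,
    *,
    min_len: int | None = None,
    max_len: int | None = None,
) -> tuple[list[tuple[int, int, float]], np.ndarray]:
    """Subsequence DTW of a peak template against a normalized trace.

    Scoring matrix S over rows i (signal) and columns j (pattern) with local
    cost |x_i − p_j| and steps {(1,0), (0,1), (1,1)}; the first pattern column
    carries only its local cost (free start), and the virtual row above the
    first signal sample is +∞. Candidate occurrences end at local minima of
    the last column with S below ``threshold`` (default 0.15 × pattern
    samples, i.e. a mean per-step dissimilarity of 0.15) and their starts are
    found by backtracking. Candidates shorter than half or longer than 4× the
    pattern are rejected as degenerate warps.

    Returns (candidates, score matrix), candidates as (start, end, cost) in
    sample indices, end inclusive.
    """
    x = np.asarray(signal, dtype=float)
    p = np.asarray(pattern, dtype=float)
    n, m = x.size, p.size
    if n == 0:
        raise ValueError("empty signal")
    if threshold is None:
        threshold = 0.15 * m
    if min_len is None:
        min_len = max(2, m // 2)
    if max_len is None:
        max_len = 4 * m

    cost = np.abs(x[:, None] - p[None, :])
    S = np.empty((n, m))
    S[:, 0] = cost[:, 0]  # free start: no accumulated prior cost
    # first signal row: only horizontal steps are possible (virtual +inf row)
    S[0, 1:] = cost[0, 1:].cumsum() + cost[0, 0]
    for i in range(1, n):
        ci = cost[i]
        si = S[i]
        sp = S[i - 1]
        for j in range(1, m):
            si[j] = ci[j] + min(sp[j], si[j - 1], sp[j - 1])

    # candidate ends: local minima of the last column below the threshold;
    # a flat run (plateau) contributes its leftmost index, and the array
    # bounds count as +inf
    last = S[:, m - 1]
    ends = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and last[j + 1] == last[i]:
            j += 1
        left = last[i - 1] if i > 0 else np.inf
        right = last[j + 1] if j + 1 < n else np.inf
        if last[i] < left and last[i] < right and last[i] < threshold:
            ends.append(i)
        i = j + 1

    candidates = []
    for end in ends:
        i, j = end, m - 1
        while j > 0:
            if i > 0:
                moves = (S[i - 1, j - 1], S[i - 1, j], S[i, j - 1])
                best = int(np.argmin(moves))
            else:
                best = 2
            if best == 0:
                i, j = i - 1, j - 1
            elif best == 1:
                i -= 1
            else:
                j -= 1
        length = end - i + 1
        if min_len <= length <= max_len:
            candidates.append((i, end, float(last[end])))
    return candidates, S


def filter_overlaps(
    candidates: list[tuple[int, int, float]],
) -> list[tuple[int, int, float]]:
    """Greedy non-overlap filter: accept in ascending cost order.

    Any positive-length intersection in time counts as overlap; two matches
    that merely share one boundary sample (the valley between two pulses)
    intersect in a single point of zero duration and are both kept.
    Survivors are returned in temporal order.
    """
    accepted: list[tuple[int, int, float]] = []
    for start, end, cost in sorted(candidates, key=lambda c: (c[2], c[0])):
        if all(end <= a_start or start >= a_end for a_start, a_end, _ in accepted):
            accepted.append((start, end, cost))
    return sorted(accepted, key=lambda c: c[0])


def pulse_features(
    raw_signal: np.ndarray,
    matches: list[tuple[int, int, float]],
    dt_h: float,
    cell_id: str = "",
) -> list[PulseFeature]:
    """Durations and amplitudes of accepted matches.

    Amplitude is max − min of the *raw* (preprocessed, cross-experiment
    normalized) trace within the match, not of the band-normalized one.
    """
    x = np.asarray(raw_signal, dtype=float)
    out = []
    for k, (start, end, cost) in enumerate(sorted(matches, key=lambda c: c[0])):
        seg = x[start : end + 1]
        out.append(
            PulseFeature(
                cell_id=cell_id,
                start_h=start * dt_h,
                end_h=end * dt_h,
                amplitude=float(seg.max() - seg.min()),
                cost=cost,
                index=k,
            )
        )
    return out


def detect_pulses(
    traj: CellTrajectory,
    constants: BandConstants | None = None,
    *,
    pattern_length_h: float = 4.0,
    threshold: float | None = None,
) -> list[PulseFeature]:
    """Full per-cell pulse detection: band → normalize → DTW → features."""
    dt = traj.dt
    constants = constants or BandConstants()
    env = band_envelope(traj.p53, constants, dt)
    norm = band_normalize(traj.p53, env)
    pattern = make_peak_pattern(pattern_length_h, dt)
    cands, _ = dtw_match(norm, pattern, threshold)
    accepted = filter_overlaps(cands)
    return pulse_features(traj.p53, accepted, dt, cell_id=traj.cell_id)


def pulse_state_probabilities(
    features_by_cell: dict[str, list[PulseFeature]],
    times: np.ndarray,
    max_pulse_index: int = 5,
) -> np.ndarray:
    """P_k(t): fraction of cells whose k-th pulse interval contains t.

    Returns an array of shape (max_pulse_index, len(times)); the column sums
    never exceed 1 because one cell occupies at most one pulse state at a
    time.
    """
    times = np.asarray(times, dtype=float)
    n_cells = len(features_by_cell)
    probs = np.zeros((max_pulse_index, times.size))
    if n_cells == 0:
        return probs
    for feats in features_by_cell.values():
        for f in feats:
            if f.index >= max_pulse_index:
                continue
            inside = (times >= f.start_h) & (times <= f.end_h)
            probs[f.index, inside] += 1.0
    return probs / n_cells
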