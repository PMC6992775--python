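"""Synthetic single-cell p53 trajectory generator.

Emulates the statistical structure of time-lapse p53 reporter data: pulsatile
nuclear accumulation after ionizing radiation with a temperature-dependent
period (Q10 scaling of the pulse rate), cell-to-cell asynchrony and amplitude
heterogeneity, the sustained non-pulsatile regime above ~40 °C, segmentation
spikes and sustained intensity shifts, division events (nuclear-area halving,
marker discontinuity, a single-frame p53 spike) and per-experiment affine
batch effects.

Truth tables record every injected pulse, artifact and division so that each
downstream stage can be scored against ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import CellTrajectory, Experiment, TemperatureProtocol

__all__ = [
    "GeneratorConfig",
    "period_at",
    "division_rate_per_24h",
    "pulse_train",
    "sustained_trajectory",
    "inject_artifacts",
    "generate_experiment",
]


@dataclass
class GeneratorConfig:
    """All parameters of the synthetic trajectory model.

    Times are hours, intensities arbitrary units. Amplitude and baseline vary
    across cells as lognormals with the given coefficient of variation.
    """

    dt: float = 0.25
    duration: float = 24.0

    # pulsatile regime
    period_37: float = 5.5           # mean inter-pulse period at 37 °C
    q10: float = 1.5                 # fold change of pulse rate per +10 °C
    period_jitter_cv: float = 0.08   # per-interval multiplicative jitter
    first_peak_delay_mean: float = 3.0
    first_peak_delay_sd: float = 0.5
    pulse_width_37: float = 4.5      # full width of one pulse at 37 °C
    amplitude_mean: float = 100.0
    amplitude_cv: float = 0.25
    amplitude_damping: float = 0.9   # per-pulse multiplicative damping
    baseline_mean: float = 50.0
    baseline_cv: float = 0.2
    drift_39: float = 0.0            # a.u./h slow rise of unirradiated cells ≥39 °C

    # sustained (hyperthermia) regime
    regime_switch_temp: float = 40.0
    sustained_peak_time_irr: float = 8.0    # pre-equilibrated, irradiated
    sustained_peak_time_acute: float = 4.0  # acutely shifted, irradiated
    plateau_frac_unirr: float = 0.6         # unirradiated plateau vs irr. peak
    sustained_amp_factor: float = 1.5       # vs pulse amplitude at 37 °C
    plateau_tau: float = 4.0                # rise time constant, unirradiated

    # artifacts
    noise_sd: float = 4.0
    spike_rate: float = 0.5          # expected segmentation spikes / trajectory
    spike_magnitude_mean: float = 150.0
    spike_magnitude_sd: float = 30.0
    shift_rate: float = 0.3          # expected sustained shifts / trajectory
    shift_magnitude_mean: float = 100.0
    shift_magnitude_sd: float = 20.0
    shift_duration_range: tuple[float, float] = (1.0, 3.0)  # hours
    division_rate_24h_37: float = 1.2
    division_rate_irradiated: float = 0.05
    division_spike: float = 80.0     # single-frame p53 jump at mitosis
    area_mean: float = 1.0
    marker_mean: float = 1.0
    area_noise_cv: float = 0.02
    area_recovery_h: float = 10.0    # regrowth time after division halving

    # batch effect (affine, per experiment)
    batch_gain: float = 1.0
    batch_offset: float = 0.0

    # temperature ramp between protocol segments (0 = instantaneous)
    ramp_duration_h: float = 0.0

    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.q10 <= 0:
            raise ValueError("q10 must be positive")
        if not 0.0 <= self.plateau_frac_unirr <= 1.0:
            raise ValueError("plateau_frac_unirr must lie in [0, 1]")
        if self.amplitude_cv < 0:
            raise ValueError("amplitude_cv must be nonnegative")

    @property
    def times(self) -> np.ndarray:
        n = int(round(self.duration / self.dt)) + 1
        return np.arange(n) * self.dt

    def to_dict(self) -> dict:
        return asdict(self)


def period_at(config: GeneratorConfig, temperature: float) -> float:
    """Mean inter-pulse period at ``temperature``: period_37 · q10^((37−T)/10)."""
    return config.period_37 * config.q10 ** ((37.0 - temperature) / 10.0)


def division_rate_per_24h(
    config: GeneratorConfig, temperature: float, irradiated: bool
) -> float:
    """Expected divisions per cell per 24 h.

    Unirradiated proliferation peaks at normothermia and falls off on both
    sides (near-arrest at 41 °C); irradiated cells arrest at all temperatures.
    """
    if irradiated:
        return config.division_rate_irradiated
    return config.division_rate_24h_37 * math.exp(-(((temperature - 37.0) / 3.0) ** 2))


def _lognormal(rng: np.random.Generator, mean: float, cv: float) -> float:
    if cv <= 0:
        return mean
    sigma2 = math.log(1.0 + cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, math.sqrt(sigma2)))


def _raised_cosine(times: np.ndarray, peak: float, width: float, amp: float) -> np.ndarray:
    """Symmetric raised-cosine pulse: 0 → amp → 0 over ``width`` hours."""
    out = np.zeros_like(times)
    half = width / 2.0
    mask = np.abs(times - peak) <= half
    if half > 0:
        out[mask] = amp * np.sin(np.pi * (times[mask] - peak + half) / width) ** 2
    return out


def pulse_train(
    config: GeneratorConfig,
    temperature: float,
    irradiated: bool,
    rng: np.random.Generator,
    *,
    t_start: float = 0.0,
    t_end: float | None = None,
    baseline: float | None = None,
    amplitude: float | None = None,
) -> tuple[np.ndarray, list[dict]]:
    """Clean pulsatile p53 trace plus per-pulse truth records.

    Pulses are symmetric raised cosines on a flat baseline. Peak spacing
    follows the Q10-scaled period with multiplicative jitter; widths scale
    with the same temperature factor and are clipped so neighbouring pulses
    never overlap. Unirradiated cells below 39 °C emit no pulses; at ≥39 °C a
    small optional drift can be enabled (default off).
    """
    if temperature >= config.regime_switch_temp:
        raise ValueError(
            "pulse_train requires temperature below the regime switch; "
            "use sustained_trajectory"
        )
    times = config.times
    if t_end is None:
        t_end = float(times[-1])
    if baseline is None:
        baseline = _lognormal(rng, config.baseline_mean, config.baseline_cv)
    signal = np.full_like(times, baseline)

    if not irradiated:
        if temperature >= 39.0 and config.drift_39 > 0:
            in_span = (times >= t_start) & (times <= t_end)
            signal[in_span] += config.drift_39 * (times[in_span] - t_start)
        return signal, []

    scale = config.q10 ** ((37.0 - temperature) / 10.0)
    period = config.period_37 * scale
    width = config.pulse_width_37 * scale
    if amplitude is None:
        amplitude = _lognormal(rng, config.amplitude_mean, config.amplitude_cv)

    # peak times: temperature-scaled first-peak delay, then jittered periods;
    # only pulses fully inside [t_start, t_end] are emitted, so every truth
    # record corresponds to a completely observed pulse
    peaks = []
    delay = scale * rng.normal(config.first_peak_delay_mean, config.first_peak_delay_sd)
    t = t_start + max(width / 2.0 + config.dt, delay)
    while t + width / 2.0 <= t_end + 1e-9:
        peaks.append(t)
        step = period * max(0.3, 1.0 + rng.normal(0.0, config.period_jitter_cv))
        t = t + step
    truth: list[dict] = []
    for k, peak in enumerate(peaks):
        w = width
        if k > 0:
            w = min(w, 1.96 * (peak - peaks[k - 1]) / 2.0)
        if k + 1 < len(peaks):
            w = min(w, 1.96 * (peaks[k + 1] - peak) / 2.0)
        amp = amplitude * config.amplitude_damping**k
        signal += _raised_cosine(times, peak, w, amp)
        truth.append(
            {
                "pulse_index": k,
                "start_h": peak - w / 2.0,
                "peak_h": peak,
                "end_h": peak + w / 2.0,
                "amplitude": amp,
                "width_h": w,
            }
        )
    return signal, truth


def _gamma_bump(t: np.ndarray, t_peak: float, shape: float) -> np.ndarray:
    """Unimodal curve in [0, 1] peaking exactly at ``t_peak``."""
    x = np.clip(t / t_peak, 0.0, None)
    return x**shape * np.exp(shape * (1.0 - x))


def sustained_trajectory(
    config: GeneratorConfig,
    irradiated: bool,
    pre_equilibrated: bool,
    rng: np.random.Generator,
    *,
    t_start: float = 0.0,
    baseline: float | None = None,
    amplitude: float | None = None,
) -> np.ndarray:
    """Clean p53 trace in the hyperthermia regime (≥ regime switch temp).

    Irradiated, pre-equilibrated cells rise to a maximum at
    ``sustained_peak_time_irr`` (default 8 h) then decline slowly; acutely
    shifted irradiated cells peak at 4 h and decay faster. Unirradiated,
    pre-equilibrated cells rise monotonically to ``plateau_frac_unirr`` of the
    irradiated peak; acutely shifted unirradiated cells reach ~85% of the
    irradiated peak around 6 h and decline slowly afterwards.
    """
    times = config.times
    if baseline is None:
        baseline = _lognormal(rng, config.baseline_mean, config.baseline_cv)
    if amplitude is None:
        amplitude = _lognormal(
            rng, config.amplitude_mean * config.sustained_amp_factor, config.amplitude_cv
        )
    t = np.clip(times - t_start, 0.0, None)
    if irradiated and pre_equilibrated:
        resp = amplitude * _gamma_bump(t, config.sustained_peak_time_irr, 2.0)
    elif irradiated:
        resp = amplitude * _gamma_bump(t, config.sustained_peak_time_acute, 2.0)
    elif pre_equilibrated:
        resp = (
            config.plateau_frac_unirr
            * amplitude
            * (1.0 - np.exp(-t / config.plateau_tau))
        )
    else:
        resp = 0.85 * amplitude * _gamma_bump(t, 6.0, 1.0)
    return baseline + resp


def inject_artifacts(
    clean: CellTrajectory,
    config: GeneratorConfig,
    rng: np.random.Generator,
    *,
    temperature: float = 37.0,
    irradiated: bool = True,
) -> tuple[CellTrajectory, dict]:
    """Add measurement noise, segmentation spikes/shifts and division events.

    Returns the corrupted trajectory and a truth dict with keys ``spikes``
    (index, magnitude), ``shifts`` (start/end index, magnitude) and
    ``divisions`` (times). Signals are clipped at zero.
    """
    traj = clean.copy()
    n = traj.times.size
    dt = config.dt
    truth: dict = {"spikes": [], "shifts": [], "divisions": []}

    # division events: Poisson count, uniform times, ≥2 h apart
    rate = division_rate_per_24h(config, temperature, irradiated)
    n_div = rng.poisson(rate * config.duration / 24.0)
    div_times: list[float] = []
    for _ in range(n_div):
        for _attempt in range(20):
            t_d = float(rng.uniform(1.0, max(1.0 + dt, config.duration - 1.0)))
            if all(abs(t_d - u) >= 2.0 for u in div_times):
                div_times.append(t_d)
                break
    div_times.sort()

    area = np.full(n, config.area_mean, dtype=float)
    marker = np.full(n, config.marker_mean, dtype=float)
    for t_d in div_times:
        idx = int(round(t_d / dt))
        if idx >= n:
            continue
        # area halves at division, then regrows linearly toward the mean
        rec = np.clip((traj.times[idx:] - traj.times[idx]) / config.area_recovery_h, 0, 1)
        factor = 0.5 + 0.5 * rec
        prev_area = area[idx - 1] if idx > 0 else config.area_mean
        prev_marker = marker[idx - 1] if idx > 0 else config.marker_mean
        area[idx:] = prev_area * factor
        marker[idx:] = prev_marker * factor
        traj.p53[idx] += config.division_spike  # mitotic autofluorescence
        truth["divisions"].append(traj.times[idx])

    # single-frame spikes
    for _ in range(rng.poisson(config.spike_rate)):
        idx = int(rng.integers(1, n - 1))
        mag = max(
            50.0, rng.normal(config.spike_magnitude_mean, config.spike_magnitude_sd)
        ) * (1 if rng.random() < 0.7 else -1)
        traj.p53[idx] += mag
        truth["spikes"].append({"index": idx, "time_h": traj.times[idx], "magnitude": mag})

    # sustained shifts: plateau offset that returns to the original level
    for _ in range(rng.poisson(config.shift_rate)):
        dur = rng.uniform(*config.shift_duration_range)
        span = max(2, int(round(dur / dt)))
        if n - span - 2 <= 1:
            continue
        start = int(rng.integers(1, n - span - 1))
        mag = max(
            40.0, rng.normal(config.shift_magnitude_mean, config.shift_magnitude_sd)
        ) * (1 if rng.random() < 0.5 else -1)
        traj.p53[start : start + span] += mag
        truth["shifts"].append(
            {
                "start_index": start,
                "end_index": start + span - 1,
                "time_h": traj.times[start],
                "magnitude": mag,
            }
        )

    if config.noise_sd > 0:
        traj.p53 += rng.normal(0.0, config.noise_sd, size=n)
    if config.area_noise_cv > 0:
        area += rng.normal(0.0, config.area_noise_cv * config.area_mean, size=n)
        marker += rng.normal(0.0, config.area_noise_cv * config.marker_mean, size=n)

    traj.p53 = np.clip(traj.p53, 0.0, None)
    traj.area = np.clip(area, 0.0, None)
    traj.marker = np.clip(marker, 0.0, None)
    traj.divisions = list(truth["divisions"])
    return traj, truth


def _cell_trace(
    config: GeneratorConfig,
    protocol: TemperatureProtocol,
    irradiated: bool,
    pre_equilibrated: bool,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[dict], float]:
    """Clean p53 trace over the full protocol, switching regimes at shifts."""
    times = config.times
    baseline = _lognormal(rng, config.baseline_mean, config.baseline_cv)
    amplitude = _lognormal(rng, config.amplitude_mean, config.amplitude_cv)
    signal = np.full_like(times, baseline)
    truth: list[dict] = []
    spans = protocol.spans(config.duration)
    for seg_i, (start, end, temp) in enumerate(spans):
        mask = (times >= start - 1e-9) & (times <= end + 1e-9)
        if temp < config.regime_switch_temp:
            seg, seg_truth = pulse_train(
                config,
                temp,
                irradiated,
                rng,
                t_start=start,
                t_end=end,
                baseline=baseline,
                amplitude=amplitude,
            )
            # drop pulses whose peak falls outside this segment
            kept = [p for p in seg_truth if start - 1e-9 <= p["peak_h"] < end + 1e-9]
            signal[mask] = seg[mask]
            truth.extend(kept)
        else:
            amp_s = amplitude * config.sustained_amp_factor
            # a shift mid-experiment is by definition acute at the new temperature
            pre_eq = pre_equilibrated and seg_i == 0
            seg = sustained_trajectory(
                config,
                irradiated,
                pre_eq,
                rng,
                t_start=start,
                baseline=baseline,
                amplitude=amp_s,
            )
            signal[mask] = seg[mask]
    return signal, truth, baseline


def generate_experiment(
    config: GeneratorConfig,
    protocol: TemperatureProtocol,
    dose_gy: float,
    n_cells: int,
    pre_equilibrated: bool = True,
    seed: int | None = None,
    experiment_id: str = "exp",
) -> tuple[Experiment, dict[str, pd.DataFrame]]:
    """Generate an experiment with truth tables.

    Per-cell randomness comes from independent substreams seeded by
    ``(seed, cell index)``, so the population is reproducible and individual
    cells are independent of the population size. The per-experiment affine
    batch effect (``batch_gain``, ``batch_offset``) is applied to the
    intensity channels (p53 and marker) after artifact injection.

    Returns the experiment and truth tables: ``pulses`` (one row per injected
    pulse), ``artifacts`` (spikes and shifts) and ``divisions``.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be at least 1")
    if not isinstance(protocol, TemperatureProtocol):
        raise TypeError("protocol must be a TemperatureProtocol")
    if seed is None:
        seed = config.seed
    irradiated = dose_gy > 0
    times = config.times

    trajectories: list[CellTrajectory] = []
    pulse_rows, artifact_rows, division_rows = [], [], []
    for k in range(n_cells):
        rng = np.random.default_rng([int(seed), k])
        cell_id = f"{experiment_id}_c{k:04d}"
        signal, pulses, _base = _cell_trace(
            config, protocol, irradiated, pre_equilibrated, rng
        )
        clean = CellTrajectory(
            cell_id,
            times,
            signal,
            np.full_like(times, config.area_mean),
            np.full_like(times, config.marker_mean),
        )
        temp0 = protocol.temperature_at(0.0)
        traj, art = inject_artifacts(
            clean, config, rng, temperature=temp0, irradiated=irradiated
        )
        traj.p53 = config.batch_gain * traj.p53 + config.batch_offset
        traj.marker = config.batch_gain * traj.marker + config.batch_offset
        trajectories.append(traj)
        for p in pulses:
            pulse_rows.append({"cell_id": cell_id, **p})
        for s in art["spikes"]:
            artifact_rows.append({"cell_id": cell_id, "kind": "spike", **s})
        for s in art["shifts"]:
            artifact_rows.append({"cell_id": cell_id, "kind": "shift", **s})
        for t_d in art["divisions"]:
            division_rows.append({"cell_id": cell_id, "time_h": t_d})

    exp = Experiment(
        experiment_id=experiment_id,
        protocol=protocol,
        dose_gy=dose_gy,
        pre_equilibrated=pre_equilibrated,
        trajectories=trajectories,
        metadata={"seed": int(seed), "generator": config.to_dict()},
    )
    truth = {
        "pulses": pd.DataFrame(
            pulse_rows,
            columns=["cell_id", "pulse_index", "start_h", "peak_h", "end_h", "amplitude", "width_h"],
        ),
        "artifacts": pd.DataFrame(
            artifact_rows,
            columns=["cell_id", "kind", "index", "time_h", "magnitude", "start_index", "end_index"],
        ),
        "divisions": pd.DataFrame(division_rows, columns=["cell_id", "time_h"]),
    }
    return exp, truth
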