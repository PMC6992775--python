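# p53pulse

Analysis of pulsatile p53 dynamics in single-cell time-lapse trajectories.

After DNA damage (e.g. 10 Gy ionizing radiation), nuclear p53 accumulates in
repeated pulses whose timing is temperature sensitive: cooling below
normothermia slows the pulse clock, mild hyperthermia (~41 °C) abolishes
pulsing altogether and replaces it with a single sustained accumulation.
Quantifying this from fluorescent-reporter movies requires a chain of
trajectory-level methods, which this package implements as a tested, reusable
pipeline for anyone analysing per-cell reporter time series (p53 or other
pulsatile signalling systems):

- **Artifact filtering** — single-frame spikes and sustained intensity shifts
  from segmentation/tracking errors are detected from a cell-specific
  threshold (the standard deviation of the processed trajectory) and replaced
  by linear interpolation, iteratively. Cell divisions are located with a 1-D
  Prewitt derivative filter (75 min support) on the combined, mean-normalized
  nuclear area and marker-intensity traces, and the frames around each
  division are interpolated out of the p53 signal.
- **Inter-experiment normalization** — all experiments share one condition at
  the baseline time point (37 °C, not yet irradiated), so per-rank weights
  `w = sort(reference baseline) / sort(query baseline)` remove the
  multiplicative, time-constant session gain; each cell's whole trajectory is
  scaled by its rank weight.
- **Pitch detection (AMDF)** — the average magnitude difference function
  `D(τ) = mean |x(n) − x(n+τ)|` over windows of 4.5–7 h dips at the lags
  where the trace recurs; the lags of its successive admissible minima (lag
  ≥ 2 h, ≥ 2 h apart) are the *pitch positions*, averaged across window
  lengths. The Q10 temperature coefficient of the pulse rate is
  `exp(10 · slope)` from regressing the log median rate (reciprocal 3rd-pitch
  position) on temperature, with a bootstrap CI over cells.
- **Pulse detection (band-normalized subsequence DTW)** — each trace is
  rescaled into [0, 1] by a running-extrema band with width/cap/floor
  constraints, then a symmetric 4-h peak template is matched by a local
  (Smith-Waterman-style) dynamic time warping: free start in the first
  template column, +∞ above the first signal row, occurrence ends at local
  minima of the last column, starts recovered by backtracking, overlaps
  filtered greedily by cost. Pulse duration and amplitude (max − min of the
  raw trace inside the match) follow directly.
- **Population statistics** — median/inter-quartile trajectories, coefficient
  of variation over time, time-by-time autocorrelation heatmaps, integrated
  p53 load, proliferation curves, and permutation-based 95% confidence
  intervals for condition differences.
- **Synthetic data generator** — produces populations with the statistical
  structure the analysis assumes (Q10-scaled pulse periods, asynchrony and
  amplitude heterogeneity, the sustained ≥40 °C regime, segmentation
  artifacts, divisions, affine batch effects) together with truth tables, so
  every stage is validated against ground truth without external data.

## Worked example

```python
import numpy as np
from p53pulse import (
    GeneratorConfig, TemperatureProtocol, generate_experiment,
    preprocess_trajectory, band_constants_for_population, detect_pulses,
    detect_pitches,
)

cfg = GeneratorConfig()  # 24 h at 15-min sampling, period 5.5 h at 37 °C

# irradiated population at 37 °C with default artifact rates
exp, truth = generate_experiment(
    cfg, TemperatureProtocol.constant(37.0), dose_gy=10.0, n_cells=100, seed=1
)

constants = band_constants_for_population([t.p53 for t in exp.trajectories])
counts, durations = [], []
for traj in exp.trajectories:
    cleaned, qc = preprocess_trajectory(traj)
    pulses = detect_pulses(cleaned, constants)
    counts.append(len(pulses))
    durations.extend(f.duration_h for f in pulses)

print("median pulses per cell:", np.median(counts))
print("median pulse duration (h):", round(np.median(durations), 2))

res = detect_pitches(exp.trajectories[0].p53, exp.trajectories[0].dt)
print("first three pitch positions (h):", np.round(res.positions_h, 2))
```

Output:

```
median pulses per cell: 4.0
median pulse duration (h): 4.5
first three pitch positions (h): [ 5.   10.79 16.55]
```

Four pulses fit the 24-h movie at a 5.5-h period; detected durations match
the generator's 4.5-h pulse width; the pitch positions sit near multiples of
the period (the cell's own jittered clock, not exactly 5.5/11/16.5).

The same stages are available from the shell:

```
p53pulse run-all --config run.yaml        # simulate/load → ... → heatmaps
p53pulse simulate|preprocess|normalize|pitch|pulses|stats|viz ...
```

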