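# Methods

This note documents the models and procedures implemented in `p53pulse`,
their assumptions, the parameters that matter, and the design choices made
where the methods' published descriptions leave the design open.

## Data model

A trajectory is one cell's median nuclear p53 reporter intensity, nuclear
area, and integrated nuclear-marker intensity on a uniform grid (default
0.25 h over 24 h; arbitrary units). An experiment is a population of
trajectories sharing one temperature protocol (piecewise-constant schedule),
radiation dose, pre-equilibration flag and time grid, with a baseline index
at which all experiments are assumed to be in the same condition (37 °C,
untreated, by default the first frame).

## Synthetic trajectory generator

The generator emulates the statistical structure of the real data so that
every stage can be scored against truth tables; it is a phenomenological
model, not a mechanistic one.

**Pulsatile regime (below 40 °C).** Irradiated cells emit symmetric
raised-cosine pulses on a flat per-cell baseline. The mean inter-pulse
period at temperature T is `period_37 · q10^((37−T)/10)` — an Arrhenius-type
(Q10) scaling of the pulse rate — and the pulse width scales with the same
factor (pulses lengthen as the clock slows). Asynchrony across cells comes
from a random first-peak delay (scaled by the same temperature factor) plus
multiplicative per-interval jitter; heterogeneity from lognormal per-cell
amplitudes and baselines; later pulses are damped by a per-pulse factor.
Only pulses that fit entirely inside the observation window are generated
and recorded, so the truth table is exactly the set of fully observed
pulses. Unirradiated cells below 39 °C are flat (an optional slow drift at
≥39 °C is off by default). Defaults: period 5.5 h and width 4.5 h at 37 °C
(the first-pulse duration at normothermia is ~4.5 h, rising toward 6.5 h at
33 °C), q10 1.5, first-peak delay 3.0 ± 0.5 h, jitter CV 0.08, amplitude
100 ± 25% a.u., damping 0.9, baseline 50 ± 20% a.u.

**Sustained regime (≥40 °C).** Pulsing is replaced by a single long
accumulation. Irradiated, pre-equilibrated cells follow a gamma-shaped bump
peaking at 8 h with a slow decline; acutely shifted irradiated cells peak at
4 h and decay faster; unirradiated pre-equilibrated cells rise monotonically
to 60% of the irradiated peak (time constant 4 h); acutely shifted
unirradiated cells reach ~85% of the peak near 6 h and decline slowly. The
sustained amplitude is 1.5× the pulsatile amplitude. A temperature shift
mid-experiment switches regime at the shift (treated as instantaneous;
a linear ramp option exists for the ~30-min cooling of a real incubator).

**Artifacts.** Measurement noise is additive Gaussian (SD 4 a.u.).
Segmentation spikes are single-frame excursions (Poisson count, default 0.5
per trajectory, magnitude ~150 a.u., 70% positive — a wrongly segmented
bright object; negative spikes model lost nuclei and are clipped at zero,
so their realized depth is at most the local signal level). Sustained
shifts are offset plateaus of 1–3 h (0.3 per trajectory, ~100 a.u.) that
return to the original level. Divisions halve the nuclear area and marker
intensity with linear regrowth over 10 h and add a one-frame p53 spike
(mitotic autofluorescence); the division rate is 1.2/24 h at 37 °C with a
Gaussian fall-off on both sides (near-arrest at 41 °C) and ~0.05/24 h after
10 Gy. A per-experiment affine batch effect (gain, offset) multiplies the
intensity channels after artifact injection. All randomness derives from
per-cell substreams seeded by (seed, cell index), so populations are
bit-reproducible and individual cells do not depend on population size.

**What the generator does not emulate:** dose–response beyond a single
dose flag, lineage structure after division, photobleaching or focus drift,
mechanistic p53–Mdm2–Wip1 feedback, and cell-cycle gating of pulse timing.
Passing recovery tests on this model therefore demonstrates correctness of
the pipeline's algorithms under the stated statistical assumptions, not
performance on any particular microscope's data.

## Preprocessing

Spikes and shifts are excursions whose entry and exit increments both exceed
the standard deviation of the processed trajectory (strict inequality,
configurable), with the two steps of opposite sign separated by at most 4 h.
A multi-sample excursion must additionally be a plateau — interior
peak-to-peak range no larger than the bounding steps — which distinguishes a
sustained shift from a slow pulse arch whose noisy edges graze the
threshold; without this, occasional small-amplitude pulses are interpolated
away. Detected ranges are replaced by linear interpolation between flanking
retained points (nearest-value extension at the boundary), and the pass
iterates with the SD re-estimated on the working copy (the running estimate
tightens as artifacts disappear) until convergence or `max_iterations`.

Divisions are detected on the geometry channels: area and marker are
normalized to their means, smoothed by the same artifact pass (a division
step survives it, having no return step), averaged, and convolved with a
1-D Prewitt derivative kernel of 75-min support (5 taps, [-1,-1,0,1,1], at
15-min sampling). Runs of |response| above the threshold (default 0.5,
chosen to maximize F1 on synthetic truth — a halving step yields |response|
≈ 1) merge into one event at the run's extremum. Frames within ±2 samples
of each division are interpolated out of the p53 trace before artifact
filtering.

## Normalization

Sessions differ by a gain assumed multiplicative and constant in time.
Weights are the elementwise ratios of ascending-sorted baseline
distributions; for unequal cell counts the sorted reference is interpolated
at the query's midpoint quantile positions ((i+½)/n), extrapolating linearly
beyond the extremes. The default application gives each cell the weight of
its baseline rank (ties broken by stable cell order) and scales its whole
trajectory; a per-time-point re-ranking mode exists because the alternative
reading — re-applying weights by rank at every frame — cannot be excluded.
After normalization the sorted baseline equals the reference's exactly for
equal n.

## AMDF pitch detection and Q10

`D(τ)` is computed with the analysis window anchored at the trace start, for
all lags up to length-minus-window. Pitch positions are the lags of the
first three admissible local minima: lag ≥ 2 h, ≥ 2 h after the previous
pitch, plateaus taking the leftmost index. Windows sweep 4.5–7 h in 0.5-h
steps and the k-th positions are averaged across windows.

Minima must also clear a prominence floor: `max(3σ_D, 0.25·ptp(D))`, where
σ_D is a robust noise scale from successive differences of D. Both guards
are necessary in practice: measurement noise sprinkles shallow strict minima
over D (which otherwise drag the k-th pitch systematically earlier — a
temperature-dependent bias that corrupts Q10 by ~0.1), and windows shorter
than the period leave weak structural side-minima where a pulse aligns into
the inter-pulse gap. On noise-free traces σ_D = 0 and true pitch minima are
near-full-range, so the rule reduces to plain local minima. Both thresholds
are exposed as parameters.

Q10 is estimated from per-cell k-th pitch positions (k = 3 by default; the
3rd recurrence integrates three pulse intervals and is the least noisy) at
two or more temperatures: rate = 1/position, then a log-linear regression of
the per-temperature median rate on temperature gives `q10 = exp(10·slope)`
(reducing to the two-point Q10 formula for two temperatures). The 95% CI is
a percentile bootstrap over cells within each temperature. Populations used
for Q10 studies run 36 h so the 3rd pitch plus the longest window fits the
trace even at 33 °C with strong temperature scaling; shorter windows
truncate slow-pulsing cells and bias the estimate.

## Band normalization and subsequence DTW

The band's lower/upper envelopes are running minima/maxima over a 6-h window
(1.5× the template length) on the anchor-extended trace (edge-value
extension, 3 h). The lower bound is capped from above at the cell's 60th
percentile, the upper floored at the 40th percentile plus the minimum width;
the band is kept at least `min_band_width` wide (default 10% of the
population's 2nd-to-98th percentile range). Normalized values are hard-
clipped to [0, 1].

The template is a raised cosine `sin²(πj/(M−1))` of length 4 h. The scoring
matrix uses local cost |x_i − p_j| and steps {down, right, diagonal}; the
first template column carries only its local cost (free start — "zero
accumulated prior cost"), and the virtual row above the first signal sample
is +∞. Candidate ends are local minima of the last column (plateau →
leftmost index, array bounds count as +∞) below the acceptance threshold
(default 0.15 × template samples, i.e. mean per-step dissimilarity 0.15,
calibrated on synthetic truth); starts come from backtracking with the tie
order diagonal → vertical → horizontal. Matches shorter than half or longer
than 4× the template are rejected as degenerate warps. Overlap filtering is
greedy in ascending cost; any positive-duration intersection disqualifies a
candidate, but two matches sharing a single boundary sample (the valley
between consecutive pulses, where backtracking naturally lands) intersect
with zero duration and are both kept. Amplitude is max − min of the raw
(preprocessed, cross-experiment-normalized) trace inside the match, not of
the band-normalized one.

## Population statistics

Quantiles interpolate linearly between order statistics; SD uses the n−1
convention; integration is trapezoidal on the uniform grid, with
division-masked (interpolated) frames used as-is. The autocorrelation
heatmap is the Pearson correlation across cells between every pair of time
points, symmetrized exactly and with the trivial main diagonal masked.

Confidence intervals for condition differences (statistic: difference of
group medians by default) use, by default, the permutation-null interval:
the estimate shifted by the central 2.5–97.5% of the label-permutation
distribution of the statistic. This matches the "permutation testing"
description of the error bars, and its type-I error is controlled by
construction (the CI excludes 0 exactly when the two-sided permutation test
rejects at α = 0.05) — the empirical rate over null simulations is required
to fall in [0.03, 0.07] by the test suite. A within-group bootstrap
percentile mode is provided as the alternative resampling scheme; groups
are sorted internally so results are invariant to input order under a fixed
seed. Default 10,000 resamples.

## Heatmap enhancement

Rows (cells) are sorted by the duration of the first pulse at/after a
reference time (ascending; cells without one last; a start-position key is
also supported since both orderings are in use). The matrix is smoothed
with an 11×11 Gaussian (σ = 11/6 so the support covers ±3σ — the size is
fixed but the σ was an open choice), a 31×31 median filter is applied to
the smoothed result, and the output is their difference (G − M). Both
filters use replicate padding, so a constant matrix maps to exactly zero;
matrices smaller than a filter shrink it with a warning.

## Numerical and interface choices

Time is stored in hours (floats), indices 0-based, sampling 0.25 h by
default; pulse intervals are half-open in samples and reported inclusive in
hours. Tables are tidy long-format CSV with `%.17g` floats and round-trip
parsing, so write→read is bit-exact; short gaps (configurable run length)
are linearly interpolated on read, longer ones are an error naming the
cells. The pipeline runs synthetic-or-loaded input → preprocess → normalize
→ pitch → pulses → stats → heatmaps, records every stage in a manifest, and
is bit-reproducible for a fixed config and seed.

## Known limitations

The spike/shift filter cannot remove excursions smaller than the processed
trajectory's SD (e.g. a lost-nucleus drop on a strongly pulsing cell): with
default settings ~3–6% of injected spikes fall in this blind spot. The DTW
detector reports partial pulses at trace edges unreliably (the template must
be consumed in full), which is why the generator only scores fully observed
pulses. Band constants and the DTW threshold are calibrated on synthetic
truth, not on any real dataset; applying the pipeline to real data should
start by re-examining those defaults. The Q10 regression weights all
temperatures equally and assumes exponential rate scaling over the whole
range.
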