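"""Population-level summaries and resampling inference.

Median/IQR trajectories, coefficients of variation over time, time-by-time
autocorrelation heatmaps, integrated p53 load, permutation/bootstrap
confidence intervals for condition differences, and proliferation curves.
"""

from __future__ import annotations

import warnings

import numpy as np

from .core import Experiment, PermutationCI, PopulationSummary

__all__ = [
    "population_summary",
    "cv_over_time",
    "autocorrelation_heatmap",
    "integrated_p53",
    "permutation_ci",
    "proliferation",
]


def population_summary(
    experiment: Experiment, q_lower: float = 0.25, q_upper: float = 0.75
) -> PopulationSummary:
    """Per-time-point median and inter-quantile band across cells.

    Quantiles use linear interpolation between order statistics.
    """
    mat = experiment.p53_matrix()
    return PopulationSummary(
        times=experiment.times,
        median=np.median(mat, axis=0),
        lower=np.quantile(mat, q_lower, axis=0),
        upper=np.quantile(mat, q_upper, axis=0),
        n_cells=experiment.n_cells,
        q_lower=q_lower,
        q_upper=q_upper,
    )


def cv_over_time(experiment: Experiment) -> np.ndarray:
    """Coefficient of variation (sample SD / mean) across cells per time point.

    Time points with zero mean yield NaN.
    """
    mat = experiment.p53_matrix()
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean != 0, sd / mean, np.nan)
    return cv


def autocorrelation_heatmap(experiment: Experiment) -> np.ndarray:
    """Pearson correlation across cells between every pair of time points.

    Returns a symmetric (n_times, n_times) matrix with the main diagonal set
    to NaN (it is 1 by definition and hidden in the usual display); time
    points with zero variance across cells give NaN rows/columns.
    """
    mat = experiment.p53_matrix()
    if mat.shape[0] < 3:
        raise ValueError("autocorrelation needs at least 3 cells")
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.corrcoef(mat, rowvar=False)
    r = 0.5 * (r + r.T)  # exact symmetry (corrcoef is symmetric only to fp error)
    np.fill_diagonal(r, np.nan)
    return r


def integrated_p53(trajectory_p53: np.ndarray, times: np.ndarray, horizon_h: float = 24.0) -> float:
    """Trapezoidal integral of p53 over [0, horizon] (a.u.·h)."""
    times = np.asarray(times, dtype=float)
    x = np.asarray(trajectory_p53, dtype=float)
    if horizon_h > times[-1] + 1e-9:
        raise ValueError("horizon exceeds trajectory duration")
    mask = times <= horizon_h + 1e-9
    return float(np.trapezoid(x[mask], times[mask]))


def permutation_ci(
    group_a: np.ndarray,
    group_b: np.ndarray,
    *,
    statistic: str = "median",
    n_resamples: int = 10_000,
    seed: int = 0,
    method: str = "permutation",
) -> PermutationCI:
    """Difference of group statistics with a resampling 95% CI.

    The point estimate is stat(A) − stat(B) (median by default). With
    ``method="permutation"`` the CI is the estimate shifted by the central
    2.5–97.5% of the label-permutation null distribution of the statistic,
    and a two-sided permutation p-value is reported; the CI excludes 0
    exactly when the permutation test rejects at α = 0.05. With
    ``method="bootstrap"`` the CI is the percentile interval of the statistic
    under within-group resampling.
    """
    # canonical (sorted) order makes the result invariant to how the caller
    # ordered the values within each group, for a fixed seed
    a = np.sort(np.asarray(group_a, dtype=float))
    b = np.sort(np.asarray(group_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if n_resamples < 100:
        warnings.warn("fewer than 100 resamples gives unstable intervals")
    stat = {"median": np.median, "mean": np.mean}[statistic]
    estimate = float(stat(a) - stat(b))
    rng = np.random.default_rng(seed)

    if method == "permutation":
        pooled = np.concatenate([a, b])
        n_a = a.size
        shuffled = rng.permuted(np.tile(pooled, (n_resamples, 1)), axis=1)
        perm = stat(shuffled[:, :n_a], axis=1) - stat(shuffled[:, n_a:], axis=1)
        lo, hi = np.percentile(perm, [2.5, 97.5])
        ci_low, ci_high = estimate + lo, estimate + hi
        p = float((np.abs(perm) >= abs(estimate) - 1e-12).mean())
    elif method == "bootstrap":
        ra = a[rng.integers(0, a.size, (n_resamples, a.size))]
        rb = b[rng.integers(0, b.size, (n_resamples, b.size))]
        boots = stat(ra, axis=1) - stat(rb, axis=1)
        ci_low, ci_high = np.percentile(boots, [2.5, 97.5])
        p = None
    else:
        raise ValueError(f"unknown method: {method}")
    return PermutationCI(
        statistic=f"difference of {statistic}s",
        estimate=estimate,
        ci_low=float(min(ci_low, estimate)),
        ci_high=float(max(ci_high, estimate)),
        n_resamples=n_resamples,
        seed=seed,
        method=method,
        p_value=p,
    )


def proliferation(
    experiment: Experiment, horizon_h: float = 24.0
) -> tuple[np.ndarray, np.ndarray]:
    """Division counts per cell and the cumulative fraction of divided cells.

    Returns (counts, cumulative): ``counts[k]`` is the number of divisions of
    cell k within the horizon; ``cumulative[j]`` is the fraction of cells
    with at least one division by time ``experiment.times[j]`` — monotone
    non-decreasing in [0, 1].
    """
    counts = np.array(
        [
            sum(1 for d in traj.divisions if d <= horizon_h + 1e-9)
            for traj in experiment.trajectories
        ]
    )
    times = experiment.times
    first_division = np.array(
        [min(traj.divisions) if traj.divisions else np.inf for traj in experiment.trajectories]
    )
    cumulative = (first_division[None, :] <= times[:, None] + 1e-9).mean(axis=1)
    return counts, cumulative
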