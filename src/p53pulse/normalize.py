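"""Inter-experiment normalization via sorted-baseline quantile weights.

Imaging sessions differ by an (approximately) multiplicative, time-constant
gain. All experiments share one condition at the baseline time point (cells at
37 °C, not yet irradiated), so the per-quantile ratio of the sorted baseline
p53 distributions of a reference experiment and a query experiment estimates
that gain per rank: weight = sort(reference) / sort(query). Applying each
cell's rank weight to its whole trajectory maps the query population onto the
reference scale.
"""

from __future__ import annotations

import numpy as np

from .core import Experiment, QuantileWeights

__all__ = [
    "baseline_quantile_weights",
    "apply_normalization",
    "normalize_experiment_set",
]


def baseline_quantile_weights(
    reference_baseline: np.ndarray,
    query_baseline: np.ndarray,
    *,
    reference_id: str = "reference",
    query_id: str = "query",
    mode: str = "per-cell-rank",
) -> QuantileWeights:
    """Per-rank weights fitting the query baseline onto the reference.

    With equal cell counts the weights are the elementwise ratios of the
    ascending-sorted baselines. With unequal counts the sorted reference is
    linearly interpolated onto the query's quantile positions (midpoint
    positions (i + 1/2)/n), extrapolating linearly beyond the extremes.
    """
    ref = np.sort(np.asarray(reference_baseline, dtype=float))
    qry = np.sort(np.asarray(query_baseline, dtype=float))
    if ref.size == 0 or qry.size == 0:
        raise ValueError("baselines must be nonempty")
    if np.any(qry <= 0):
        raise ValueError("query baseline values must be positive")
    q_pos = (np.arange(qry.size) + 0.5) / qry.size
    if ref.size == qry.size:
        ref_at_q = ref
    else:
        r_pos = (np.arange(ref.size) + 0.5) / ref.size
        ref_at_q = _interp_linear_extrap(q_pos, r_pos, ref)
        # linear extrapolation can undershoot zero for extreme tails; clamp
        # so the weights stay strictly positive (baselines are positive)
        ref_at_q = np.maximum(ref_at_q, 1e-9 * ref[0])
    weights = ref_at_q / qry
    return QuantileWeights(
        reference_id=reference_id,
        query_id=query_id,
        quantiles=q_pos,
        weights=weights,
        mode=mode,
    )


def _interp_linear_extrap(x: np.ndarray, xp: np.ndarray, fp: np.ndarray) -> np.ndarray:
    """np.interp with linear extrapolation from the two extreme points."""
    y = np.interp(x, xp, fp)
    if xp.size >= 2:
        lo = x < xp[0]
        hi = x > xp[-1]
        slope_lo = (fp[1] - fp[0]) / (xp[1] - xp[0])
        slope_hi = (fp[-1] - fp[-2]) / (xp[-1] - xp[-2])
        y[lo] = fp[0] + slope_lo * (x[lo] - xp[0])
        y[hi] = fp[-1] + slope_hi * (x[hi] - xp[-1])
    return y


def apply_normalization(experiment: Experiment, weights: QuantileWeights) -> Experiment:
    """Scale each cell (or each time point) by its rank weight.

    ``per-cell-rank`` (default): each cell gets the weight of its baseline
    rank and its whole p53 trajectory is multiplied by that constant — the
    non-biological error is assumed constant in time. Ties at baseline are
    broken by the stable order of cell ids. ``per-timepoint-quantile``
    re-ranks the population at every time point.
    """
    n = experiment.n_cells
    if weights.weights.size != n:
        raise ValueError("weights were not built from this experiment's baseline")
    idx = {t.cell_id: i for i, t in enumerate(experiment.trajectories)}
    if weights.mode == "per-cell-rank":
        baseline = experiment.baseline_values()
        order = np.argsort(baseline, kind="stable")  # ranks; ties by cell order
        w_cell = np.empty(n)
        w_cell[order] = weights.weights
        out = experiment.map_p53(lambda traj: traj.p53 * w_cell[idx[traj.cell_id]])
    elif weights.mode == "per-timepoint-quantile":
        mat = experiment.p53_matrix()
        out_mat = np.empty_like(mat)
        for j in range(mat.shape[1]):
            order = np.argsort(mat[:, j], kind="stable")
            w = np.empty(n)
            w[order] = weights.weights
            out_mat[:, j] = mat[:, j] * w
        out = experiment.map_p53(lambda traj: out_mat[idx[traj.cell_id]])
    else:
        raise ValueError(f"unknown application mode: {weights.mode}")
    out.metadata = dict(experiment.metadata)
    out.metadata["normalization"] = {
        "reference_id": weights.reference_id,
        "mode": weights.mode,
    }
    return out


def normalize_experiment_set(
    experiments: list[Experiment],
    reference_id: str,
    *,
    mode: str = "per-cell-rank",
) -> list[Experiment]:
    """Fit every experiment onto the designated reference experiment.

    The reference is returned unchanged; each other experiment is normalized
    with weights computed from the two baseline distributions. The weights
    used are attached to each experiment's metadata.
    """
    by_id = {e.experiment_id: e for e in experiments}
    if reference_id not in by_id:
        raise KeyError(f"reference experiment {reference_id!r} not found")
    reference = by_id[reference_id]
    ref_baseline = reference.baseline_values()
    out = []
    for exp in experiments:
        if exp.experiment_id == reference_id:
            out.append(exp)
            continue
        w = baseline_quantile_weights(
            ref_baseline,
            exp.baseline_values(),
            reference_id=reference_id,
            query_id=exp.experiment_id,
            mode=mode,
        )
        normalized = apply_normalization(exp, w)
        normalized.metadata["normalization"]["weights"] = w.weights.tolist()
        out.append(normalized)
    return out
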