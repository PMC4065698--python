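"""ROC benchmarking of the segmentation engine on simulated data.

Performance is scored position-wise: every position inherits the mean of its
containing estimated segment, and a threshold ``t`` sweeping from the maximum
to the minimum value declares positions positive (above ``t`` for gain/peak
detection, below ``t`` for loss detection).  True/false positive rates are

    TPR = N(positive | true state of interest) / N(true state of interest)
    FPR = N(positive | not of interest)        / N(not of interest)

and the area under the (FPR, TPR) curve summarizes a sweep.  Segment-count
accuracy is summarized by the mean absolute error sum|n_est - n_true|/n, the
root mean squared error, and the median/mean estimated count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .emission import init_emission_quantile
from .engine import EMConfig, HSMMSpec, decode_smoothed, em_fit, forward_backward, uniform_offdiag, viterbi
from .segmentation import states_to_segments
from .simulate import SimulatedSequence, draw_layout, draw_values
from .sojourn import flat_sojourn, resolve_max_sojourn

__all__ = [
    "ROCResult",
    "roc_points",
    "auc",
    "segment_count_errors",
    "segment_simulated",
    "run_benchmark",
]


@dataclass
class ROCResult:
    """Threshold-sweep operating points and area under the curve."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    direction: str  # "above" | "below"
    auc: float


def roc_points(true_states, est_position_values, interest, direction: str = "above") -> ROCResult:
    """Threshold-sweep ROC over per-position estimated segment means.

    ``true_states`` are 1-based generating states; ``interest`` the set of
    true states of interest.  ``direction="above"`` marks positions with
    value strictly greater than the threshold as positive (gain/peak);
    ``"below"`` marks values strictly smaller (loss).  The sweep runs over the
    sorted unique estimated values from the strictest to the loosest
    threshold, with the degenerate all-negative and all-positive operating
    points pinned at (0,0) and (1,1).
    """
    if direction not in ("above", "below"):
        raise ValueError("direction must be 'above' or 'below'")
    s = np.asarray(true_states)
    x = np.asarray(est_position_values, dtype=float)
    if s.shape != x.shape:
        raise ValueError("true_states and est_position_values must have equal length")
    pos_truth = np.isin(s, list(interest))
    n_pos = int(pos_truth.sum())
    n_neg = int(s.size - n_pos)
    if n_pos == 0:
        raise ValueError("no position belongs to the states of interest; TPR undefined")
    score = x if direction == "above" else -x
    grid = np.unique(score)[::-1]  # strictest first
    # positive: score > threshold
    order = np.argsort(-score, kind="stable")
    sorted_score = score[order]
    sorted_pos = pos_truth[order]
    cum_tp = np.cumsum(sorted_pos)
    cum_fp = np.cumsum(~sorted_pos)
    # index of last element with score > t for each t in grid
    counts = np.searchsorted(-sorted_score, -grid, side="left")
    tp = np.concatenate(([0], np.where(counts > 0, cum_tp[np.maximum(counts - 1, 0)], 0), [n_pos]))
    fp = np.concatenate(([0], np.where(counts > 0, cum_fp[np.maximum(counts - 1, 0)], 0), [n_neg]))
    tpr = tp / n_pos
    fpr = fp / max(n_neg, 1)
    thresholds = np.concatenate(([np.inf], grid, [-np.inf]))
    if direction == "below":
        thresholds = -thresholds
    area = float(np.trapezoid(tpr, fpr))
    return ROCResult(thresholds=thresholds, tpr=tpr, fpr=fpr, direction=direction, auc=area)


def auc(roc: ROCResult) -> float:
    """Trapezoidal area under the ROC curve (endpoints pinned)."""
    order = np.lexsort((roc.tpr, roc.fpr))
    return float(np.trapezoid(roc.tpr[order], roc.fpr[order]))


def segment_count_errors(estimated, truth) -> dict:
    """Segment-count accuracy across replicates.

    MAE = sum|n_est - n_true|/n, RMSE = sqrt(sum (n_est - n_true)^2 / n),
    plus the median and mean of the estimated counts.
    """
    est = np.asarray(estimated, dtype=float)
    tru = np.asarray(truth, dtype=float)
    if est.shape != tru.shape or est.size == 0:
        raise ValueError("estimated and truth must be equal-length, non-empty")
    diff = est - tru
    return {
        "MAE": float(np.abs(diff).mean()),
        "RMSE": float(np.sqrt((diff**2).mean())),
        "median": float(np.median(est)),
        "mean": float(est.mean()),
    }


def _default_spec(values: np.ndarray, scenario: str) -> HSMMSpec:
    family = "norm" if scenario == "cnv" else "pois"
    T = values.size
    M = resolve_max_sojourn(np.arange(1, T + 1), None, None)
    emission = init_emission_quantile(values, 3, family)
    sojourn = flat_sojourn("gamma", 3, M)
    return HSMMSpec(3, np.full(3, 1.0 / 3), uniform_offdiag(3), emission, sojourn, M)


def segment_simulated(
    sim: SimulatedSequence, decode: str = "smoothed", em: EMConfig | None = None
):
    """Segment one simulated sequence with the default engine settings.

    Default settings: J=3, normal (cnv) or Poisson (counts) emissions with
    quantile initialization, gamma sojourn from the flat prior, uniform
    embedded transitions, smoothed-posterior decoding.  Returns
    ``(per-position estimated segment means, decoded states, segment count)``.
    """
    spec0 = _default_spec(sim.values, sim.scenario)
    res = em_fit(sim.values, spec0, em or EMConfig())
    if decode == "viterbi":
        states, _ = viterbi(sim.values, res.spec)
    else:
        states = decode_smoothed(forward_backward(sim.values, res.spec))
    segs = states_to_segments(states, sim.positions)
    est_means = np.empty(sim.T)
    for _, s in segs.iterrows():
        est_means[int(s.i0) : int(s.i1) + 1] = sim.values[int(s.i0) : int(s.i1) + 1].mean()
    return est_means, states, int(len(segs))


def run_benchmark(
    scenario: str,
    r_levels,
    n_formations: int = 10,
    n_iterations: int = 10,
    seed: int = 0,
    decode: str = "smoothed",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicated simulation benchmark at several interstate ratios.

    For each ``r``: ``n_formations`` segment formations are drawn, each
    segment layout fixed while ``n_iterations`` observation sets are redrawn
    on it; every sequence is segmented with the default engine settings and
    position-level (truth, estimated segment mean) pairs are pooled into one
    ROC sweep per direction (gain and loss for ``cnv``, peak for ``counts``).
    Fully seeded and deterministic.

    Returns ``(roc_table, count_table)``: one row per (scenario, r,
    direction) with the AUC, and one row per (scenario, r) with
    segment-count error summaries.
    """
    if scenario not in ("cnv", "counts"):
        raise ValueError("scenario must be 'cnv' or 'counts'")
    roc_rows, count_rows = [], []
    root = np.random.SeedSequence(seed)
    level_seeds = root.spawn(len(list(r_levels)))
    for r, ss in zip(r_levels, level_seeds):
        truth_all, est_all = [], []
        n_est, n_true = [], []
        for f_ss in ss.spawn(n_formations):
            streams = f_ss.spawn(n_iterations + 1)
            layout_rng = np.random.default_rng(streams[0])
            states, lengths = draw_layout(layout_rng, scenario)
            for it_ss in streams[1:]:
                rng = np.random.default_rng(it_ss)
                values = draw_values(rng, states, lengths, r, scenario)
                sim = SimulatedSequence(
                    values=values,
                    true_states=np.repeat(states, lengths),
                    true_segments=int(len(states)),
                    r=float(r),
                    scenario=scenario,
                )
                est_means, _, n_seg = segment_simulated(sim, decode=decode)
                truth_all.append(sim.true_states + 1)
                est_all.append(est_means)
                n_est.append(n_seg)
                n_true.append(sim.true_segments)
        truth = np.concatenate(truth_all)
        est = np.concatenate(est_all)
        if scenario == "cnv":
            sweeps = [({3}, "above", "gain"), ({1}, "below", "loss")]
        else:
            sweeps = [({3}, "above", "peak")]
        for interest, direction, label in sweeps:
            roc = roc_points(truth, est, interest, direction)
            roc_rows.append(
                {"scenario": scenario, "r": r, "direction": label, "auc": roc.auc,
                 "n_positions": truth.size}
            )
        errs = segment_count_errors(n_est, n_true)
        count_rows.append({"scenario": scenario, "r": r, "n_replicates": len(n_est), **errs})
    return pd.DataFrame(roc_rows), pd.DataFrame(count_rows)
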