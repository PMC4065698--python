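"""State-occupancy (sojourn) distributions on discrete durations.

A hidden semi-Markov model replaces the geometric state-occupancy law of an
HMM with an explicit sojourn distribution ``d_j(u)``: the probability of
spending exactly ``u`` consecutive positions in state ``j``.  All families are
defined on the truncated support ``u in {1..M}`` and renormalized there, where
``M`` bounds the time spent in a single state and thereby the O(J*T*M) memory
of the inference recursions.

Supported families
------------------
nonparametric
    A free probability vector of length ``M``.
gamma
    A continuous gamma(shape, scale) discretized by integrating the density
    over unit cells ``[u-1, u)``.
poisson
    Poisson(rate) on the shifted support ``u - 1`` (so ``u = 1`` always has
    positive mass).
nbinom
    Negative binomial(size, prob) on the shifted support ``u - 1``.
geometric
    ``d_j(u) = p^(u-1) (1 - p)`` with self-transition probability ``p``; with
    this family the model reduces to an ordinary HMM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "SojournModel",
    "sojourn_pmf",
    "sojourn_survivor",
    "fit_sojourn_mstep",
    "sojourn_from_annotation",
    "resolve_max_sojourn",
    "flat_sojourn",
    "rescale_sojourn",
]

_FAMILIES = ("nonparametric", "gamma", "poisson", "nbinom", "geometric")

#: relative variance floor applied before gamma/nbinom moment inversion
VARIANCE_FLOOR_FRAC = 1e-2


@dataclass
class SojournModel:
    """Per-state sojourn distributions truncated to ``{1..M}``.

    ``params`` holds one dict per state:

    * nonparametric: ``{"d": vector of length M}``
    * gamma: ``{"shape": a > 0, "scale": s > 0}``
    * poisson: ``{"rate": lam >= 0}``
    * nbinom: ``{"size": n > 0, "prob": p in (0, 1)}``
    * geometric: ``{"p": self-transition probability in (0, 1)}``
    """

    family: str
    M: int
    params: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown sojourn family {self.family!r}")
        if self.M < 1:
            raise ValueError("duration bound M must be >= 1")
        for p in self.params:
            _validate_params(self.family, p, self.M)

    @property
    def J(self) -> int:
        return len(self.params)

    def pmf_matrix(self) -> np.ndarray:
        """Truncated-renormalized pmf, shape ``(J, M)``."""
        return np.vstack([_raw_pmf(self.family, p, self.M) for p in self.params])

    def survivor_matrix(self) -> np.ndarray:
        """Survivor ``D_j(u) = sum_{v>=u} d_j(v)``, shape ``(J, M)``."""
        d = self.pmf_matrix()
        return np.cumsum(d[:, ::-1], axis=1)[:, ::-1]


def _validate_params(family: str, p: dict, M: int) -> None:
    if family == "nonparametric":
        d = np.asarray(p["d"], dtype=float)
        if d.shape != (M,) or np.any(d < 0) or not np.isfinite(d).all():
            raise ValueError("nonparametric sojourn needs a length-M nonnegative vector")
        if d.sum() <= 0:
            raise ValueError("nonparametric sojourn vector has zero mass")
    elif family == "gamma":
        if not (p["shape"] > 0 and p["scale"] > 0):
            raise ValueError("gamma sojourn requires shape > 0 and scale > 0")
    elif family == "poisson":
        if not p["rate"] >= 0:
            raise ValueError("poisson sojourn requires rate >= 0")
    elif family == "nbinom":
        if not (p["size"] > 0 and 0 < p["prob"] < 1):
            raise ValueError("nbinom sojourn requires size > 0 and prob in (0,1)")
    elif family == "geometric":
        if not 0 < p["p"] < 1:
            raise ValueError("geometric sojourn requires p in (0,1)")


def _raw_pmf(family: str, p: dict, M: int) -> np.ndarray:
    u = np.arange(1, M + 1)
    if family == "nonparametric":
        d = np.asarray(p["d"], dtype=float)
    elif family == "gamma":
        edges = np.arange(0, M + 1, dtype=float)
        cdf = stats.gamma.cdf(edges, a=p["shape"], scale=p["scale"])
        d = np.diff(cdf)
    elif family == "poisson":
        d = stats.poisson.pmf(u - 1, p["rate"])
    elif family == "nbinom":
        d = stats.nbinom.pmf(u - 1, p["size"], p["prob"])
    else:  # geometric
        d = p["p"] ** (u - 1.0) * (1.0 - p["p"])
    total = d.sum()
    if total <= 0 or not np.isfinite(total):
        # all mass beyond M: put it on the bound
        d = np.zeros(M)
        d[-1] = 1.0
        return d
    return d / total


def sojourn_pmf(model: SojournModel, state: int, u: int) -> float:
    """Probability of staying exactly ``u`` positions in ``state`` (0-based)."""
    _check_u(model, state, u)
    return float(_raw_pmf(model.family, model.params[state], model.M)[u - 1])


def sojourn_survivor(model: SojournModel, state: int, u: int) -> float:
    """Tail mass ``D_state(u) = sum_{v=u..M} d_state(v)``; ``D(1) = 1``."""
    _check_u(model, state, u)
    d = _raw_pmf(model.family, model.params[state], model.M)
    return float(d[u - 1 :].sum())


def _check_u(model: SojournModel, state: int, u: int) -> None:
    if not 0 <= state < model.J:
        raise IndexError(f"state {state} out of range for J={model.J}")
    if not 1 <= u <= model.M:
        raise ValueError(f"duration u={u} outside {{1..{model.M}}}")


def _weighted_moments(durations: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    wsum = weights.sum()
    mean = float(np.dot(weights, durations) / wsum)
    var = float(np.dot(weights, (durations - mean) ** 2) / wsum)
    return mean, var


def fit_sojourn_mstep(
    durations,
    weights,
    family: str,
    M: int | None = None,
) -> dict:
    """Point-estimate sojourn parameters from (duration, weight) pairs.

    The parametric M-step of the EM algorithm: gamma and nbinom by weighted
    method of moments, poisson by the weighted mean of the shifted durations,
    nonparametric by the normalized weighted histogram over ``1..M``.  A
    variance floor of ``1e-2 * mean^2`` is applied before gamma/nbinom
    inversion so that degenerate (zero-variance) inputs stay finite.
    """
    durations = np.asarray(durations, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if durations.shape != weights.shape:
        raise ValueError("durations and weights must have equal length")
    if np.any(weights < 0) or np.any(durations < 1):
        raise ValueError("weights must be >= 0 and durations >= 1")
    if weights.sum() <= 0:
        raise ValueError("total weight is zero; cannot estimate sojourn parameters")

    mean, var = _weighted_moments(durations, weights)

    if family == "poisson":
        return {"rate": max(mean - 1.0, 0.0)}
    if family == "geometric":
        # mean of geometric on {1,2,...} with success prob 1-p is 1/(1-p)
        return {"p": float(np.clip(1.0 - 1.0 / max(mean, 1.0 + 1e-12), 1e-12, 1 - 1e-12))}
    if family == "gamma":
        var = max(var, VARIANCE_FLOOR_FRAC * mean**2)
        return {"shape": mean**2 / var, "scale": var / mean}
    if family == "nbinom":
        ms = max(mean - 1.0, 1e-9)
        var = max(var, VARIANCE_FLOOR_FRAC * mean**2, ms * (1.0 + VARIANCE_FLOOR_FRAC))
        return {"size": ms**2 / (var - ms), "prob": ms / var}
    if family == "nonparametric":
        if M is None:
            raise ValueError("nonparametric fit requires M")
        hist = np.zeros(M)
        idx = np.clip(np.rint(durations).astype(int), 1, M) - 1
        np.add.at(hist, idx, weights)
        return {"d": hist / hist.sum()}
    raise ValueError(f"unknown sojourn family {family!r}")


def flat_sojourn(family: str, J: int, M: int) -> SojournModel:
    """Uninformative sojourn prior: uniform over ``{1..M}``.

    For parametric families the parameters are moment-matched to the discrete
    uniform (mean ``(M+1)/2``, variance ``(M^2-1)/12``).
    """
    if family == "nonparametric":
        params = [{"d": np.full(M, 1.0 / M)} for _ in range(J)]
        return SojournModel("nonparametric", M, params)
    u = np.arange(1, M + 1, dtype=float)
    w = np.ones(M)
    p = fit_sojourn_mstep(u, w, family, M)
    return SojournModel(family, M, [dict(p) for _ in range(J)])


def sojourn_from_annotation(
    intervals,
    family: str,
    J: int,
    M: int,
    scale: float = 1.0,
) -> SojournModel:
    """Learn a sojourn prior from annotation interval widths.

    ``intervals`` is an iterable of ``(start, end, label)`` in 1-based closed
    coordinates (``label`` may be ``None``).  Widths are divided by ``scale``
    (e.g. the median inter-feature spacing) so the resulting parameters live on
    the engine's feature-count duration axis.  Label classes are rank-mapped by
    mean width: the shortest-width class becomes state 0.  Unlabeled intervals
    are partitioned into ``J`` classes by clustering log-widths.  States with
    no intervals fall back to the flat prior.
    """
    intervals = list(intervals)
    if not intervals:
        return flat_sojourn(family, J, M)

    widths = np.array([max(float(e) - float(s) + 1.0, 1.0) for s, e, _ in intervals])
    widths = np.maximum(widths / float(scale), 1.0)
    labels = [lab for _, _, lab in intervals]

    if all(lab is None for lab in labels):
        groups = _cluster_widths(widths, J)
    else:
        keys = sorted({lab for lab in labels if lab is not None})
        groups = {}
        for w, lab in zip(widths, labels):
            if lab is not None:
                groups.setdefault(lab, []).append(w)
        groups = {k: np.asarray(v) for k, v in groups.items()}
        _ = keys

    # rank classes by mean width: shortest -> state 0
    ordered = sorted(groups.values(), key=lambda w: w.mean())
    flat = flat_sojourn(family, 1, M).params[0]
    params: list[dict] = []
    for j in range(J):
        if j < len(ordered) and len(ordered[j]) > 0:
            w = ordered[j]
            params.append(fit_sojourn_mstep(w, np.ones_like(w), family, M))
        else:
            warnings.warn(f"no annotation intervals for state {j}; using flat prior")
            params.append(dict(flat))
    return SojournModel(family, M, params)


def _cluster_widths(widths: np.ndarray, J: int) -> dict:
    if len(widths) < J:
        return {0: widths}
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=J, n_init=10, random_state=0)
    lab = km.fit_predict(np.log(widths).reshape(-1, 1))
    return {k: widths[lab == k] for k in np.unique(lab)}


def rescale_sojourn(model: SojournModel, scale: float) -> SojournModel:
    """Convert sojourn parameters between duration units (divide by ``scale``).

    Used to map base-pair-unit priors learned from annotation onto the
    feature-count axis: durations scale by ``1/scale``, so the mean scales by
    ``1/scale`` and the variance by ``1/scale**2``; parameters are re-derived
    by moment matching.
    """
    if scale == 1.0:
        return model
    s = float(scale)
    params: list[dict] = []
    for p in model.params:
        if model.family == "gamma":
            params.append({"shape": p["shape"], "scale": p["scale"] / s})
        elif model.family == "poisson":
            params.append({"rate": max((p["rate"] + 1.0) / s - 1.0, 0.0)})
        elif model.family == "geometric":
            mean = max(1.0 / (1.0 - p["p"]) / s, 1.0 + 1e-12)
            params.append({"p": 1.0 - 1.0 / mean})
        elif model.family == "nbinom":
            m = p["size"] * (1.0 - p["prob"]) / p["prob"] + 1.0  # unshifted mean
            v = p["size"] * (1.0 - p["prob"]) / p["prob"] ** 2
            ms = max(m / s - 1.0, 1e-9)
            v = max(v / s**2, ms * (1.0 + VARIANCE_FLOOR_FRAC))
            params.append({"size": ms**2 / (v - ms), "prob": ms / v})
        else:  # nonparametric: rebin the probability vector
            u = np.arange(1, model.M + 1, dtype=float)
            new_u = np.clip(np.rint(u / s), 1, model.M).astype(int)
            d = np.zeros(model.M)
            np.add.at(d, new_u - 1, np.asarray(p["d"], dtype=float))
            params.append({"d": d / d.sum()})
    return SojournModel(model.family, model.M, params)


def resolve_max_sojourn(
    positions,
    max_k: int | None = None,
    max_bp: float | None = None,
    default: int = 1000,
) -> int:
    """Resolve the duration bound ``M`` from ``max_k`` or ``max_bp``.

    ``max_k`` gives ``M`` directly in feature counts; ``max_bp`` infers it as
    the largest number of consecutive features whose genomic span does not
    exceed ``max_bp``.  With neither, ``M = min(T, default)``.  ``M`` is always
    capped at the sequence length ``T``.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.size == 0:
        raise ValueError("positions are empty")
    if np.any(np.diff(positions) <= 0):
        raise ValueError("positions must be strictly increasing")
    T = positions.size
    if max_k is not None and max_bp is not None:
        raise ValueError("max_k and max_bp are mutually exclusive")
    if max_k is not None:
        if max_k < 1:
            raise ValueError("max_k must be >= 1")
        return int(min(max_k, T))
    if max_bp is not None:
        best, i = 1, 0
        for jx in range(T):
            while positions[jx] - positions[i] > max_bp:
                i += 1
            best = max(best, jx - i + 1)
        if best == 1:
            warnings.warn("max_bp smaller than every inter-feature gap; M=1")
        return int(min(best, T))
    return int(min(T, default))
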