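"""Per-state observation (emission) densities for continuous and count data.

Each hidden state ``j`` emits observations from a state-specific density
``b_j``; the model supports normal / Student-t (univariate and multivariate)
emissions for array-type log-ratio data, and Poisson / negative-binomial
emissions for sequencing counts.  Missing observations (NaN) contribute zero
to the log-density and zero weight to the M-step, so multi-sample tracks with
holes are handled without imputation.

State labels are sorted by emission location at initialization time, so
downstream code can rely on "state 0 = lowest signal, state J-1 = highest"
(loss / null / gain for copy number, background / low / peak for counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

__all__ = [
    "EmissionModel",
    "emission_logdensity",
    "init_emission_quantile",
    "init_emission_cluster",
    "fit_emission_mstep",
]

_FAMILIES = ("norm", "mvnorm", "t", "mvt", "pois", "nbinom")
_COUNT_FAMILIES = ("pois", "nbinom")
_MV_FAMILIES = ("mvnorm", "mvt")

#: default lower bound on standard deviations / covariance diagonals
DISPERSION_FLOOR = 1e-3

#: default (fixed) degrees of freedom for the t families
T_DF = 5.0


@dataclass
class EmissionModel:
    """Emission density ``B`` with one parameter dict per state.

    Parameter dicts by family:

    * ``norm``: ``{"mean", "sd"}``
    * ``t``: ``{"mean", "sd", "df"}`` (location/scale/df)
    * ``pois``: ``{"rate"}``
    * ``nbinom``: ``{"size", "prob"}``
    * ``mvnorm``: ``{"mean": (N,), "cov": (N, N)}``
    * ``mvt``: ``{"mean": (N,), "cov": (N, N), "df"}``
    """

    family: str
    N: int
    params: list[dict] = field(default_factory=list)
    floor: float = DISPERSION_FLOOR

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown emission family {self.family!r}")
        if self.N < 1:
            raise ValueError("dimension N must be >= 1")
        if self.family in _MV_FAMILIES:
            for p in self.params:
                cov = np.asarray(p["cov"], dtype=float)
                np.linalg.cholesky(cov)  # raises if not SPD
        else:
            for p in self.params:
                self._check_scalar(p)

    def _check_scalar(self, p: dict) -> None:
        if self.family in ("norm", "t"):
            if not np.isfinite(p["sd"]) or p["sd"] <= 0:
                raise ValueError("sd must be positive and finite")
        elif self.family == "pois":
            if not np.isfinite(p["rate"]) or p["rate"] < 0:
                raise ValueError("poisson rate must be >= 0")
        elif self.family == "nbinom":
            if not (p["size"] > 0 and 0 < p["prob"] < 1):
                raise ValueError("nbinom requires size > 0 and prob in (0,1)")

    @property
    def J(self) -> int:
        return len(self.params)

    def location(self, j: int) -> float:
        """Scalar summary of state j's location (mean of location vector)."""
        p = self.params[j]
        if self.family in _MV_FAMILIES:
            return float(np.mean(p["mean"]))
        if self.family == "pois":
            return float(p["rate"])
        if self.family == "nbinom":
            return float(p["size"] * (1 - p["prob"]) / p["prob"])
        return float(p["mean"])


def _as_matrix(x: np.ndarray, N: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None] if N == 1 else x[None, :]
    if x.shape[1] != N:
        raise ValueError(f"observation dimension {x.shape[1]} != model dimension {N}")
    return x


def emission_logdensity(model: EmissionModel, x) -> np.ndarray:
    """Log emission densities ``log b_j(x_t)``, shape ``(T, J)``.

    NaN entries of ``x`` contribute zero to the log-density (for multivariate
    families the remaining coordinates are evaluated under the corresponding
    marginal distribution).
    """
    X = _as_matrix(x, model.N)
    T = X.shape[0]
    out = np.zeros((T, model.J))
    if model.family in _COUNT_FAMILIES:
        finite = np.isfinite(X)
        vals = X[finite]
        if np.any(vals < 0) or np.any(vals != np.rint(vals)):
            raise ValueError("count emission families require non-negative integers")
    if model.family in _MV_FAMILIES:
        return _mv_logdensity(model, X)
    xcol = X[:, 0]
    miss = ~np.isfinite(xcol)
    xs = np.where(miss, 0.0, xcol)
    for j, p in enumerate(model.params):
        if model.family == "norm":
            lp = stats.norm.logpdf(xs, loc=p["mean"], scale=p["sd"])
        elif model.family == "t":
            lp = stats.t.logpdf(xs, df=p["df"], loc=p["mean"], scale=p["sd"])
        elif model.family == "pois":
            lp = stats.poisson.logpmf(xs.astype(int), p["rate"])
        else:
            lp = stats.nbinom.logpmf(xs.astype(int), p["size"], p["prob"])
        out[:, j] = np.where(miss, 0.0, lp)
    return out


def _mv_logdensity(model: EmissionModel, X: np.ndarray) -> np.ndarray:
    T = X.shape[0]
    out = np.zeros((T, model.J))
    miss = ~np.isfinite(X)
    complete = ~miss.any(axis=1)
    for j, p in enumerate(model.params):
        mean = np.asarray(p["mean"], dtype=float)
        cov = np.asarray(p["cov"], dtype=float)
        if model.family == "mvnorm":
            rv = stats.multivariate_normal(mean=mean, cov=cov)
        else:
            rv = stats.multivariate_t(loc=mean, shape=cov, df=p["df"])
        if complete.any():
            out[complete, j] = rv.logpdf(X[complete])
        for t in np.nonzero(~complete)[0]:
            keep = ~miss[t]
            if not keep.any():
                out[t, j] = 0.0
                continue
            sub_cov = cov[np.ix_(keep, keep)]
            if model.family == "mvnorm":
                out[t, j] = stats.multivariate_normal(mean[keep], sub_cov).logpdf(X[t, keep])
            else:
                out[t, j] = stats.multivariate_t(mean[keep], sub_cov, df=p["df"]).logpdf(
                    X[t, keep]
                )
    return out


def _sort_states(model: EmissionModel) -> EmissionModel:
    order = np.argsort([model.location(j) for j in range(model.J)], kind="stable")
    return replace(model, params=[model.params[j] for j in order])


def init_emission_quantile(data, J: int, family: str, floor: float = DISPERSION_FLOOR) -> EmissionModel:
    """Initialize emissions from evenly spaced quantiles of the pooled data.

    State ``j`` (0-based) takes its location from the empirical quantile at
    level ``(2j+1)/(2J)``; dispersion parameters are estimated once from the
    pooled data and shared across states.
    """
    X = np.asarray(data, dtype=float)
    N = 1 if X.ndim == 1 or family not in _MV_FAMILIES else X.shape[1]
    if family in _MV_FAMILIES:
        X2 = _as_matrix(X, X.shape[1] if X.ndim > 1 else 1)
        N = X2.shape[1]
        levels = (2 * np.arange(J) + 1) / (2 * J)
        locs = np.nanquantile(X2, levels, axis=0)
        cov = _pooled_cov(X2, floor)
        params = [{"mean": locs[j], "cov": cov.copy()} for j in range(J)]
        if family == "mvt":
            for p in params:
                p["df"] = T_DF
        return _sort_states(EmissionModel(family, N, params, floor))

    vals = X.ravel()
    vals = vals[np.isfinite(vals)]
    if vals.size < J:
        raise ValueError(f"need at least J={J} finite observations")
    if np.unique(vals).size == 1:
        import warnings

        warnings.warn("constant data: all states initialized at the same location")
    levels = (2 * np.arange(J) + 1) / (2 * J)
    locs = np.quantile(vals, levels)
    sd = max(float(vals.std()), floor)
    m = float(vals.mean())
    v = max(float(vals.var()), floor)
    params: list[dict] = []
    for j in range(J):
        if family == "norm":
            params.append({"mean": float(locs[j]), "sd": sd})
        elif family == "t":
            params.append({"mean": float(locs[j]), "sd": sd, "df": T_DF})
        elif family == "pois":
            params.append({"rate": max(float(locs[j]), 1e-6)})
        else:  # nbinom: shared size from pooled moments, per-state prob
            size = m**2 / (v - m) if v > m * (1 + 1e-6) else 100.0
            mu = max(float(locs[j]), 1e-6)
            params.append({"size": size, "prob": size / (size + mu)})
    return _sort_states(EmissionModel(family, 1, params, floor))


def init_emission_cluster(
    data, J: int, family: str, floor: float = DISPERSION_FLOOR, seed: int = 0
) -> EmissionModel:
    """Initialize emissions by centroid-based partitioning (k-means).

    The centroid of each cluster becomes the state's location; dispersion is
    estimated within each cluster.  Suited to asymmetric, non-uniform signal
    distributions where quantile levels would misplace the states.
    """
    from sklearn.cluster import KMeans

    X = np.asarray(data, dtype=float)
    mv = family in _MV_FAMILIES
    X2 = _as_matrix(X, X.shape[1] if (X.ndim > 1 and mv) else 1) if mv else X.ravel()[:, None]
    rows = X2[np.isfinite(X2).all(axis=1)]
    if rows.shape[0] < J:
        raise ValueError(f"need at least J={J} complete observations")
    km = KMeans(n_clusters=J, n_init=10, random_state=seed)
    lab = km.fit_predict(rows)
    params: list[dict] = []
    pooled_sd = max(float(rows.std()), floor)
    for j in range(J):
        mem = rows[lab == j]
        if mem.shape[0] == 0:  # pragma: no cover - kmeans guards against this
            mem = rows
        center = km.cluster_centers_[j]
        if mv:
            cov = _pooled_cov(mem, floor) if mem.shape[0] > 1 else np.eye(X2.shape[1]) * floor
            p = {"mean": center, "cov": cov}
            if family == "mvt":
                p["df"] = T_DF
            params.append(p)
        else:
            loc = float(center[0])
            sd = max(float(mem.std()), floor) if mem.shape[0] > 1 else pooled_sd
            if family == "norm":
                params.append({"mean": loc, "sd": sd})
            elif family == "t":
                params.append({"mean": loc, "sd": sd, "df": T_DF})
            elif family == "pois":
                params.append({"rate": max(loc, 1e-6)})
            else:
                mu = max(loc, 1e-6)
                v = max(float(mem.var()), mu * (1 + 1e-2))
                size = mu**2 / (v - mu)
                params.append({"size": size, "prob": size / (size + mu)})
    N = X2.shape[1] if mv else 1
    return _sort_states(EmissionModel(family, N, params, floor))


def _pooled_cov(X: np.ndarray, floor: float) -> np.ndarray:
    rows = X[np.isfinite(X).all(axis=1)]
    cov = np.cov(rows, rowvar=False)
    cov = np.atleast_2d(cov)
    return _floor_cov(cov, floor)


def _floor_cov(cov: np.ndarray, floor: float) -> np.ndarray:
    cov = 0.5 * (cov + cov.T)
    d = np.diag(cov).copy()
    bump = np.maximum(floor - d, 0.0)
    cov = cov + np.diag(bump)
    # jitter until Cholesky succeeds
    eps = 1e-10 * max(np.trace(cov), 1.0)
    for _ in range(10):
        try:
            np.linalg.cholesky(cov)
            return cov
        except np.linalg.LinAlgError:
            cov = cov + np.eye(cov.shape[0]) * eps
            eps *= 10
    return cov


def fit_emission_mstep(
    data,
    posterior: np.ndarray,
    model: EmissionModel,
) -> EmissionModel:
    """Weighted maximum-likelihood / moment re-estimation of the emissions.

    ``posterior`` is the T x J matrix of smoothed state probabilities.  States
    whose total weight falls below 1e-8 keep their previous parameters.  NaN
    observations get zero weight.  Standard deviations and covariance
    diagonals are floored at ``model.floor``.
    """
    X = _as_matrix(data, model.N)
    gamma = np.asarray(posterior, dtype=float)
    if gamma.shape != (X.shape[0], model.J):
        raise ValueError("posterior shape must be (T, J)")
    params: list[dict] = []
    for j in range(model.J):
        w = gamma[:, j]
        prev = model.params[j]
        if model.family in _MV_FAMILIES:
            params.append(_mstep_mv(X, w, prev, model))
        else:
            params.append(_mstep_scalar(X[:, 0], w, prev, model))
    return replace(model, params=params)


def _mstep_scalar(x: np.ndarray, w: np.ndarray, prev: dict, model: EmissionModel) -> dict:
    finite = np.isfinite(x)
    w = np.where(finite, w, 0.0)
    wsum = w.sum()
    if wsum < 1e-8:
        import warnings

        warnings.warn("state weight below 1e-8; keeping previous emission parameters")
        return dict(prev)
    xs = np.where(finite, x, 0.0)
    mean = float(np.dot(w, xs) / wsum)
    var = float(np.dot(w, (xs - mean) ** 2) / wsum)
    if model.family == "norm":
        return {"mean": mean, "sd": max(np.sqrt(var), model.floor)}
    if model.family == "t":
        df = prev["df"]
        scale2 = var * (df - 2.0) / df if df > 2 else var
        return {"mean": mean, "sd": max(np.sqrt(scale2), model.floor), "df": df}
    if model.family == "pois":
        return {"rate": max(mean, 1e-10)}
    # nbinom by weighted moments on the shifted support
    mu = max(mean, 1e-9)
    v = max(var, mu * (1.0 + 1e-2))
    size = mu**2 / (v - mu)
    return {"size": size, "prob": size / (size + mu)}


def _mstep_mv(X: np.ndarray, w: np.ndarray, prev: dict, model: EmissionModel) -> dict:
    finite = np.isfinite(X).all(axis=1)
    w = np.where(finite, w, 0.0)
    wsum = w.sum()
    if wsum < 1e-8:
        import warnings

        warnings.warn("state weight below 1e-8; keeping previous emission parameters")
        return dict(prev)
    Xs = np.where(finite[:, None], X, 0.0)
    mean = (w[:, None] * Xs).sum(axis=0) / wsum
    dx = Xs - mean
    cov = (w[:, None] * dx).T @ dx / wsum
    cov = _floor_cov(cov, model.floor)
    out = {"mean": mean, "cov": cov}
    if model.family == "mvt":
        out["df"] = prev["df"]
        out["cov"] = _floor_cov(cov * (prev["df"] - 2.0) / prev["df"], model.floor)
    return out
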