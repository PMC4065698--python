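"""Exact inference and EM estimation for the hidden semi-Markov model.

The model is parameterized by theta = (pi, A, B, D): initial state
probabilities pi, the embedded transition matrix A (zero diagonal — the
embedded chain moves between *distinct* states), per-state emission densities
B and per-state sojourn distributions D truncated to ``{1..M}``.  The
likelihood of an observation sequence decomposes over runs of constant state:
the first R-1 sojourns contribute their pmf, the final sojourn is
right-censored and contributes its survivor function.

The E-step (forward-backward over run endpoints), smoothed posterior and
Viterbi decoding are implemented as compiled kernels in
:mod:`hsmmseg._kernels`; this module owns the model containers, the EM loop
and the log-space preparation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .emission import EmissionModel, emission_logdensity, fit_emission_mstep
from .sojourn import SojournModel, fit_sojourn_mstep

__all__ = [
    "HSMMSpec",
    "PosteriorProfile",
    "EMConfig",
    "EMResult",
    "forward_backward",
    "complete_likelihood",
    "em_fit",
    "viterbi",
    "decode_smoothed",
    "uniform_offdiag",
]


def uniform_offdiag(J: int) -> np.ndarray:
    """Embedded transition matrix with uniform off-diagonal rows."""
    if J == 1:
        return np.zeros((1, 1))
    A = np.full((J, J), 1.0 / (J - 1))
    np.fill_diagonal(A, 0.0)
    return A


@dataclass
class HSMMSpec:
    """Full HSMM parameter set theta = (pi, A, B, D) with duration bound M."""

    J: int
    pi: np.ndarray
    A: np.ndarray
    emission: EmissionModel
    sojourn: SojournModel
    M: int

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        if self.pi.shape != (self.J,) or abs(self.pi.sum() - 1.0) > 1e-8 or np.any(self.pi < 0):
            raise ValueError("pi must be a length-J probability vector")
        if self.A.shape != (self.J, self.J):
            raise ValueError("A must be J x J")
        if np.any(np.abs(np.diag(self.A)) > 1e-12):
            raise ValueError("A must have a zero diagonal (embedded chain)")
        if self.J > 1 and np.any(np.abs(self.A.sum(axis=1) - 1.0) > 1e-8):
            raise ValueError("rows of A must sum to 1")
        if self.emission.J != self.J or self.sojourn.J != self.J:
            raise ValueError("emission and sojourn must have exactly J states")
        if self.sojourn.M != self.M:
            raise ValueError("sojourn bound must equal spec.M")


@dataclass
class PosteriorProfile:
    """E-step output: smoothed probabilities and EM sufficient statistics."""

    gamma: np.ndarray  # (T, J) smoothed state probabilities
    loglik: float
    duration_weights: np.ndarray  # (J, M) expected complete-sojourn counts
    censored_weights: np.ndarray  # (J, M) expected censored-sojourn mass
    transition_counts: np.ndarray  # (J, J) expected embedded transitions
    first_state: np.ndarray  # (J,) posterior of the initial run's state


@dataclass
class EMConfig:
    max_iter: int = 100
    tol: float = 1e-4  # relative log-likelihood change
    estimate_emission: bool = True
    estimate_sojourn: bool = True
    estimate_A: bool = True
    estimate_pi: bool = False


@dataclass
class EMResult:
    spec: HSMMSpec
    loglik_trace: list = field(default_factory=list)
    converged: bool = False

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1]


def _prepare(obs, spec: HSMMSpec):
    logb = emission_logdensity(spec.emission, obs)
    T = logb.shape[0]
    rowmax = logb.max(axis=1)
    dead = np.nonzero(~np.isfinite(rowmax))[0]
    if dead.size:
        raise FloatingPointError(
            f"all emission densities vanish at position index {int(dead[0])}"
        )
    cum = np.zeros((T + 1, spec.J))
    np.cumsum(logb, axis=0, out=cum[1:])
    d = spec.sojourn.pmf_matrix()
    D = spec.sojourn.survivor_matrix()
    with np.errstate(divide="ignore"):
        logd = np.log(d)
        logD = np.log(D)
        logA = np.log(spec.A) if spec.J > 1 else np.full((1, 1), -np.inf)
        logpi = np.log(spec.pi)
    umax = np.zeros(spec.J, dtype=np.int64)
    for j in range(spec.J):
        nz = np.nonzero(d[j] > 0.0)[0]
        umax[j] = int(nz[-1]) + 1 if nz.size else 1
    return logb, cum, logd, logD, logA, logpi, umax


def forward_backward(obs, spec: HSMMSpec) -> PosteriorProfile:
    """Smoothed state posterior and sufficient statistics (E-step).

    The returned log-likelihood is the total probability of the observations
    under the censored-sojourn likelihood: a sum over all segmentations, with
    the final run weighted by the sojourn survivor function.
    """
    _, cum, logd, logD, logA, logpi, umax = _prepare(obs, spec)
    loglik, logF, logG = _kernels.forward_pass(cum, logd, logD, logA, logpi, umax)
    if not np.isfinite(loglik):
        raise FloatingPointError("zero total likelihood (no admissible segmentation)")
    logE, logB = _kernels.backward_pass(cum, logd, logD, logA, umax)
    gamma, eta, eta_c, xi, first = _kernels.posterior_pass(
        cum, logd, logD, logA, logpi, umax, logF, logG, logE, logB, loglik
    )
    rows = gamma.sum(axis=1)
    if np.any(np.abs(rows - 1.0) > 1e-6):
        raise FloatingPointError("posterior rows deviate from 1; numerical failure")
    gamma = gamma / rows[:, None]
    return PosteriorProfile(gamma, float(loglik), eta, eta_c, xi, first)


def complete_likelihood(states, obs, spec: HSMMSpec) -> float:
    """Log of the complete-data likelihood of one state sequence.

    Direct evaluation of the censored-sojourn factorization: initial
    probability, sojourn pmf of every completed run, embedded transition
    probabilities, the survivor function of the final run, and the emission
    densities.  Serves as the enumeration oracle for the recursions.
    Runs longer than M are impossible and yield ``-inf``.
    """
    states = np.asarray(states, dtype=int)
    logb = emission_logdensity(spec.emission, obs)
    T = states.size
    if logb.shape[0] != T:
        raise ValueError("states and observations must have equal length")
    d = spec.sojourn.pmf_matrix()
    D = spec.sojourn.survivor_matrix()
    with np.errstate(divide="ignore"):
        total = float(np.log(spec.pi[states[0]]))
    total += float(logb[np.arange(T), states].sum())
    # run-length decomposition
    change = np.nonzero(np.diff(states) != 0)[0]
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change, [T - 1]))
    for k in range(starts.size):
        j = states[starts[k]]
        u = int(ends[k] - starts[k] + 1)
        if u > spec.M:
            return -np.inf
        last = k == starts.size - 1
        mass = D[j, u - 1] if last else d[j, u - 1]
        if mass <= 0.0:
            return -np.inf
        total += float(np.log(mass))
        if not last:
            nxt = states[starts[k + 1]]
            a = spec.A[j, nxt]
            if a <= 0.0:
                return -np.inf
            total += float(np.log(a))
    return total


def viterbi(obs, spec: HSMMSpec) -> tuple[np.ndarray, float]:
    """Most probable state sequence and its complete log-likelihood score."""
    _, cum, logd, logD, logA, logpi, umax = _prepare(obs, spec)
    states, score = _kernels.viterbi_pass(cum, logd, logD, logA, logpi, umax)
    if not np.isfinite(score):
        raise FloatingPointError("no admissible state sequence (check M and sojourn support)")
    return states, float(score)


def decode_smoothed(posterior: PosteriorProfile) -> np.ndarray:
    """Per-position argmax of the smoothed probabilities (ties: lower state)."""
    return np.argmax(posterior.gamma, axis=1)


def _sojourn_q(eta_row: np.ndarray, logd_row: np.ndarray) -> float:
    # ignore durations with negligible posterior mass and clip underflowed
    # log-pmf values, so the comparison reflects the mass that matters
    mask = eta_row > 1e-12 * eta_row.sum()
    if not mask.any():
        return 0.0
    return float(np.dot(eta_row[mask], np.maximum(logd_row[mask], -745.0)))


def _update_sojourn(sojourn: SojournModel, eta: np.ndarray, eta_c: np.ndarray) -> SojournModel:
    """Parametric sojourn M-step with a generalized-EM acceptance guard.

    Method-of-moments point estimates (per the parametric M-step) need not
    maximize the expected complete-data log-likelihood exactly, so each
    state's update is kept only if it does not decrease
    ``sum_u eta_j(u) log d_j(u)``; this preserves EM monotonicity.
    """
    M = sojourn.M
    u = np.arange(1, M + 1, dtype=float)
    with np.errstate(divide="ignore"):
        logd_old = np.log(sojourn.pmf_matrix())
        logD_old = np.log(sojourn.survivor_matrix())
    params = []
    for j in range(sojourn.J):
        w = eta[j]
        if w.sum() < 1e-8:
            w = w + eta_c[j]
        if w.sum() < 1e-10:
            params.append(dict(sojourn.params[j]))
            continue
        try:
            cand = fit_sojourn_mstep(u, w, sojourn.family, M)
        except ValueError:
            params.append(dict(sojourn.params[j]))
            continue
        trial = SojournModel(sojourn.family, M, [cand])
        with np.errstate(divide="ignore"):
            logd_new = np.log(trial.pmf_matrix()[0])
            logD_new = np.log(trial.survivor_matrix()[0])
        # full expected sojourn log-likelihood: complete runs via the pmf,
        # the censored final run via the survivor function
        q_new = _sojourn_q(eta[j], logd_new) + _sojourn_q(eta_c[j], logD_new)
        q_old = _sojourn_q(eta[j], logd_old[j]) + _sojourn_q(eta_c[j], logD_old[j])
        params.append(cand if q_new >= q_old - 1e-12 else dict(sojourn.params[j]))
    return SojournModel(sojourn.family, M, params)


_GUARDED_EMISSIONS = ("nbinom", "t", "mvt")


def _update_emission(
    emission: EmissionModel, obs, gamma: np.ndarray, logb_old: np.ndarray
) -> EmissionModel:
    new = fit_emission_mstep(obs, gamma, emission)
    if emission.family not in _GUARDED_EMISSIONS:
        return new
    # moment-based updates are not exact MLEs: accept per state only if the
    # expected emission log-likelihood does not decrease
    logb_new = emission_logdensity(new, obs)
    params = []
    for j in range(emission.J):
        w = gamma[:, j]
        mask = w > 1e-12 * max(w.sum(), 1e-300)
        q_new = float(np.dot(w[mask], np.maximum(logb_new[mask, j], -745.0)))
        q_old = float(np.dot(w[mask], np.maximum(logb_old[mask, j], -745.0)))
        params.append(new.params[j] if q_new >= q_old - 1e-12 else dict(emission.params[j]))
    return replace(new, params=params)


def em_fit(obs, spec0: HSMMSpec, config: EMConfig | None = None) -> EMResult:
    """Fit the HSMM by EM with a parametric sojourn M-step.

    Alternates the forward-backward E-step with weighted re-estimation of the
    emissions, the embedded transition matrix, optionally pi, and the sojourn
    parameters (from the expected duration weights of complete runs).  Stops
    when the relative log-likelihood change falls below ``tol`` or after
    ``max_iter`` iterations.  The trace is non-decreasing (up to floating
    point): every sub-update either maximizes its block of the expected
    complete-data log-likelihood or is guarded against decreasing it.
    """
    cfg = config or EMConfig()
    if cfg.max_iter < 1 or cfg.tol <= 0:
        raise ValueError("max_iter must be >= 1 and tol > 0")
    spec = spec0
    trace: list[float] = []
    converged = False
    for it in range(cfg.max_iter):
        logb = emission_logdensity(spec.emission, obs)
        post = forward_backward(obs, spec)
        if not np.isfinite(post.loglik):
            raise FloatingPointError(f"non-finite log-likelihood at EM iteration {it}")
        trace.append(post.loglik)
        if len(trace) > 1:
            rel = abs(trace[-1] - trace[-2]) / (1.0 + abs(trace[-2]))
            if rel < cfg.tol:
                converged = True
                break
        emission = (
            _update_emission(spec.emission, obs, post.gamma, logb)
            if cfg.estimate_emission
            else spec.emission
        )
        A = spec.A
        if cfg.estimate_A and spec.J > 1:
            rows = post.transition_counts.sum(axis=1)
            A = spec.A.copy()
            for i in range(spec.J):
                if rows[i] > 1e-12:
                    A[i] = post.transition_counts[i] / rows[i]
            np.fill_diagonal(A, 0.0)
            norm = A.sum(axis=1, keepdims=True)
            norm[norm == 0] = 1.0
            A = A / norm
        pi = post.first_state / post.first_state.sum() if cfg.estimate_pi else spec.pi
        sojourn = (
            _update_sojourn(spec.sojourn, post.duration_weights, post.censored_weights)
            if cfg.estimate_sojourn
            else spec.sojourn
        )
        spec = HSMMSpec(spec.J, pi, A, emission, sojourn, spec.M)
    else:
        warnings.warn("EM reached max_iter without meeting the tolerance")
    return EMResult(spec=spec, loglik_trace=trace, converged=converged)
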