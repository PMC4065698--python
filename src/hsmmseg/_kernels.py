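"""Compiled recursions for explicit-duration HSMM inference.

All kernels work in log space on pre-computed arrays:

``cum``
    (T+1, J) cumulative per-state emission log-densities,
    ``cum[t, j] = sum_{s < t} log b_j(x_s)``, so a run of state ``j`` over
    positions ``t0..e-1`` contributes ``cum[e, j] - cum[t0, j]``.
``logd`` / ``logD``
    (J, M) log sojourn pmf and survivor, truncated-renormalized on ``{1..M}``.
``logA``
    (J, J) log embedded transition matrix, ``-inf`` on the diagonal.
``umax``
    per-state effective duration support (last ``u`` with ``d_j(u) > 0``);
    looping only up to ``umax`` keeps the inner sums proportional to the
    actual sojourn support instead of the nominal bound ``M``.

The forward variable ``F_t(j)`` is the probability of the observations up to
``t`` jointly with a sojourn of state ``j`` ending exactly at ``t``; ``G_t(j)``
aggregates transitions into a run of ``j`` starting at ``t + 1`` (``G_0`` is
the initial distribution).  The final, right-censored sojourn is closed with
the survivor function, matching the censored-sojourn likelihood.  Complexity
is O(J T min(T, M)) time and O(J T) memory.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = -np.inf


@njit(cache=True)
def forward_pass(cum, logd, logD, logA, logpi, umax):
    T = cum.shape[0] - 1
    J = logpi.shape[0]
    logF = np.full((T, J), NEG_INF)
    logG = np.full((T, J), NEG_INF)
    for j in range(J):
        logG[0, j] = logpi[j]
    for t in range(1, T):
        for j in range(J):
            um = min(t, umax[j])
            best = NEG_INF
            acc = 0.0
            for u in range(1, um + 1):
                v = cum[t, j] - cum[t - u, j] + logd[j, u - 1] + logG[t - u, j]
                if v == NEG_INF:
                    continue
                if v <= best:
                    acc += np.exp(v - best)
                else:
                    acc = acc * np.exp(best - v) + 1.0
                    best = v
            if best > NEG_INF:
                logF[t, j] = best + np.log(acc)
        for j in range(J):
            best = NEG_INF
            acc = 0.0
            for i in range(J):
                if i == j:
                    continue
                v = logF[t, i] + logA[i, j]
                if v == NEG_INF:
                    continue
                if v <= best:
                    acc += np.exp(v - best)
                else:
                    acc = acc * np.exp(best - v) + 1.0
                    best = v
            if best > NEG_INF:
                logG[t, j] = best + np.log(acc)
    # right-censored final sojourn
    best = NEG_INF
    acc = 0.0
    for j in range(J):
        um = min(T, umax[j])
        for u in range(1, um + 1):
            v = cum[T, j] - cum[T - u, j] + logD[j, u - 1] + logG[T - u, j]
            if v == NEG_INF:
                continue
            if v <= best:
                acc += np.exp(v - best)
            else:
                acc = acc * np.exp(best - v) + 1.0
                best = v
    loglik = best + np.log(acc) if best > NEG_INF else NEG_INF
    return loglik, logF, logG


@njit(cache=True)
def backward_pass(cum, logd, logD, logA, umax):
    T = cum.shape[0] - 1
    J = logA.shape[0]
    logE = np.full((T, J), NEG_INF)  # obs after t given run starts at t+1
    logB = np.full((T, J), NEG_INF)  # obs after t given run ends at t
    for t in range(T - 1, -1, -1):
        for j in range(J):
            um = min(T - t, umax[j])
            best = NEG_INF
            acc = 0.0
            for u in range(1, um + 1):
                if t + u < T:
                    v = cum[t + u, j] - cum[t, j] + logd[j, u - 1] + logB[t + u, j]
                else:  # u == T - t: censored run reaching the end
                    v = cum[T, j] - cum[t, j] + logD[j, u - 1]
                if v == NEG_INF:
                    continue
                if v <= best:
                    acc += np.exp(v - best)
                else:
                    acc = acc * np.exp(best - v) + 1.0
                    best = v
            if best > NEG_INF:
                logE[t, j] = best + np.log(acc)
        if t >= 1:
            for j in range(J):
                best = NEG_INF
                acc = 0.0
                for k in range(J):
                    if k == j:
                        continue
                    v = logA[j, k] + logE[t, k]
                    if v == NEG_INF:
                        continue
                    if v <= best:
                        acc += np.exp(v - best)
                    else:
                        acc = acc * np.exp(best - v) + 1.0
                        best = v
                if best > NEG_INF:
                    logB[t, j] = best + np.log(acc)
    return logE, logB


@njit(cache=True)
def posterior_pass(cum, logd, logD, logA, logpi, umax, logF, logG, logE, logB, loglik):
    """Smoothed state probabilities and EM sufficient statistics.

    Sums segment posteriors P(run of j over [t0+1, e] | obs) into a difference
    array (O(1) per segment) whose cumulative sum along t yields gamma, and
    simultaneously accumulates expected duration weights (eta for complete
    runs, eta_c for the censored final run) and expected transition counts.
    """
    T = cum.shape[0] - 1
    J = logpi.shape[0]
    M = logd.shape[1]
    diff = np.zeros((T + 1, J))
    eta = np.zeros((J, M))
    eta_c = np.zeros((J, M))
    for j in range(J):
        for t0 in range(T):
            g = logG[t0, j]
            if g == NEG_INF:
                continue
            um = min(T - t0, umax[j])
            for u in range(1, um + 1):
                e = t0 + u
                if e < T:
                    lp = g + cum[e, j] - cum[t0, j] + logd[j, u - 1] + logB[e, j] - loglik
                else:
                    lp = g + cum[e, j] - cum[t0, j] + logD[j, u - 1] - loglik
                if lp < -745.0:
                    continue
                p = np.exp(lp)
                if e < T:
                    eta[j, u - 1] += p
                else:
                    eta_c[j, u - 1] += p
                diff[t0, j] += p
                diff[e, j] -= p
    gamma = np.empty((T, J))
    for j in range(J):
        run = 0.0
        for t in range(T):
            run += diff[t, j]
            gamma[t, j] = run
    xi = np.zeros((J, J))
    for t in range(1, T):
        for i in range(J):
            if logF[t, i] == NEG_INF:
                continue
            for k in range(J):
                if k == i or logA[i, k] == NEG_INF or logE[t, k] == NEG_INF:
                    continue
                lp = logF[t, i] + logA[i, k] + logE[t, k] - loglik
                if lp >= -745.0:
                    xi[i, k] += np.exp(lp)
    first = np.zeros(J)
    for j in range(J):
        lp = logpi[j] + logE[0, j] - loglik
        if lp >= -745.0:
            first[j] = np.exp(lp)
    return gamma, eta, eta_c, xi, first


@njit(cache=True)
def viterbi_pass(cum, logd, logD, logA, logpi, umax):
    """Most probable state sequence under the censored-sojourn likelihood.

    Ties are broken toward the lower state index (and the shorter duration)
    by strict-improvement comparisons over ascending loops.
    """
    T = cum.shape[0] - 1
    J = logpi.shape[0]
    logV = np.full((T, J), NEG_INF)
    logGV = np.full((T, J), NEG_INF)
    btu = np.zeros((T, J), dtype=np.int64)
    bti = np.full((T, J), -1, dtype=np.int64)
    for j in range(J):
        logGV[0, j] = logpi[j]
    for t in range(1, T):
        for j in range(J):
            um = min(t, umax[j])
            best = NEG_INF
            barg = 0
            for u in range(1, um + 1):
                v = cum[t, j] - cum[t - u, j] + logd[j, u - 1] + logGV[t - u, j]
                if v > best:
                    best = v
                    barg = u
            logV[t, j] = best
            btu[t, j] = barg
        for j in range(J):
            best = NEG_INF
            barg = -1
            for i in range(J):
                if i == j:
                    continue
                v = logV[t, i] + logA[i, j]
                if v > best:
                    best = v
                    barg = i
            logGV[t, j] = best
            bti[t, j] = barg
    best = NEG_INF
    bj = 0
    bu = 1
    for j in range(J):
        um = min(T, umax[j])
        for u in range(1, um + 1):
            v = cum[T, j] - cum[T - u, j] + logD[j, u - 1] + logGV[T - u, j]
            if v > best:
                best = v
                bj = j
                bu = u
    states = np.empty(T, dtype=np.int64)
    t = T - bu
    cur = bj
    for s in range(t, T):
        states[s] = cur
    while t > 0:
        i = bti[t, cur]
        u = btu[t, i]
        for s in range(t - u, t):
            states[s] = i
        cur = i
        t -= u
    return states, best
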