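"""Numerically safe HMM recursions, JIT-compiled for speed.

The scaled forward-backward scheme normalizes alpha at every bin and keeps
the per-bin scaling constants, so the log-likelihood is the sum of their
logs and the EM sufficient statistics come out exact without log-space
arithmetic. Inner loops are written allocation-free: a single EM fit on a
2880-bin trace has to run thousands of times in the model-selection and
surrogate-recovery paths.
"""
from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=True)
def forward_scaled(B, pi, T):
    """Scaled forward pass.

    B : (n, K) emission likelihoods P(obs_t | state k)
    Returns (alpha, c, loglik) where alpha rows are filtered posteriors and
    c[t] is the per-bin normalization constant.
    """
    n, K = B.shape
    alpha = np.empty((n, K))
    c = np.empty(n)
    s = 0.0
    for k in range(K):
        v = pi[k] * B[0, k]
        alpha[0, k] = v
        s += v
    c[0] = s
    inv = 1.0 / s
    for k in range(K):
        alpha[0, k] *= inv
    for t in range(1, n):
        s = 0.0
        for j in range(K):
            acc = 0.0
            for i in range(K):
                acc += alpha[t - 1, i] * T[i, j]
            v = acc * B[t, j]
            alpha[t, j] = v
            s += v
        c[t] = s
        inv = 1.0 / s
        for j in range(K):
            alpha[t, j] *= inv
    ll = 0.0
    for t in range(n):
        ll += math.log(c[t])
    return alpha, c, ll


@njit(cache=True)
def backward_scaled(B, T, c):
    """Scaled backward pass using the forward scaling constants."""
    n, K = B.shape
    beta = np.empty((n, K))
    for k in range(K):
        beta[n - 1, k] = 1.0
    for t in range(n - 2, -1, -1):
        inv = 1.0 / c[t + 1]
        for i in range(K):
            acc = 0.0
            for j in range(K):
                acc += T[i, j] * B[t + 1, j] * beta[t + 1, j]
            beta[t, i] = acc * inv
    return beta


@njit(cache=True)
def forward_backward(B, pi, T):
    """Full smoothing pass.

    Returns (gamma, xi_sum, loglik): per-bin posteriors, summed expected
    transition counts, and the sequence log-likelihood.
    """
    n, K = B.shape
    alpha, c, loglik = forward_scaled(B, pi, T)
    beta = backward_scaled(B, T, c)
    gamma = np.empty((n, K))
    for t in range(n):
        s = 0.0
        for k in range(K):
            v = alpha[t, k] * beta[t, k]
            gamma[t, k] = v
            s += v
        inv = 1.0 / s
        for k in range(K):
            gamma[t, k] *= inv
    xi_sum = np.zeros((K, K))
    w = np.empty(K)
    for t in range(n - 1):
        inv = 1.0 / c[t + 1]
        for j in range(K):
            w[j] = B[t + 1, j] * beta[t + 1, j] * inv
        for i in range(K):
            a = alpha[t, i]
            for j in range(K):
                xi_sum[i, j] += a * T[i, j] * w[j]
    return gamma, xi_sum, loglik


@njit(cache=True)
def viterbi_path(logB, logpi, logT):
    """Exact MAP path; ties broken toward the lowest state index."""
    n, K = logB.shape
    delta = logpi + logB[0]
    back = np.zeros((n, K), dtype=np.int64)
    new = np.empty(K)
    for t in range(1, n):
        for j in range(K):
            best_i = 0
            best = delta[0] + logT[0, j]
            for i in range(1, K):
                v = delta[i] + logT[i, j]
                if v > best:  # strict: first (lowest) index wins ties
                    best = v
                    best_i = i
            new[j] = best + logB[t, j]
            back[t, j] = best_i
        delta = new.copy()
    path = np.empty(n, dtype=np.int64)
    best_j = 0
    best = delta[0]
    for j in range(1, K):
        if delta[j] > best:
            best = delta[j]
            best_j = j
    path[n - 1] = best_j
    for t in range(n - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path, best


@njit(cache=True)
def _em_sweep(obs, lg, offsets, pi, T, rates, pi_acc, xi_acc, gamma_obs, gamma_tot):
    """One E-step over all chains, accumulating sufficient statistics.

    Returns the total log-likelihood at the current parameters.
    """
    K = rates.shape[0]
    n_chains = offsets.shape[0] - 1
    loglam = np.log(rates)
    ll = 0.0
    for c in range(n_chains):
        o = obs[offsets[c]:offsets[c + 1]]
        g = lg[offsets[c]:offsets[c + 1]]
        n = o.shape[0]
        B = np.empty((n, K))
        for t in range(n):
            for k in range(K):
                B[t, k] = math.exp(o[t] * loglam[k] - rates[k] - g[t])
        gamma, xi_sum, chain_ll = forward_backward(B, pi, T)
        ll += chain_ll
        for k in range(K):
            pi_acc[k] += gamma[0, k]
            for j in range(K):
                xi_acc[k, j] += xi_sum[k, j]
        for t in range(n):
            for k in range(K):
                gamma_obs[k] += gamma[t, k] * o[t]
                gamma_tot[k] += gamma[t, k]
    return ll


@njit(cache=True)
def em_run(obs, offsets, pi0, T0, rates0, max_iter, tol, rate_floor):
    """Full Baum-Welch loop over one or more independent chains.

    obs : concatenated observations; chain c spans obs[offsets[c]:offsets[c+1]].
    Returns (pi, T, rates, ll_history, n_iter, converged, final_ll) where
    final_ll is the log-likelihood of the returned (post-M-step) parameters.
    """
    K = rates0.shape[0]
    pi = pi0.copy()
    T = T0.copy()
    rates = np.maximum(rates0, rate_floor)
    lg = np.empty(obs.shape[0])
    for t in range(obs.shape[0]):
        lg[t] = math.lgamma(obs[t] + 1.0)
    ll_history = np.empty(max_iter)
    prev_ll = -np.inf
    converged = False
    n_iter = 0
    for _ in range(max_iter):
        pi_acc = np.zeros(K)
        xi_acc = np.zeros((K, K))
        gamma_obs = np.zeros(K)
        gamma_tot = np.zeros(K)
        ll = _em_sweep(obs, lg, offsets, pi, T, rates, pi_acc, xi_acc, gamma_obs, gamma_tot)
        ll_history[n_iter] = ll
        n_iter += 1
        # M-step
        pi = pi_acc / pi_acc.sum()
        for i in range(K):
            rs = xi_acc[i].sum()
            if rs > 0.0:
                for j in range(K):
                    T[i, j] = xi_acc[i, j] / rs
        for k in range(K):
            denom = gamma_tot[k] if gamma_tot[k] > 1e-300 else 1e-300
            r = gamma_obs[k] / denom
            rates[k] = r if r > rate_floor else rate_floor
        if np.isfinite(prev_ll):
            denom = abs(prev_ll) if abs(prev_ll) > 1.0 else 1.0
            if (ll - prev_ll) / denom < tol:
                converged = True
                break
        prev_ll = ll
    # log-likelihood of the returned parameters
    n_chains = offsets.shape[0] - 1
    loglam = np.log(rates)
    final_ll = 0.0
    for c in range(n_chains):
        o = obs[offsets[c]:offsets[c + 1]]
        g = lg[offsets[c]:offsets[c + 1]]
        n = o.shape[0]
        B = np.empty((n, K))
        for t in range(n):
            for k in range(K):
                B[t, k] = math.exp(o[t] * loglam[k] - rates[k] - g[t])
        _, _, chain_ll = forward_scaled(B, pi, T)
        final_ll += chain_ll
    return pi, T, rates, ll_history[:n_iter], n_iter, converged, final_ll


@njit(cache=True)
def sample_markov_path(pi, T, n, u):
    """Draw a hidden path from pre-generated uniforms u (length n)."""
    K = pi.shape[0]
    path = np.empty(n, dtype=np.int64)
    cdf = np.cumsum(pi)
    s = K - 1
    for k in range(K):
        if u[0] <= cdf[k]:
            s = k
            break
    path[0] = s
    for t in range(1, n):
        cdf = np.cumsum(T[s])
        nxt = K - 1
        for k in range(K):
            if u[t] <= cdf[k]:
                nxt = k
                break
        s = nxt
        path[t] = s
    return path
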