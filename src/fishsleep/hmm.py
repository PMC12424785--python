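"""Poisson hidden Markov model: likelihood, posteriors, decoding, EM, sampling.

Observations are integer counts (seconds active per 1-minute bin). Emission
distributions are Poisson with per-state rates; rates are floored at
``RATE_FLOOR`` so a zero-rate state never produces -inf likelihood.
"""
from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
from scipy.special import gammaln

from . import _kernels
from .types import (
    MAX_ACTIVITY,
    RATE_FLOOR,
    ActivityTrace,
    HMMParameters,
    PosteriorMatrix,
    StateSequence,
    generic_labels,
    validate_counts,
)

logger = logging.getLogger(__name__)

EM_TOL = 1e-6
EM_MAX_ITER = 500

TraceLike = "ActivityTrace | Sequence[int] | np.ndarray"


def _as_counts(trace) -> np.ndarray:
    if isinstance(trace, ActivityTrace):
        return trace.values
    return validate_counts(trace)


def _as_trace_list(traces) -> list[np.ndarray]:
    if isinstance(traces, (ActivityTrace, np.ndarray)) or (
        len(traces) > 0 and np.isscalar(traces[0])
    ):
        return [_as_counts(traces)]
    return [_as_counts(t) for t in traces]


def poisson_log_pmf(obs: np.ndarray, rates: np.ndarray) -> np.ndarray:
    """(n, K) matrix of log P(obs_t | rate_k) with rates floored."""
    lam = np.maximum(np.asarray(rates, dtype=float), RATE_FLOOR)
    obs = np.asarray(obs, dtype=float)
    return obs[:, None] * np.log(lam)[None, :] - lam[None, :] - gammaln(obs + 1.0)[:, None]


def _emission_matrix(obs: np.ndarray, rates: np.ndarray) -> np.ndarray:
    return np.exp(poisson_log_pmf(obs, rates))


def log_likelihood(trace, params: HMMParameters) -> float:
    """Log P(observations | params) via the scaled forward recursion."""
    obs = _as_counts(trace)
    B = _emission_matrix(obs, params.rates)
    _, _, ll = _kernels.forward_scaled(B, params.initial_probs, params.transition_matrix)
    return float(ll)


def posterior_state_probs(trace, params: HMMParameters) -> PosteriorMatrix:
    """Forward-backward smoothed per-bin state posteriors."""
    obs = _as_counts(trace)
    B = _emission_matrix(obs, params.rates)
    gamma, _, ll = _kernels.forward_backward(B, params.initial_probs, params.transition_matrix)
    return PosteriorMatrix(probs=gamma, log_likelihood=float(ll))


def viterbi_decode(trace, params: HMMParameters) -> StateSequence:
    """Exact maximum-probability state path (ties toward lowest index)."""
    obs = _as_counts(trace)
    logB = poisson_log_pmf(obs, params.rates)
    with np.errstate(divide="ignore"):
        logpi = np.log(params.initial_probs)
        logT = np.log(params.transition_matrix)
    path, _ = _kernels.viterbi_path(logB, logpi, logT)
    return StateSequence(states=path, labels=generic_labels(params.n_states))


def bic_score(log_lik: float, K: int, n: int) -> float:
    """BIC = p ln(n) - 2 logL with p = (K-1) + K(K-1) + K = K^2 + K - 1."""
    if n <= 0:
        raise ValueError("n must be positive")
    p = K * K + K - 1
    return p * np.log(n) - 2.0 * log_lik


def emission_posterior_given_obs(
    obs: int, params: HMMParameters, priors: np.ndarray | None = None
) -> np.ndarray:
    """Per-state probability that a single count came from each state.

    priors default to uniform; pass the stationary occupancy to weight by
    how often each state occurs.
    """
    K = params.n_states
    if priors is None:
        priors = np.full(K, 1.0 / K)
    priors = np.asarray(priors, dtype=float)
    if priors.shape != (K,) or np.any(priors < 0) or abs(priors.sum() - 1.0) > 1e-9:
        raise ValueError("priors must be a length-K probability vector")
    w = priors * np.exp(poisson_log_pmf(np.array([obs]), params.rates)[0])
    total = w.sum()
    if total <= 0:
        raise ValueError("zero posterior mass for this observation")
    return w / total


def stationary_distribution(transition_matrix: np.ndarray) -> np.ndarray:
    """Stationary occupancy: dominant left eigenvector of the transition matrix.

    Falls back (with a warning) to the long-run Cesaro average for chains
    where the unit eigenvalue is not simple or the eigenvector is not a
    valid distribution (reducible/periodic chains).
    """
    T = np.asarray(transition_matrix, dtype=float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.any(T < 0) or np.any(np.abs(T.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError("transition matrix must be row-stochastic")
    K = T.shape[0]
    if K == 1:
        return np.array([1.0])
    vals, vecs = np.linalg.eig(T.T)
    close = np.flatnonzero(np.abs(vals - 1.0) < 1e-9)
    if close.size == 1:
        v = np.real(vecs[:, close[0]])
        v = np.where(np.abs(v) < 1e-15, 0.0, v)
        if np.all(v >= 0) or np.all(v <= 0):
            v = np.abs(v)
            return v / v.sum()
    warnings.warn(
        "transition matrix is reducible or periodic; using long-run average occupancy",
        RuntimeWarning,
        stacklevel=2,
    )
    pi = np.full(K, 1.0 / K)
    avg = np.zeros(K)
    for _ in range(10000):
        avg += pi
        pi = pi @ T
    return avg / avg.sum()


def sample_sequence(
    params: HMMParameters, n: int, seed: int | np.random.Generator
) -> tuple[StateSequence, ActivityTrace]:
    """Seeded draw of a hidden path and clipped Poisson observations."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.random(n)
    path = _kernels.sample_markov_path(
        params.initial_probs, params.transition_matrix, n, u
    )
    lam = np.maximum(params.rates, RATE_FLOOR)
    obs = rng.poisson(lam[path])
    n_clipped = int(np.count_nonzero(obs > MAX_ACTIVITY))
    if n_clipped:
        logger.info("clipped %d observations to %d", n_clipped, MAX_ACTIVITY)
        obs = np.minimum(obs, MAX_ACTIVITY)
    seq = StateSequence(states=path, labels=generic_labels(params.n_states))
    trace = ActivityTrace(animal_id="sampled", values=obs)
    return seq, trace


def _init_params(
    obs_all: np.ndarray, K: int, rng: np.random.Generator
) -> HMMParameters:
    """Restart initialization: quantile-spread rates with lognormal jitter,
    diagonally-boosted Dirichlet transition rows."""
    qs = np.linspace(0.05, 0.95, K)
    rates = np.quantile(obs_all, qs).astype(float)
    rates = rates * rng.lognormal(mean=0.0, sigma=0.2, size=K)
    rates = np.maximum(rates + rng.uniform(0, 1e-2, size=K), RATE_FLOOR)
    alpha = np.ones(K)
    T = np.empty((K, K))
    for i in range(K):
        a = alpha.copy()
        a[i] += 5.0  # favor sticky chains, as seen in the data
        T[i] = rng.dirichlet(a)
    pi = rng.dirichlet(np.ones(K))
    return HMMParameters(initial_probs=pi, transition_matrix=T, rates=rates)


def em_fit(
    traces,
    K: int,
    seed: int = 0,
    max_iter: int = EM_MAX_ITER,
    tol: float = EM_TOL,
    init: HMMParameters | None = None,
) -> tuple[HMMParameters, float]:
    """Baum-Welch fit of a K-state Poisson HMM.

    Multiple traces are treated as independent chains sharing parameters
    (no transition is counted across a trace boundary). Returns the fitted
    parameters and the final total log-likelihood.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    obs_list = _as_trace_list(traces)
    obs_all = np.concatenate(obs_list)
    rng = np.random.default_rng(seed)
    n_distinct = np.unique(obs_all).size
    if K > n_distinct:
        warnings.warn(
            f"K={K} exceeds the {n_distinct} distinct observed values; "
            "fitting with jittered initialization",
            RuntimeWarning,
            stacklevel=2,
        )
    params = init if init is not None else _init_params(obs_all, K, rng)

    offsets = np.cumsum([0] + [o.size for o in obs_list]).astype(np.int64)
    pi, T, rates, ll_history, n_iter, converged, final_ll = _kernels.em_run(
        obs_all,
        offsets,
        params.initial_probs.astype(float),
        params.transition_matrix.astype(float),
        params.rates.astype(float),
        int(max_iter),
        float(tol),
        RATE_FLOOR,
    )
    # normalization hygiene after the compiled M-steps
    pi = pi / pi.sum()
    T = T / T.sum(axis=1, keepdims=True)
    ll = float(final_ll)
    fitted = HMMParameters(
        initial_probs=pi,
        transition_matrix=T,
        rates=rates,
        fit_meta={
            "seed": int(seed) if np.isscalar(seed) else None,
            "n_iter": int(n_iter),
            "converged": bool(converged),
            "log_likelihood": ll,
            "ll_history": [float(x) for x in ll_history],
        },
    )
    return fitted, ll
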