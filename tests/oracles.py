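"""Independent brute-force oracles used to pin expected values.

These deliberately avoid the package's recursions: likelihoods, posteriors
and MAP paths are computed by exhaustive enumeration over all K^n hidden
paths, and permutation p-values by exact enumeration of group splits.
"""
from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.stats import poisson


def _all_paths(K: int, n: int) -> np.ndarray:
    """(K^n, n) array of every hidden path."""
    grids = np.meshgrid(*([np.arange(K)] * n), indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=1)


def _path_probs(obs, pi, T, rates) -> tuple[np.ndarray, np.ndarray]:
    obs = np.asarray(obs)
    n = obs.size
    K = len(rates)
    paths = _all_paths(K, n)
    pmf = poisson.pmf(obs[None, :], np.asarray(rates)[paths])
    probs = pi[paths[:, 0]] * np.prod(pmf, axis=1)
    if n > 1:
        trans = T[paths[:, :-1], paths[:, 1:]]
        probs = probs * np.prod(trans, axis=1)
    return paths, probs


def enum_log_likelihood(obs, pi, T, rates) -> float:
    _, probs = _path_probs(obs, pi, T, rates)
    return float(np.log(probs.sum()))


def enum_posteriors(obs, pi, T, rates) -> np.ndarray:
    paths, probs = _path_probs(obs, pi, T, rates)
    n = len(obs)
    K = len(rates)
    post = np.zeros((n, K))
    for k in range(K):
        post[:, k] = probs @ (paths == k)
    return post / post.sum(axis=1, keepdims=True)


def enum_viterbi(obs, pi, T, rates) -> np.ndarray:
    """MAP path; ties resolved toward the lexicographically smallest path,
    matching the lowest-index tie rule."""
    paths, probs = _path_probs(obs, pi, T, rates)
    best = np.max(probs)
    tied = paths[probs >= best * (1 - 1e-12)]
    idx = np.lexsort(tied.T[::-1])
    return tied[idx[0]]


def path_log_prob(obs, pi, T, rates, path) -> float:
    """Joint log-probability of one hidden path and the observations."""
    obs = np.asarray(obs)
    path = np.asarray(path)
    lp = np.log(pi[path[0]]) + poisson.logpmf(obs[0], rates[path[0]])
    for t in range(1, obs.size):
        lp += np.log(T[path[t - 1], path[t]]) + poisson.logpmf(obs[t], rates[path[t]])
    return float(lp)


def exact_perm_pvalue(a, b) -> float:
    """Exact two-sided permutation p-value (difference of means) by full
    enumeration of group splits; feasible for n_a + n_b <= 12."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    n, n_a = pooled.size, a.size
    obs = abs(a.mean() - b.mean())
    count = 0
    total = 0
    for idx in combinations(range(n), n_a):
        sel = np.zeros(n, dtype=bool)
        sel[list(idx)] = True
        stat = abs(pooled[sel].mean() - pooled[~sel].mean())
        count += stat >= obs - 1e-12
        total += 1
    return count / total
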