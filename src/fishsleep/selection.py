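"""Multi-restart fitting, BIC selection of the state count, and surrogate
parameter-recovery experiments."""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .hmm import bic_score, em_fit, sample_sequence, viterbi_decode, _as_trace_list
from .types import ActivityTrace, HMMParameters

#: Restart count used in production single-animal runs; tests and the
#: desk-scale recovery experiments use fewer.
PRODUCTION_RESTARTS = 1000
DEFAULT_K_RANGE = range(2, 7)


@dataclass
class SelectionResult:
    """Per-K best fits and BIC scores over a candidate range of state counts."""

    k_range: list[int]
    log_likelihoods: dict[int, float]
    bics: dict[int, float]
    best_params: dict[int, HMMParameters]
    optimal_k: int
    restart_count: int
    restart_log: dict[int, list[float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "k_range": self.k_range,
            "log_likelihoods": {str(k): v for k, v in self.log_likelihoods.items()},
            "bics": {str(k): v for k, v in self.bics.items()},
            "optimal_k": self.optimal_k,
            "restart_count": self.restart_count,
            "best_params": {str(k): p.to_dict() for k, p in self.best_params.items()},
        }


@dataclass
class RecoveryReport:
    """Outcome of refitting sequences simulated from known parameters."""

    truth: HMMParameters
    length: int
    selected_k: list[int]
    rate_rel_errors: list[np.ndarray]
    transition_abs_errors: list[np.ndarray]

    @property
    def n_replicates(self) -> int:
        return len(self.selected_k)

    def fraction_selecting(self, k: int) -> float:
        return float(np.mean([s == k for s in self.selected_k]))

    def median_rate_rel_error(self) -> float:
        if not self.rate_rel_errors:
            return float("nan")
        return float(np.median([np.mean(e) for e in self.rate_rel_errors]))

    def max_transition_abs_error(self) -> float:
        if not self.transition_abs_errors:
            return float("nan")
        return float(np.median([np.max(e) for e in self.transition_abs_errors]))

    def to_dict(self) -> dict:
        return {
            "length": self.length,
            "n_replicates": self.n_replicates,
            "selected_k": self.selected_k,
            "fraction_truth_k": self.fraction_selecting(self.truth.n_states),
            "median_rate_rel_error": self.median_rate_rel_error(),
            "median_max_transition_abs_error": self.max_transition_abs_error(),
        }


def multi_restart_fit(
    traces,
    K: int,
    n_restarts: int = 20,
    base_seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> tuple[HMMParameters, float]:
    """Fit with n_restarts seeded EM runs; return the best by log-likelihood.

    Restart r uses seed base_seed + r, so increasing n_restarts never loses
    a previously found optimum.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    best: HMMParameters | None = None
    best_ll = -np.inf
    restart_lls: list[float] = []
    any_converged = False
    for r in range(n_restarts):
        fit, ll = em_fit(traces, K, seed=base_seed + r, max_iter=max_iter, tol=tol)
        restart_lls.append(ll)
        any_converged = any_converged or fit.fit_meta.get("converged", False)
        if ll > best_ll:
            best, best_ll = fit, ll
    if not any_converged:
        warnings.warn(
            f"no restart converged for K={K}; returning best-so-far",
            RuntimeWarning,
            stacklevel=2,
        )
    meta = dict(best.fit_meta)
    meta.update(
        restarts=n_restarts,
        base_seed=int(base_seed),
        restart_log_likelihoods=restart_lls,
        any_converged=bool(any_converged),
    )
    best = HMMParameters(
        initial_probs=best.initial_probs,
        transition_matrix=best.transition_matrix,
        rates=best.rates,
        fit_meta=meta,
    )
    return best, float(best_ll)


def select_state_count(
    traces,
    k_range: Sequence[int] = DEFAULT_K_RANGE,
    n_restarts: int = 20,
    base_seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> SelectionResult:
    """Fit every K in k_range by multi-restart EM and pick the min-BIC model.

    BIC ties break toward the smaller K (parsimony). Each K gets its own
    seed block so results are independent of the order of the range.
    """
    k_list = sorted(set(int(k) for k in k_range))
    if not k_list:
        raise ValueError("k_range must be nonempty")
    n_total = sum(t.size for t in _as_trace_list(traces))
    lls: dict[int, float] = {}
    bics: dict[int, float] = {}
    best_params: dict[int, HMMParameters] = {}
    restart_log: dict[int, list[float]] = {}
    for k in k_list:
        params, ll = multi_restart_fit(
            traces, k, n_restarts=n_restarts, base_seed=base_seed + 10_000 * k,
            max_iter=max_iter, tol=tol,
        )
        lls[k] = ll
        bics[k] = bic_score(ll, k, n_total)
        best_params[k] = params
        restart_log[k] = params.fit_meta["restart_log_likelihoods"]
    optimal = min(k_list, key=lambda k: (bics[k], k))
    return SelectionResult(
        k_range=k_list,
        log_likelihoods=lls,
        bics=bics,
        best_params=best_params,
        optimal_k=optimal,
        restart_count=n_restarts,
        restart_log=restart_log,
    )


def match_states_by_rate(truth: HMMParameters, fit: HMMParameters) -> tuple[np.ndarray, np.ndarray]:
    """Permutations sorting truth and fit states by ascending rate.

    Label switching makes state identity unidentifiable; rate order is the
    canonical alignment used for all error reports.
    """
    return np.argsort(truth.rates, kind="stable"), np.argsort(fit.rates, kind="stable")


def _parameter_errors(truth: HMMParameters, fit: HMMParameters) -> tuple[np.ndarray, np.ndarray]:
    ti, fi = match_states_by_rate(truth, fit)
    lam_t = truth.rates[ti]
    lam_f = fit.rates[fi]
    rate_rel = np.abs(lam_f - lam_t) / np.maximum(np.abs(lam_t), 1e-12)
    T_t = truth.transition_matrix[np.ix_(ti, ti)]
    T_f = fit.transition_matrix[np.ix_(fi, fi)]
    return rate_rel, np.abs(T_f - T_t)


def surrogate_recovery(
    params: HMMParameters,
    n_replicates: int = 100,
    length: int = 2880,
    k_range: Sequence[int] = DEFAULT_K_RANGE,
    n_restarts: int = 10,
    seed: int = 0,
    max_iter: int = 500,
) -> RecoveryReport:
    """Generate sequences from params, re-select K per replicate, and score
    parameter errors whenever the selected K equals the generating K."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    truth_k = params.n_states
    selected: list[int] = []
    rate_errs: list[np.ndarray] = []
    trans_errs: list[np.ndarray] = []
    for rep in range(n_replicates):
        rep_seed = seed + rep
        _, trace = sample_sequence(params, length, seed=rep_seed)
        res = select_state_count(
            trace, k_range, n_restarts=n_restarts,
            base_seed=rep_seed * 1_000_003, max_iter=max_iter,
        )
        selected.append(res.optimal_k)
        if res.optimal_k == truth_k:
            rr, te = _parameter_errors(params, res.best_params[truth_k])
            rate_errs.append(rr)
            trans_errs.append(te)
    return RecoveryReport(
        truth=params,
        length=length,
        selected_k=selected,
        rate_rel_errors=rate_errs,
        transition_abs_errors=trans_errs,
    )


def length_sufficiency(
    params: HMMParameters,
    lengths: Sequence[int] = (500, 1000, 1500, 2880, 3500),
    n_replicates: int = 20,
    seed: int = 0,
    n_restarts: int = 5,
    max_iter: int = 500,
) -> dict[int, RecoveryReport]:
    """Refit the generating K at several sequence lengths and report how
    parameter error shrinks with data length."""
    lengths = [int(x) for x in lengths]
    if any(b <= a for a, b in zip(lengths, lengths[1:])):
        raise ValueError("lengths must be strictly increasing")
    truth_k = params.n_states
    out: dict[int, RecoveryReport] = {}
    for li, length in enumerate(lengths):
        selected: list[int] = []
        rate_errs: list[np.ndarray] = []
        trans_errs: list[np.ndarray] = []
        for rep in range(n_replicates):
            rep_seed = seed + 7919 * li + rep
            _, trace = sample_sequence(params, length, seed=rep_seed)
            fit, _ = multi_restart_fit(
                trace, truth_k, n_restarts=n_restarts,
                base_seed=rep_seed * 1_000_003, max_iter=max_iter,
            )
            # degenerate fit: the MAP path never uses some state (flagged -1)
            decoded = viterbi_decode(trace, fit)
            degenerate = np.unique(decoded.states).size < truth_k
            selected.append(truth_k if not degenerate else -1)
            rr, te = _parameter_errors(params, fit)
            rate_errs.append(rr)
            trans_errs.append(te)
        out[length] = RecoveryReport(
            truth=params,
            length=length,
            selected_k=selected,
            rate_rel_errors=rate_errs,
            transition_abs_errors=trans_errs,
        )
    return out
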