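"""Canonical state naming, occupancy, smoothed probability time courses,
day/night proportions, bout statistics, and activity-conditioned assignment.

State names follow the sleep/wake convention: for a 4-state model the states
in ascending rate order are S2 (deep sleep, rate ~0), S1 (light sleep, ~1),
W1 (~4) and W2 (~8 s/min). A 3-state model is S2/S1/W; anything else gets
generic L1..LK names.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hmm import stationary_distribution
from .types import HMMParameters, StateSequence

CANONICAL_NAMES = {3: ["S2", "S1", "W"], 4: ["S2", "S1", "W1", "W2"]}


@dataclass(frozen=True)
class LabeledFit:
    """Fitted parameters with canonical names and stationary occupancy.

    ``order[i]`` is the original state index of the i-th state by ascending
    rate; ``labels`` maps original indices to canonical names.
    """

    params: HMMParameters
    labels: dict[int, str]
    order: np.ndarray
    occupancy: np.ndarray

    @property
    def names_by_rate(self) -> list[str]:
        return [self.labels[int(i)] for i in self.order]

    def occupancy_by_name(self) -> dict[str, float]:
        return {self.labels[i]: float(self.occupancy[i]) for i in range(self.params.n_states)}


def canonical_label(params: HMMParameters) -> LabeledFit:
    """Relabel fitted states deterministically by ascending Poisson rate."""
    K = params.n_states
    rates = params.rates
    if np.unique(np.round(rates, 9)).size < K:
        warnings.warn(
            "duplicate rates within 1e-9; ties broken by original state index",
            RuntimeWarning,
            stacklevel=2,
        )
    order = np.argsort(rates, kind="stable")
    names = CANONICAL_NAMES.get(K, [f"L{i + 1}" for i in range(K)])
    labels = {int(orig): names[pos] for pos, orig in enumerate(order)}
    occ = stationary_distribution(params.transition_matrix)
    return LabeledFit(params=params, labels=labels, order=order, occupancy=occ)


def relabel_sequence(seq: StateSequence, fit: LabeledFit) -> StateSequence:
    return StateSequence(states=seq.states, labels=fit.labels)


def smoothed_state_probabilities(
    posteriors: np.ndarray | list[np.ndarray], window: int = 60
) -> np.ndarray:
    """Across-animal mean state probabilities, smoothed by a centered moving
    average with the window truncated at the edges.

    Accepts one (n, K) matrix or a list of aligned ones. The output rows
    still sum to 1 because averaging and truncated smoothing are convex.
    """
    if isinstance(posteriors, np.ndarray) and posteriors.ndim == 2:
        mats = [posteriors]
    else:
        mats = [np.asarray(p, dtype=float) for p in posteriors]
    n = mats[0].shape[0]
    if any(m.shape != mats[0].shape for m in mats):
        raise ValueError("posterior matrices must be aligned (same shape)")
    mean = np.mean(mats, axis=0)
    if window <= 1:
        return mean
    half = window // 2
    csum = np.cumsum(np.vstack([np.zeros((1, mean.shape[1])), mean]), axis=0)
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + (window - half), n)
    out = (csum[hi] - csum[lo]) / (hi - lo)[:, None]
    return out


def day_night_proportions(
    seq: StateSequence, photoperiod: np.ndarray
) -> pd.DataFrame:
    """Minutes and fractions spent in each state, split by photoperiod.

    Returns a tidy frame with one row per (period, state); a period absent
    from the mask is flagged with ``defined=False`` and NaN fractions.
    """
    mask = np.asarray(photoperiod, dtype=bool)
    if mask.shape != seq.states.shape:
        raise ValueError("photoperiod mask must align with the state sequence")
    state_ids = sorted(seq.labels)
    rows = []
    for period, sel in (("day", mask), ("night", ~mask)):
        total = int(sel.sum())
        for s in state_ids:
            minutes = int(np.count_nonzero(seq.states[sel] == s))
            rows.append(
                {
                    "period": period,
                    "state": seq.labels[s],
                    "minutes": minutes,
                    "fraction": minutes / total if total else np.nan,
                    "defined": total > 0,
                }
            )
    return pd.DataFrame(rows)


def _runs(states: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal runs as (state, start, length)."""
    if states.size == 0:
        return []
    change = np.flatnonzero(np.diff(states)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [states.size]])
    return [(int(states[a]), int(a), int(b - a)) for a, b in zip(starts, ends)]


def bout_statistics(
    seq: StateSequence, photoperiod: np.ndarray
) -> pd.DataFrame:
    """Mean/median bout durations per state per period.

    A bout is a maximal run of one state; bouts crossing a light transition
    are split at the boundary, each part counted in its own period. The
    split conserves total minutes.
    """
    mask = np.asarray(photoperiod, dtype=bool)
    if mask.shape != seq.states.shape:
        raise ValueError("photoperiod mask must align with the state sequence")
    bouts: dict[tuple[str, int], list[int]] = {}
    for state, start, length in _runs(seq.states):
        seg = mask[start:start + length]
        for period_flag, a, plen in _runs(seg.astype(np.int64)):
            period = "day" if period_flag else "night"
            bouts.setdefault((period, state), []).append(plen)
    rows = []
    for s in sorted(seq.labels):
        for period in ("day", "night"):
            durs = bouts.get((period, s), [])
            rows.append(
                {
                    "period": period,
                    "state": seq.labels[s],
                    "n_bouts": len(durs),
                    "total_minutes": int(np.sum(durs)) if durs else 0,
                    "mean_duration": float(np.mean(durs)) if durs else np.nan,
                    "median_duration": float(np.median(durs)) if durs else np.nan,
                }
            )
    return pd.DataFrame(rows)


def activity_conditioned_assignment(
    traces,
    sequences: list[StateSequence],
    activity_level: int,
    condition: str = "all",
    photoperiods: list[np.ndarray] | None = None,
) -> pd.DataFrame:
    """Among bins with a given observed activity count, the fraction decoded
    to each state (optionally restricted to day or night bins)."""
    if condition not in {"all", "day", "night"}:
        raise ValueError("condition must be all, day or night")
    if condition != "all" and photoperiods is None:
        raise ValueError("day/night conditioning requires photoperiod masks")
    labels = sequences[0].labels
    counts: dict[int, int] = {s: 0 for s in labels}
    total = 0
    for i, (trace, seq) in enumerate(zip(traces, sequences)):
        values = trace.values if hasattr(trace, "values") else np.asarray(trace)
        sel = values == activity_level
        if condition != "all":
            mask = np.asarray(photoperiods[i], dtype=bool)
            sel = sel & (mask if condition == "day" else ~mask)
        for s in labels:
            counts[s] += int(np.count_nonzero(seq.states[sel] == s))
        total += int(sel.sum())
    rows = [
        {
            "state": labels[s],
            "n_bins": counts[s],
            "fraction": counts[s] / total if total else np.nan,
            "defined": total > 0,
        }
        for s in sorted(labels)
    ]
    return pd.DataFrame(rows)
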