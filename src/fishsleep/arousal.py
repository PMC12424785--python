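"""Stimulus-response (arousability) analysis.

The assay spans a single night. Stimuli are aligned so each falls just after
a 1-minute bin boundary; the decoded state of the bin ending at the stimulus
is taken as the state at stimulus time. A response is any movement in the
2 s after the stimulus; the baseline applies the same 2-s rule anchored to
the end of the bin starting 2 min earlier, and is subtracted.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .semantics import canonical_label, relabel_sequence
from .selection import multi_restart_fit
from .hmm import viterbi_decode
from .types import ActivityTrace, HMMParameters, StateSequence

logger = logging.getLogger(__name__)

RESPONSE_WINDOW_S = 2


@dataclass
class ArousalDataset:
    """Per-second movement traces for a cohort plus the stimulus schedule.

    seconds : list of per-second movement indicators/counts, one per animal.
    stimulus_bins : bin indices b such that stimulus k fires at second b*60,
        i.e. just after the end of bin b-1.
    """

    animal_ids: list[str]
    seconds: list[np.ndarray]
    stimulus_bins: np.ndarray
    start_clock: str = "23:00"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.stimulus_bins = np.asarray(self.stimulus_bins, dtype=np.int64)
        if np.any(np.diff(self.stimulus_bins) <= 0):
            raise ValueError("stimulus times must be strictly increasing")
        self.seconds = [np.asarray(s, dtype=np.int64) for s in self.seconds]
        n = {s.size for s in self.seconds}
        if len(n) != 1:
            raise ValueError("all per-second traces must have equal length")
        if next(iter(n)) % 60 != 0:
            raise ValueError("per-second traces must cover whole minutes")

    @property
    def n_bins(self) -> int:
        return self.seconds[0].size // 60

    def binned_traces(self) -> list[ActivityTrace]:
        """1-min binned traces; per-minute sums of the per-second series."""
        out = []
        for aid, sec in zip(self.animal_ids, self.seconds):
            values = (sec > 0).astype(np.int64).reshape(-1, 60).sum(axis=1)
            out.append(
                ActivityTrace(
                    animal_id=aid,
                    values=values,
                    start_clock=self.start_clock,
                )
            )
        return out


@dataclass
class ArousalResult:
    """Pooled and per-animal response proportions per state."""

    by_state: pd.DataFrame
    per_animal: pd.DataFrame
    n_dropped: int

    def corrected(self, state: str) -> float:
        row = self.by_state[self.by_state["state"] == state]
        return float(row["corrected"].iloc[0])


def fit_concatenated(
    dataset_or_traces,
    K: int = 4,
    n_restarts: int = 20,
    base_seed: int = 0,
    concatenate: bool = False,
) -> tuple[HMMParameters, list[StateSequence]]:
    """Fit one shared K-state model across the cohort, then decode each animal.

    Default treats animals as independent chains sharing parameters; with
    ``concatenate=True`` the traces are joined end to end into one chain
    (compatibility mode; spurious transitions are counted at the joins).
    """
    if isinstance(dataset_or_traces, ArousalDataset):
        traces = dataset_or_traces.binned_traces()
    else:
        traces = list(dataset_or_traces)
    if not traces:
        raise ValueError("empty cohort")
    if concatenate:
        joined = np.concatenate([t.values for t in traces])
        fit_input = [joined]
    else:
        fit_input = traces
    params, _ = multi_restart_fit(fit_input, K, n_restarts=n_restarts, base_seed=base_seed)
    labeled = canonical_label(params)
    sequences = [
        relabel_sequence(viterbi_decode(t, params), labeled) for t in traces
    ]
    return params, sequences


def filter_complete_state_usage(
    sequences: list[StateSequence], K: int = 4
) -> list[int]:
    """Indices of animals whose decoded sequence visits every state at least once."""
    keep = [
        i for i, seq in enumerate(sequences) if np.unique(seq.states).size >= K
    ]
    logger.info(
        "excluded %d of %d animals lacking full state usage",
        len(sequences) - len(keep),
        len(sequences),
    )
    return keep


def _window_any(sec: np.ndarray, start_s: int) -> bool:
    return bool(np.any(sec[start_s:start_s + RESPONSE_WINDOW_S] > 0))


def _collect_events(
    dataset: ArousalDataset, sequences: list[StateSequence]
) -> tuple[pd.DataFrame, int]:
    rows = []
    dropped = 0
    for ai, (sec, seq) in enumerate(zip(dataset.seconds, sequences)):
        if seq.n_bins != dataset.n_bins:
            raise ValueError("state sequence does not align with the dataset")
        for b in dataset.stimulus_bins:
            b = int(b)
            if b - 2 < 0 or b * 60 + RESPONSE_WINDOW_S > sec.size:
                dropped += 1
                logger.info("dropped stimulus at bin %d for animal %d", b, ai)
                continue
            state_bin = b - 1  # bin ending exactly at the stimulus
            rows.append(
                {
                    "animal": ai,
                    "animal_id": dataset.animal_ids[ai],
                    "stim_bin": b,
                    "state": seq.labels[int(seq.states[state_bin])],
                    "pre_activity": int((sec[state_bin * 60:b * 60] > 0).sum()),
                    "response": _window_any(sec, b * 60),
                    # same 2-s rule anchored to the end of the bin that
                    # starts 2 min before the stimulus
                    "baseline": _window_any(sec, (b - 1) * 60),
                }
            )
    return pd.DataFrame(rows), dropped


def _summarize(events: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for state, grp in events.groupby("state"):
        raw = float(grp["response"].mean())
        base = float(grp["baseline"].mean())
        rows.append(
            {
                "state": state,
                "n_events": len(grp),
                "raw": raw,
                "baseline": base,
                "corrected": raw - base,
            }
        )
    return pd.DataFrame(rows)


def response_proportions(
    dataset: ArousalDataset, sequences: list[StateSequence]
) -> ArousalResult:
    """Baseline-corrected response proportion per state, pooled over
    (animal, stimulus) events, with a per-animal breakdown for t-tests."""
    events, dropped = _collect_events(dataset, sequences)
    by_state = _summarize(events)
    per_animal = (
        events.groupby(["animal_id", "state"])
        .agg(
            n_events=("response", "size"),
            raw=("response", "mean"),
            baseline=("baseline", "mean"),
        )
        .reset_index()
    )
    per_animal["corrected"] = per_animal["raw"] - per_animal["baseline"]
    return ArousalResult(by_state=by_state, per_animal=per_animal, n_dropped=dropped)


def pairwise_response_tests(
    result: ArousalResult, pairs: list[tuple[str, str]] = (("W1", "S1"), ("S1", "S2"))
) -> pd.DataFrame:
    """Across-animal Welch t-tests of corrected response proportions for
    pairs of states."""
    rows = []
    pa = result.per_animal
    for hi, lo in pairs:
        x = pa[pa["state"] == hi]["corrected"].to_numpy(dtype=float)
        y = pa[pa["state"] == lo]["corrected"].to_numpy(dtype=float)
        if x.size < 2 or y.size < 2:
            p = np.nan
        else:
            p = float(sps.ttest_ind(x, y, equal_var=False).pvalue)
        rows.append(
            {
                "higher": hi,
                "lower": lo,
                "mean_higher": float(x.mean()) if x.size else np.nan,
                "mean_lower": float(y.mean()) if y.size else np.nan,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)


def matched_activity_arousability(
    dataset: ArousalDataset,
    sequences: list[StateSequence],
    activity_level: int = 5,
    labels: tuple[str, str] = ("S1", "W1"),
) -> pd.DataFrame:
    """Restrict to stimuli whose preceding bin has exactly the given activity
    count, split events by decoded label, and compare response proportions.

    The p-value is a Fisher exact test on the raw response counts (baseline
    subtraction shifts both proportions by a shared constant in expectation).
    """
    events, _ = _collect_events(dataset, sequences)
    matched = events[events["pre_activity"] == activity_level]
    rows = []
    counts = {}
    for lab in labels:
        grp = matched[matched["state"] == lab]
        n = len(grp)
        counts[lab] = (int(grp["response"].sum()), n)
        rows.append(
            {
                "state": lab,
                "n_events": n,
                "raw": float(grp["response"].mean()) if n else np.nan,
                "baseline": float(grp["baseline"].mean()) if n else np.nan,
                "corrected": (
                    float(grp["response"].mean() - grp["baseline"].mean()) if n else np.nan
                ),
                "fraction_of_level": n / len(matched) if len(matched) else np.nan,
            }
        )
    out = pd.DataFrame(rows)
    (r1, n1), (r2, n2) = counts[labels[0]], counts[labels[1]]
    if n1 > 0 and n2 > 0:
        _, p = sps.fisher_exact([[r1, n1 - r1], [r2, n2 - r2]])
        out.attrs["p_value"] = float(p)
        out.attrs["comparison_skipped"] = False
    else:
        out.attrs["p_value"] = float("nan")
        out.attrs["comparison_skipped"] = True
    out.attrs["n_matched_events"] = int(len(matched))
    return out
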