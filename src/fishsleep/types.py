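"""Core domain types: model parameters, activity traces, decoded sequences.

All probability vectors/matrices are validated on construction; tolerances
follow the package-wide convention of 1e-9 for stochasticity checks.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

PROB_TOL = 1e-9
#: Lower bound applied to Poisson rates; a rate of exactly 0 with a nonzero
#: observation would give -inf log-likelihood.
RATE_FLOOR = 1e-3
#: Activity is seconds-active per 1-minute bin, so it cannot exceed 60.
MAX_ACTIVITY = 60

DAY_MINUTES = 24 * 60


def parse_clock(clock: str | int) -> int:
    """Parse "HH:MM" (or minutes-since-midnight int) to minutes since midnight."""
    if isinstance(clock, (int, np.integer)):
        m = int(clock)
    else:
        try:
            hh, mm = clock.split(":")
            m = int(hh) * 60 + int(mm)
        except (ValueError, AttributeError) as exc:
            raise ValueError(f"cannot parse clock time {clock!r}") from exc
    if not 0 <= m < DAY_MINUTES:
        raise ValueError(f"clock time {clock!r} out of range")
    return m


def format_clock(minutes: int) -> str:
    minutes = int(minutes) % DAY_MINUTES
    return f"{minutes // 60:02d}:{minutes % 60:02d}"


def photoperiod_mask(
    n: int,
    start_clock: str | int = "09:00",
    lights_on: str | int = "09:00",
    lights_off: str | int = "23:00",
) -> np.ndarray:
    """Boolean mask over n one-minute bins: True where white lights are on.

    Bin i covers clock minute (start + i) mod 1440; "day" is the half-open
    interval [lights_on, lights_off).
    """
    start = parse_clock(start_clock)
    on = parse_clock(lights_on)
    off = parse_clock(lights_off)
    clock = (start + np.arange(n)) % DAY_MINUTES
    if on <= off:
        return (clock >= on) & (clock < off)
    return (clock >= on) | (clock < off)


@dataclass(frozen=True)
class HMMParameters:
    """Parameters of a K-state hidden Markov model with Poisson emissions.

    Attributes
    ----------
    initial_probs : (K,) probability vector over the state at the first bin.
    transition_matrix : (K, K) row-stochastic matrix; entry [i, j] is the
        probability of moving from state i to state j between bins.
    rates : (K,) Poisson means, in seconds-active per minute.
    fit_meta : optional record of how the parameters were obtained.
    """

    initial_probs: np.ndarray
    transition_matrix: np.ndarray
    rates: np.ndarray
    fit_meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        pi = np.asarray(self.initial_probs, dtype=float)
        T = np.asarray(self.transition_matrix, dtype=float)
        lam = np.asarray(self.rates, dtype=float)
        object.__setattr__(self, "initial_probs", pi)
        object.__setattr__(self, "transition_matrix", T)
        object.__setattr__(self, "rates", lam)
        K = pi.shape[0]
        if pi.ndim != 1 or T.shape != (K, K) or lam.shape != (K,):
            raise ValueError(
                f"inconsistent dimensions: pi {pi.shape}, T {T.shape}, rates {lam.shape}"
            )
        if K < 1:
            raise ValueError("need at least one state")
        if np.any(pi < 0) or np.any(T < 0):
            raise ValueError("probabilities must be nonnegative")
        if abs(pi.sum() - 1.0) > PROB_TOL:
            raise ValueError(f"initial_probs sums to {pi.sum()!r}, not 1")
        rowsum = T.sum(axis=1)
        if np.any(np.abs(rowsum - 1.0) > PROB_TOL):
            raise ValueError(f"transition rows sum to {rowsum!r}, not 1")
        if np.any(lam < 0):
            raise ValueError("rates must be nonnegative")
        if np.any(~np.isfinite(pi)) or np.any(~np.isfinite(T)) or np.any(~np.isfinite(lam)):
            raise ValueError("parameters must be finite")

    @property
    def n_states(self) -> int:
        return self.initial_probs.shape[0]

    def to_dict(self) -> dict:
        return {
            "n_states": self.n_states,
            "initial_probs": self.initial_probs.tolist(),
            "transition_matrix": self.transition_matrix.tolist(),
            "rates": self.rates.tolist(),
            "fit_meta": dict(self.fit_meta),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: Mapping) -> "HMMParameters":
        params = cls(
            initial_probs=np.asarray(d["initial_probs"], dtype=float),
            transition_matrix=np.asarray(d["transition_matrix"], dtype=float),
            rates=np.asarray(d["rates"], dtype=float),
            fit_meta=dict(d.get("fit_meta", {})),
        )
        if "n_states" in d and int(d["n_states"]) != params.n_states:
            raise ValueError("n_states does not match vector dimensions")
        return params

    @classmethod
    def from_json(cls, path) -> "HMMParameters":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class ActivityTrace:
    """One animal's binned locomotor activity (integer seconds active/minute)."""

    animal_id: str
    values: np.ndarray
    start_clock: str = "09:00"
    lights_on: str = "09:00"
    lights_off: str = "23:00"
    photoperiod: np.ndarray | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.ndim != 1 or vals.size == 0:
            raise ValueError("trace must be a nonempty 1-D sequence")
        if not np.issubdtype(vals.dtype, np.integer):
            as_int = np.asarray(vals, dtype=float)
            if np.any(as_int != np.round(as_int)):
                raise ValueError("activity values must be integers")
            vals = as_int.astype(np.int64)
        else:
            vals = vals.astype(np.int64)
        if np.any(vals < 0) or np.any(vals > MAX_ACTIVITY):
            bad = int(np.flatnonzero((vals < 0) | (vals > MAX_ACTIVITY))[0])
            raise ValueError(
                f"activity out of range [0, {MAX_ACTIVITY}] at bin {bad} "
                f"(value {vals[bad]}) for animal {self.animal_id!r}"
            )
        object.__setattr__(self, "values", vals)
        mask = self.photoperiod
        if mask is None:
            mask = photoperiod_mask(vals.size, self.start_clock, self.lights_on, self.lights_off)
        else:
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != vals.shape:
                raise ValueError("photoperiod mask length must match trace length")
        object.__setattr__(self, "photoperiod", mask)

    @property
    def n_bins(self) -> int:
        return int(self.values.size)

    def clock_minutes(self) -> np.ndarray:
        """Clock time (minutes since midnight) of every bin."""
        return (parse_clock(self.start_clock) + np.arange(self.n_bins)) % DAY_MINUTES


@dataclass(frozen=True)
class PosteriorMatrix:
    """Per-bin smoothed state posteriors plus the trace log-likelihood."""

    probs: np.ndarray
    log_likelihood: float

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        if p.ndim != 2:
            raise ValueError("posterior must be an n x K matrix")
        if np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-8):
            raise ValueError("posterior rows must sum to 1")
        if not np.isfinite(self.log_likelihood):
            raise ValueError("log-likelihood must be finite")

    @property
    def n_states(self) -> int:
        return self.probs.shape[1]


@dataclass(frozen=True)
class StateSequence:
    """Decoded per-bin state indices with canonical display labels."""

    states: np.ndarray
    labels: Mapping[int, str]

    def __post_init__(self) -> None:
        s = np.asarray(self.states, dtype=np.int64)
        object.__setattr__(self, "states", s)
        used = set(int(i) for i in np.unique(s))
        missing = used - set(self.labels)
        if missing:
            raise ValueError(f"states {sorted(missing)} have no label")
        names = [self.labels[k] for k in self.labels]
        if len(names) != len(set(names)):
            raise ValueError("state labels must be distinct")

    @property
    def n_bins(self) -> int:
        return int(self.states.size)

    def label_array(self) -> np.ndarray:
        return np.asarray([self.labels[int(s)] for s in self.states], dtype=object)


def generic_labels(K: int) -> dict[int, str]:
    return {i: f"L{i + 1}" for i in range(K)}


def validate_counts(values: Sequence) -> np.ndarray:
    """Validate an observation vector as nonnegative integer counts."""
    arr = np.asarray(values)
    if arr.size == 0:
        raise ValueError("empty observation sequence")
    flt = np.asarray(arr, dtype=float)
    if np.any(~np.isfinite(flt)) or np.any(flt != np.round(flt)) or np.any(flt < 0):
        raise ValueError("observations must be nonnegative integers")
    return flt.astype(np.int64)
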