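"""File I/O: wide activity CSVs, per-second movement CSVs, parameter JSON,
and the YAML experiment config."""
from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .arousal import ArousalDataset
from .types import MAX_ACTIVITY, ActivityTrace


@dataclass
class ExperimentConfig:
    """Experiment-level settings parsed from YAML."""

    lights_on: str = "09:00"
    lights_off: str = "23:00"
    start_clock: str = "09:00"
    bin_minutes: int = 1
    k_min: int = 2
    k_max: int = 6
    n_restarts: int = 20
    seed: int = 0
    n_permutations: int = 10_000
    alpha: float = 0.05
    groups: dict = field(default_factory=dict)  # group name -> list of animal ids
    scenario: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bin_minutes != 1:
            raise ValueError("only 1-minute bins are supported")
        if self.k_min < 1 or self.k_max < self.k_min:
            raise ValueError("k range must satisfy 1 <= k_min <= k_max")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def write_traces_csv(traces: list[ActivityTrace], path) -> None:
    """Wide CSV: first column `minute` (index from recording start), one
    column per animal."""
    n = {t.n_bins for t in traces}
    if len(n) != 1:
        raise ValueError("all traces must have the same length")
    df = pd.DataFrame({"minute": np.arange(next(iter(n)))})
    for t in traces:
        df[t.animal_id] = t.values
    df.to_csv(path, index=False)


def read_traces_csv(
    path,
    start_clock: str = "09:00",
    lights_on: str = "09:00",
    lights_off: str = "23:00",
) -> list[ActivityTrace]:
    """Read a wide activity CSV with strict integer validation.

    Out-of-range or non-integer cells are reported with column and row so
    bad inputs are traceable.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected a time column plus at least one animal")
    animal_cols = list(df.columns[1:])
    traces = []
    for col in animal_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != np.floor(vals)) | (vals < 0) | (vals > MAX_ACTIVITY)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: invalid activity value {df[col].iloc[row]!r} "
                f"(column {col!r}, data row {row}); "
                f"expected an integer in [0, {MAX_ACTIVITY}]"
            )
        traces.append(
            ActivityTrace(
                animal_id=str(col),
                values=vals.to_numpy(dtype=np.int64),
                start_clock=start_clock,
                lights_on=lights_on,
                lights_off=lights_off,
            )
        )
    return traces


def write_seconds_csv(dataset: ArousalDataset, path) -> None:
    """Long per-second CSV: second, animal_id, movement."""
    frames = []
    for aid, sec in zip(dataset.animal_ids, dataset.seconds):
        frames.append(
            pd.DataFrame({"second": np.arange(sec.size), "animal_id": aid, "movement": sec})
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_seconds_csv(
    path, stimulus_bins, start_clock: str = "23:00"
) -> ArousalDataset:
    df = pd.read_csv(path)
    required = {"second", "animal_id", "movement"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    ids, seconds = [], []
    for aid, grp in df.groupby("animal_id", sort=True):
        grp = grp.sort_values("second")
        ids.append(str(aid))
        seconds.append(grp["movement"].to_numpy(dtype=np.int64))
    return ArousalDataset(
        animal_ids=ids,
        seconds=seconds,
        stimulus_bins=np.asarray(stimulus_bins, dtype=np.int64),
        start_clock=start_clock,
    )


def write_state_sequences_csv(sequences, traces, path) -> None:
    """Long CSV of decoded states: minute, animal_id, state_label."""
    frames = []
    for seq, trace in zip(sequences, traces):
        frames.append(
            pd.DataFrame(
                {
                    "minute": np.arange(seq.n_bins),
                    "animal_id": trace.animal_id,
                    "state_label": seq.label_array(),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
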