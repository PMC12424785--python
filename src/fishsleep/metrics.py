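"""Conventional (zero-activity bin) sleep and its comparison with decoded S2."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import ActivityTrace, StateSequence


def conventional_sleep(trace: ActivityTrace, period_mask: np.ndarray | None = None) -> int:
    """Minutes of conventional sleep: count of bins with activity exactly 0.

    At 1-minute binning this is the standard larval-zebrafish definition
    (immobility of at least one minute).
    """
    values = trace.values if isinstance(trace, ActivityTrace) else np.asarray(trace)
    if period_mask is not None:
        values = values[np.asarray(period_mask, dtype=bool)]
    return int(np.count_nonzero(values == 0))


@dataclass
class SleepComparison:
    """Per animal-period conventional vs S2 sleep minutes with pooled stats."""

    table: pd.DataFrame
    pearson_r: float
    p_value: float
    mean_deviation: float  # mean(S2 - conventional); negative = below y=x
    reliable: bool
    per_period_r: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "pearson_r": self.pearson_r,
            "p_value": self.p_value,
            "mean_deviation": self.mean_deviation,
            "reliable": self.reliable,
            "per_period_r": self.per_period_r,
        }


def compare_s2_conventional(
    traces: list[ActivityTrace],
    sequences: list[StateSequence],
    s2_label: str = "S2",
) -> SleepComparison:
    """Scatter conventional sleep against decoded S2 minutes per animal and
    period; Pearson r is pooled over day+night points, as a check against
    the identity line y = x."""
    rows = []
    for trace, seq in zip(traces, sequences):
        if seq.n_bins != trace.n_bins:
            raise ValueError("trace and state sequence must align")
        s2_states = {s for s, name in seq.labels.items() if name == s2_label}
        if not s2_states:
            raise ValueError(f"no state labeled {s2_label!r}")
        is_s2 = np.isin(seq.states, list(s2_states))
        for period, sel in (("day", trace.photoperiod), ("night", ~trace.photoperiod)):
            rows.append(
                {
                    "animal_id": trace.animal_id,
                    "period": period,
                    "conventional_min": conventional_sleep(trace, sel),
                    "s2_min": int(np.count_nonzero(is_s2 & sel)),
                }
            )
    table = pd.DataFrame(rows)
    x = table["conventional_min"].to_numpy(dtype=float)
    y = table["s2_min"].to_numpy(dtype=float)
    reliable = len(table) >= 3 and np.std(x) > 0 and np.std(y) > 0
    if reliable:
        r, p = stats.pearsonr(x, y)
    else:
        r, p = np.nan, np.nan
    per_period_r = {}
    for period in ("day", "night"):
        sub = table[table["period"] == period]
        xs = sub["conventional_min"].to_numpy(dtype=float)
        ys = sub["s2_min"].to_numpy(dtype=float)
        if len(sub) >= 3 and np.std(xs) > 0 and np.std(ys) > 0:
            per_period_r[period] = float(stats.pearsonr(xs, ys)[0])
        else:
            per_period_r[period] = float("nan")
    return SleepComparison(
        table=table,
        pearson_r=float(r),
        p_value=float(p),
        mean_deviation=float(np.mean(y - x)),
        reliable=bool(reliable),
        per_period_r=per_period_r,
    )
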