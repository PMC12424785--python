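"""Group-comparison statistics: seeded permutation tests on per-animal HMM
parameters with Bonferroni families, t-tests with Benjamini-Hochberg
correction on state amounts, and the sleep-deprivation rebound contrast.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import ActivityTrace, StateSequence, parse_clock

#: Bonferroni family sizes: 4 state occupancies / 4 rates, and all 16
#: entries of a 4-state transition matrix.
BONFERRONI_FACTORS = {"occupancy": 4, "rate": 4, "transition": 16}

ALPHA = 0.05


@dataclass
class ComparisonResult:
    """One parameter's two-group comparison with its corrected p-value."""

    parameter: str
    mean_a: float
    mean_b: float
    observed_diff: float
    p_raw: float
    p_corrected: float
    method: str
    correction: str
    factor: int

    @property
    def significant(self) -> bool:
        return self.p_corrected < ALPHA

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["significant"] = self.significant
        return d


def perm_test_parameter(
    group_a,
    group_b,
    n_permutations: int = 10_000,
    seed: int = 0,
    bootstrap: bool = False,
) -> float:
    """Two-sided permutation p-value for a difference in group means.

    p = (1 + #{|T_perm| >= |T_obs|}) / (B + 1). With ``bootstrap=True`` each
    permuted pseudo-group is additionally resampled with replacement before
    the statistic is computed (sensitivity variant; the label permutation is
    the primary procedure).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 animals")
    obs = abs(a.mean() - b.mean())
    if obs == 0 and np.ptp(np.concatenate([a, b])) == 0:
        return 1.0
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    n_a, n = a.size, pooled.size
    # vectorized batch of label permutations (argsort of uniforms)
    idx = np.argsort(rng.random((n_permutations, n)), axis=1)
    pa = pooled[idx[:, :n_a]]
    pb = pooled[idx[:, n_a:]]
    if bootstrap:
        pa = np.take_along_axis(pa, rng.integers(0, n_a, size=pa.shape), axis=1)
        pb = np.take_along_axis(pb, rng.integers(0, n - n_a, size=pb.shape), axis=1)
    stat = np.abs(pa.mean(axis=1) - pb.mean(axis=1))
    count = int(np.count_nonzero(stat >= obs - 1e-12))
    return (1 + count) / (n_permutations + 1)


def bonferroni(p_raw: float, family: str) -> float:
    """Family-wise correction: x4 for occupancies and rates, x16 for
    transition entries; capped at 1."""
    if family not in BONFERRONI_FACTORS:
        raise ValueError(f"unknown family {family!r}; expected {sorted(BONFERRONI_FACTORS)}")
    return min(1.0, p_raw * BONFERRONI_FACTORS[family])


def bh_correct(p_values, q: float = ALPHA) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: returns (adjusted p-values, reject mask).

    Adjusted p_(i) = min over j >= i of m * p_(j) / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any(~np.isfinite(p)):
        raise ValueError("p-values must be finite")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj, adj <= q


def compare_parameter_families(
    params_a: list[dict],
    params_b: list[dict],
    n_permutations: int = 10_000,
    seed: int = 0,
    bootstrap: bool = False,
) -> list[ComparisonResult]:
    """Permutation-test every occupancy, rate, and transition entry between
    two cohorts of per-animal labeled fits.

    Each element of params_a/b maps parameter names (e.g. "occupancy[S2]",
    "rate[S1]", "transition[S2->S1]") to per-animal values.
    """
    names = list(params_a[0])
    results = []
    for idx, name in enumerate(names):
        a = np.array([d[name] for d in params_a])
        b = np.array([d[name] for d in params_b])
        family = name.split("[")[0]
        p_raw = perm_test_parameter(
            a, b, n_permutations=n_permutations, seed=seed + idx, bootstrap=bootstrap
        )
        results.append(
            ComparisonResult(
                parameter=name,
                mean_a=float(a.mean()),
                mean_b=float(b.mean()),
                observed_diff=float(a.mean() - b.mean()),
                p_raw=p_raw,
                p_corrected=bonferroni(p_raw, family),
                method="permutation" + ("+bootstrap" if bootstrap else ""),
                correction="bonferroni",
                factor=BONFERRONI_FACTORS[family],
            )
        )
    return results


def state_minutes_table(
    sequences: list[StateSequence],
    photoperiods: list[np.ndarray],
    animal_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Per-animal minutes in each state by period (wide, one row per animal-period)."""
    rows = []
    for i, (seq, mask) in enumerate(zip(sequences, photoperiods)):
        mask = np.asarray(mask, dtype=bool)
        aid = animal_ids[i] if animal_ids else f"animal_{i}"
        for period, sel in (("day", mask), ("night", ~mask)):
            row = {"animal_id": aid, "period": period}
            for s in sorted(seq.labels):
                row[seq.labels[s]] = int(np.count_nonzero(seq.states[sel] == s))
            rows.append(row)
    return pd.DataFrame(rows)


def state_amount_tests(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    period: str,
    welch: bool = True,
) -> list[ComparisonResult]:
    """Unpaired two-sample t-tests of per-animal state minutes (one test per
    state), BH-corrected across states. Welch's t by default."""
    a = table_a[table_a["period"] == period]
    b = table_b[table_b["period"] == period]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 animals")
    states = [c for c in a.columns if c not in ("animal_id", "period")]
    raw = []
    means = []
    for s in states:
        xa = a[s].to_numpy(dtype=float)
        xb = b[s].to_numpy(dtype=float)
        t = sps.ttest_ind(xa, xb, equal_var=not welch)
        raw.append(float(t.pvalue) if np.isfinite(t.pvalue) else 1.0)
        means.append((xa.mean(), xb.mean()))
    adj, _ = bh_correct(raw)
    return [
        ComparisonResult(
            parameter=f"minutes[{s}|{period}]",
            mean_a=float(ma),
            mean_b=float(mb),
            observed_diff=float(ma - mb),
            p_raw=raw[i],
            p_corrected=float(adj[i]),
            method="welch_t" if welch else "student_t",
            correction="benjamini_hochberg",
            factor=len(states),
        )
        for i, (s, (ma, mb)) in enumerate(zip(states, means))
    ]


def paired_state_amount_tests(table: pd.DataFrame, welch: bool = True) -> list[ComparisonResult]:
    """Within-animal day-vs-night paired t-tests per state, BH-corrected."""
    day = table[table["period"] == "day"].set_index("animal_id")
    night = table[table["period"] == "night"].set_index("animal_id")
    common = day.index.intersection(night.index)
    if len(common) < 2:
        raise ValueError("need at least 2 animals with both periods")
    states = [c for c in table.columns if c not in ("animal_id", "period")]
    raw = []
    means = []
    for s in states:
        xd = day.loc[common, s].to_numpy(dtype=float)
        xn = night.loc[common, s].to_numpy(dtype=float)
        t = sps.ttest_rel(xd, xn)
        raw.append(float(t.pvalue) if np.isfinite(t.pvalue) else 1.0)
        means.append((xd.mean(), xn.mean()))
    adj, _ = bh_correct(raw)
    return [
        ComparisonResult(
            parameter=f"minutes[{s}|day_vs_night]",
            mean_a=float(md),
            mean_b=float(mn),
            observed_diff=float(md - mn),
            p_raw=raw[i],
            p_corrected=float(adj[i]),
            method="paired_t",
            correction="benjamini_hochberg",
            factor=len(states),
        )
        for i, (s, (md, mn)) in enumerate(zip(states, means))
    ]


@dataclass
class DeprivationSchedule:
    """48-h recording starting at lights-on; on night 2 white lights stay on
    from normal lights-off until ``deprivation_end`` and the rebound window
    runs from there to the end of the night."""

    start_clock: str = "09:00"
    lights_on: str = "09:00"
    lights_off: str = "23:00"
    deprivation_end: str = "05:00"

    def windows(self, n_bins: int) -> tuple[slice, slice]:
        """(night-1 matched window, night-2 rebound window) as bin slices."""
        start = parse_clock(self.start_clock)
        on = parse_clock(self.lights_on)
        off = parse_clock(self.lights_off)
        dep_end = parse_clock(self.deprivation_end)
        day_len = (off - on) % (24 * 60)
        night_len = 24 * 60 - day_len
        rebound_len = (on - dep_end) % (24 * 60)
        if start != on:
            raise ValueError("schedule assumes the trace starts at lights-on")
        night1_start = day_len
        night2_start = 24 * 60 + day_len
        n1 = slice(night1_start + night_len - rebound_len, night1_start + night_len)
        n2 = slice(night2_start + night_len - rebound_len, night2_start + night_len)
        if n2.stop > n_bins:
            raise ValueError(
                f"trace has {n_bins} bins but the schedule needs {n2.stop}"
            )
        return n1, n2


def deprivation_contrast(
    sequences: list[StateSequence],
    schedule: DeprivationSchedule,
    states: tuple[str, ...] = ("S2", "S1"),
) -> pd.DataFrame:
    """Per-animal minutes of each state in the rebound window of night 2
    versus the clock-matched window of night 1, with paired t-tests."""
    rows = []
    for i, seq in enumerate(sequences):
        w1, w2 = schedule.windows(seq.n_bins)
        inv = {name: s for s, name in seq.labels.items()}
        for name in states:
            if name not in inv:
                raise ValueError(f"no state labeled {name!r}")
            s = inv[name]
            rows.append(
                {
                    "animal": i,
                    "state": name,
                    "night1_min": int(np.count_nonzero(seq.states[w1] == s)),
                    "night2_min": int(np.count_nonzero(seq.states[w2] == s)),
                }
            )
    table = pd.DataFrame(rows)
    out = []
    for name in states:
        sub = table[table["state"] == name]
        x1 = sub["night1_min"].to_numpy(dtype=float)
        x2 = sub["night2_min"].to_numpy(dtype=float)
        if len(sub) >= 2 and (np.ptp(x2 - x1) > 0):
            p = float(sps.ttest_rel(x2, x1).pvalue)
        else:
            p = 1.0
        out.append(
            {
                "state": name,
                "night1_mean": float(x1.mean()),
                "night2_mean": float(x2.mean()),
                "diff": float((x2 - x1).mean()),
                "p_paired_t": p,
            }
        )
    summary = pd.DataFrame(out)
    summary.attrs["per_animal"] = table
    return summary
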