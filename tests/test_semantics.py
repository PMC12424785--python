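import numpy as np
import pandas as pd
import pytest

from fishsleep import hmm, semantics
from fishsleep.semantics import (
    activity_conditioned_assignment,
    bout_statistics,
    canonical_label,
    day_night_proportions,
    smoothed_state_probabilities,
)
from fishsleep.types import HMMParameters, StateSequence


def make_params(rates, sticky=0.9):
    K = len(rates)
    T = np.full((K, K), (1 - sticky) / (K - 1))
    np.fill_diagonal(T, sticky)
    return HMMParameters(initial_probs=np.full(K, 1 / K), transition_matrix=T, rates=rates)


class TestCanonicalLabel:
    def test_four_state_fitted_order(self):
        fit = canonical_label(make_params([3.82, 0.02, 7.53, 1.14]))
        assert [fit.labels[i] for i in range(4)] == ["W1", "S2", "W2", "S1"]

    def test_three_state(self):
        fit = canonical_label(make_params([0.03, 1.2, 4.1]))
        assert [fit.labels[i] for i in range(3)] == ["S2", "S1", "W"]

    def test_generic_fallback_k5(self):
        fit = canonical_label(make_params([0.1, 1, 2, 3, 4]))
        assert sorted(fit.labels.values()) == ["L1", "L2", "L3", "L4", "L5"]

    def test_duplicate_rates_warn_and_keep_order(self):
        with pytest.warns(RuntimeWarning, match="duplicate"):
            fit = canonical_label(make_params([2.0, 2.0, 5.0]))
        assert fit.labels[0] == "S2" and fit.labels[1] == "S1"

    def test_invariant_to_state_permutation(self):
        p = make_params([0.02, 1.14, 3.82, 7.53])
        perm = np.array([2, 0, 3, 1])
        q = HMMParameters(
            initial_probs=p.initial_probs[perm],
            transition_matrix=p.transition_matrix[np.ix_(perm, perm)],
            rates=p.rates[perm],
        )
        fp, fq = canonical_label(p), canonical_label(q)
        assert {fp.labels[i]: p.rates[i] for i in range(4)} == {
            fq.labels[i]: q.rates[i] for i in range(4)
        }

    def test_occupancy_matches_viterbi_frequencies(self):
        p = make_params([0.2, 3.0, 8.0], sticky=0.85)
        fit = canonical_label(p)
        seq, trace = hmm.sample_sequence(p, 60_000, seed=5)
        decoded = hmm.viterbi_decode(trace, p)
        freq = np.bincount(decoded.states, minlength=3) / decoded.n_bins
        assert np.all(np.abs(freq - fit.occupancy) < 0.02)


class TestSmoothing:
    def test_constant_unchanged(self):
        probs = np.tile([0.3, 0.7], (200, 1))
        assert np.allclose(smoothed_state_probabilities(probs, 60), probs)

    def test_step_becomes_ramp(self):
        n, b = 300, 150
        probs = np.zeros((n, 2))
        probs[:b, 0] = 1.0
        probs[b:, 1] = 1.0
        sm = smoothed_state_probabilities(probs, 60)
        # hand-computed truncated centered average: window [t-30, t+30)
        for t in (100, 130, 149, 150, 170, 200):
            lo, hi = max(t - 30, 0), min(t + 30, n)
            assert sm[t, 0] == pytest.approx(np.mean(probs[lo:hi, 0]))
        assert 0 < sm[b, 0] < 1

    def test_rows_still_sum_to_one(self, rng):
        probs = rng.dirichlet(np.ones(4), size=500)
        sm = smoothed_state_probabilities(probs, 60)
        assert np.allclose(sm.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(sm >= 0) and np.all(sm <= 1)

    def test_misaligned_inputs_rejected(self, rng):
        a = rng.dirichlet(np.ones(2), size=100)
        b = rng.dirichlet(np.ones(2), size=90)
        with pytest.raises(ValueError):
            smoothed_state_probabilities([a, b], 60)


LAB4 = {0: "S2", 1: "S1", 2: "W1", 3: "W2"}


class TestDayNightProportions:
    def test_pure_split(self):
        day = np.concatenate([np.ones(840, bool), np.zeros(600, bool)])
        states = np.where(day, 2, 0)  # W1 by day, S2 at night
        df = day_night_proportions(StateSequence(states=states, labels=LAB4), day)
        get = lambda p, s: df[(df.period == p) & (df.state == s)].iloc[0]
        assert get("night", "S2").fraction == 1.0
        assert get("day", "W1").fraction == 1.0
        assert df.groupby("period").minutes.sum().to_dict() == {"day": 840, "night": 600}

    def test_wt_cohort_sleeps_more_at_night(self, wt_cohort):
        night_sleep, day_sleep = [], []
        for seq, trace in zip(wt_cohort.states, wt_cohort.traces):
            df = day_night_proportions(seq, trace.photoperiod)
            s = df[df.state.isin(["S2", "S1"])].groupby("period").fraction.sum()
            night_sleep.append(s["night"])
            day_sleep.append(s["day"])
        assert np.mean(night_sleep) > np.mean(day_sleep)
        assert 0.5 < np.mean(night_sleep) < 0.9

    def test_empty_period_flagged(self):
        mask = np.ones(100, bool)  # no night bins at all
        seq = StateSequence(states=np.zeros(100, np.int64), labels=LAB4)
        df = day_night_proportions(seq, mask)
        night = df[df.period == "night"]
        assert not night.defined.any()
        assert night.fraction.isna().all()


class TestBoutStatistics:
    def test_hand_counted(self):
        states = np.array([0, 0, 1, 0, 0, 0])
        mask = np.ones(6, bool)
        df = bout_statistics(StateSequence(states=states, labels=LAB4), mask)
        s2_day = df[(df.state == "S2") & (df.period == "day")].iloc[0]
        assert s2_day.n_bouts == 2
        assert s2_day.mean_duration == pytest.approx(2.5)

    def test_split_at_light_transition(self):
        states = np.zeros(7, np.int64)
        mask = np.array([1, 1, 1, 0, 0, 0, 0], bool)  # lights off after bin 2
        df = bout_statistics(StateSequence(states=states, labels=LAB4), mask)
        day = df[(df.state == "S2") & (df.period == "day")].iloc[0]
        night = df[(df.state == "S2") & (df.period == "night")].iloc[0]
        assert day.total_minutes == 3 and night.total_minutes == 4
        assert day.n_bouts == 1 and night.n_bouts == 1

    def test_minutes_conserved(self, wt_cohort):
        seq = wt_cohort.states[0]
        mask = wt_cohort.traces[0].photoperiod
        df = bout_statistics(seq, mask)
        assert df.total_minutes.sum() == seq.n_bins

    def test_night_sleep_bouts_longer(self, wt_cohort):
        ratios = []
        for seq, trace in zip(wt_cohort.states, wt_cohort.traces):
            df = bout_statistics(seq, trace.photoperiod).set_index(["state", "period"])
            for s in ("S2", "S1"):
                ratios.append(
                    df.loc[(s, "night")].mean_duration / df.loc[(s, "day")].mean_duration
                )
        assert np.mean(ratios) > 1.0


class TestActivityConditionedAssignment:
    def test_forced_state(self):
        # only S2 emits 0 by construction
        traces = [np.array([0, 5, 0, 6, 0])]
        seqs = [StateSequence(states=np.array([0, 2, 0, 2, 0]), labels=LAB4)]
        df = activity_conditioned_assignment(traces, seqs, activity_level=0)
        assert df[df.state == "S2"].fraction.iloc[0] == 1.0

    def test_fractions_sum_to_one(self, wt_cohort):
        for level in (0, 2, 5):
            df = activity_conditioned_assignment(
                wt_cohort.traces, wt_cohort.states, activity_level=level
            )
            if df.defined.iloc[0]:
                assert df.fraction.sum() == pytest.approx(1.0)

    def test_night_shifts_assignment_toward_sleep(self, wt_cohort):
        kw = dict(photoperiods=[t.photoperiod for t in wt_cohort.traces])
        night = activity_conditioned_assignment(
            wt_cohort.traces, wt_cohort.states, 2, condition="night", **kw
        ).set_index("state")
        day = activity_conditioned_assignment(
            wt_cohort.traces, wt_cohort.states, 2, condition="day", **kw
        ).set_index("state")
        assert night.loc["S1"].fraction > day.loc["S1"].fraction
        assert day.loc["W1"].fraction > night.loc["W1"].fraction

    def test_missing_level_flagged(self):
        traces = [np.array([1, 1])]
        seqs = [StateSequence(states=np.array([1, 1]), labels=LAB4)]
        df = activity_conditioned_assignment(traces, seqs, activity_level=60)
        assert not df.defined.any()
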