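import numpy as np
import pytest

from fishsleep import hmm
from fishsleep.types import HMMParameters

from .conftest import random_params
from . import oracles


def params2(pi=(0.5, 0.5), T=((0.5, 0.5), (0.5, 0.5)), rates=(1.0, 2.0)):
    return HMMParameters(initial_probs=pi, transition_matrix=T, rates=rates)


class TestLogLikelihood:
    def test_two_state_single_obs(self):
        # P(0) = 0.5 e^-1 + 0.5 e^-2
        expected = np.log(0.5 * np.exp(-1) + 0.5 * np.exp(-2))
        assert hmm.log_likelihood([0], params2()) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(-1.3798, abs=1e-4)

    def test_single_state_closed_form(self):
        p = HMMParameters(initial_probs=[1.0], transition_matrix=[[1.0]], rates=[1.0])
        assert hmm.log_likelihood([1, 1], p) == pytest.approx(-2.0, abs=1e-12)

    def test_matches_enumeration(self, rng):
        for _ in range(10):
            K = int(rng.integers(1, 4))
            p = random_params(rng, K)
            obs = rng.integers(0, 10, 6)
            expected = oracles.enum_log_likelihood(
                obs, p.initial_probs, p.transition_matrix, p.rates
            )
            assert hmm.log_likelihood(obs, p) == pytest.approx(expected, abs=1e-9)

    def test_invalid_observations(self):
        with pytest.raises(ValueError):
            hmm.log_likelihood([1.5], params2())
        with pytest.raises(ValueError):
            hmm.log_likelihood([-1], params2())

    def test_zero_rate_is_floored(self):
        p = params2(rates=(0.0, 2.0))
        assert np.isfinite(hmm.log_likelihood([3, 0, 3], p))


class TestPosteriors:
    def test_single_state_degenerate(self):
        p = HMMParameters(initial_probs=[1.0], transition_matrix=[[1.0]], rates=[2.0])
        post = hmm.posterior_state_probs([1, 4, 0], p)
        assert np.allclose(post.probs, 1.0)

    def test_absorbing_start(self):
        p = params2(pi=(1.0, 0.0), T=((1.0, 0.0), (0.0, 1.0)), rates=(1.0, 5.0))
        post = hmm.posterior_state_probs([5, 5, 5], p)
        assert np.allclose(post.probs[:, 0], 1.0)

    def test_matches_enumeration(self, rng):
        for _ in range(10):
            p = random_params(rng, 2)
            obs = rng.integers(0, 8, 5)
            expected = oracles.enum_posteriors(
                obs, p.initial_probs, p.transition_matrix, p.rates
            )
            got = hmm.posterior_state_probs(obs, p)
            assert np.allclose(got.probs, expected, atol=1e-9)

    def test_rows_sum_to_one(self, rng):
        p = random_params(rng, 3)
        post = hmm.posterior_state_probs(rng.integers(0, 10, 50), p)
        assert np.allclose(post.probs.sum(axis=1), 1.0, atol=1e-9)


class TestViterbi:
    def test_two_bin_switch(self):
        p = params2(T=((0.9, 0.1), (0.1, 0.9)), rates=(0.1, 5.0))
        seq = hmm.viterbi_decode([0, 6], p)
        assert seq.states.tolist() == [0, 1]

    def test_tie_breaks_to_lowest_index(self):
        p = params2(rates=(1.0, 1.0))
        seq = hmm.viterbi_decode([2, 2, 2], p)
        assert seq.states.tolist() == [0, 0, 0]

    def test_matches_enumeration(self, rng):
        for _ in range(10):
            K = int(rng.integers(2, 4))
            p = random_params(rng, K)
            obs = rng.integers(0, 8, 7)
            expected = oracles.enum_viterbi(
                obs, p.initial_probs, p.transition_matrix, p.rates
            )
            assert hmm.viterbi_decode(obs, p).states.tolist() == expected.tolist()


class TestEMFit:
    def test_two_state_recovery(self):
        truth = params2(T=((0.95, 0.05), (0.05, 0.95)), rates=(0.5, 6.0))
        _, trace = hmm.sample_sequence(truth, 2880, seed=9)
        fit, _ = hmm.em_fit(trace, 2, seed=1)
        lam = np.sort(fit.rates)
        assert np.all(np.abs(lam - [0.5, 6.0]) / [0.5, 6.0] < 0.10)
        order = np.argsort(fit.rates)
        T = fit.transition_matrix[np.ix_(order, order)]
        assert np.all(np.abs(T - truth.transition_matrix) < 0.05)

    def test_single_state_closed_form(self):
        fit, _ = hmm.em_fit([3, 4, 5, 8], 1, seed=0)
        assert fit.rates[0] == pytest.approx(5.0, abs=1e-12)

    def test_monotone_log_likelihood(self, rng):
        for _ in range(50):
            K = int(rng.integers(1, 4))
            obs = rng.integers(0, 12, 200)
            fit, _ = hmm.em_fit(obs, K, seed=int(rng.integers(0, 10_000)), max_iter=100)
            h = fit.fit_meta["ll_history"]
            assert all(b - a >= -1e-8 for a, b in zip(h, h[1:]))

    def test_k_exceeding_distinct_values_warns(self):
        with pytest.warns(RuntimeWarning, match="distinct"):
            hmm.em_fit([1, 1, 2, 2, 1], 3, seed=0, max_iter=10)

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            hmm.em_fit([], 2, seed=0)

    def test_multiple_traces_share_parameters(self):
        truth = params2(T=((0.9, 0.1), (0.1, 0.9)), rates=(0.3, 5.0))
        traces = [hmm.sample_sequence(truth, 800, seed=s)[1] for s in range(4)]
        fit, _ = hmm.em_fit(traces, 2, seed=5)
        assert np.all(np.abs(np.sort(fit.rates) - [0.3, 5.0]) / [0.3, 5.0] < 0.2)


class TestSampling:
    def test_seed_determinism(self, wt_params):
        s1, t1 = hmm.sample_sequence(wt_params, 500, seed=42)
        s2, t2 = hmm.sample_sequence(wt_params, 500, seed=42)
        assert np.array_equal(s1.states, s2.states)
        assert np.array_equal(t1.values, t2.values)

    def test_sample_mean_clt(self):
        p = HMMParameters(initial_probs=[1.0], transition_matrix=[[1.0]], rates=[4.0])
        _, trace = hmm.sample_sequence(p, 10_000, seed=7)
        assert abs(trace.values.mean() - 4.0) < 3 * 2 / 100

    def test_empirical_occupancy_matches_stationary(self):
        p = params2(T=((0.95, 0.05), (0.10, 0.90)), rates=(1.0, 6.0))
        seq, _ = hmm.sample_sequence(p, 200_000, seed=3)
        emp = np.bincount(seq.states, minlength=2) / seq.n_bins
        stat = hmm.stationary_distribution(p.transition_matrix)
        assert np.all(np.abs(emp - stat) < 0.02)


class TestBIC:
    def test_hand_example(self):
        assert hmm.bic_score(-150.0, 2, 100) == pytest.approx(300 + 5 * np.log(100))
        assert 300 + 5 * np.log(100) == pytest.approx(323.03, abs=0.01)

    def test_single_state(self):
        assert hmm.bic_score(0.0, 1, 10) == pytest.approx(np.log(10))

    def test_parameter_count_k4(self):
        # p = K^2 + K - 1 = 19 for K = 4
        assert hmm.bic_score(0.0, 4, np.e) == pytest.approx(19.0)

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            hmm.bic_score(0.0, 2, 0)


class TestEmissionPosterior:
    def test_uniform_priors(self, wt_params):
        post = hmm.emission_posterior_given_obs(0, wt_params)
        assert np.allclose(post, [0.741, 0.242, 0.017, 0.0004], atol=5e-4)

    def test_occupancy_weighted_priors(self, wt_params):
        priors = np.array([0.354, 0.095, 0.334, 0.216])
        priors = priors / priors.sum()
        post = hmm.emission_posterior_given_obs(0, wt_params, priors)
        assert np.allclose(100 * post, [90.1, 7.9, 1.9, 0.03], atol=0.15)

    def test_single_state(self):
        p = HMMParameters(initial_probs=[1.0], transition_matrix=[[1.0]], rates=[3.0])
        assert hmm.emission_posterior_given_obs(7, p) == pytest.approx([1.0])

    def test_zero_mass_error(self):
        p = params2(rates=(800.0, 1.0))
        with pytest.raises(ValueError, match="zero posterior mass"):
            hmm.emission_posterior_given_obs(0, p, priors=np.array([1.0, 0.0]))


class TestStationaryDistribution:
    def test_symmetric(self):
        assert np.allclose(
            hmm.stationary_distribution([[0.9, 0.1], [0.1, 0.9]]), [0.5, 0.5]
        )

    def test_hand_solved(self):
        got = hmm.stationary_distribution([[0.5, 0.5], [0.25, 0.75]])
        assert np.allclose(got, [1 / 3, 2 / 3], atol=1e-12)

    def test_matches_long_run_empirical(self, rng):
        K = 3
        T = np.stack([rng.dirichlet(np.ones(K) * 3) for _ in range(K)])
        p = HMMParameters(initial_probs=np.full(K, 1 / 3), transition_matrix=T, rates=[1, 2, 3])
        seq, _ = hmm.sample_sequence(p, 1_000_000, seed=8)
        emp = np.bincount(seq.states, minlength=K) / seq.n_bins
        assert np.all(np.abs(emp - hmm.stationary_distribution(T)) < 0.01)

    def test_non_stochastic_rejected(self):
        with pytest.raises(ValueError):
            hmm.stationary_distribution([[0.5, 0.6], [0.5, 0.5]])

    def test_reducible_falls_back_with_warning(self):
        with pytest.warns(RuntimeWarning, match="reducible"):
            got = hmm.stationary_distribution(np.eye(2))
        assert got.sum() == pytest.approx(1.0)


class TestHmmlearnCrossCheck:
    def test_log_likelihood_agrees(self, rng):
        hmmlearn_hmm = pytest.importorskip("hmmlearn.hmm")
        p = random_params(rng, 3)
        obs = rng.integers(0, 12, 400)
        model = hmmlearn_hmm.PoissonHMM(n_components=3)
        model.startprob_ = p.initial_probs
        model.transmat_ = p.transition_matrix
        model.lambdas_ = p.rates.reshape(-1, 1)
        expected = model.score(obs.reshape(-1, 1))
        assert hmm.log_likelihood(obs, p) == pytest.approx(expected, abs=1e-7)
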