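"""HMM fitting and decoding against brute-force oracles and known truth."""

from itertools import product

import numpy as np
import pytest
from scipy.stats import norm

from fretbind.hmm import (
    HmmModel,
    InsufficientDataError,
    SIGMA_FLOOR,
    classify_bound,
    fit_hmm,
    loglikelihood,
    merge_short_events,
    viterbi,
)


def toy_model(mu=(0.0, 0.6), sd=(0.05, 0.05), pi=(0.5, 0.5),
              self_p=0.9) -> HmmModel:
    t = np.array([[self_p, 1 - self_p], [1 - self_p, self_p]])
    return HmmModel(np.asarray(pi, float), t, np.asarray(mu, float),
                    np.asarray(sd, float))


def brute_force_loglik(model: HmmModel, obs: np.ndarray) -> float:
    """Sum the joint probability over all state paths explicitly."""
    k = model.n_states
    total = 0.0
    for path in product(range(k), repeat=len(obs)):
        p = model.initial_probs[path[0]] * norm.pdf(
            obs[0], model.emission_mean[path[0]], model.emission_sd[path[0]])
        for prev, cur, o in zip(path, path[1:], obs[1:]):
            p *= model.transition_matrix[prev, cur] * norm.pdf(
                o, model.emission_mean[cur], model.emission_sd[cur])
        total += p
    return float(np.log(total))


def brute_force_viterbi(model: HmmModel, obs: np.ndarray):
    best_path, best_logp = None, -np.inf
    for path in product(range(model.n_states), repeat=len(obs)):
        logp = np.log(model.initial_probs[path[0]]) + norm.logpdf(
            obs[0], model.emission_mean[path[0]], model.emission_sd[path[0]])
        for prev, cur, o in zip(path, path[1:], obs[1:]):
            logp += np.log(model.transition_matrix[prev, cur]) + norm.logpdf(
                o, model.emission_mean[cur], model.emission_sd[cur])
        if logp > best_logp:
            best_logp, best_path = logp, path
    return np.array(best_path), best_logp


class TestForwardAlgorithm:
    @pytest.mark.parametrize("n", [1, 2, 5, 10])
    def test_matches_brute_force_summation(self, n, rng):
        model = toy_model(mu=(0.1, 0.7), sd=(0.08, 0.12), pi=(0.3, 0.7),
                          self_p=0.85)
        obs = rng.uniform(-0.1, 1.0, n)
        assert loglikelihood(model, obs) == pytest.approx(
            brute_force_loglik(model, obs), abs=1e-8)

    def test_extreme_observations_no_underflow(self):
        model = toy_model(sd=(SIGMA_FLOOR, SIGMA_FLOOR))
        ll = loglikelihood(model, np.array([50.0, -50.0, 0.0]))
        assert np.isfinite(ll)


class TestViterbi:
    def test_matches_exhaustive_enumeration(self, rng):
        model = toy_model(mu=(0.05, 0.65), sd=(0.1, 0.15), pi=(0.6, 0.4),
                          self_p=0.8)
        obs = rng.uniform(0, 0.8, 8)
        got = viterbi(model, obs)
        want_path, want_logp = brute_force_viterbi(model, obs)
        np.testing.assert_array_equal(got.states, want_path)
        assert got.log_likelihood == pytest.approx(want_logp, abs=1e-8)

    def test_single_frame_tie_goes_to_lower_state(self):
        # equal emissions and equal priors: the lower-mean state wins
        model = toy_model(mu=(0.4, 0.4001), sd=(0.1, 0.1), pi=(0.5, 0.5))
        path = viterbi(model, np.array([0.40005]))
        assert path.states[0] == 0

    def test_far_outlier_run_stays_in_closer_state(self, rng):
        model = toy_model(mu=(0.0, 0.6), sd=(0.05, 0.05), self_p=0.95)
        obs = np.full(5, 3.0)  # far above both means, closer to state 1
        got = viterbi(model, obs)
        want_path, _ = brute_force_viterbi(model, obs)
        np.testing.assert_array_equal(got.states, want_path)
        assert got.states.tolist() == [1] * 5

    def test_empty_observations_empty_path(self):
        assert len(viterbi(toy_model(), np.array([]))) == 0


class TestFitHmm:
    def test_recovers_mixture_means(self):
        rng = np.random.default_rng(101)
        obs = np.concatenate([rng.normal(0.0, 0.05, 1000),
                              rng.normal(0.6, 0.05, 1000)])
        rng.shuffle(obs)
        model, _ = fit_hmm(obs)
        np.testing.assert_allclose(model.emission_mean, [0.0, 0.6], atol=0.02)

    def test_loglik_monotone_nondecreasing(self):
        rng = np.random.default_rng(7)
        obs = np.concatenate([rng.normal(0.0, 0.08, 300),
                              rng.normal(0.5, 0.08, 300)])
        _, history = fit_hmm(obs)
        diffs = np.diff(history)
        assert np.all(diffs >= -1e-9 * np.maximum(1.0, np.abs(history[:-1])))

    def test_constant_observations_no_exception(self):
        model, _ = fit_hmm(np.full(100, 0.5))
        assert np.any(np.isclose(model.emission_mean, 0.5, atol=1e-3))
        assert np.all(model.emission_sd >= SIGMA_FLOOR)

    def test_insufficient_data_error(self):
        with pytest.raises(InsufficientDataError):
            fit_hmm(np.array([0.1, 0.2, 0.3]))

    def test_nonfinite_observations_rejected(self):
        with pytest.raises(ValueError):
            fit_hmm(np.array([0.1, np.nan] + [0.2] * 20))

    def test_emissions_invariant_to_time_reversal(self):
        rng = np.random.default_rng(23)
        obs = np.concatenate([rng.normal(0.0, 0.06, 400),
                              rng.normal(0.7, 0.06, 400),
                              rng.normal(0.0, 0.06, 400)])
        fwd, _ = fit_hmm(obs)
        rev, _ = fit_hmm(obs[::-1].copy())
        np.testing.assert_allclose(fwd.emission_mean, rev.emission_mean,
                                   atol=1e-3)
        np.testing.assert_allclose(fwd.emission_sd, rev.emission_sd, atol=1e-3)
        np.testing.assert_allclose(fwd.transition_matrix,
                                   rev.transition_matrix.T, atol=0.02)

    def test_pooled_fit_across_sequences(self):
        rng = np.random.default_rng(31)
        seqs = [np.concatenate([rng.normal(0.0, 0.05, 30),
                                rng.normal(0.6, 0.05, 30)])
                for _ in range(10)]
        model, _ = fit_hmm(seqs)
        np.testing.assert_allclose(model.emission_mean, [0.0, 0.6], atol=0.02)

    def test_states_sorted_by_mean(self):
        rng = np.random.default_rng(5)
        obs = np.concatenate([rng.normal(0.8, 0.05, 500),
                              rng.normal(0.1, 0.05, 500)])
        model, _ = fit_hmm(obs)
        assert model.emission_mean[0] < model.emission_mean[1]

    def test_matches_hmmlearn_emissions(self):
        """Independent cross-check against hmmlearn's GaussianHMM."""
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        rng = np.random.default_rng(77)
        # Markov data so transitions are meaningful
        states = [0]
        for _ in range(1499):
            states.append(rng.choice(2) if rng.random() < 0.1 else states[-1])
        states = np.array(states)
        obs = np.where(states == 0, rng.normal(0.0, 0.06, 1500),
                       rng.normal(0.6, 0.06, 1500))
        ours, _ = fit_hmm(obs)
        ref = hmmlearn.GaussianHMM(n_components=2, covariance_type="diag",
                                   n_iter=200, tol=1e-6, random_state=0)
        ref.fit(obs.reshape(-1, 1))
        ref_means = np.sort(ref.means_.ravel())
        np.testing.assert_allclose(ours.emission_mean, ref_means, atol=0.02)


class TestClassifyBound:
    def test_normal_case(self):
        cls = classify_bound(toy_model(mu=(0.02, 0.63)))
        assert cls.state_class == ("unbound", "bound")
        assert cls.flag == "normal"
        assert cls.bound_states == [1]

    def test_always_bound_when_both_means_high(self):
        cls = classify_bound(toy_model(mu=(0.57, 0.80)))
        assert cls.flag == "always_bound"
        assert cls.state_class == ("bound", "bound")

    def test_always_unbound_when_both_means_low(self):
        cls = classify_bound(toy_model(mu=(0.02, 0.05)))
        assert cls.flag == "always_unbound"


class TestMergeShortEvents:
    def test_single_frame_flicker_absorbed(self):
        s = np.array([0, 0, 0, 1, 0, 0, 0])
        np.testing.assert_array_equal(merge_short_events(s, 2), np.zeros(7))

    def test_long_events_untouched(self):
        s = np.array([0, 0, 1, 1, 0, 0])
        np.testing.assert_array_equal(merge_short_events(s, 2), s)

    def test_min_frames_one_is_identity(self):
        s = np.array([0, 1, 0, 1])
        np.testing.assert_array_equal(merge_short_events(s, 1), s)


def test_pure_python_kernels_match_jitted(rng):
    """The numba-compiled forward-backward/Viterbi kernels agree exactly
    with their plain-Python definitions (the fallback when numba is
    absent)."""
    from fretbind.hmm import (
        _forward_backward,
        _forward_backward_impl,
        _log_emissions,
        _viterbi_impl,
        _viterbi_kernel,
    )

    model = toy_model(mu=(0.1, 0.7), sd=(0.06, 0.1), self_p=0.9)
    obs = rng.uniform(0, 1, 40)
    logb = _log_emissions(obs, model.emission_mean, model.emission_sd)
    g1, x1, ll1 = _forward_backward(logb, model.initial_probs,
                                    model.transition_matrix)
    g2, x2, ll2 = _forward_backward_impl(logb, model.initial_probs,
                                         model.transition_matrix)
    np.testing.assert_allclose(g1, g2, rtol=1e-12)
    np.testing.assert_allclose(x1, x2, rtol=1e-12)
    assert ll1 == pytest.approx(ll2, abs=1e-10)
    logpi = np.log(model.initial_probs)
    logt = np.log(model.transition_matrix)
    s1, p1 = _viterbi_kernel(logb, logpi, logt)
    s2, p2 = _viterbi_impl(logb, logpi, logt)
    np.testing.assert_array_equal(s1, s2)
    assert p1 == pytest.approx(p2, abs=1e-10)


def test_frame_accuracy_above_95_when_well_separated():
    """Viterbi frame-level accuracy >= 95% at >= 4 sigma state separation."""
    rng = np.random.default_rng(55)
    true = [0]
    for _ in range(2999):
        true.append(1 - true[-1] if rng.random() < 0.05 else true[-1])
    true = np.array(true)
    obs = np.where(true == 0, rng.normal(0.0, 0.1, 3000),
                   rng.normal(0.6, 0.1, 3000))  # separation 6 sigma
    model, _ = fit_hmm(obs)
    path = viterbi(model, obs)
    assert (path.states == true).mean() >= 0.95
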