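"""HMM tests: brute-force likelihood oracle, EM behaviour, model
selection, and Viterbi decoding."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.special import logsumexp

from clampfret import hmm


def brute_force_loglik(obs, pi, a, means, sigmas):
    """Exhaustive sum over all K^T hidden paths (independent oracle)."""
    k = len(pi)
    t_len = len(obs)
    log_terms = []
    for path in itertools.product(range(k), repeat=t_len):
        lp = np.log(pi[path[0]])
        lp += stats.norm.logpdf(obs[0], means[path[0]], sigmas[path[0]])
        for t in range(1, t_len):
            lp += np.log(a[path[t - 1], path[t]])
            lp += stats.norm.logpdf(obs[t], means[path[t]], sigmas[path[t]])
        log_terms.append(lp)
    return float(logsumexp(log_terms))


def _random_instance(rng, k, t_len):
    pi = rng.dirichlet(np.ones(k))
    a = rng.dirichlet(np.ones(k), size=k)
    means = np.sort(rng.uniform(0, 1, k))
    sigmas = rng.uniform(0.02, 0.3, k)
    obs = rng.uniform(-0.2, 1.2, t_len)
    return obs, pi, a, means, sigmas


class TestForwardAlgorithm:
    def test_matches_brute_force_enumeration(self):
        """100 random instances, K <= 3, T <= 8, agreement to 1e-12."""
        rng = np.random.default_rng(123)
        worst = 0.0
        for _ in range(100):
            k = int(rng.integers(1, 4))
            t_len = int(rng.integers(1, 9))
            obs, pi, a, means, sigmas = _random_instance(rng, k, t_len)
            got = hmm.forward_loglik(obs, pi, a, means, sigmas)
            want = brute_force_loglik(obs, pi, a, means, sigmas)
            worst = max(worst, abs(got - want))
        assert worst < 1e-12

    def test_single_state_reduces_to_iid_gaussian(self):
        rng = np.random.default_rng(0)
        obs = rng.normal(0.3, 0.05, 50)
        got = hmm.forward_loglik(obs, [1.0], [[1.0]], [0.3], [0.05])
        want = stats.norm.logpdf(obs, 0.3, 0.05).sum()
        assert got == pytest.approx(want, abs=1e-10)

    def test_identical_emissions_make_likelihood_transition_free(self):
        rng = np.random.default_rng(1)
        obs = rng.normal(0.3, 0.05, 30)
        pi = [0.5, 0.5]
        means = [0.3, 0.3]
        sigmas = [0.05, 0.05]
        lls = [
            hmm.forward_loglik(obs, pi, a, means, sigmas)
            for a in ([[0.9, 0.1], [0.1, 0.9]], [[0.5, 0.5], [0.5, 0.5]],
                      [[0.99, 0.01], [0.7, 0.3]])
        ]
        assert np.ptp(lls) < 1e-9


@given(data=st.data())
@settings(max_examples=25)
def test_forward_oracle_property(data):
    """Property form of the enumeration identity on tiny instances."""
    rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
    k = data.draw(st.integers(1, 3))
    t_len = data.draw(st.integers(1, 6))
    obs, pi, a, means, sigmas = _random_instance(rng, k, t_len)
    got = hmm.forward_loglik(obs, pi, a, means, sigmas)
    want = brute_force_loglik(obs, pi, a, means, sigmas)
    assert got == pytest.approx(want, abs=1e-11)


def _two_state_data(rng, n_traces=100, t_len=500, p=0.02, means=(0.2, 0.4), sigma=0.03):
    seqs, paths = [], []
    for _ in range(n_traces):
        path = np.empty(t_len, dtype=int)
        path[0] = rng.integers(0, 2)
        flips = rng.random(t_len - 1) < p
        path[1:] = np.where(flips, 1, 0)
        for t in range(1, t_len):
            path[t] = 1 - path[t - 1] if flips[t - 1] else path[t - 1]
        obs = np.asarray(means)[path] + rng.normal(0, sigma, t_len)
        seqs.append(obs)
        paths.append(path)
    return seqs, paths


class TestFitHmm:
    def test_two_state_parameter_recovery(self):
        rng = np.random.default_rng(7)
        seqs, _ = _two_state_data(rng)
        fit = hmm.fit_hmm(seqs, 2, hmm.HmmConfig(seed=0))
        assert np.allclose(fit.means, [0.2, 0.4], atol=0.01)
        p_rec = fit.transition_matrix[0, 1], fit.transition_matrix[1, 0]
        for p in p_rec:
            assert abs(p - 0.02) / 0.02 < 0.20
        assert np.allclose(fit.transition_matrix.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(np.diff(fit.means) > 0)

    def test_fitted_likelihood_dominates_truth(self):
        rng = np.random.default_rng(8)
        seqs, _ = _two_state_data(rng, n_traces=30, t_len=200)
        fit = hmm.fit_hmm(seqs, 2, hmm.HmmConfig(seed=0))
        truth_ll = hmm.total_loglik(
            seqs, [0.5, 0.5], [[0.98, 0.02], [0.02, 0.98]], [0.2, 0.4], [0.03, 0.03]
        )
        assert fit.log_likelihood >= truth_ll

    def test_em_loglik_monotone(self):
        rng = np.random.default_rng(9)
        seqs, _ = _two_state_data(rng, n_traces=10, t_len=200)
        fit = hmm.fit_hmm(seqs, 2, hmm.HmmConfig(seed=0, n_restarts=1, tol=1e-6))
        assert np.all(np.diff(fit.loglik_history) > -1e-6)

    def test_single_state_fit(self):
        rng = np.random.default_rng(10)
        obs = rng.normal(0.3, 0.02, 500)
        fit = hmm.fit_hmm([obs], 1, hmm.HmmConfig(seed=0))
        assert fit.means[0] == pytest.approx(obs.mean(), abs=1e-6)
        assert fit.sigmas[0] == pytest.approx(obs.std(), rel=0.01)

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            hmm.fit_hmm([], 2, hmm.HmmConfig())
        with pytest.raises(ValueError):
            hmm.fit_hmm([np.empty(0)], 2, hmm.HmmConfig())

    def test_sigma_floor_prevents_collapse(self):
        fit = hmm.fit_hmm([np.full(100, 0.3)], 1, hmm.HmmConfig(seed=0))
        assert fit.sigmas[0] >= 1e-4

    def test_agrees_with_independent_hmm_library(self):
        """Cross-check against hmmlearn's Gaussian HMM on the same data."""
        hmmlearn_hmm = pytest.importorskip("hmmlearn.hmm")
        rng = np.random.default_rng(11)
        seqs, _ = _two_state_data(rng, n_traces=20, t_len=300)
        fit = hmm.fit_hmm(seqs, 2, hmm.HmmConfig(seed=0))
        x = np.concatenate(seqs)[:, None]
        lengths = [len(s) for s in seqs]
        ref = hmmlearn_hmm.GaussianHMM(
            n_components=2, covariance_type="diag", n_iter=200, tol=1e-4,
            random_state=0, min_covar=1e-8,
        )
        ref.fit(x, lengths)
        ref_means = np.sort(ref.means_.ravel())
        assert np.allclose(fit.means, ref_means, atol=0.005)
        assert fit.log_likelihood == pytest.approx(ref.score(x, lengths), abs=5.0)


class TestModelSelection:
    def test_three_state_data_selects_three(self):
        rng = np.random.default_rng(12)
        means = np.array([0.2, 0.3, 0.41])
        seqs = []
        for _ in range(60):
            path = rng.integers(0, 3, 1)
            out = [path[0]]
            for _ in range(299):
                s = out[-1]
                if rng.random() < 0.08:
                    s = rng.choice([x for x in range(3) if x != s])
                out.append(s)
            out = np.asarray(out)
            seqs.append(means[out] + rng.normal(0, 0.04, 300))
        fits = [hmm.fit_hmm(seqs, k, hmm.HmmConfig(seed=0)) for k in (2, 3, 4)]
        best, table = hmm.select_model(fits)
        assert best.k == 3
        assert list(table["K"]) == [2, 3, 4]

    def test_single_state_data_prefers_smallest_k(self):
        rng = np.random.default_rng(13)
        seqs = [rng.normal(0.3, 0.05, 400) for _ in range(10)]
        fits = [hmm.fit_hmm(seqs, k, hmm.HmmConfig(seed=0)) for k in (2, 3)]
        best, _ = hmm.select_model(fits)
        assert best.k == 2

    def test_aic_tie_goes_to_smaller_k(self):
        def fake(k, ll):
            return hmm.HmmFit(
                k=k, means=np.linspace(0.2, 0.4, k), sigmas=np.full(k, 0.05),
                pi=np.full(k, 1 / k), transition_matrix=np.eye(k),
                log_likelihood=ll, n_obs=100,
            )

        # equal AIC by construction: ll compensates the parameter count
        f2 = fake(2, hmm.aic_n_params(2))
        f3 = fake(3, hmm.aic_n_params(3))
        assert f2.aic == f3.aic == 0.0
        best, _ = hmm.select_model([f3, f2])
        assert best.k == 2

    def test_needs_at_least_two_fits(self):
        with pytest.raises(ValueError):
            hmm.select_model([hmm.HmmFit(
                k=2, means=np.array([0.2, 0.4]), sigmas=np.full(2, 0.05),
                pi=np.full(2, 0.5), transition_matrix=np.eye(2),
                log_likelihood=0.0, n_obs=10,
            )])


class TestDecoding:
    def test_noiseless_alternation_decoded_exactly(self):
        path_true = np.tile([0, 1], 25)
        obs = np.where(path_true == 0, 0.2, 0.4)
        fit = hmm.HmmFit(
            k=2, means=np.array([0.2, 0.4]), sigmas=np.array([0.02, 0.02]),
            pi=np.array([0.5, 0.5]),
            transition_matrix=np.array([[0.5, 0.5], [0.5, 0.5]]),
            log_likelihood=0.0, n_obs=50,
        )
        assert np.array_equal(hmm.decode_path(obs, fit), path_true)

    def test_decoding_accuracy_on_noisy_traces(self):
        rng = np.random.default_rng(14)
        seqs, paths = _two_state_data(rng, n_traces=20, t_len=300, sigma=0.03)
        fit = hmm.fit_hmm(seqs, 2, hmm.HmmConfig(seed=0))
        correct = total = 0
        for obs, true_path in zip(seqs, paths):
            dec = hmm.decode_path(obs, fit)
            correct += (dec == true_path).sum()
            total += len(dec)
        assert correct / total >= 0.95

    def test_posterior_marginals_normalized_and_confident(self):
        rng = np.random.default_rng(15)
        seqs, paths = _two_state_data(rng, n_traces=3, t_len=200, sigma=0.02)
        fit = hmm.fit_hmm(seqs, 2, hmm.HmmConfig(seed=0))
        post = hmm.state_posteriors(seqs[0], fit)
        assert post.shape == (200, 2)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)
        # with 10-sigma state separation the posterior matches the truth
        assert (post.argmax(axis=1) == paths[0]).mean() > 0.99

    def test_single_frame_outlier_absorbed(self):
        """With sticky transitions, a lone outlier between long dwells is
        smoothed over (unlike pointwise argmax)."""
        obs = np.full(41, 0.2)
        obs[20] = 0.33  # pointwise closer to the 0.4 state
        fit = hmm.HmmFit(
            k=2, means=np.array([0.2, 0.4]), sigmas=np.array([0.05, 0.05]),
            pi=np.array([0.5, 0.5]),
            transition_matrix=np.array([[0.99, 0.01], [0.01, 0.99]]),
            log_likelihood=0.0, n_obs=41,
        )
        dec = hmm.decode_path(obs, fit)
        assert (dec == 0).all()
        pointwise = np.argmin(
            np.abs(obs[:, None] - fit.means[None, :]), axis=1
        )
        assert pointwise[20] == 1  # argmax would have flickered
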