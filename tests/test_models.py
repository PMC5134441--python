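"""GMM fitting/classification, transitions, forward decoding and voting."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from conftest import brute_force_filtered_posteriors
from semgrasp.errors import InvalidConfigError, InvalidInputError
from semgrasp.features import EpochFeatures, FeatureConfig
from semgrasp.labeling import STATES, LabelSequence
from semgrasp.models import (
    GMMModel,
    HMMModel,
    TransitionMatrix,
    apply_voting,
    fit_gmm,
    fit_transitions,
    forward_filter,
    gmm_classify,
    gmm_classify_sequence,
    gmm_logpdf,
    hmm_classify,
    load_model,
    save_model,
)
from semgrasp.preprocess import EpochSpec


def _seq(labels):
    return LabelSequence(labels=np.array(labels, object), start_times=np.arange(len(labels), dtype=float))


def _obs(X, ngram="unigram"):
    X = np.atleast_2d(X)
    return EpochFeatures(
        X=X, feature_names=[f"f{i}" for i in range(X.shape[1])],
        start_times=np.arange(len(X), dtype=float), ngram=ngram,
    )


class TestGmmLogpdf:
    def test_standard_normal_peak(self):
        m = GMMModel(weights=[1.0], means=[[0.0]], covariances=[[[1.0]]])
        assert gmm_logpdf(m, [0.0]) == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-12)

    def test_symmetric_two_component_mixture(self):
        m = GMMModel(weights=[0.5, 0.5], means=[[-1.0], [1.0]], covariances=[[[1.0]], [[1.0]]])
        # at 0 both components contribute N(0,1) evaluated at 1
        expected = np.log(multivariate_normal(mean=1.0, cov=1.0).pdf(0.0))
        assert gmm_logpdf(m, [0.0]) == pytest.approx(expected, abs=1e-12)

    def test_matches_linear_domain_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            K, D = 3, 2
            w = rng.dirichlet(np.ones(K))
            means = rng.standard_normal((K, D))
            covs = np.array([np.diag(rng.uniform(0.5, 2.0, D)) for _ in range(K)])
            m = GMMModel(weights=w, means=means, covariances=covs)
            x = rng.standard_normal(D)
            naive = sum(
                w[k] * multivariate_normal(mean=means[k], cov=covs[k]).pdf(x) for k in range(K)
            )
            assert gmm_logpdf(m, x) == pytest.approx(np.log(naive), rel=1e-10)

    def test_dimension_mismatch(self):
        m = GMMModel(weights=[1.0], means=[[0.0, 0.0]], covariances=[np.eye(2)])
        with pytest.raises(InvalidInputError):
            gmm_logpdf(m, [0.0])


class TestFitGmm:
    def test_single_component_closed_form(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((200, 3)) * [1.0, 2.0, 0.5] + [1.0, -2.0, 0.0]
        m = fit_gmm(X, K=1, reg=0.05, seed=0)
        np.testing.assert_allclose(m.means[0], X.mean(axis=0), atol=1e-12)
        expected_cov = np.cov(X.T, bias=True) + 0.05 * np.eye(3)
        np.testing.assert_allclose(m.covariances[0], expected_cov, atol=1e-12)

    def test_log_likelihood_monotone(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.standard_normal((100, 2)), rng.standard_normal((100, 2)) + 4.0])
        m = fit_gmm(X, K=3, reg=0.01, seed=1)
        path = np.array(m.log_likelihood_path)
        assert np.all(np.diff(path) >= -1e-9)

    def test_two_cluster_mean_recovery(self):
        rng = np.random.default_rng(2)
        mu = np.array([[0.0, 0.0], [5.0, 5.0]])
        n = 400
        X = np.vstack([rng.standard_normal((n, 2)) + mu[0], rng.standard_normal((n, 2)) + mu[1]])
        m = fit_gmm(X, K=2, reg=1e-6, seed=2)
        order = np.argsort(m.means[:, 0])
        se = 1.0 / np.sqrt(n)  # per-coordinate standard error of a cluster mean
        assert np.all(np.abs(m.means[order] - mu) < 3 * se)

    def test_agrees_with_reference_em(self):
        # scikit-learn's EM with the same diagonal regularization is the oracle
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(3)
        X = np.vstack([rng.standard_normal((300, 2)), rng.standard_normal((300, 2)) + 6.0])
        ours = fit_gmm(X, K=2, reg=0.05, seed=3)
        ref = GaussianMixture(2, reg_covar=0.05, random_state=3, n_init=3).fit(X)
        ours_sorted = ours.means[np.argsort(ours.means[:, 0])]
        ref_sorted = ref.means_[np.argsort(ref.means_[:, 0])]
        np.testing.assert_allclose(ours_sorted, ref_sorted, atol=0.05)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((120, 3))
        a = fit_gmm(X, K=4, seed=7)
        b = fit_gmm(X, K=4, seed=7)
        np.testing.assert_array_equal(a.means, b.means)
        np.testing.assert_array_equal(a.covariances, b.covariances)

    def test_degenerate_identical_points(self):
        X = np.ones((30, 2))
        m = fit_gmm(X, K=2, reg=0.05, seed=0)
        np.testing.assert_allclose(m.means, 1.0)
        for cov in m.covariances:
            np.testing.assert_allclose(cov, 0.05 * np.eye(2), atol=1e-12)

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(InvalidConfigError):
            fit_gmm(np.ones((2, 1)), K=5)


def _three_class_models(rng, D=2, spread=4.0):
    models = {}
    for i, s in enumerate(STATES):
        mean = np.zeros(D)
        mean[0] = i * spread
        models[s] = GMMModel(weights=[1.0], means=[mean], covariances=[np.eye(D)])
    return models


class TestClassify:
    def test_class_mean_wins(self):
        models = _three_class_models(np.random.default_rng(0))
        assert gmm_classify(models, [4.0, 0.0]) == "grasp"

    def test_tie_breaks_in_state_order(self):
        m = GMMModel(weights=[1.0], means=[[0.0]], covariances=[[[1.0]]])
        models = {"steady": m, "grasp": m, "release": m}
        assert gmm_classify(models, [2.0]) == "steady"

    def test_matches_brute_force_density_comparison(self):
        rng = np.random.default_rng(5)
        models = {
            s: GMMModel(
                weights=rng.dirichlet(np.ones(2)),
                means=rng.standard_normal((2, 3)),
                covariances=np.array([np.eye(3)] * 2) * rng.uniform(0.5, 2),
            )
            for s in STATES
        }
        for _ in range(30):
            x = rng.standard_normal(3)
            best = max(STATES, key=lambda s: gmm_logpdf(models[s], x))
            assert gmm_classify(models, x) == best


class TestTransitions:
    def test_hand_counted_sequence(self):
        tm = fit_transitions([_seq(["steady", "steady", "grasp", "grasp", "release", "steady"])])
        np.testing.assert_allclose(tm.T[0], [0.4, 0.4, 0.2])  # from steady: 1 SS, 1 SG
        np.testing.assert_allclose(tm.T[1], [0.2, 0.4, 0.4])  # from grasp: 1 GG, 1 GR
        np.testing.assert_allclose(tm.T[2], [0.5, 0.25, 0.25])  # from release: 1 RS

    def test_small_alpha_approaches_empirical(self):
        labels = ["steady"] * 500 + ["grasp"] * 500
        tm = fit_transitions([_seq(labels)], alpha=1e-9)
        assert tm.T[0, 0] == pytest.approx(499 / 500, abs=1e-6)

    def test_rows_stochastic_and_positive(self):
        tm = fit_transitions([_seq(["steady", "grasp"])])
        assert np.all(tm.T > 0)
        np.testing.assert_allclose(tm.T.sum(axis=1), 1.0, atol=1e-12)

    def test_no_transition_across_sequences(self):
        tm = fit_transitions([_seq(["steady", "grasp"]), _seq(["grasp", "release"])], alpha=1e-9)
        # no grasp->grasp pair exists even though grasp ends one sequence and starts the next
        assert tm.T[1, 1] < 1e-6


def _random_hmm(rng, D=1):
    T = rng.dirichlet(np.ones(3), size=3)
    pi = rng.dirichlet(np.ones(3))
    emissions = {
        s: GMMModel(weights=[1.0], means=[rng.standard_normal(D)], covariances=[np.eye(D)])
        for s in STATES
    }
    hmm = HMMModel(pi=pi, transitions=TransitionMatrix(T=T, alpha=1.0), emissions=emissions)
    return hmm


class TestForward:
    def test_uniform_symmetric_model_gives_uniform_posterior(self):
        m = GMMModel(weights=[1.0], means=[[0.0]], covariances=[[[1.0]]])
        hmm = HMMModel(
            pi=np.full(3, 1 / 3),
            transitions=TransitionMatrix(T=np.full((3, 3), 1 / 3)),
            emissions={s: m for s in STATES},
        )
        post = forward_filter(hmm, _obs(np.random.default_rng(0).standard_normal((5, 1))))
        np.testing.assert_allclose(post, 1 / 3, atol=1e-12)

    def test_concentrates_on_emitting_state(self):
        rng = np.random.default_rng(1)
        hmm = _random_hmm(rng)
        for s in STATES:
            hmm.emissions[s].means[0][:] = {"steady": -20, "grasp": 0, "release": 20}[s]
        T = np.full((3, 3), 0.05)
        np.fill_diagonal(T, 0.9)
        hmm.transitions = TransitionMatrix(T=T)
        obs = _obs(np.array([[0.0]] * 6))
        post = forward_filter(hmm, obs)
        assert np.all(post[:, 1] > 0.95)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(2)
        from semgrasp.models import gmm_log_likelihoods

        for _ in range(10):
            hmm = _random_hmm(rng)
            n = int(rng.integers(2, 9))
            X = rng.standard_normal((n, 1))
            post = forward_filter(hmm, _obs(X))
            logB = np.stack([gmm_log_likelihoods(hmm.emissions[s], X) for s in STATES], axis=1)
            oracle = brute_force_filtered_posteriors(hmm.pi, hmm.transitions.T, logB)
            assert np.max(np.abs(post - oracle)) < 1e-10

    def test_posteriors_normalized(self):
        rng = np.random.default_rng(3)
        post = forward_filter(_random_hmm(rng), _obs(rng.standard_normal((12, 1))))
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-12)

    def test_causality_future_epochs_do_not_change_past(self):
        rng = np.random.default_rng(4)
        hmm = _random_hmm(rng)
        X = rng.standard_normal((10, 1))
        full = hmm_classify(hmm, _obs(X))
        for k in range(2, 10):
            prefix = hmm_classify(hmm, _obs(X[:k]))
            assert list(prefix.labels) == list(full.labels[:k])

    def test_uniform_prior_and_transitions_reduce_to_gmm(self):
        rng = np.random.default_rng(5)
        emissions = {
            s: GMMModel(weights=[1.0], means=[rng.standard_normal(2)], covariances=[np.eye(2)])
            for s in STATES
        }
        hmm = HMMModel(
            pi=np.full(3, 1 / 3),
            transitions=TransitionMatrix(T=np.full((3, 3), 1 / 3)),
            emissions=emissions,
        )
        obs = _obs(rng.standard_normal((40, 2)))
        assert list(hmm_classify(hmm, obs).labels) == list(
            gmm_classify_sequence(emissions, obs).labels
        )

    def test_ngram_mismatch_rejected(self):
        rng = np.random.default_rng(6)
        hmm = _random_hmm(rng)
        with pytest.raises(InvalidInputError):
            forward_filter(hmm, _obs(rng.standard_normal((3, 1)), ngram="bigram"))


class TestVoting:
    def test_n_zero_is_identity(self):
        raw = _seq(["steady", "grasp", "release", "grasp"])
        out = apply_voting(raw, 0)
        assert list(out.labels) == list(raw.labels)

    def test_hand_traced_n2(self):
        raw = _seq(["steady", "steady", "grasp", "steady", "grasp", "grasp", "grasp"])
        out = apply_voting(raw, 2)
        assert list(out.labels) == ["steady"] * 6 + ["grasp"]

    def test_constant_sequence_unchanged(self):
        raw = _seq(["release"] * 7)
        assert list(apply_voting(raw, 3).labels) == ["release"] * 7

    def test_never_introduces_absent_label(self):
        rng = np.random.default_rng(7)
        raw = _seq(list(rng.choice(STATES, size=60)))
        out = apply_voting(raw, 2)
        for e in range(2, 60):
            window = set(raw.labels[max(0, e - 2) : e + 1]) | {out.labels[e - 1]}
            assert out.labels[e] in window

    def test_at_most_one_switch_per_window(self):
        rng = np.random.default_rng(8)
        raw = _seq(list(rng.choice(STATES, size=200)))
        n = 3
        out = apply_voting(raw, n)
        changes = [e for e in range(n, 200) if out.labels[e] != out.labels[e - 1]]
        assert all(b - a > n for a, b in zip(changes, changes[1:]))


class TestSerialization:
    def test_round_trip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((60, 4))
        emissions = {s: fit_gmm(X + i, K=2, seed=i, label=s) for i, s in enumerate(STATES)}
        tm = fit_transitions([_seq(["steady", "grasp", "release", "steady"])])
        hmm = HMMModel.uniform_pi(tm, emissions, "unigram")
        path = tmp_path / "model.json"
        save_model(path, hmm, ["IAV", "WFL"], FeatureConfig(), EpochSpec())
        back, kept, fcfg, spec = load_model(path)
        assert kept == ["IAV", "WFL"]
        assert fcfg == FeatureConfig()
        assert spec == EpochSpec()
        np.testing.assert_array_equal(back.transitions.T, hmm.transitions.T)
        for s in STATES:
            np.testing.assert_array_equal(back.emissions[s].means, hmm.emissions[s].means)
            np.testing.assert_array_equal(back.emissions[s].covariances, hmm.emissions[s].covariances)
            np.testing.assert_array_equal(back.emissions[s].weights, hmm.emissions[s].weights)
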