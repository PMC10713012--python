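"""HMM core: exact-inference oracles, EM behaviour, state matching."""

import itertools

import numpy as np
import pytest
from scipy.stats import multivariate_normal

import statedyn as sd
from statedyn import hmm
from statedyn.containers import ParcellatedTimeSeries


# ---------------------------------------------------------------------------
# brute-force oracle: exhaustive enumeration over all K^T paths


def brute_force(model: hmm.HMMModel, X: np.ndarray):
    """Marginal log-likelihood, posteriors, and the best joint path by
    explicit enumeration (tractable for T <= 8, K <= 3)."""
    T, K = X.shape[0], model.n_states
    logB = np.array(
        [
            [
                multivariate_normal.logpdf(
                    x, model.means[k], model.covariances[k]
                )
                for k in range(K)
            ]
            for x in X
        ]
    )
    with np.errstate(divide="ignore"):
        logA = np.log(model.transition_matrix)
        logpi = np.log(model.initial_probs)
    total = -np.inf
    post = np.full((T, K), -np.inf)
    best_path, best_lp = None, -np.inf
    for path in itertools.product(range(K), repeat=T):
        lp = logpi[path[0]] + logB[0, path[0]]
        for t in range(1, T):
            lp += logA[path[t - 1], path[t]] + logB[t, path[t]]
        total = np.logaddexp(total, lp)
        for t in range(T):
            post[t, path[t]] = np.logaddexp(post[t, path[t]], lp)
        if lp > best_lp:
            best_lp, best_path = lp, path
    return total, np.exp(post - total), np.array(best_path)


def random_model(K: int, R: int, seed: int) -> hmm.HMMModel:
    rng = np.random.default_rng(seed)
    covs = np.stack(
        [np.eye(R) * s for s in rng.uniform(0.3, 2.0, size=K)]
    )
    return hmm.HMMModel(
        n_states=K,
        means=rng.normal(size=(K, R)),
        covariances=covs,
        transition_matrix=rng.dirichlet(np.ones(K), size=K),
        initial_probs=rng.dirichlet(np.ones(K)),
    )


@pytest.mark.parametrize(
    "K,T,seed", [(2, 4, 0), (2, 6, 1), (2, 8, 2), (3, 4, 3), (3, 6, 4),
                 (3, 8, 5)]
)
def test_inference_matches_exhaustive_enumeration(K, T, seed):
    """Forward-backward log-likelihood, posteriors, and Viterbi agree with
    the enumeration oracle to 1e-10."""
    model = random_model(K, R=2, seed=seed)
    X = np.random.default_rng(100 + seed).normal(size=(T, 2))
    ll_bf, post_bf, vit_bf = brute_force(model, X)
    path = hmm.forward_backward(model, X)
    assert path.log_likelihood == pytest.approx(ll_bf, abs=1e-10)
    np.testing.assert_allclose(path.posteriors, post_bf, atol=1e-10)
    np.testing.assert_allclose(
        path.posteriors.sum(axis=1), 1.0, atol=1e-8
    )
    vit = hmm.decode(model, X, method="viterbi")
    np.testing.assert_array_equal(vit.states, vit_bf)


def test_single_state_closed_form(rng):
    """K = 1: posteriors are all 1 and the log-likelihood is the plain sum
    of Gaussian log-densities."""
    model = random_model(1, R=3, seed=0)
    X = rng.normal(size=(50, 3))
    path = hmm.forward_backward(model, X)
    expected = multivariate_normal.logpdf(
        X, model.means[0], model.covariances[0]
    ).sum()
    assert path.log_likelihood == pytest.approx(expected, rel=1e-12)
    np.testing.assert_allclose(path.posteriors, 1.0)


def test_viterbi_beats_argmax_on_joint_probability(rng):
    model = random_model(3, R=2, seed=9)
    X = rng.normal(size=(40, 2))
    amax = hmm.decode(model, X, method="posterior_argmax")
    vit = hmm.decode(model, X, method="viterbi")
    assert hmm.path_log_probability(model, X, vit.states) >= \
        hmm.path_log_probability(model, X, amax.states) - 1e-12


def test_posterior_tie_breaks_to_lowest_index():
    # two identical states: posteriors are exactly 0.5/0.5 everywhere
    model = hmm.HMMModel(
        n_states=2, means=np.zeros((2, 2)),
        covariances=np.stack([np.eye(2)] * 2),
        transition_matrix=np.full((2, 2), 0.5),
        initial_probs=np.array([0.5, 0.5]),
    )
    X = np.random.default_rng(0).normal(size=(10, 2))
    path = hmm.decode(model, X)
    np.testing.assert_allclose(path.posteriors, 0.5)
    assert np.all(path.states == 0)


# ---------------------------------------------------------------------------
# normalisation / concatenation


class TestNormalize:
    def test_zscores_rows(self):
        ts = ParcellatedTimeSeries("s", "g", [[1.0, 2.0, 3.0]], 0.5)
        out = sd.normalize_timeseries(ts)
        assert out.data.mean() == pytest.approx(0.0, abs=1e-12)
        assert out.data.std() == pytest.approx(1.0, abs=1e-12)

    def test_constant_row_zeroed_and_flagged(self):
        ts = ParcellatedTimeSeries(
            "s", "g", [[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]], 0.5
        )
        out = sd.normalize_timeseries(ts)
        np.testing.assert_array_equal(out.data[0], 0.0)
        assert out.constant_rois == [0]

    def test_idempotent(self, rng):
        ts = ParcellatedTimeSeries("s", "g", rng.normal(size=(4, 30)), 0.5)
        once = sd.normalize_timeseries(ts)
        twice = sd.normalize_timeseries(once)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-12)


class TestConcatenate:
    def test_boundaries(self, rng):
        ts = [
            ParcellatedTimeSeries(f"s{i}", "g", rng.normal(size=(3, 100)),
                                  0.5)
            for i in range(2)
        ]
        X, b = sd.concatenate_subjects(ts)
        assert X.shape == (200, 3)
        np.testing.assert_array_equal(b, [0, 100, 200])

    def test_single_subject_identity(self, rng):
        ts = ParcellatedTimeSeries("s", "g", rng.normal(size=(3, 50)), 0.5)
        X, b = sd.concatenate_subjects([ts])
        np.testing.assert_array_equal(X, ts.data.T)
        np.testing.assert_array_equal(b, [0, 50])

    def test_roi_mismatch_names_subject(self, rng):
        ts = [
            ParcellatedTimeSeries("ok", "g", rng.normal(size=(3, 10)), 0.5),
            ParcellatedTimeSeries("bad", "g", rng.normal(size=(4, 10)), 0.5),
        ]
        with pytest.raises(ValueError, match="bad"):
            sd.concatenate_subjects(ts)

    def test_no_transitions_counted_across_boundary(self):
        """Two one-state-each subjects: the fitted transition matrix must
        contain no cross-subject step."""
        rng = np.random.default_rng(0)
        a = rng.normal(loc=-4, size=(300, 2))
        b = rng.normal(loc=+4, size=(300, 2))
        X = np.concatenate([a, b])
        model = hmm.fit_hmm(X, [0, 300, 600], 2, n_restarts=1, max_iter=50,
                            seed=0)
        # each segment sits in one state throughout; with the boundary
        # respected there is no evidence of any cross-state transition
        off_diag = model.transition_matrix[
            ~np.eye(2, dtype=bool)
        ]
        assert np.all(off_diag < 1e-3)
        # and both states start a segment
        np.testing.assert_allclose(model.initial_probs, 0.5, atol=1e-6)


# ---------------------------------------------------------------------------
# EM fitting


class TestFit:
    def test_k1_closed_form(self, rng):
        X = rng.normal(size=(500, 3))
        model = hmm.fit_hmm(X, None, 1, n_restarts=1, seed=0)
        np.testing.assert_allclose(model.means[0], X.mean(axis=0),
                                   atol=1e-12)
        np.testing.assert_allclose(
            model.covariances[0], np.cov(X.T, bias=True), atol=1e-4
        )
        assert model.converged

    def test_em_trace_monotone_nondecreasing(self, small_design, small_gt):
        ts, _, _ = sd.simulate_subject(
            small_gt, small_design, "younger", "s", 4
        )
        model = hmm.fit_hmm(ts.data.T, None, 3, n_restarts=1, max_iter=40,
                            seed=1)
        trace = np.array(model.loglik_trace)
        assert np.all(np.diff(trace) > -1e-8 * np.abs(trace[:-1]))

    def test_transition_rows_stochastic_after_fit(self, small_design,
                                                  small_gt):
        ts, _, _ = sd.simulate_subject(
            small_gt, small_design, "older", "s", 5
        )
        model = hmm.fit_hmm(ts.data.T, None, 4, n_restarts=1, max_iter=30,
                            seed=0)
        np.testing.assert_allclose(
            model.transition_matrix.sum(axis=1), 1.0, atol=1e-10
        )
        assert model.initial_probs.sum() == pytest.approx(1.0, abs=1e-10)

    def test_loglik_invariant_to_subject_order(self, small_design,
                                               small_gt):
        subs = [
            sd.simulate_subject(small_gt, small_design, "younger", f"s{i}",
                                i)[0]
            for i in range(3)
        ]
        model = hmm.fit_hmm(
            *sd.concatenate_subjects(subs), 4, n_restarts=1, max_iter=10,
            seed=0,
        )

        def total_ll(order):
            X, b = sd.concatenate_subjects([subs[i] for i in order])
            ll = 0.0
            for i in order:
                ll += hmm.forward_backward(model, subs[i]).log_likelihood
            return ll

        assert total_ll([0, 1, 2]) == pytest.approx(
            total_ll([2, 0, 1]), abs=1e-8
        )

    def test_recovery_degrades_with_noise(self, small_design):
        """Decoding accuracy is non-increasing along a noise ladder."""
        accs = []
        for noise in (0.5, 2.0, 8.0):
            acc = []
            for seed in range(10):
                gt = sd.sample_ground_truth(
                    small_design, n_rois=6, noise_scale=noise, seed=seed,
                    calibrate=False,
                )
                ts, path, _ = sd.simulate_subject(
                    gt, small_design, "younger", "s", seed
                )
                model = hmm.HMMModel(
                    n_states=gt.n_states, means=gt.state_means,
                    covariances=gt.state_covs,
                    transition_matrix=gt.tp_by_cell[("younger", "rest")],
                    initial_probs=gt.initial_probs,
                )
                decoded = hmm.decode(model, ts)
                acc.append(np.mean(decoded.states == path.states))
            accs.append(np.mean(acc))
        assert accs[0] >= accs[1] >= accs[2]


class TestSelectK:
    def test_singleton_range(self, small_design, small_gt):
        ts, _, _ = sd.simulate_subject(
            small_gt, small_design, "younger", "s", 6
        )
        report = hmm.select_k(ts.data.T, None, [5], n_restarts=1,
                              max_iter=20, seed=0)
        assert report.selected_K == 5

    def test_default_range_is_3_to_20(self):
        import inspect

        sig = inspect.signature(hmm.select_k)
        assert list(sig.parameters["k_range"].default) == list(range(3, 21))


class TestMatchStates:
    def test_self_match_is_identity(self, small_gt):
        model = hmm.HMMModel(
            n_states=small_gt.n_states, means=small_gt.state_means,
            covariances=small_gt.state_covs,
            transition_matrix=small_gt.tp_by_cell[("younger", "rest")],
            initial_probs=small_gt.initial_probs,
        )
        m = hmm.match_states(model, model)
        np.testing.assert_array_equal(m.mapping,
                                      np.arange(small_gt.n_states))
        np.testing.assert_allclose(m.scores, 1.0, atol=1e-12)

    def test_recovers_label_permutation(self, small_gt):
        perm = np.array([2, 0, 3, 1])
        a = hmm.HMMModel(
            n_states=4, means=small_gt.state_means,
            covariances=small_gt.state_covs,
            transition_matrix=np.full((4, 4), 0.25),
            initial_probs=np.full(4, 0.25),
        )
        b = hmm.HMMModel(
            n_states=4, means=small_gt.state_means[perm],
            covariances=small_gt.state_covs[perm],
            transition_matrix=np.full((4, 4), 0.25),
            initial_probs=np.full(4, 0.25),
        )
        m = hmm.match_states(a, b)
        # b's state j holds a's state perm[j]; mapping sends a -> b
        np.testing.assert_array_equal(m.mapping, np.argsort(perm))

    @pytest.mark.parametrize("K", [3, 4, 5])
    def test_assignment_matches_exhaustive_search(self, K, rng):
        means_a = rng.normal(size=(K, 6))
        means_b = rng.normal(size=(K, 6))
        covs = np.stack([np.eye(6)] * K)
        mk = lambda m: hmm.HMMModel(  # noqa: E731
            n_states=K, means=m, covariances=covs,
            transition_matrix=np.full((K, K), 1.0 / K),
            initial_probs=np.full(K, 1.0 / K),
        )
        m = hmm.match_states(mk(means_a), mk(means_b))
        S = m.similarity
        best = max(
            sum(S[i, p[i]] for i in range(K))
            for p in itertools.permutations(range(K))
        )
        assert sum(S[i, m.mapping[i]] for i in range(K)) == \
            pytest.approx(best, abs=1e-12)

    def test_many_to_one_for_unequal_k(self, rng):
        means7 = rng.normal(size=(7, 6))
        means4 = means7[[0, 2, 4, 6]]
        covs = lambda k: np.stack([np.eye(6)] * k)  # noqa: E731
        a = hmm.HMMModel(
            n_states=7, means=means7, covariances=covs(7),
            transition_matrix=np.full((7, 7), 1 / 7),
            initial_probs=np.full(7, 1 / 7),
        )
        b = hmm.HMMModel(
            n_states=4, means=means4, covariances=covs(4),
            transition_matrix=np.full((4, 4), 0.25),
            initial_probs=np.full(4, 0.25),
        )
        m = hmm.match_states(a, b, mode="many_to_one")
        # the four shared states map to themselves with similarity 1
        for a_idx, b_idx in zip([0, 2, 4, 6], range(4)):
            assert m.mapping[a_idx] == b_idx
            assert m.scores[a_idx] == pytest.approx(1.0, abs=1e-12)

    def test_zero_norm_mean_flagged(self):
        covs = np.stack([np.eye(2)] * 2)
        a = hmm.HMMModel(
            n_states=2, means=np.array([[0.0, 0.0], [1.0, 0.0]]),
            covariances=covs, transition_matrix=np.full((2, 2), 0.5),
            initial_probs=np.array([0.5, 0.5]),
        )
        m = hmm.match_states(a, a)
        assert ("a", 0) in m.zero_norm_states
        assert m.similarity[0, 0] == 0.0


# ---------------------------------------------------------------------------
# independent library cross-check


def test_loglik_matches_hmmlearn(rng):
    """Marginal likelihood and posteriors agree with hmmlearn's
    GaussianHMM on the same fixed parameters."""
    hmmlearn_hmm = pytest.importorskip("hmmlearn.hmm")
    K, R, T = 3, 4, 200
    model = random_model(K, R, seed=42)
    X = rng.normal(size=(T, R))
    ref = hmmlearn_hmm.GaussianHMM(n_components=K, covariance_type="full",
                                   init_params="")
    ref.startprob_ = model.initial_probs
    ref.transmat_ = model.transition_matrix
    ref.means_ = model.means
    ref.covars_ = model.covariances
    ll_ref = ref.score(X)
    post_ref = ref.predict_proba(X)
    path = hmm.forward_backward(model, X)
    assert path.log_likelihood == pytest.approx(ll_ref, abs=1e-8)
    np.testing.assert_allclose(path.posteriors, post_ref, atol=1e-8)
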