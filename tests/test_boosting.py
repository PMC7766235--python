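"""Boosting wrapper: domain split, weight dynamics, final vote, end-to-end."""

from math import ceil

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from instance_easytl import LabeledDomain
from instance_easytl.boosting import (
    EPS_CLIP,
    InstanceEasyTL,
    beta_factors,
    final_hypothesis,
    fit_predict,
    init_weights,
    normalize_weights,
    split_domains,
    update_weights,
    weighted_error,
)


def _labeled(rng, n, D=3):
    return LabeledDomain(rng.normal(size=(n, D)), rng.integers(0, 2, size=n))


class TestSplitDomains:
    def test_paper_scale_split_counts(self, rng):
        target = LabeledDomain(rng.normal(size=(1400, 2)), np.repeat([0, 1], 700))
        split = split_domains(_labeled(rng, 10), target, lam=0.3, seed=0)
        assert split.n_borrow == 420
        assert split.idx_test.size == 980
        # stratification: 210 borrowed per class
        assert np.sum(split.y_borrow == 0) == 210
        assert np.sum(split.y_borrow == 1) == 210

    def test_lam_zero_borrows_nothing(self, rng):
        target = _labeled(rng, 50)
        split = split_domains(_labeled(rng, 10), target, lam=0.0)
        assert split.n_borrow == 0
        assert np.array_equal(split.idx_test, np.arange(50))

    def test_borrow_and_test_partition_target(self, rng):
        target = LabeledDomain(rng.normal(size=(100, 2)), np.repeat([0, 1], 50))
        split = split_domains(_labeled(rng, 10), target, lam=0.25, seed=3)
        combined = np.sort(np.concatenate([split.idx_borrow, split.idx_test]))
        assert np.array_equal(combined, np.arange(100))

    def test_deterministic_given_seed(self, rng):
        target = LabeledDomain(rng.normal(size=(60, 2)), np.repeat([0, 1], 30))
        source = _labeled(rng, 10)
        a = split_domains(source, target, 0.3, seed=11)
        b = split_domains(source, target, 0.3, seed=11)
        assert np.array_equal(a.idx_borrow, b.idx_borrow)

    def test_invalid_lam_rejected(self, rng):
        with pytest.raises(ValueError, match="lam"):
            split_domains(_labeled(rng, 5), _labeled(rng, 20), lam=1.0)


class TestWeights:
    def test_uniform_init_normalizes_to_quarter(self):
        w_sd, w_td = init_weights(2, 2)
        p = normalize_weights(np.concatenate([w_sd, w_td]))
        assert np.allclose(p, 0.25)

    def test_init_without_borrowed_pool(self):
        w_sd, w_td = init_weights(3, 0)
        assert w_sd.shape == (3,) and w_td.shape == (0,)
        assert np.allclose(normalize_weights(w_sd), 1 / 3)

    @pytest.mark.parametrize(
        "w, expected",
        [([1, 3], [0.25, 0.75]), ([2, 2, 4], [0.25, 0.25, 0.5])],
    )
    def test_normalization_forced_arithmetic(self, w, expected):
        assert np.allclose(normalize_weights(np.array(w, float)), expected)

    def test_normalization_sums_to_one(self, rng):
        p = normalize_weights(rng.uniform(0.01, 5, size=37))
        assert abs(p.sum() - 1.0) < 1e-12

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            normalize_weights(np.array([1.0, 0.0]))


class TestWeightedError:
    def test_perfect_predictions_clip_to_floor(self):
        y = np.array([0, 1, 1])
        eps = weighted_error(y, y, np.ones(3))
        assert eps == EPS_CLIP[0]

    def test_half_error_clips_to_ceiling(self):
        eps = weighted_error(np.array([0, 0]), np.array([1, 0]), np.array([0.5, 0.5]))
        assert eps == EPS_CLIP[1]

    def test_matches_weighted_sum_oracle_before_clipping(self, rng):
        h = rng.integers(0, 2, size=25)
        y = rng.integers(0, 2, size=25)
        w = rng.uniform(0.1, 3, size=25)
        raw = weighted_error(h, y, w, clip=False)
        oracle = sum(w[i] * abs(int(h[i]) - int(y[i])) for i in range(25)) / w.sum()
        assert np.isclose(raw, oracle)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            weighted_error(np.empty(0), np.empty(0), np.empty(0))


class TestBetaFactors:
    def test_quarter_error_gives_one_third(self):
        beta_t, _ = beta_factors(0.25, 10, 30)
        assert beta_t == pytest.approx(1 / 3)

    def test_source_factor_value(self):
        # 1 / (1 + sqrt(2 ln 100 / 30))
        _, beta = beta_factors(0.1, 100, 30)
        assert beta == pytest.approx(0.643468, abs=1e-4)

    def test_beta_t_monotone_in_eps(self):
        values = [beta_factors(e, 10, 30)[0] for e in (0.01, 0.1, 0.3, 0.49)]
        assert all(a < b for a, b in zip(values, values[1:]))
        assert all(0 < v < 1 for v in values)

    def test_beta_iteration_independent(self):
        assert beta_factors(0.1, 50, 30)[1] == beta_factors(0.4, 50, 30)[1]

    def test_out_of_range_eps_rejected(self):
        with pytest.raises(ValueError):
            beta_factors(0.5, 10, 30)


class TestUpdateWeights:
    def test_all_correct_leaves_weights_unchanged(self, rng):
        y_s = rng.integers(0, 2, 10)
        y_b = rng.integers(0, 2, 5)
        w_s, w_b = update_weights(
            np.ones(10), np.ones(5), y_s, y_s, y_b, y_b, 0.5, 0.25
        )
        assert np.allclose(w_s, 1.0) and np.allclose(w_b, 1.0)

    def test_forced_arithmetic(self):
        w_s, w_b = update_weights(
            np.array([1.0]), np.array([1.0]),
            np.array([1]), np.array([0]),  # source misclassified
            np.array([0]), np.array([1]),  # borrowed misclassified
            beta=0.5, beta_t=0.25,
        )
        assert w_s[0] == pytest.approx(0.5)
        assert w_b[0] == pytest.approx(4.0)

    def test_matches_elementwise_oracle(self, rng):
        n, m = 20, 8
        w_s0 = rng.uniform(0.1, 2, n)
        w_b0 = rng.uniform(0.1, 2, m)
        h_s, y_s = rng.integers(0, 2, n), rng.integers(0, 2, n)
        h_b, y_b = rng.integers(0, 2, m), rng.integers(0, 2, m)
        beta, beta_t = 0.7, 0.2
        w_s, w_b = update_weights(w_s0, w_b0, h_s, y_s, h_b, y_b, beta, beta_t)
        assert np.allclose(w_s, [w_s0[i] * beta ** abs(int(h_s[i]) - int(y_s[i])) for i in range(n)])
        assert np.allclose(w_b, [w_b0[i] * beta_t ** -abs(int(h_b[i]) - int(y_b[i])) for i in range(m)])

    def test_monotone_dynamics(self, rng):
        """Misclassified source weights never rise; borrowed never fall."""
        n, m = 30, 12
        w_s0 = rng.uniform(0.1, 2, n)
        w_b0 = rng.uniform(0.1, 2, m)
        h_s, y_s = rng.integers(0, 2, n), rng.integers(0, 2, n)
        h_b, y_b = rng.integers(0, 2, m), rng.integers(0, 2, m)
        w_s, w_b = update_weights(w_s0, w_b0, h_s, y_s, h_b, y_b, 0.6, 0.3)
        assert np.all(w_s[h_s != y_s] <= w_s0[h_s != y_s])
        assert np.all(w_b[h_b != y_b] >= w_b0[h_b != y_b])
        assert np.all(w_s > 0) and np.all(w_b > 0)


def _vote_oracle(h_hist, beta_t_hist, N):
    """Direct product-inequality evaluation in extended precision."""
    start = ceil(N / 2) - 1
    labels = []
    for x in range(h_hist.shape[1]):
        left = np.prod(
            [np.longdouble(beta_t_hist[t]) ** (-h_hist[t, x]) for t in range(start, N)]
        )
        right = np.prod(
            [np.longdouble(beta_t_hist[t]) ** (-0.5) for t in range(start, N)]
        )
        labels.append(1 if left >= right else 0)
    return np.array(labels)


class TestFinalHypothesis:
    def test_unanimous_votes(self):
        beta_t = np.full(6, 0.3)
        assert np.all(final_hypothesis(np.ones((6, 4), int), beta_t) == 1)
        assert np.all(final_hypothesis(np.zeros((6, 4), int), beta_t) == 0)

    def test_only_last_half_counts(self):
        # N=4: iterations 2..4 vote (1-based); iteration 1 is ignored
        h = np.array([[0, 0], [1, 1], [1, 0], [1, 0]])
        beta_t = np.array([0.01, 0.3, 0.3, 0.3])
        out = final_hypothesis(h, beta_t, N=4)
        assert np.array_equal(out, [1, 0])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000_000))
    def test_matches_product_inequality_oracle(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(1, 16))
        l = int(rng.integers(1, 10))
        h = rng.integers(0, 2, size=(N, l))
        beta_t = rng.uniform(1e-6, 0.999, size=N)
        assert np.array_equal(
            final_hypothesis(h, beta_t, N), _vote_oracle(h, beta_t, N)
        )


class TestFitPredict:
    def test_lam_zero_single_iteration_matches_plain_easytl(self, mini_transfer):
        from instance_easytl.easytl import EasyTLClassifier

        source, target = mini_transfer
        res = fit_predict(source, target, lam=0.0, N=1, seed=0)
        plain = EasyTLClassifier().fit(source.X, source.y).predict(target.X)
        assert np.array_equal(res.hf, plain)
        assert res.idx_test.size == target.n_samples

    def test_end_to_end_deterministic(self, mini_transfer):
        source, target = mini_transfer
        a = fit_predict(source, target, lam=0.3, N=5, seed=42)
        b = fit_predict(source, target, lam=0.3, N=5, seed=42)
        assert np.array_equal(a.hf, b.hf)
        assert np.array_equal(a.eps_history, b.eps_history)
        assert np.array_equal(a.idx_borrow, b.idx_borrow)

    def test_history_invariants(self, mini_transfer):
        source, target = mini_transfer
        res = fit_predict(source, target, lam=0.3, N=8, seed=1)
        assert res.eps_history.shape == (8,)
        assert np.all(res.eps_history > 0) and np.all(res.eps_history < 0.5)
        assert np.all(res.beta_t_history > 0) and np.all(res.beta_t_history < 1)
        assert 0 < res.beta < 1
        assert set(np.unique(res.hf)) <= {0, 1}

    def test_identical_distributions_borrowing_harmless(self, rng):
        """No shift, separable classes: boosting within 2 points of plain EasyTL.

        With class overlap the hard boundary samples can be amplified by the
        multiplicative updates and drag the centers (a known instance-boosting
        pathology), so harmlessness is a separable-regime property.
        """
        from instance_easytl import CohortSpec, gen_cohort

        accs, accs0 = [], []
        for seed in range(5):
            spec = CohortSpec(
                n_subjects=2, windows_per_class=80, subject_shift=0.0,
                separation=6.0, seed=seed,
            )
            cohort = gen_cohort(spec)
            source, target = cohort[0], cohort[1]
            res = fit_predict(source, target, lam=0.3, N=10, seed=seed)
            accs.append(np.mean(res.hf == target.y[res.idx_test]))
            res0 = fit_predict(source, target, lam=0.0, N=1, seed=seed)
            accs0.append(np.mean(res0.hf == target.y[res0.idx_test]))
        assert np.mean(accs) >= np.mean(accs0) - 0.02

    def test_multiclass_rejected(self, rng):
        source = LabeledDomain(rng.normal(size=(30, 2)), rng.integers(0, 3, 30))
        target = LabeledDomain(rng.normal(size=(30, 2)), rng.integers(0, 2, 30))
        with pytest.raises(ValueError, match="binary"):
            fit_predict(source, target)


class TestInstanceEasyTLEstimator:
    def test_sklearn_protocol(self):
        from sklearn.base import clone

        est = InstanceEasyTL(lam=0.2, n_iter=5, random_state=3)
        assert est.get_params()["lam"] == 0.2
        assert clone(est).get_params() == est.get_params()

    def test_fit_exposes_transductive_labels(self, mini_transfer):
        source, target = mini_transfer
        est = InstanceEasyTL(lam=0.3, n_iter=5, random_state=0)
        est.fit(source.X, source.y, X_target=target.X, y_target=target.y)
        assert est.labels_.shape == est.test_indices_.shape
        assert np.array_equal(est.predict(), est.labels_)
        acc = est.score_test(target.y)
        assert 0.0 <= acc <= 1.0

    def test_predict_on_fresh_samples_is_sane(self, mini_transfer):
        """Re-voting stored centers labels held-out test rows mostly like fit did."""
        source, target = mini_transfer
        est = InstanceEasyTL(lam=0.3, n_iter=6, random_state=0)
        est.fit(source.X, source.y, X_target=target.X, y_target=target.y)
        fresh = est.predict(target.X[est.test_indices_])
        agreement = np.mean(fresh == est.labels_)
        assert agreement >= 0.9

    def test_missing_target_rejected(self, rng):
        est = InstanceEasyTL()
        with pytest.raises(ValueError, match="target"):
            est.fit(rng.normal(size=(10, 2)), rng.integers(0, 2, 10))
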