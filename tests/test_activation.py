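"""Activation-mapping stages against hand computations and dense oracles."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

import painmap as pm
from painmap.activation import (
    ActivationMapper,
    contribution_curve,
    feature_covariance,
    fit_linear_classifier,
    haufe_transform,
    rank_regions,
    zscore_regions,
)
from painmap.containers import RegionActivationMatrix, ValidationError


def _ram(counts, groups=None, names=None):
    counts = np.asarray(counts, float)
    n, m = counts.shape
    if groups is None:
        groups = ["CON"] * (n // 2) + ["MA"] * (n - n // 2)
    if names is None:
        names = [f"R{i:02d}" for i in range(m)]
    return RegionActivationMatrix(counts=counts, region_names=names, group_labels=np.array(groups))


class TestZscore:
    def test_hand_computed_column(self):
        data = _ram([[1, 5], [2, 5], [3, 5]], groups=["CON", "CON", "MA"])
        z = zscore_regions(data)
        # sample SD of (1,2,3) is 1 -> (-1, 0, 1)
        np.testing.assert_allclose(z.zscores[:, 0], [-1.0, 0.0, 1.0], atol=1e-12)

    def test_constant_column_flagged_zero(self):
        data = _ram([[1, 5], [2, 5], [3, 5]], groups=["CON", "CON", "MA"])
        z = zscore_regions(data)
        np.testing.assert_array_equal(z.zscores[:, 1], 0.0)
        assert z.degenerate_regions.tolist() == [False, True]

    def test_columns_centered(self, small_counts):
        z = zscore_regions(small_counts[0])
        assert np.abs(z.zscores.mean(axis=0)).max() < 1e-12
        sd = z.zscores.std(axis=0, ddof=1)
        np.testing.assert_allclose(sd[~z.degenerate_regions], 1.0, atol=1e-12)


class TestClassifier:
    def test_separable_1d_groups(self):
        counts = np.column_stack([np.r_[np.zeros(4), np.ones(4) * 10], np.ones(8)])
        data = _ram(counts, groups=["CON"] * 4 + ["MA"] * 4)
        model = fit_linear_classifier(zscore_regions(data))
        assert model.training_accuracy == 1.0
        # positive decision side is the later class (MA), which has high values
        assert model.weights[0, 0] > 0

    def test_paper_scale_weight_shape(self):
        data, _ = pm.gen_region_counts(
            pm.RegionCountSpec(n_per_group=3, region_names=[f"R{i:03d}" for i in range(129)], seed=0)
        )
        model = fit_linear_classifier(zscore_regions(data))
        assert model.weights.shape == (129, 1)

    def test_single_class_rejected(self):
        data = _ram(np.arange(8.0).reshape(4, 2), groups=["CON"] * 3 + ["MA"])
        data.group_labels = np.array(["CON"] * 4)  # degrade after validation
        with pytest.raises(ValidationError):
            fit_linear_classifier(zscore_regions(data))


class TestCovariance:
    def test_perfect_correlation_no_shrinkage(self):
        x = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0], [4.0, 8.0]])
        z = (x - x.mean(0)) / x.std(0, ddof=1)
        sigma, s = feature_covariance(z, shrinkage=0.0)
        assert s == 0.0
        np.testing.assert_allclose(sigma[0, 1], 1.0, atol=1e-12)

    def test_full_shrinkage_is_diagonal(self, rng):
        x = rng.normal(size=(6, 4))
        sigma, _ = feature_covariance(x, shrinkage=1.0)
        off = sigma[~np.eye(4, dtype=bool)]
        np.testing.assert_allclose(off, 0.0, atol=1e-15)

    def test_matches_direct_sum_oracle(self, rng):
        x = rng.normal(size=(4, 3))
        sigma, _ = feature_covariance(x, shrinkage=0.0)
        xb = x.mean(axis=0)
        brute = sum(np.outer(r - xb, r - xb) for r in x) / (len(x) - 1)
        np.testing.assert_allclose(sigma, brute, atol=1e-12)

    def test_auto_shrinkage_in_unit_interval(self, rng):
        x = rng.normal(size=(6, 30))
        _, s = feature_covariance(x, shrinkage="auto")
        assert 0.0 <= s <= 1.0


class TestHaufe:
    def test_identity_covariance_worked_example(self):
        # Σx = I, w = (3,4): Σŝ = 25, A = w/25 = (0.12, 0.16)
        pat = haufe_transform(np.array([[3.0], [4.0]]), np.eye(2))
        np.testing.assert_allclose(pat.sigma_s, [[25.0]], atol=1e-12)
        np.testing.assert_allclose(pat.A.ravel(), [0.12, 0.16], atol=1e-12)

    def test_matches_brute_force_product(self, rng):
        m, k = 5, 2
        w = rng.normal(size=(m, k))
        b = rng.normal(size=(m, m))
        sigma = b @ b.T + 0.1 * np.eye(m)
        pat = haufe_transform(w, sigma)
        # independent dense oracle: element-wise triple product
        def matmul(a, b):
            out = np.zeros((a.shape[0], b.shape[1]))
            for i in range(a.shape[0]):
                for j in range(b.shape[1]):
                    out[i, j] = sum(a[i, q] * b[q, j] for q in range(a.shape[1]))
            return out

        sigma_s = matmul(matmul(w.T, sigma), w)
        oracle = matmul(matmul(sigma, w), np.linalg.inv(sigma_s))
        np.testing.assert_allclose(pat.A, oracle, atol=1e-10)

    def test_scale_equivariance_of_pattern(self, rng):
        # scaling W by c leaves the pattern direction unchanged (Σŝ absorbs
        # c², the numerator is linear in c, so A itself scales as 1/c)
        w = rng.normal(size=(6, 1))
        b = rng.normal(size=(6, 6))
        sigma = b @ b.T + 0.5 * np.eye(6)
        a1 = haufe_transform(w, sigma).A.ravel()
        a2 = haufe_transform(7.5 * w, sigma).A.ravel()
        cos = a1 @ a2 / (np.linalg.norm(a1) * np.linalg.norm(a2))
        assert abs(cos - 1.0) < 1e-12
        np.testing.assert_allclose(a2, a1 / 7.5, atol=1e-10)

    def test_singular_latent_covariance_errors(self):
        w = np.zeros((3, 1))
        with pytest.raises(ValidationError, match="shrinkage"):
            haufe_transform(w, np.eye(3))

    def test_dimension_mismatch_errors(self):
        with pytest.raises(ValidationError, match="mismatch"):
            haufe_transform(np.ones((3, 1)), np.eye(4))


class TestContributionCurve:
    def test_single_contributor(self):
        pat = pm.activation.ActivationPattern(
            A=np.array([[0.0], [0.0], [5.0]]), sigma_x=np.eye(3), sigma_s=np.eye(1),
            shrinkage_used=0.0, region_names=["a", "b", "c"],
        )
        curve = contribution_curve(pat)
        assert curve.ordered_regions[0] == "c"
        np.testing.assert_allclose(curve.cumulative_fraction, [1.0, 1.0, 1.0])

    def test_hand_arithmetic(self):
        pat = pm.activation.ActivationPattern(
            A=np.array([[3.0], [-2.0], [1.0]]), sigma_x=np.eye(3), sigma_s=np.eye(1),
            shrinkage_used=0.0, region_names=["r1", "r2", "r3"],
        )
        curve = contribution_curve(pat)
        np.testing.assert_allclose(curve.cumulative_fraction, [0.5, 5 / 6, 1.0], atol=1e-12)
        assert curve.ordered_regions == ["r1", "r2", "r3"]

    def test_all_zero_pattern_errors(self):
        pat = pm.activation.ActivationPattern(
            A=np.zeros((3, 1)), sigma_x=np.eye(3), sigma_s=np.eye(1), shrinkage_used=0.0
        )
        with pytest.raises(ValidationError):
            contribution_curve(pat)

    @given(st.lists(st.floats(min_value=-100, max_value=100), min_size=2, max_size=12))
    def test_monotone_terminates_at_one(self, values):
        a = np.asarray(values)
        if np.abs(a).sum() == 0:
            return
        pat = pm.activation.ActivationPattern(
            A=a[:, None], sigma_x=np.eye(len(a)), sigma_s=np.eye(1), shrinkage_used=0.0
        )
        curve = contribution_curve(pat)
        assert (np.diff(curve.cumulative_fraction) >= -1e-12).all()
        assert abs(curve.cumulative_fraction[-1] - 1.0) < 1e-9

    def test_permutation_invariance(self, rng):
        a = rng.normal(size=8)
        names = [f"r{i}" for i in range(8)]
        perm = rng.permutation(8)
        def mk(vals, nms):
            return pm.activation.ActivationPattern(
                A=np.asarray(vals)[:, None], sigma_x=np.eye(len(nms)),
                sigma_s=np.eye(1), shrinkage_used=0.0, region_names=list(nms))
        c1 = contribution_curve(mk(a, names))
        c2 = contribution_curve(mk(a[perm], [names[i] for i in perm]))
        assert c1.ordered_regions == c2.ordered_regions
        np.testing.assert_allclose(c1.cumulative_fraction, c2.cumulative_fraction, atol=1e-12)


class TestRanking:
    def test_sort_oracle_on_unique_values(self, rng):
        a = rng.permutation(np.arange(1.0, 8.0)) * rng.choice([-1, 1], 7)
        names = [f"r{i}" for i in range(7)]
        pat = pm.activation.ActivationPattern(
            A=a[:, None], sigma_x=np.eye(7), sigma_s=np.eye(1),
            shrinkage_used=0.0, region_names=names)
        got = rank_regions(pat, 7)
        expected = [names[i] for i in np.argsort(-np.abs(a), kind="stable")]
        assert got == expected

    def test_topk_equals_m_is_permutation(self, rng):
        a = rng.normal(size=5)
        pat = pm.activation.ActivationPattern(
            A=a[:, None], sigma_x=np.eye(5), sigma_s=np.eye(1),
            shrinkage_used=0.0, region_names=list("abcde"))
        assert sorted(rank_regions(pat, 5)) == list("abcde")

    def test_topk_too_large_errors(self):
        pat = pm.activation.ActivationPattern(
            A=np.ones((3, 1)), sigma_x=np.eye(3), sigma_s=np.eye(1), shrinkage_used=0.0)
        with pytest.raises(ValidationError):
            rank_regions(pat, 4)


class TestCrossValidation:
    def test_separable_groups_loo_perfect(self):
        counts = np.column_stack([np.r_[np.zeros(4), np.full(4, 50.0)],
                                  np.r_[np.zeros(4), np.full(4, 50.0)]])
        counts += np.random.default_rng(0).normal(scale=0.5, size=counts.shape) ** 2
        data = _ram(counts, groups=["CON"] * 4 + ["MA"] * 4)
        res = pm.cross_validate(zscore_regions(data), scheme="leave-one-out")
        assert res["mean_accuracy"] == 1.0

    def test_infeasible_stratified_design_errors(self):
        counts = np.random.default_rng(1).random((3, 4)) + 1
        data = _ram(counts, groups=["CON", "CON", "MA"])
        with pytest.raises(ValidationError, match="infeasible"):
            pm.cross_validate(zscore_regions(data), scheme="stratified-k", n_splits=2)


class TestActivationMapper:
    def test_sklearn_params_roundtrip(self):
        est = ActivationMapper(C=2.0, shrinkage=0.3, random_state=7)
        params = est.get_params()
        assert params == {"C": 2.0, "shrinkage": 0.3, "random_state": 7}
        est.set_params(C=1.0)
        assert est.C == 1.0

    def test_fit_predict_and_pattern_consistency(self, small_counts):
        data, truth = small_counts
        est = ActivationMapper(random_state=0).fit(data.counts, data.group_labels)
        assert est.training_accuracy_ == 1.0
        assert (est.predict(data.counts) == data.group_labels).all()
        # estimator path equals the functional path
        z, model, pattern, _ = pm.map_activation(data, seed=0)
        np.testing.assert_allclose(est.pattern_, pattern.A.ravel(), atol=1e-10)

    def test_forward_model_aligns_with_mean_difference(self, rng):
        # equal-covariance Gaussian classes: A converges to the class-mean
        # difference direction (forward-model consistency)
        m, n = 10, 200
        delta = rng.normal(size=m)
        x = np.vstack([rng.normal(size=(n, m)), delta + rng.normal(size=(n, m))])
        y = np.array(["CON"] * n + ["MA"] * n)
        est = ActivationMapper(shrinkage=0.0, random_state=0).fit(x, y)
        # compare against the z-scored mean-difference direction
        z = (x - x.mean(0)) / x.std(0, ddof=1)
        zdiff = z[y == "MA"].mean(0) - z[y == "CON"].mean(0)
        rho = np.corrcoef(est.pattern_, zdiff)[0, 1]
        assert rho > 0.95

    def test_planted_regions_recovered(self):
        data, truth = pm.gen_region_counts(
            pm.RegionCountSpec(
                n_per_group=20,
                region_names=[f"R{i:03d}" for i in range(129)],
                effect_regions=[3, 17, 42, 88, 120],
                effect_log_fold=1.0,
                seed=11,
            )
        )
        est = ActivationMapper(random_state=0).fit(data.counts, data.group_labels)
        top10 = rank_regions(est.activation_pattern(data.region_names), 10)
        hits = len(set(top10) & set(truth["effect_regions"]))
        assert hits >= 4
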