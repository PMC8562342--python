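"""Chemometrics: autoscaling, PCA, SIMPLS, cross-validation, iPLS, ANOVA."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vinoflux.chemometrics import (
    anova_tukey,
    autoscale,
    cross_validate,
    ipls_reverse,
    pca,
    regression_summary,
    simpls_fit,
    venetian_blinds_split,
)


class TestAutoscale:
    def test_closed_form(self):
        Xs, c, s = autoscale(np.array([[1.0], [2.0], [3.0]]))
        assert Xs[:, 0] == pytest.approx([-1.0, 0.0, 1.0])
        assert c[0] == 2.0 and s[0] == 1.0

    def test_constant_column_warns(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            Xs, _, s = autoscale(np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]]))
        assert s[1] == 1.0  # left unscaled

    def test_round_trip(self, rng):
        X = rng.normal(size=(20, 6))
        Xs, c, s = autoscale(X)
        assert np.allclose(Xs * s + c, X, atol=1e-12)


class TestPCA:
    def test_collinear_data_is_rank_one(self):
        x = np.linspace(-1, 1, 10)
        X = np.column_stack([x, 2 * x])
        _, _, pct = pca(X, 1)
        assert pct[0] == pytest.approx(100.0)

    def test_matches_eigendecomposition_oracle(self, rng):
        X = rng.normal(size=(10, 4))
        X -= X.mean(axis=0)
        scores, loadings, pct = pca(X, 4)
        # oracle: eigenvectors of the scatter matrix
        evals, evecs = np.linalg.eigh(X.T @ X)
        order = np.argsort(evals)[::-1]
        evecs = evecs[:, order]
        for j in range(4):
            cos = abs(loadings[:, j] @ evecs[:, j])
            assert cos == pytest.approx(1.0, abs=1e-8)
        assert pct == pytest.approx(
            100 * evals[order] / evals.sum(), abs=1e-9
        )

    def test_variance_fractions_sum_to_100(self, rng):
        X = rng.normal(size=(12, 5))
        _, _, pct = pca(X, 5)
        assert pct.sum() == pytest.approx(100.0, abs=1e-9)
        assert np.all(np.diff(pct) <= 1e-12)

    def test_row_permutation_invariance(self, rng):
        X = rng.normal(size=(15, 4))
        _, _, p1 = pca(X, 4)
        _, _, p2 = pca(X[rng.permutation(15)], 4)
        assert p1 == pytest.approx(p2, abs=1e-9)


class TestSIMPLS:
    def test_exact_univariate_relationship(self, rng):
        X = rng.normal(size=(30, 4))
        X -= X.mean(0)
        Q, _ = np.linalg.qr(X)  # orthogonal predictors
        y = 2.0 * Q[:, [0]]
        model = simpls_fit(Q, y, n_lv=1)
        coefs = model.regression_vector_raw[:, 0]
        assert coefs[0] == pytest.approx(2.0, abs=1e-8)
        assert np.allclose(coefs[1:], 0.0, atol=1e-8)
        assert model.metrics["R2"] == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_nipals_oracle_per_lv(self, seed):
        # single-response PLS: SIMPLS and NIPALS give identical predictions
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(24, 18))
        y = rng.normal(size=(24, 1))
        from sklearn.cross_decomposition import PLSRegression

        for n_lv in (1, 3, 7):
            ours = simpls_fit(X, y, n_lv=n_lv)
            sk = PLSRegression(n_components=n_lv, scale=True).fit(X, y)
            assert np.allclose(
                ours.predict(X), sk.predict(X), atol=1e-8
            ), f"n_lv={n_lv}"

    def test_full_rank_equals_ols(self, rng):
        X = rng.normal(size=(40, 6))
        y = rng.normal(size=(40, 1))
        model = simpls_fit(X, y, n_lv=6)
        Xd = np.column_stack([np.ones(40), X])
        beta = np.linalg.lstsq(Xd, y, rcond=None)[0]
        assert np.allclose(model.predict(X), Xd @ beta, atol=1e-8)

    def test_variance_captured_monotone_and_bounded(self, rng):
        X = rng.normal(size=(30, 8))
        y = rng.normal(size=(30, 1))
        model = simpls_fit(X, y, n_lv=6)
        vx, _ = model.variance_per_lv
        assert np.all(vx >= -1e-12)
        assert vx.sum() <= 100 + 1e-9

    def test_too_many_lvs_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        y = rng.normal(size=(10, 1))
        with pytest.raises(ValueError, match="n_lv"):
            simpls_fit(X, y, n_lv=7)


class TestVenetianBlinds:
    def test_definition(self):
        splits = venetian_blinds_split(6, 3)
        assert [list(s) for s in splits] == [[0, 3], [1, 4], [2, 5]]

    def test_leave_one_out_limit(self):
        splits = venetian_blinds_split(24, 24)
        assert len(splits) == 24 and all(len(s) == 1 for s in splits)

    def test_fewer_rows_than_splits_falls_back(self):
        with pytest.warns(UserWarning, match="leave-one-out"):
            splits = venetian_blinds_split(10, 24)
        assert len(splits) == 10

    @given(n=st.integers(4, 200), k=st.integers(2, 30))
    @settings(max_examples=40, deadline=None)
    def test_disjoint_cover(self, n, k):
        if n < k:
            return
        splits = venetian_blinds_split(n, k)
        all_idx = np.concatenate(splits)
        assert len(all_idx) == n
        assert set(all_idx) == set(range(n))


class TestCrossValidation:
    def test_noise_free_linear_system(self, rng):
        X = rng.normal(size=(48, 5))
        beta = rng.normal(size=(5, 1))
        y = X @ beta
        rmsecv, q2, chosen = cross_validate(X, y, max_lv=5, n_splits=24)
        assert rmsecv[chosen - 1] < 1e-8
        assert q2[chosen - 1] > 1 - 1e-12

    def test_permuted_response_has_no_predictivity(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(48, 5))
        y = X @ rng.normal(size=(5, 1))
        best_q2 = []
        for _ in range(20):
            yp = y[rng.permutation(48)]
            _, q2, _ = cross_validate(X, yp, max_lv=5, n_splits=24)
            best_q2.append(q2.max())
        assert np.mean(best_q2) <= 0.2

    def test_q2_not_above_r2(self, rng):
        for _ in range(5):
            X = rng.normal(size=(36, 6))
            y = X @ rng.normal(size=(6, 1)) + 0.5 * rng.normal(size=(36, 1))
            rmsecv, q2, chosen = cross_validate(X, y, max_lv=6)
            model = simpls_fit(X, y, n_lv=chosen)
            assert q2[chosen - 1] <= model.metrics["R2"] + 1e-9

    def test_tiny_fold_rejected(self, rng):
        X = rng.normal(size=(3, 2))
        y = rng.normal(size=(3, 1))
        with pytest.raises(ValueError):
            cross_validate(X, y, n_splits=2)


class TestIPLS:
    def test_recovers_known_support(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(60, 18))
        informative = [0, 4, 7, 11, 15]
        beta = np.zeros((18, 1))
        beta[informative, 0] = rng.uniform(1.0, 2.0, size=5)
        y = X @ beta
        mask = ipls_reverse(X, y, interval_size=1, max_lv=10)
        assert all(mask[j] for j in informative)

    def test_single_predictor_kept(self, rng):
        X = rng.normal(size=(20, 1))
        y = 2 * X
        assert ipls_reverse(X, y).tolist() == [True]

    def test_all_necessary_predictors_retained(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 4))
        y = X.sum(axis=1, keepdims=True)
        mask = ipls_reverse(X, y, max_lv=4)
        assert mask.all()

    def test_selected_never_worse_than_full(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(48, 10))
        y = X[:, :3] @ rng.normal(size=(3, 1)) + 0.1 * rng.normal(size=(48, 1))
        mask = ipls_reverse(X, y, max_lv=8)
        r_full, _, c_full = cross_validate(X, y, max_lv=8)
        r_sel, _, c_sel = cross_validate(X[:, mask], y, max_lv=8)
        assert r_sel[c_sel - 1] <= r_full[c_full - 1] + 1e-12


class TestSignSummary:
    def test_signs_and_unselected_zero(self, rng):
        X = rng.normal(size=(30, 3))
        y = (2 * X[:, [0]] - 3 * X[:, [1]])
        mask = np.array([True, True, False])
        model = simpls_fit(X[:, mask], y, n_lv=2, selected_mask=mask)
        summary = regression_summary([model], ["y"], ["a", "b", "c"])
        assert summary.entries[0].tolist() == ["+", "-", "0"]


class TestAnovaTukey:
    def test_identical_means(self):
        groups = {"a": np.array([1.0, 2.0, 3.0]), "b": np.array([1.0, 2.0, 3.0])}
        f, p, _ = anova_tukey(groups)
        assert f == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_three_group_hand_oracle(self):
        # groups (2,3,4), (2,3,4), (12,13,14): SSB = 200, SSW = 6,
        # F = (200/2)/(6/6) = 100 exactly
        groups = {
            "g1": np.array([2.0, 3.0, 4.0]),
            "g2": np.array([2.0, 3.0, 4.0]),
            "g3": np.array([12.0, 13.0, 14.0]),
        }
        f, p, pairwise = anova_tukey(groups)
        assert f == pytest.approx(100.0, abs=1e-6)
        assert p < 1e-4
        assert pairwise[("g1", "g3")] < 0.01
        assert pairwise[("g2", "g3")] < 0.01
        assert pairwise[("g1", "g2")] > 0.99

    def test_degenerate_variance_rejected(self):
        groups = {"a": np.array([1.0, 1.0]), "b": np.array([2.0, 2.0])}
        with pytest.raises(ValueError):
            anova_tukey(groups)
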