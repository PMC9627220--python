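"""NIPALS PLS1, VIP and Q2 against independent oracles and invariants."""

import numpy as np
import pandas as pd
import pytest

from specfx import (SyntheticSpec, cv_q2, gen_spectrum_effect, pls_fit,
                    pls_screen, pls_select, vip_scores)
from specfx.errors import SpecfxError

from oracles import svd_pls1


def _random_problem(rng, n=8, p=6):
    X = pd.DataFrame(rng.standard_normal((n, p)),
                     columns=[f"P{j + 1}" for j in range(p)])
    y = rng.standard_normal(n)
    return X, y


class TestPlsFit:
    def test_single_column_proportional_response(self, rng):
        x = rng.uniform(1, 5, 10)
        X = pd.DataFrame({"P1": x})
        model = pls_fit(X, 3.0 * x, n_components=1)
        assert model.r2y == pytest.approx(1.0)

    def test_matches_svd_oracle(self, rng):
        for _ in range(20):
            X, y = _random_problem(rng)
            model = pls_fit(X, y, n_components=2)
            oracle = svd_pls1(X.to_numpy(), y, 2)
            np.testing.assert_allclose(model.weights, oracle["W"], atol=1e-8)
            np.testing.assert_allclose(model.scores, oracle["T"], atol=1e-8)
            np.testing.assert_allclose(model.x_loadings, oracle["P"], atol=1e-8)
            np.testing.assert_allclose(model.coef_scaled, oracle["coef"], atol=1e-8)

    def test_matches_sklearn_predictions(self, rng):
        from sklearn.cross_decomposition import PLSRegression
        X, y = _random_problem(rng, n=10, p=7)
        model = pls_fit(X, y, n_components=3)
        sk = PLSRegression(n_components=3, scale=True).fit(X.to_numpy(), y)
        np.testing.assert_allclose(model.predict(X.to_numpy()),
                                   sk.predict(X.to_numpy()).ravel(), atol=1e-8)

    def test_score_orthogonality(self, rng):
        X, y = _random_problem(rng, n=9, p=6)
        model = pls_fit(X, y, n_components=4)
        G = model.scores.T @ model.scores
        np.testing.assert_allclose(G - np.diag(np.diag(G)), 0.0, atol=1e-9)

    def test_r2y_nondecreasing_in_components(self, rng):
        X, y = _random_problem(rng, n=10, p=6)
        r2 = [pls_fit(X, y, n_components=a).r2y for a in (1, 2, 3, 4)]
        assert all(b >= a - 1e-12 for a, b in zip(r2, r2[1:]))
        assert all(0.0 <= v <= 1.0 + 1e-12 for v in r2)

    def test_centering_makes_constant_shift_irrelevant(self, rng):
        X, y = _random_problem(rng)
        m1 = pls_fit(X, y, n_components=2)
        m2 = pls_fit(X, y + 57.0, n_components=2)
        np.testing.assert_allclose(m1.coef_scaled, m2.coef_scaled, atol=1e-12)

    def test_zero_variance_column_dropped_with_warning(self, rng):
        X, y = _random_problem(rng)
        X["P_const"] = 4.2
        with pytest.warns(UserWarning, match="P_const"):
            model = pls_fit(X, y, n_components=2)
        assert "P_const" not in model.feature_names

    def test_component_count_validated(self, rng):
        X, y = _random_problem(rng, n=5, p=3)
        with pytest.raises(SpecfxError, match="n_components"):
            pls_fit(X, y, n_components=5)


class TestVip:
    def test_single_predictor_vip_is_one(self, rng):
        x = rng.uniform(1, 5, 8)
        model = pls_fit(pd.DataFrame({"P1": x}), 2 * x + rng.normal(0, 0.1, 8), 1)
        assert vip_scores(model)["P1"] == pytest.approx(1.0)

    def test_sum_of_squares_equals_predictor_count(self, rng):
        for _ in range(10):
            X, y = _random_problem(rng, n=9, p=6)
            model = pls_fit(X, y, n_components=3)
            vip = vip_scores(model)
            assert float((vip ** 2).sum()) == pytest.approx(6.0, abs=1e-8)

    def test_matches_direct_formula(self, rng):
        X, y = _random_problem(rng)
        model = pls_fit(X, y, n_components=2)
        vip = vip_scores(model)
        p = len(model.feature_names)
        expected = np.sqrt(
            p * sum(model.ssy[a] * (model.weights[:, a]
                                    / np.linalg.norm(model.weights[:, a])) ** 2
                    for a in range(model.n_components)) / model.ssy.sum())
        np.testing.assert_allclose(vip.to_numpy(), expected, atol=1e-12)


class TestQ2:
    def test_noiseless_linear_response_predicts_well(self, rng):
        n, p = 12, 5
        X = rng.standard_normal((n, p))
        y = X @ np.array([1.0, -2.0, 0.5, 0.0, 0.0])
        res = cv_q2(X, y, max_components=5)
        assert res.q2 >= 0.99

    def test_pure_noise_q2_nonpositive_on_average(self):
        q2s = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((10, 8))
            y = rng.standard_normal(10)
            q2s.append(cv_q2(X, y, max_components=3).q2)
        assert np.mean(q2s) <= 0.0

    def test_plateau_rule_prefers_fewest_components(self, rng):
        n, p = 12, 4
        # near rank-one X whose single latent factor drives y: the Q2
        # profile plateaus at one component
        t = rng.standard_normal(n)
        load = rng.uniform(0.5, 1.5, p)
        X = np.outer(t, load) + 1e-6 * rng.standard_normal((n, p))
        res = cv_q2(X, t, max_components=4)
        assert res.n_components == 1
        # and the chosen A always obeys the plateau rule
        best = res.q2_by_components.max()
        assert res.q2 >= best - 0.01
        assert all(v < best - 0.01
                   for v in res.q2_by_components.loc[:res.n_components - 1])


class TestSelection:
    def test_negative_drivers_excluded_when_positive_required(self, rng):
        X, _ = _random_problem(rng, n=10, p=4)
        y = -2.0 * X["P1"].to_numpy() - 1.5 * X["P2"].to_numpy()
        model = pls_fit(X, y, n_components=2)
        vip = vip_scores(model)
        assert pls_select(model, vip, require_positive=True) == set()
        assert "P1" in pls_select(model, vip, require_positive=False)

    def test_zero_noise_planted_positive_drivers_recovered_exactly(self):
        # enough batches that chance in-sample correlation of null peaks
        # stays below the VIP threshold
        spec = SyntheticSpec(n_batches=30, n_peaks=8, n_active=3, noise_sd=0.0,
                             batch_effect_sd=0.0, endpoints=("frap",), seed=5)
        matrix, effects, truth = gen_spectrum_effect(spec)
        res = pls_screen(matrix.areas, effects.activity["frap"])
        assert res.selected == set(truth.active_peak_ids["frap"])

    def test_planted_peaks_outscore_all_others(self, small_clean_dataset):
        (matrix, effects, truth), _ = small_clean_dataset
        res = pls_screen(matrix.areas, effects.activity["frap"])
        planted = set(truth.active_peak_ids["frap"])
        others = set(matrix.peak_ids) - planted
        assert res.vip[sorted(planted)].min() > res.vip[sorted(others)].max()
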