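import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit, logsumexp

from dtscoring import (INDIVIDUAL_RATERS, ModelSpec, RaterIRT, RaterParams,
                       category_probs, compare_models, eap_scores,
                       grm_cumulative, item_information, marginal_loglik,
                       sample_grm_rating, tif)
from dtscoring.irt import _loglik_rows, quadrature


def simulate_ratings(raters, theta, seed):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({p.rater_id: sample_grm_rating(p, theta, rng)
                         for p in raters}).astype(float)


def fine_grid_posterior(params_list, X, n=100_001, lo=-8.0, hi=8.0):
    """Brute-force Riemann/trapezoid oracle for EAP and marginal loglik."""
    grid = np.linspace(lo, hi, n)
    logw = -0.5 * grid ** 2
    logw -= logsumexp(logw)
    L = _loglik_rows(params_list, np.asarray(X, dtype=float), grid)
    ll = logsumexp(L + logw, axis=1)
    post = np.exp(L + logw - ll[:, None])
    return post @ grid, ll


class TestGrmProbabilities:
    def test_logistic_symmetry(self):
        assert grm_cumulative(1.0, [0.0], 0.0)[0] == pytest.approx(0.5)

    def test_preset_rater_boundary(self):
        # a=2.26, d1=1.83 at theta=0: P*2 = logistic(1.83)
        p = grm_cumulative(2.26, [1.83, -0.87, -3.12, -5.48], 0.0)
        assert p[0] == pytest.approx(expit(1.83))
        assert p[0] == pytest.approx(0.8617617, abs=1e-6)

    def test_limits(self):
        lo = grm_cumulative(2.0, [1.0, 0.0, -1.0], -50.0)
        hi = grm_cumulative(2.0, [1.0, 0.0, -1.0], 50.0)
        assert np.allclose(lo, 0) and np.allclose(hi, 1)

    def test_category_one_from_boundary(self):
        p = category_probs(INDIVIDUAL_RATERS[0], np.array([0.0]))[0]
        assert p[0] == pytest.approx(1 - expit(1.83), abs=1e-7)

    def test_gpcm_balanced_steps_uniform(self):
        params = RaterParams("g", 1.7, b=(0.0, 0.0, 0.0, 0.0), family="gpcm")
        p = category_probs(params, np.array([0.0]))[0]
        assert np.allclose(p, 0.2)

    @given(st.integers(0, 10_000))
    @settings(max_examples=200, deadline=None)
    def test_normalization_fuzz(self, seed):
        rng = np.random.default_rng(seed)
        K = int(rng.integers(2, 7))
        a = float(rng.uniform(0, 4))
        theta = rng.uniform(-5, 5, size=3)
        if rng.random() < 0.5:
            d = np.sort(rng.uniform(-6, 6, K - 1))[::-1]
            if rng.random() < 0.3:           # unsorted intercepts stay valid
                rng.shuffle(d)
            params = RaterParams("x", a, d=tuple(d))
        else:
            params = RaterParams("x", a, b=tuple(rng.uniform(-4, 4, K - 1)),
                                 family="gpcm")
        p = category_probs(params, theta)
        assert np.all(p >= 0)
        assert np.allclose(p.sum(axis=-1), 1.0, atol=1e-12)


class TestMarginalLoglik:
    def test_zero_slope_collapses_integral(self):
        params = RaterParams("flat", 0.0, d=(1.0, 0.0, -1.0, -2.0))
        X = pd.DataFrame({"flat": [3.0]})
        expected = np.log(category_probs(params, np.array([0.0]))[0][2])
        assert marginal_loglik([params], X) == pytest.approx(expected, abs=1e-12)

    def test_fine_grid_oracle(self):
        theta = np.random.default_rng(3).standard_normal(100)
        X = simulate_ratings(INDIVIDUAL_RATERS, theta, 4)
        X = X.mask(np.random.default_rng(5).random(X.shape) < 0.25)
        ll_quad = marginal_loglik(list(INDIVIDUAL_RATERS), X, per_unit=True)
        _, ll_oracle = fine_grid_posterior(list(INDIVIDUAL_RATERS), X)
        assert np.max(np.abs(ll_quad - ll_oracle)) < 1e-6

    def test_all_missing_unit_contributes_nothing(self):
        X = pd.DataFrame({"R1": [3.0, np.nan], "R2": [4.0, np.nan],
                          "R3": [3.0, np.nan]})
        with_row = marginal_loglik(list(INDIVIDUAL_RATERS), X)
        without = marginal_loglik(list(INDIVIDUAL_RATERS), X.iloc[:1])
        assert with_row == pytest.approx(without, abs=1e-12)


class TestEap:
    def test_all_missing_gets_prior(self):
        X = pd.DataFrame({"R1": [np.nan], "R2": [np.nan], "R3": [np.nan]})
        ab = eap_scores(list(INDIVIDUAL_RATERS), X)
        assert ab.theta_eap.iloc[0] == pytest.approx(0.0, abs=1e-10)
        assert ab.psd.iloc[0] == pytest.approx(1.0, abs=1e-6)

    def test_monotone_in_ratings(self):
        X = pd.DataFrame({"R1": [3.0, 4.0], "R2": [3.0, 4.0], "R3": [3.0, 4.0]})
        ab = eap_scores(list(INDIVIDUAL_RATERS), X)
        assert ab.theta_eap.iloc[1] > ab.theta_eap.iloc[0]

    def test_psd_within_prior_bound(self, small_grm):
        model, wide = small_grm
        ab = model.eap(wide)
        assert ((ab.psd > 0) & (ab.psd <= 1.0 + 1e-9)).all()

    def test_fine_grid_oracle(self):
        theta = np.random.default_rng(8).standard_normal(60)
        X = simulate_ratings(INDIVIDUAL_RATERS, theta, 9)
        ab = eap_scores(list(INDIVIDUAL_RATERS), X)
        oracle, _ = fine_grid_posterior(list(INDIVIDUAL_RATERS), X)
        assert np.max(np.abs(ab.theta_eap.to_numpy() - oracle)) < 1e-4


class TestInformation:
    def test_binary_closed_form(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            a, d, theta = rng.uniform(0.2, 3), rng.uniform(-3, 3), rng.uniform(-4, 4)
            params = RaterParams("b", a, d=(d,))
            p = expit(a * theta + d)
            assert item_information(params, theta) == pytest.approx(
                a ** 2 * p * (1 - p), rel=1e-10)

    def test_tif_additivity(self):
        grid = np.linspace(-3, 3, 61)
        total = tif(list(INDIVIDUAL_RATERS), grid)
        parts = sum(item_information(p, grid) for p in INDIVIDUAL_RATERS)
        assert np.allclose(total, parts)
        assert np.all(total >= 0)

    def test_individual_preset_peak_location(self):
        grid = np.arange(-4.0, 4.0001, 0.01)
        curve = tif(list(INDIVIDUAL_RATERS), grid)
        assert round(grid[np.argmax(curve)], 1) == 0.5


class TestFit:
    def test_recovery_from_presets(self):
        theta = np.random.default_rng(21).standard_normal(4000)
        X = simulate_ratings(INDIVIDUAL_RATERS, theta, 22)
        m = RaterIRT(family="grm", K=5).fit(X)
        assert m.converged_
        # single-seed sampling error in a-hat is ~0.12 at this n
        for true, est in zip(INDIVIDUAL_RATERS, m.rater_params_):
            assert est.a == pytest.approx(true.a, abs=0.4)
        td = np.concatenate([p.d for p in INDIVIDUAL_RATERS])
        ed = np.concatenate([p.d for p in m.rater_params_])
        assert np.corrcoef(td, ed)[0, 1] > 0.95

    def test_information_criteria_identities(self, small_grm):
        m, _ = small_grm
        assert m.aic_ == pytest.approx(-2 * m.loglik_ + 2 * m.n_params_, abs=1e-9)
        assert m.bic_ == pytest.approx(
            -2 * m.loglik_ + m.n_params_ * np.log(m.n_units_), abs=1e-9)

    @pytest.mark.parametrize("family,expected", [
        ("grm", 15), ("cgrm", 13), ("grsm", 9), ("cgrsm", 7),
        ("pcm", 12), ("gpcm", 15), ("rsm", 6)])
    def test_parameter_counts(self, small_grm, family, expected):
        """Documented free-parameter counts for J=3 raters, K=5."""
        _, wide = small_grm
        m = RaterIRT(family=family, K=5, max_iter=30).fit(wide)
        assert m.n_params_ == expected

    def test_nesting_partial_order(self, small_study):
        from dtscoring import to_wide
        wide = to_wide(small_study.individual_table)
        ll = {f: RaterIRT(family=f, K=5).fit(wide).loglik_
              for f in ("grm", "cgrm", "grsm", "cgrsm", "gpcm", "pcm", "rsm")}
        tol = 1e-4
        assert ll["grm"] >= ll["cgrm"] - tol
        assert ll["grm"] >= ll["grsm"] - tol
        assert ll["cgrm"] >= ll["cgrsm"] - tol
        assert ll["grsm"] >= ll["cgrsm"] - tol
        assert ll["gpcm"] >= ll["pcm"] - tol
        assert ll["pcm"] >= ll["rsm"] - tol

    def test_loglik_ascent_trace(self, small_grm):
        m, _ = small_grm
        trace = np.asarray(m.loglik_trace_)
        assert np.all(np.diff(trace) >= -1e-8)

    def test_single_category_rater_dropped(self):
        X = pd.DataFrame({"r1": [1, 2, 3, 4, 5] * 20,
                          "r2": [2, 3, 3, 4, 5] * 20,
                          "r3": [3.0] * 100})
        with pytest.warns(UserWarning, match="dropped"):
            m = RaterIRT(family="grm", K=5).fit(X)
        assert m.dropped_raters_ == ["r3"]
        assert len(m.rater_params_) == 2

    def test_empty_category_collapsed(self):
        rng = np.random.default_rng(31)
        theta = rng.standard_normal(500)
        X = simulate_ratings(INDIVIDUAL_RATERS[:2], theta, 32)
        X["R1"] = X["R1"].clip(upper=4)  # rater never awards a 5
        m = RaterIRT(family="grm", K=5).fit(X)
        assert "R1" in m.collapsed_
        assert m.rater_params_[0].n_categories == len(m.collapsed_["R1"])

    def test_severity_shift_lowers_expected_rating(self):
        base = INDIVIDUAL_RATERS[0]
        severe = RaterParams(base.rater_id, base.a,
                             d=tuple(np.asarray(base.d) - 1.0))
        grid = np.linspace(-3, 3, 31)
        k = np.arange(1, 6)
        e_base = category_probs(base, grid) @ k
        e_severe = category_probs(severe, grid) @ k
        assert np.all(e_severe < e_base)


class TestCompareModels:
    def test_table_contract(self, small_grm):
        _, wide = small_grm
        specs = [ModelSpec(f, 5, max_iter=60) for f in ("grm", "cgrm", "rsm")]
        table = compare_models(specs, wide)
        assert len(table) == 3
        assert table["aic"].is_monotonic_increasing
        assert table["aic_best"].sum() == 1 and table["bic_best"].sum() == 1
        assert table.loc[0, "aic_best"]

    def test_deterministic_rerun(self, small_grm):
        _, wide = small_grm
        specs = [ModelSpec(f, 5, max_iter=60) for f in ("grm", "cgrm")]
        a = compare_models(specs, wide).drop(columns=["error"])
        b = compare_models(specs, wide).drop(columns=["error"])
        pd.testing.assert_frame_equal(a, b)

    def test_equal_slope_data_prefers_constrained(self):
        """AIC selects the constrained GRM on equal-slope data (most seeds)."""
        shared = [RaterParams(f"r{j}", 1.8, d=tuple(np.array([2.2, 0.8, -0.8, -2.2])
                                                    - 0.4 * j))
                  for j in range(3)]
        wins = 0
        for seed in range(10):
            theta = np.random.default_rng(100 + seed).standard_normal(3000)
            X = simulate_ratings(shared, theta, 200 + seed)
            table = compare_models([ModelSpec("cgrm", 5), ModelSpec("grm", 5)], X)
            by = table.set_index("family")
            if by.loc["cgrm", "aic"] <= by.loc["grm", "aic"]:
                wins += 1
        assert wins >= 8
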