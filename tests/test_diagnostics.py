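import numpy as np
import pandas as pd
import pytest

from dtscoring import INDIVIDUAL_RATERS, RaterIRT, category_probs, sample_grm_rating
from dtscoring.diagnostics import icc_3k, infit_outfit, jcc, parallel_analysis


class TestInfitOutfit:
    def test_brute_force_two_unit_oracle(self, small_grm):
        model, _ = small_grm
        X = pd.DataFrame({"R1": [2.0, 4.0], "R2": [3.0, 5.0], "R3": [2.0, 4.0]})
        stats = infit_outfit(model, X)
        theta = model.eap(X).theta_eap.to_numpy()
        for j, params in enumerate(model.rater_params_):
            num_out, num_res, num_w = [], [], []
            for i in range(2):
                p = category_probs(params, np.array([theta[i]]))[0]
                k = np.arange(1, 6)
                E = float(p @ k)
                W = float(p @ k ** 2 - E ** 2)
                x = X.iloc[i, j]
                num_out.append((x - E) ** 2 / W)
                num_res.append((x - E) ** 2)
                num_w.append(W)
            assert stats.iloc[j]["outfit"] == pytest.approx(np.mean(num_out), abs=1e-10)
            assert stats.iloc[j]["infit"] == pytest.approx(
                np.sum(num_res) / np.sum(num_w), abs=1e-10)

    def test_model_true_statistics_moderate(self, small_grm):
        """Statistics on model-consistent data stay in a sane band (EAP
        shrinkage pulls the mean-squares somewhat below 1)."""
        model, wide = small_grm
        stats = infit_outfit(model, wide)
        assert ((stats["outfit"] > 0.4) & (stats["outfit"] < 1.2)).all()
        assert ((stats["infit"] > 0.4) & (stats["infit"] < 1.2)).all()

    def test_noise_rater_flagged_against_clean_fit(self, small_grm):
        model, wide = small_grm
        rng = np.random.default_rng(17)
        noisy = wide.values.copy()
        noisy["R2"] = rng.integers(1, 6, len(noisy)).astype(float)
        stats = infit_outfit(model, noisy)
        assert stats.loc["R2", "outfit"] > 1.4
        assert not stats.loc["R2", "acceptable"]


class TestJcc:
    def test_preset_rater_sorted(self, small_grm):
        curves = jcc(list(INDIVIDUAL_RATERS), "R1")
        assert curves.attrs["sorted"]
        probs = curves.drop(columns=["theta"]).to_numpy()
        assert np.allclose(probs.sum(axis=1), 1.0)

    def test_unsorted_intercepts_flagged(self):
        from dtscoring import RaterParams
        params = RaterParams("bad", 1.5, d=(1.0, 2.0, 0.0, -1.0))
        curves = jcc([params], "bad")
        assert not curves.attrs["sorted"]


class TestParallelAnalysis:
    def test_independent_noise_retains_nothing(self):
        rng = np.random.default_rng(3)
        data = pd.DataFrame(rng.standard_normal((500, 5)))
        report = parallel_analysis(data, n_sim=50, seed=1)
        assert report.n_retained <= 1
        assert report.ratio_1_2 < 2

    def test_strong_one_factor_structure(self):
        rng = np.random.default_rng(4)
        f = rng.standard_normal((600, 1))
        data = pd.DataFrame(0.8 * f + 0.6 * rng.standard_normal((600, 5)))
        report = parallel_analysis(data, n_sim=50, seed=2)
        assert report.n_retained == 1
        assert report.ratio_1_2 > 4

    def test_rank_one_degenerate(self):
        rng = np.random.default_rng(5)
        col = rng.standard_normal(100)
        data = pd.DataFrame({f"r{j}": col for j in range(4)})
        report = parallel_analysis(data, n_sim=20, seed=3)
        assert report.ratio_1_2 > 1e6

    def test_invariance_to_column_order_and_scale(self):
        rng = np.random.default_rng(6)
        f = rng.standard_normal((300, 1))
        data = pd.DataFrame(0.7 * f + 0.7 * rng.standard_normal((300, 4)),
                            columns=list("abcd"))
        base = parallel_analysis(data, n_sim=30, seed=7)
        shuffled = data[["c", "a", "d", "b"]].copy()
        shuffled["a"] = 5.0 * shuffled["a"] - 3.0
        alt = parallel_analysis(shuffled, n_sim=30, seed=7)
        assert np.allclose(base.eigenvalues, alt.eigenvalues)
        assert base.n_retained == alt.n_retained

    def test_too_few_complete_rows_rejected(self):
        data = pd.DataFrame(np.random.default_rng(0).standard_normal((8, 4)))
        with pytest.raises(ValueError, match="complete"):
            parallel_analysis(data)


class TestIcc3k:
    def test_identical_raters_give_one(self):
        col = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        icc, _ = icc_3k(pd.DataFrame({"a": col, "b": col, "c": col}))
        assert icc == pytest.approx(1.0)

    def test_brute_force_anova_oracle(self):
        X = np.array([[1, 2, 3], [2, 2, 4], [3, 4, 4], [5, 4, 5]], dtype=float)
        icc, _ = icc_3k(pd.DataFrame(X))
        n, k = X.shape
        grand = X.mean()
        ss_rows = k * ((X.mean(axis=1) - grand) ** 2).sum()
        ss_cols = n * ((X.mean(axis=0) - grand) ** 2).sum()
        ss_err = ((X - grand) ** 2).sum() - ss_rows - ss_cols
        ms_rows = ss_rows / (n - 1)
        ms_err = ss_err / ((n - 1) * (k - 1))
        assert icc == pytest.approx((ms_rows - ms_err) / ms_rows, abs=1e-10)

    def test_against_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(11)
        f = rng.standard_normal((25, 1))
        X = pd.DataFrame(f + 0.5 * rng.standard_normal((25, 4)),
                         columns=[f"r{j}" for j in range(4)])
        icc, ci = icc_3k(X)
        long = X.reset_index().melt(id_vars="index", var_name="rater",
                                    value_name="score")
        ref = pingouin.intraclass_corr(long, targets="index", raters="rater",
                                       ratings="score")
        row = ref[ref["Type"] == "ICC(C,k)"].iloc[0]
        assert icc == pytest.approx(row["ICC"], abs=1e-8)
        ci_col = "CI95%" if "CI95%" in ref.columns else "CI95"
        assert ci[0] == pytest.approx(row[ci_col][0], abs=6e-3)
        assert ci[1] == pytest.approx(row[ci_col][1], abs=6e-3)

    def test_permuted_raters_near_zero(self):
        """Permuting each rater's column destroys the ICC; a single draw
        at N=200 has SD ~0.14 so the null check averages a few seeds."""
        vals = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            f = rng.standard_normal((200, 1))
            X = f + 0.4 * rng.standard_normal((200, 3))
            for j in range(3):  # destroy row alignment
                X[:, j] = rng.permutation(X[:, j])
            vals.append(icc_3k(pd.DataFrame(X))[0])
        assert abs(np.mean(vals)) < 0.15

    def test_zero_row_variance_rejected(self):
        X = pd.DataFrame({"a": [2.0, 2.0, 2.0], "b": [3.0, 3.0, 3.0]})
        with pytest.raises(ValueError, match="ICC"):
            icc_3k(X)


def test_model_true_simulation_calibration_roster():
    """Mean-squares concentrate near 1 when no rater dominates the EAP."""
    from dtscoring import RaterParams
    raters = [RaterParams(f"J{j+1}", 0.7,
                          d=tuple(np.array([2.0, 0.7, -0.7, -2.0]) + 0.3 * (j - 3)))
              for j in range(6)]
    rng = np.random.default_rng(0)
    theta = rng.standard_normal(2000)
    X = pd.DataFrame({p.rater_id: sample_grm_rating(p, theta, rng)
                      for p in raters}).astype(float)
    model = RaterIRT(family="grm", K=5).fit(X)
    stats = infit_outfit(model, X)
    assert ((stats["outfit"] > 0.8) & (stats["outfit"] < 1.2)).all()
    assert ((stats["infit"] > 0.8) & (stats["infit"] < 1.2)).all()
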