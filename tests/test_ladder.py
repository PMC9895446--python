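"""Model ladders: OLS engine, BIC convention, Bayes factors, diagnostics."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from langexp.ladder import (
    ModelSpec,
    VocabularyLadder,
    bf_from_bic,
    bic,
    cohens_f2,
    evidence_label,
    fit_ols,
    ks_residual_normality,
    outlier_filter,
    run_h3_ladder,
    standardize_for_report,
)


def toy_frame(n=60, seed=0, beta_x=0.0, sigma=1.0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    z = rng.normal(size=n)
    y = 1.0 + 0.5 * z + beta_x * x + rng.normal(0, sigma, n)
    return pd.DataFrame({"y": y, "x": x, "z": z})


def spec(terms=("x",), covariates=("z",), name="m"):
    return ModelSpec(
        name=name, outcome="y", covariates=covariates, index_terms=terms
    )


class TestFitOls:
    def test_noise_free_fit_is_exact(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"y": 2 + 3 * x, "x": x})
        fit = fit_ols(df, spec(covariates=("x",), terms=()))
        assert fit.params["Intercept"] == pytest.approx(2.0)
        assert fit.params["x"] == pytest.approx(3.0)
        assert fit.rsquared == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        # textbook (X'X)^-1 X'y on a 6-case hand dataset
        df = pd.DataFrame(
            {
                "y": [1.0, 2.0, 1.5, 3.0, 2.5, 4.0],
                "x": [0.0, 1.0, 0.5, 2.0, 1.5, 3.0],
                "z": [1.0, 0.0, 1.0, 0.0, 1.0, 0.0],
            }
        )
        fit = fit_ols(df, spec())
        X = np.column_stack([np.ones(6), df["z"], df["x"]])
        beta = np.linalg.solve(X.T @ X, X.T @ df["y"].to_numpy())
        assert fit.params["Intercept"] == pytest.approx(beta[0], abs=1e-10)
        assert fit.params["z"] == pytest.approx(beta[1], abs=1e-10)
        assert fit.params["x"] == pytest.approx(beta[2], abs=1e-10)

    def test_null_slope_t_statistic_calibration(self):
        hits = 0
        for seed in range(200):
            fit = fit_ols(toy_frame(n=200, seed=seed), spec())
            hits += abs(fit.tvalues["x"]) < 1.96
        assert 0.90 <= hits / 200 <= 0.99

    def test_duplicated_column_raises_rank_error(self):
        df = toy_frame()
        df["x2"] = df["x"]
        with pytest.raises(ValueError, match="rank"):
            fit_ols(df, spec(terms=("x", "x2")))

    def test_missing_values_list_case_ids(self):
        df = toy_frame(n=20)
        df.loc[3, "x"] = np.nan
        with pytest.raises(ValueError, match="3"):
            fit_ols(df, spec())

    def test_categorical_treatment_coding(self):
        df = toy_frame(n=30)
        df["g"] = ["b", "a", "c"] * 10
        fit = fit_ols(df, spec(terms=(), covariates=("g",)))
        # lexicographic: 'a' is the reference level
        assert "g[T.b]" in fit.params.index
        assert "g[T.c]" in fit.params.index
        assert "g[T.a]" not in fit.params.index


class TestBic:
    def test_hand_arithmetic_intercept_only(self):
        df = pd.DataFrame({"y": [0.0, 1.0, 2.0, 3.0], "x": [0.0, 1.0, 2.0, 3.0]})
        fit = fit_ols(df, spec(terms=(), covariates=()))
        rss = float(((df["y"] - df["y"].mean()) ** 2).sum())
        assert fit.rss == pytest.approx(rss)
        assert bic(fit) == pytest.approx(4 * np.log(rss / 4) + 2 * np.log(4))

    def test_equal_fits_equal_bic(self):
        f1 = fit_ols(toy_frame(seed=5), spec())
        f2 = fit_ols(toy_frame(seed=5), spec())
        assert bic(f1) == bic(f2)

    def test_useless_regressor_increases_bic(self):
        wins = 0
        for seed in range(40):
            df = toy_frame(n=500, seed=seed)
            full = fit_ols(df, spec())
            red = fit_ols(df, spec(terms=()))
            wins += bic(full) > bic(red)
        assert wins >= 38

    def test_zero_rss_raises(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"y": 2 + 3 * x, "x": x})
        fit = fit_ols(df, spec(covariates=("x",), terms=()))
        with pytest.raises(ValueError):
            bic(fit)

    def test_delta_bic_matches_statsmodels(self):
        # conventions differ by constants that cancel in differences
        df = toy_frame(n=120, seed=2, beta_x=0.4)
        full = fit_ols(df, spec())
        red = fit_ols(df, spec(terms=()))
        X_full = sm.add_constant(df[["z", "x"]])
        X_red = sm.add_constant(df[["z"]])
        sm_delta = (
            sm.OLS(df["y"], X_full).fit().bic - sm.OLS(df["y"], X_red).fit().bic
        )
        assert (full.bic - red.bic) == pytest.approx(sm_delta, abs=1e-8)


class TestBayesFactors:
    def test_equal_bic_gives_unity(self):
        assert bf_from_bic(10.0, 10.0) == 1.0

    def test_delta_six_is_about_twenty(self):
        assert bf_from_bic(6.0, 0.0) == pytest.approx(np.exp(3), abs=1e-12)
        assert bf_from_bic(6.0, 0.0) == pytest.approx(20.09, abs=0.01)

    def test_reciprocal_symmetry(self):
        assert bf_from_bic(3.0, 7.0) * bf_from_bic(7.0, 3.0) == pytest.approx(1.0)

    def test_chain_consistency(self):
        b0, b1, b3 = 12.0, 9.5, 4.25
        assert bf_from_bic(b0, b3) == pytest.approx(
            bf_from_bic(b1, b3) * bf_from_bic(b0, b1)
        )

    @pytest.mark.parametrize(
        "bf, label",
        [
            (1.5, "anecdotal"),
            (5.0, "positive"),
            (25.0, "strong"),
            (200.0, "very strong"),
            (0.2, "for null: positive"),
        ],
    )
    def test_evidence_labels(self, bf, label):
        assert evidence_label(bf) == label


class TestCohensF2:
    def test_zero_when_no_gain(self):
        df = toy_frame(seed=1)
        f = fit_ols(df, spec())
        assert cohens_f2(f, f) == 0.0

    def test_direct_formula(self):
        a = fit_ols(toy_frame(n=80, seed=3, beta_x=1.0), spec())
        b = fit_ols(toy_frame(n=80, seed=3, beta_x=1.0), spec(terms=()))
        expected = (a.rsquared - b.rsquared) / (1 - a.rsquared)
        assert cohens_f2(a, b) == pytest.approx(expected)

    def test_simulated_effect_size_recovered(self):
        # generating f2 = 0.10 at n=144: estimates stay in a plausible band
        vals = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=144)
            z = rng.normal(size=144)
            y = 0.5 * z + np.sqrt(0.10) * x + rng.normal(size=144)
            df = pd.DataFrame({"y": y, "x": x, "z": z})
            vals.append(cohens_f2(fit_ols(df, spec()), fit_ols(df, spec(terms=()))))
        assert 0.03 <= np.median(vals) <= 0.20


class TestLadders:
    def test_redundant_distance_regressor_rejected(self):
        # all-zero L2 distances: m2 adds nothing over m1
        rng = np.random.default_rng(7)
        n = 80
        df = pd.DataFrame(
            {
                "receptive_score": rng.normal(100, 10, n),
                "exposure_english": rng.uniform(0.5, 1.0, n),
                "l2_distance": np.zeros(n),
                "age_years": rng.uniform(5, 6.4, n),
                "gender": list("fm" * (n // 2)),
                "ses_years": rng.normal(17, 2, n),
                "nonverbal_score": rng.normal(100, 15, n),
            }
        )
        with pytest.raises(ValueError, match="rank"):
            run_h3_ladder(df, "receptive_score")

    def test_near_constant_distance_gives_no_m2_evidence(self):
        rng = np.random.default_rng(7)
        n = 80
        df = pd.DataFrame(
            {
                "receptive_score": rng.normal(100, 10, n),
                "exposure_english": rng.uniform(0.5, 1.0, n),
                "l2_distance": rng.normal(0.9, 1e-6, n),
                "age_years": rng.uniform(5, 6.4, n),
                "gender": list("fm" * (n // 2)),
                "ses_years": rng.normal(17, 2, n),
                "nonverbal_score": rng.normal(100, 15, n),
            }
        )
        res = run_h3_ladder(df, "receptive_score")
        assert res.bf10("m2", "m1") < 1.0

    def test_ladder_chain_identity_and_report_shape(self, cohort_small):
        from langexp.exposure import english_majority_filter, index_table
        from langexp.ladder import run_h2_ladder
        from langexp.synth import synth_outcomes

        profiles, D = cohort_small
        synth_outcomes(profiles, D, index="exposure_english", f2=0.1, seed=0)
        kept, _ = english_majority_filter(profiles)
        tbl = index_table(kept, D).dropna(subset=["receptive_score"])
        res = run_h2_ladder(tbl, "receptive_score")
        assert res.bf10("m3", "m0") == pytest.approx(
            res.bf10("m3", "m1") * res.bf10("m1", "m0")
        )
        frame = res.to_frame()
        assert {"model", "beta", "t", "DF", "p", "delta_R2", "BF10"} <= set(
            frame.columns
        )
        assert "m3" in res.summary()


class TestDiagnostics:
    def test_ks_conservative_under_normality(self):
        # standardizing by the sample mean/SD without a Lilliefors
        # correction makes the test conservative: false-rejection rate
        # stays at or below the nominal level, p-values skew high
        ps = np.array([
            ks_residual_normality(
                fit_ols(toy_frame(n=150, seed=seed), spec())
            )
            for seed in range(100)
        ])
        assert np.mean(ps < 0.05) <= 0.05
        assert np.mean(ps) > 0.5
        assert ps.min() < ps.max()

    def test_ks_detects_heavy_tails(self):
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            df = toy_frame(n=150, seed=seed)
            df["y"] = df["z"] * 0.5 + rng.standard_t(2, size=150)
            hits += ks_residual_normality(fit_ols(df, spec())) < 0.05
        assert hits > 20

    def test_ks_degenerate_residuals_raise(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"y": 2 + 3 * x, "x": x})
        fit = fit_ols(df, spec(covariates=("x",), terms=()))
        with pytest.raises(ValueError):
            ks_residual_normality(fit)

    def test_outlier_filter_masks_only_the_extreme_point(self):
        rng = np.random.default_rng(0)
        scores = np.append(rng.normal(0, 1, 100), 10.0)
        mask = outlier_filter(scores)
        assert not mask[-1]
        assert mask[:-1].all()

    def test_outlier_filter_identical_values_warns_keeps_all(self):
        with pytest.warns(UserWarning):
            assert outlier_filter(np.ones(10)).all()

    def test_outlier_boundary_exactly_three_sd_retained(self):
        scores = np.array([-1.0, 1.0] * 50)
        z3 = scores.mean() + 3 * scores.std(ddof=1)
        mask = outlier_filter(np.append(scores, z3))
        assert mask[-1]

    def test_standardize_for_report(self):
        x = np.array([-1.0, 0.0, 1.0])
        out = standardize_for_report(x)
        assert out.mean() == pytest.approx(100.0, abs=1e-9)
        assert out.std(ddof=1) == pytest.approx(15.0)
        y = 3.0 * np.random.default_rng(1).normal(size=50) + 7
        out = standardize_for_report(y)
        assert out.mean() == pytest.approx(100.0, abs=1e-9)
        assert np.all(np.argsort(out) == np.argsort(y))
        with pytest.raises(ValueError):
            standardize_for_report(np.ones(5))
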