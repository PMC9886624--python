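"""Linear association stage: OLS, FDR screen, stratified GRS models."""
import logging

import numpy as np
import pandas as pd
import pytest

from vdgrs.association import (
    CohortTable,
    SingularDesignError,
    VitaminDGrsModel,
    adjusted_r2_delta,
    bh_adjust,
    fit_linear_model,
    genotype_distribution_test,
    grs_association,
    screen_predictors,
)
from vdgrs.score import score_cohort
from vdgrs.simulate import simulate_cohort, study_preset, ukb_preset
from vdgrs.weights import packaged_weight_table


def _cohort_frame(n=200, seed=0, **overrides):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "sample_id": [f"S{i}" for i in range(n)],
            "vd_level": rng.normal(50, 20, n),
            "supplementing": rng.random(n) < 0.5,
            "bmi": rng.normal(27, 4, n),
            "age": rng.normal(55, 8, n),
            "sex": rng.choice(["F", "M"], n),
            "ms_status": rng.random(n) < 0.5,
            "grs_z": rng.normal(0, 1, n),
        }
    )
    df["dose"] = np.where(df["supplementing"], 800.0, 0.0)
    for k, v in overrides.items():
        df[k] = v
    return df


class TestCohortTable:
    def test_dose_implies_supplementing(self):
        df = _cohort_frame(10)
        df.loc[0, "supplementing"] = False
        df.loc[0, "dose"] = 400.0
        with pytest.raises(ValueError, match="dose"):
            CohortTable(df)

    def test_duplicate_ids_rejected(self):
        df = _cohort_frame(10)
        df.loc[1, "sample_id"] = "S0"
        with pytest.raises(ValueError, match="duplicate"):
            CohortTable(df)

    def test_vd_z_and_log_dose_derived(self):
        t = CohortTable(_cohort_frame(50))
        assert t.frame["vd_z"].mean() == pytest.approx(0, abs=1e-9)
        assert t.frame["vd_z"].std(ddof=1) == pytest.approx(1)
        assert t.frame.loc[t.frame["supplementing"], "log_dose"].iloc[0] == pytest.approx(np.log1p(800))


class TestFitLinearModel:
    def test_noise_free_fit_is_exact(self):
        df = _cohort_frame(100, seed=1)
        df["vd_z"] = 2.0 * df["grs_z"]
        table, fit = fit_linear_model(df, "vd_z", ["grs_z"])
        assert table.iloc[0]["estimate"] == pytest.approx(2.0)
        assert fit.rsquared == pytest.approx(1.0)

    def test_orthogonal_covariate_leaves_estimate_unchanged(self):
        rng = np.random.default_rng(2)
        n = 400
        x = rng.normal(size=n)
        w = rng.normal(size=n)
        w -= np.polyfit(x, w, 1)[0] * x  # make w exactly orthogonal to x
        w -= w.mean()
        df = pd.DataFrame({"y": 1.5 * x + rng.normal(size=n), "x": x, "w": w})
        est_alone = fit_linear_model(df, "y", ["x"])[0].iloc[0]["estimate"]
        with_w = fit_linear_model(df, "y", ["x", "w"])[0]
        est_adj = with_w[with_w["term"] == "x"]["estimate"].iloc[0]
        assert est_adj == pytest.approx(est_alone, abs=1e-10)

    def test_recovers_known_coefficients_within_3se(self):
        rng = np.random.default_rng(3)
        n = 2000
        df = pd.DataFrame({"x1": rng.normal(size=n), "x2": rng.normal(size=n)})
        truth = {"x1": 0.3, "x2": -0.7}
        df["y"] = truth["x1"] * df.x1 + truth["x2"] * df.x2 + rng.normal(size=n)
        table, _ = fit_linear_model(df, "y", ["x1", "x2"])
        for _, r in table.iterrows():
            assert abs(r["estimate"] - truth[r["term"]]) < 3 * r["se"]

    def test_ols_matches_normal_equations(self):
        """Estimates equal the brute-force (X'X)^-1 X'y solution."""
        rng = np.random.default_rng(4)
        for _ in range(5):
            n, k = 60, 3
            X = rng.normal(size=(n, k))
            y = rng.normal(size=n)
            df = pd.DataFrame(X, columns=["a", "b", "c"])
            df["y"] = y
            table, _ = fit_linear_model(df, "y", ["a", "b", "c"])
            Xd = np.column_stack([np.ones(n), X])
            beta = np.linalg.solve(Xd.T @ Xd, Xd.T @ y)
            got = table.set_index("term")["estimate"]
            np.testing.assert_allclose(got[["a", "b", "c"]], beta[1:], atol=1e-10)

    def test_singular_design_raises(self):
        df = CohortTable(_cohort_frame(50)).frame
        df["dup"] = df["grs_z"]
        with pytest.raises(SingularDesignError):
            fit_linear_model(df, "vd_z", ["grs_z", "dup"])

    def test_complete_case_exclusions(self):
        df = CohortTable(_cohort_frame(50)).frame
        df.loc[:4, "grs_z"] = np.nan
        table, fit = fit_linear_model(df, "vd_z", ["grs_z"])
        assert table.iloc[0]["n"] == 45


class TestBenjaminiHochberg:
    def test_hand_computed_step_up(self):
        p = [0.001, 0.01, 0.02, 0.04, 0.8]
        np.testing.assert_allclose(bh_adjust(p), [0.005, 0.025, 0.02 * 5 / 3, 0.05, 0.8])

    def test_constant_pvalues(self):
        np.testing.assert_allclose(bh_adjust([0.05] * 4), [0.05] * 4)

    def test_single_test_q_equals_p(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_q_dominates_p_and_is_monotone(self):
        rng = np.random.default_rng(0)
        p = rng.random(30)
        q = bh_adjust(p)
        assert (q >= p - 1e-12).all() and (q <= 1).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestScreenPredictors:
    def test_study_simulation_flags_behavioural_predictors(self):
        matrix, cohort = simulate_cohort(study_preset(seed=11))
        cohort = cohort.with_scores(score_cohort(matrix, packaged_weight_table()))
        screen = screen_predictors(cohort)
        flagged = set(screen.loc[screen["pass_fdr"], "term"])
        assert {"supplementing", "log_dose", "bmi", "ms_status"} <= flagged
        assert (screen["q"] >= screen["p"] - 1e-12).all()


@pytest.fixture(scope="module")
def scored_study_cohort():
    matrix, cohort = simulate_cohort(study_preset(seed=21))
    return cohort.with_scores(score_cohort(matrix, packaged_weight_table()))


class TestGrsAssociation:
    def test_three_strata_reported(self, scored_study_cohort):
        table = grs_association(scored_study_cohort)
        assert set(table["stratum"]) == {"all", "supplementers", "non_supplementers"}
        sub = table[table["stratum"] == "supplementers"]
        assert "supplementing" not in set(sub["term"])

    def test_titration_mode_nulls_supplementer_stratum(self, scored_study_cohort):
        table = grs_association(scored_study_cohort)
        row = table[(table["stratum"] == "supplementers") & (table["term"] == "grs_z")].iloc[0]
        assert abs(row["estimate"]) < 3 * row["se"]

    def test_additive_mode_recovers_effect_in_both_strata(self):
        cfg = ukb_preset(n=20_000, seed=5, grs_effect=0.14, grs_effect_supp=0.17)
        matrix, cohort = simulate_cohort(cfg)
        cohort = cohort.with_scores(score_cohort(matrix, packaged_weight_table()))
        table = grs_association(cohort, covariates=("age", "sex", "bmi", "supplementing"))
        for stratum, truth in [("non_supplementers", 0.14), ("supplementers", 0.17)]:
            row = table[(table["stratum"] == stratum) & (table["term"] == "grs_z")].iloc[0]
            assert abs(row["estimate"] - truth) < 3 * row["se"]

    def test_empty_stratum_is_skipped_with_warning(self, caplog):
        df = _cohort_frame(80, seed=6, supplementing=np.zeros(80, dtype=bool), dose=np.zeros(80))
        with caplog.at_level(logging.WARNING, logger="vdgrs.association"):
            table = grs_association(CohortTable(df))
        assert "supplementers" not in set(table["stratum"]) - {"non_supplementers"}
        assert any("empty" in rec.message for rec in caplog.records)

    def test_full_cohort_estimate_between_stratum_estimates(self, scored_study_cohort):
        table = grs_association(scored_study_cohort)
        est = {s: table[(table["stratum"] == s) & (table["term"] == "grs_z")]["estimate"].iloc[0]
               for s in ("all", "supplementers", "non_supplementers")}
        lo, hi = sorted([est["supplementers"], est["non_supplementers"]])
        assert lo - 0.05 <= est["all"] <= hi + 0.05


class TestAdjustedR2Delta:
    def test_saturating_covariate_drives_r2_to_one(self):
        df = _cohort_frame(120, seed=7)
        df["vd_level"] = 30 + 5 * df["bmi"]  # vd generated exactly from bmi
        r2 = adjusted_r2_delta(CohortTable(df), covariates=("bmi", "age"))
        assert r2.r2_base == pytest.approx(1.0)

    def test_base_equals_full_when_grs_duplicates_covariate(self):
        # delta is zero when the added term carries no new information
        df = _cohort_frame(120, seed=8)
        df["grs_z"] = 0.5 * df["bmi"] - 2  # grs collinear with an existing covariate
        with pytest.raises(SingularDesignError):
            adjusted_r2_delta(CohortTable(df), covariates=("bmi",))

    def test_pure_noise_covariate_does_not_help_on_average(self):
        rng = np.random.default_rng(9)
        deltas = []
        for _ in range(100):
            n = 100
            df = pd.DataFrame({"y": rng.normal(size=n), "x": rng.normal(size=n)})
            import statsmodels.api as sm

            base = sm.OLS(df.y, np.ones(n)).fit().rsquared_adj
            full = sm.OLS(df.y, sm.add_constant(df[["x"]])).fit().rsquared_adj
            deltas.append(full - base)
        assert np.mean(deltas) < 3 * np.std(deltas) / 10  # no gain beyond MC noise

    def test_study_preset_delta_positive(self):
        matrix, cohort = simulate_cohort(study_preset(seed=31))
        cohort = cohort.with_scores(score_cohort(matrix, packaged_weight_table()))
        r2 = adjusted_r2_delta(cohort)
        assert r2.delta == pytest.approx(r2.r2_full - r2.r2_base, abs=1e-12)
        assert r2.delta > 0


class TestGenotypeDistributionTest:
    def test_identical_distributions(self):
        assert genotype_distribution_test([10, 20, 10], [10, 20, 10]) == pytest.approx(1.0)

    def test_proportional_distributions(self):
        assert genotype_distribution_test([10, 20, 10], [20, 40, 20]) == pytest.approx(1.0)

    def test_hand_computed_2x3_table(self):
        cases, controls = [30, 10, 0], [10, 10, 20]
        # brute-force Pearson statistic from expected counts
        import scipy.stats

        table = np.array([cases, controls], dtype=float)
        row = table.sum(axis=1, keepdims=True)
        col = table.sum(axis=0, keepdims=True)
        expected = row @ col / table.sum()
        stat = ((table - expected) ** 2 / expected).sum()
        want = scipy.stats.chi2.sf(stat, df=2)
        assert genotype_distribution_test(cases, controls) == pytest.approx(want)

    def test_zero_column_collapses_df(self):
        # middle genotype absent in both groups: compare against 2x2 oracle
        import scipy.stats

        p = genotype_distribution_test([30, 0, 5], [10, 0, 25])
        table = np.array([[30, 5], [10, 25]], dtype=float)
        stat, want, _, _ = scipy.stats.chi2_contingency(table, correction=False)
        assert p == pytest.approx(want)

    def test_all_zero_counts_undefined(self):
        with pytest.raises(ValueError):
            genotype_distribution_test([0, 0, 0], [0, 0, 0])

    def test_per_variant_mapping(self):
        p = genotype_distribution_test(
            {"rs1": [10, 20, 10], "rs2": [30, 10, 0]},
            {"rs1": [10, 20, 10], "rs2": [10, 10, 20]},
        )
        assert p["rs1"] == pytest.approx(1.0)
        assert p["rs2"] < 0.001


class TestModelResults:
    def test_fit_returns_summary_and_tables(self):
        matrix, cohort = simulate_cohort(study_preset(seed=41))
        model = VitaminDGrsModel.from_components(cohort, score_cohort(matrix, packaged_weight_table()))
        res = model.fit()
        text = res.summary()
        assert "grs_z" in text and "adjusted R²" in text
        assert set(res.associations["stratum"]) == {"all", "supplementers", "non_supplementers"}
        assert res.screen is not None

    def test_missing_grs_column_rejected(self):
        df = _cohort_frame(30).drop(columns=["grs_z"])
        with pytest.raises(ValueError, match="grs_z"):
            VitaminDGrsModel(df)

    def test_plot_returns_figure(self, tmp_path):
        import matplotlib

        matplotlib.use("Agg")
        matrix, cohort = simulate_cohort(study_preset(seed=42))
        res = VitaminDGrsModel.from_components(
            cohort, score_cohort(matrix, packaged_weight_table())
        ).fit(screen=False)
        fig = res.plot_stratified()
        fig.savefig(tmp_path / "fig.png")
        assert (tmp_path / "fig.png").stat().st_size > 0
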