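"""Linear vs line-random-intercept mixed model: estimation correctness
against closed-form and independent-software oracles, and the derived
statistics (ICC, R2s, AIC, LRT, Wald tests)."""

import numpy as np
import pandas as pd
import pytest

from mikkexpr import (
    GenerativeConfig,
    analyze_gene,
    build_design,
    fit_linear,
    fit_mixed,
    generate_expression,
    icc,
    interaction_screen,
    lrt_random_effect,
    r2_conditional,
    term_chisq,
)
from mikkexpr.variance_partition import VarianceFit

INTERCEPT_ONLY = pd.DataFrame({"Intercept": np.ones(6)})
TOY_Y = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
TOY_GROUPS = np.array(["a", "a", "b", "b", "c", "c"])


def _fake_fit(**kwargs):
    base = dict(
        kind="mixed", method="REML",
        beta=pd.Series({"Intercept": 0.0}), bse=pd.Series({"Intercept": 1.0}),
        sigma2_line=1.0, sigma2_resid=1.0, loglik=0.0, k=3, n=10,
        exog_names=["Intercept"],
    )
    base.update(kwargs)
    return VarianceFit(**base)


class TestFitLinear:
    def test_perfect_fit_r2_one(self):
        X = pd.DataFrame({"Intercept": np.ones(6), "x": np.arange(6.0)})
        fit = fit_linear(2.0 + 3.0 * np.arange(6.0), X)
        assert fit.r2_multiple == pytest.approx(1.0)
        assert fit.beta["x"] == pytest.approx(3.0)

    def test_orthogonal_response_r2_zero(self):
        X = pd.DataFrame({"Intercept": np.ones(4), "x": [-1.0, 1.0, -1.0, 1.0]})
        y = np.array([1.0, 1.0, -1.0, -1.0])  # orthogonal to both columns
        fit = fit_linear(y, X)
        assert fit.r2_multiple == pytest.approx(0.0, abs=1e-12)

    def test_aic_consistent_with_loglik_and_k(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"Intercept": np.ones(30), "x": rng.normal(size=30)})
        fit = fit_linear(rng.normal(size=30), X)
        assert fit.k == 3
        assert fit.aic == pytest.approx(2 * fit.k - 2 * fit.loglik)

    def test_rank_deficiency_names_column(self):
        X = pd.DataFrame({"Intercept": np.ones(6), "dup": np.ones(6)})
        with pytest.raises(ValueError, match="dup|Intercept"):
            fit_linear(TOY_Y, X)


class TestFitMixed:
    def test_reml_matches_balanced_anova_closed_form(self):
        fit = fit_mixed(TOY_Y, INTERCEPT_ONLY, TOY_GROUPS, method="REML")
        # oracle: sigma2_e = MSW, sigma2_b = (MSB - MSW)/n0 for the balanced layout
        assert fit.sigma2_resid == pytest.approx(0.5, abs=1e-6)
        assert fit.sigma2_line == pytest.approx(3.75, abs=1e-6)
        assert fit.beta["Intercept"] == pytest.approx(3.5)

    def test_boundary_truncation_reduces_to_linear(self):
        y = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])  # equal group means
        mixed = fit_mixed(y, INTERCEPT_ONLY, TOY_GROUPS, method="ML")
        linear = fit_linear(y, INTERCEPT_ONLY)
        assert mixed.sigma2_line == 0.0
        assert mixed.boundary
        assert mixed.loglik == pytest.approx(linear.loglik, abs=1e-6)

    def test_sample_order_invariance(self, dataset):
        expression, meta = dataset
        y = expression.loc["bdnf", meta["sample_id"]].to_numpy()
        X = build_design(meta)
        fit = fit_mixed(y, X, meta["line_id"].to_numpy())
        perm = np.random.default_rng(1).permutation(len(y))
        meta_p = meta.iloc[perm].reset_index(drop=True)
        fit_p = fit_mixed(y[perm], build_design(meta_p), meta_p["line_id"].to_numpy())
        # the optimum is located to ~1e-8 in the variance ratio, and
        # permuting rows perturbs the floating-point sums, so agreement
        # is to the optimizer tolerance rather than machine precision
        assert fit_p.sigma2_line == pytest.approx(fit.sigma2_line, rel=1e-6)
        assert fit_p.loglik == pytest.approx(fit.loglik, abs=1e-8)
        pd.testing.assert_series_equal(fit.beta, fit_p.beta, rtol=1e-6)

    @pytest.mark.parametrize("method", ["REML", "ML"])
    def test_matches_statsmodels_mixedlm(self, dataset, method):
        smf = pytest.importorskip("statsmodels.formula.api")
        expression, meta = dataset
        df = meta.copy()
        df["y"] = expression.loc["bdnf", meta["sample_id"]].to_numpy()
        fit = fit_mixed(
            df["y"].to_numpy(), build_design(meta), meta["line_id"].to_numpy(), method=method
        )
        oracle = smf.mixedlm(
            "y ~ C(season, Treatment('winter')) + C(sex, Treatment('F'))",
            df,
            groups=df["line_id"],
        ).fit(reml=(method == "REML"))
        assert fit.sigma2_line == pytest.approx(float(oracle.cov_re.iloc[0, 0]), rel=1e-3)
        assert fit.sigma2_resid == pytest.approx(float(oracle.scale), rel=1e-3)
        assert fit.loglik == pytest.approx(float(oracle.llf), abs=1e-4)
        np.testing.assert_allclose(fit.beta.to_numpy(), oracle.fe_params.to_numpy(), rtol=1e-5)
        np.testing.assert_allclose(fit.bse.to_numpy(), oracle.bse_fe.to_numpy(), rtol=1e-3)

    def test_needs_two_groups(self):
        with pytest.raises(ValueError, match="2 groups"):
            fit_mixed(TOY_Y, INTERCEPT_ONLY, np.array(["a"] * 6))


class TestDerivedStatistics:
    def test_icc_formula_and_domain(self):
        assert icc(_fake_fit(sigma2_line=0.0)) == 0.0
        assert icc(_fake_fit(sigma2_line=1.0, sigma2_resid=1.0)) == 0.5
        assert icc(_fake_fit(sigma2_line=3.75, sigma2_resid=0.5)) == pytest.approx(3.75 / 4.25)
        with pytest.raises(ValueError, match="mixed"):
            icc(_fake_fit(kind="linear"))

    def test_icc_from_the_toy_reml_fit(self):
        fit = fit_mixed(TOY_Y, INTERCEPT_ONLY, TOY_GROUPS)
        assert icc(fit) == pytest.approx(0.88235, abs=1e-4)

    def test_r2_conditional_substitution(self):
        fit = _fake_fit(var_fixed=1.0, sigma2_line=1.0, sigma2_resid=2.0)
        marginal, conditional = r2_conditional(fit)
        assert marginal == pytest.approx(0.25)
        assert conditional == pytest.approx(0.5)

    def test_r2_conditional_equals_icc_when_no_fixed_variance(self):
        fit = _fake_fit(var_fixed=0.0, sigma2_line=0.6, sigma2_resid=1.4)
        marginal, conditional = r2_conditional(fit)
        assert marginal == 0.0
        assert conditional == pytest.approx(icc(fit))

    def test_r2_ordering_on_real_fit(self, dataset):
        expression, meta = dataset
        y = expression.loc["bdnf", meta["sample_id"]].to_numpy()
        fit = fit_mixed(y, build_design(meta), meta["line_id"].to_numpy())
        marginal, conditional = r2_conditional(fit)
        assert 0.0 <= marginal <= conditional <= 1.0


class TestLrt:
    def test_equal_logliks_give_zero_statistic(self):
        linear = _fake_fit(kind="linear", method="ML", loglik=-10.0)
        mixed = _fake_fit(method="ML", loglik=-10.0)
        stat, df, p = lrt_random_effect(linear, mixed)
        assert stat == 0.0 and df == 1 and p == 1.0

    def test_statistic_arithmetic(self):
        linear = _fake_fit(kind="linear", method="ML", loglik=-324.578)
        mixed = _fake_fit(method="ML", loglik=-319.0)
        stat, _, p = lrt_random_effect(linear, mixed)
        assert stat == pytest.approx(11.156)
        assert p < 0.001

    def test_floored_at_zero(self):
        linear = _fake_fit(kind="linear", method="ML", loglik=-5.0)
        mixed = _fake_fit(method="ML", loglik=-5.0000001)
        stat, _, _ = lrt_random_effect(linear, mixed)
        assert stat == 0.0

    def test_mismatches_rejected(self):
        linear = _fake_fit(kind="linear", method="ML")
        with pytest.raises(ValueError, match="ML"):
            lrt_random_effect(linear, _fake_fit(method="REML"))
        with pytest.raises(ValueError, match="fixed part|data"):
            lrt_random_effect(linear, _fake_fit(method="ML", n=99))


class TestTermChisq:
    def test_wald_definition_and_sign_invariance(self):
        fit = _fake_fit(
            beta=pd.Series({"Intercept": 1.0, "season[summer]": 2.0, "sex[M]": -3.0}),
            bse=pd.Series({"Intercept": 0.5, "season[summer]": 1.0, "sex[M]": 1.0}),
            exog_names=["Intercept", "season[summer]", "sex[M]"],
        )
        table = term_chisq(fit).set_index("term")
        assert table.loc["season[summer]", "chisq"] == pytest.approx(4.0)
        assert table.loc["sex[M]", "chisq"] == pytest.approx(9.0)
        assert (table["df"] == 1).all()

    def test_zero_coefficient_gives_p_one(self):
        fit = _fake_fit(
            beta=pd.Series({"Intercept": 1.0, "season[summer]": 0.0}),
            bse=pd.Series({"Intercept": 0.5, "season[summer]": 1.0}),
            exog_names=["Intercept", "season[summer]"],
        )
        row = term_chisq(fit).iloc[0]
        assert row["chisq"] == 0.0 and row["p_value"] == 1.0

    def test_aliased_term_rejected(self):
        fit = _fake_fit(
            beta=pd.Series({"Intercept": 1.0, "z": 0.3}),
            bse=pd.Series({"Intercept": 0.5, "z": 0.0}),
            exog_names=["Intercept", "z"],
        )
        with pytest.raises(ValueError, match="aliased"):
            term_chisq(fit)


class TestInteractionScreen:
    def _data(self, interaction_effect, seed=0, n_lines=60):
        cfg = GenerativeConfig(
            n_lines=n_lines, sigma_line_season=0.0, sigma_line_sex=0.0,
            back_transform=False, n_decoy_genes=0, seed=seed,
        )
        expression, meta = generate_expression(cfg)
        y = expression.loc["bdnf"].to_numpy().copy()
        both = ((meta["season"] == "summer") & (meta["sex"] == "M")).to_numpy()
        y[both] += interaction_effect
        return y, meta

    def test_strong_interaction_kept(self):
        y, meta = self._data(interaction_effect=5.0)
        spec, p = interaction_screen(y, meta, alpha=0.05)
        assert spec.interaction and p < 1e-6

    def test_alpha_zero_drops_even_clear_interactions(self):
        # drop iff p > alpha: at alpha = 0 any nonzero p removes the
        # interaction however strong the evidence for it
        y, meta = self._data(interaction_effect=0.5)
        spec, p = interaction_screen(y, meta, alpha=0.0)
        assert p > 0
        assert not spec.interaction

    def test_null_interaction_drop_rate(self):
        drops = 0
        n_rep = 40
        for seed in range(n_rep):
            y, meta = self._data(interaction_effect=0.0, seed=seed, n_lines=30)
            spec, _ = interaction_screen(y, meta, alpha=0.05)
            drops += not spec.interaction
        # under the null the Wald p is ~ uniform: drop rate ~ 1 - alpha
        assert drops / n_rep > 0.85

    def test_incomplete_design_rejected(self):
        y, meta = self._data(interaction_effect=0.0)
        sub = meta[~((meta["sex"] == "M") & (meta["season"] == "winter"))]
        with pytest.raises(ValueError, match="2x2"):
            interaction_screen(y[: len(sub)], sub.reset_index(drop=True), alpha=0.05)


def test_analyze_gene_reports_consistent_bundle(dataset):
    expression, meta = dataset
    out = analyze_gene(expression, meta)
    assert out["aic_linear"] == pytest.approx(2 * out["linear"].k - 2 * out["linear"].loglik)
    assert out["aic_mixed"] == pytest.approx(2 * out["mixed_ml"].k - 2 * out["mixed_ml"].loglik)
    assert 0 <= out["icc"] <= 1
    assert out["r2_conditional"] >= out["r2_marginal"]
    # strong simulated line effect: LRT and AIC must agree on the winner
    assert (out["aic_mixed"] < out["aic_linear"]) == (out["lrt"]["p_value"] < 0.157)
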