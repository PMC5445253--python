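import numpy as np
import pandas as pd
import pytest

from neuroreserve import (
    CohortConfig,
    build_design,
    education_slope,
    fit_lmm,
    generate_cohort,
    generate_outcome_and_volumes,
    genfi_truth,
    result_from_coefficients,
    slope_dose_monotonicity,
    t_allele_count,
)
from neuroreserve.lmm import ModelSpec, TERM_NAMES

SPEC = ModelSpec(outcome="latent")

#: published fixed-effect estimates in raw (uncentred) coding
PUBLISHED = {
    "GS": -0.262,
    "Education": 0.035,
    "TMEM106B": -0.035,
    "GS x Education": -0.046,
    "GS x TMEM106B": 0.055,
    "Education x TMEM106B": -0.0005,
    "GS x Education x TMEM106B": 0.110,
    "Age": -0.052,
    "Sex(F)": -0.527,
}


def simulated_frame(seed, **truth_overrides):
    cohort = generate_cohort(CohortConfig(), seed=seed)
    truth = genfi_truth(**truth_overrides)
    latent, _ = generate_outcome_and_volumes(cohort, truth, seed=seed + 100)
    return cohort.assign(latent=latent.to_numpy()), truth


class TestBuildDesign:
    def test_genotype_coding_is_t_allele_count(self):
        assert t_allele_count("CC") == 0
        assert t_allele_count("CT") == 1
        assert t_allele_count("TC") == 1
        assert t_allele_count("TT") == 2
        with pytest.raises(ValueError, match="genotype"):
            t_allele_count("CG")

    def test_noncarrier_rows_zero_all_gs_interactions(self):
        frame, _ = simulated_frame(1)
        design = build_design(frame, SPEC)
        gs0 = design.loc[design["GS"] == 0]
        for col in ("GS x Education", "GS x TMEM106B", "GS x Education x TMEM106B"):
            assert (gs0[col] == 0).all()

    def test_complete_cohort_keeps_all_rows(self):
        frame, _ = simulated_frame(2)
        design = build_design(frame, SPEC)
        assert len(design) == len(frame)
        assert design.attrs["n_dropped"] == 0

    def test_missing_values_are_dropped_and_counted(self):
        frame, _ = simulated_frame(3)
        frame.loc[frame.index[:4], "education"] = np.nan
        design = build_design(frame, SPEC)
        assert len(design) == len(frame) - 4
        assert design.attrs["n_dropped"] == 4

    def test_centring_constants_are_recorded(self):
        frame, _ = simulated_frame(4)
        design = build_design(frame, SPEC)
        assert design.attrs["education_center"] == SPEC.education_center
        assert design.attrs["tmem_center"] == SPEC.tmem_center


class TestFitLMM:
    def test_matches_ols_when_variance_components_are_zero(self):
        frame, _ = simulated_frame(0, var_pedigree=0.0, var_site=0.0)
        design = build_design(frame, SPEC)
        fit = fit_lmm(design, SPEC)
        X = design[list(TERM_NAMES)].to_numpy()
        y = design["outcome"].to_numpy()
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.max(np.abs(fit.fixed_effects["estimate"].to_numpy() - beta_ols)) < 1e-4

    def test_agrees_with_statsmodels_crossed_components(self):
        """Independent oracle: statsmodels MixedLM via the single-group
        variance-components formulation, on a dataset where it converges."""
        smf = pytest.importorskip("statsmodels.formula.api")
        frame, _ = simulated_frame(1)
        design = build_design(frame, SPEC)
        fit = fit_lmm(design, SPEC)

        df = design.copy()
        df.columns = [c.replace(" ", "_").replace("(", "").replace(")", "") for c in df.columns]
        df["one"] = 1
        terms = (
            "GS + Education + TMEM106B + GS_x_Education + GS_x_TMEM106B + "
            "Education_x_TMEM106B + GS_x_Education_x_TMEM106B + Age + SexF"
        )
        model = smf.mixedlm(
            f"outcome ~ {terms}", df, groups="one", re_formula="0",
            vc_formula={"ped": "0+C(pedigree)", "site": "0+C(site)"},
        )
        ref = model.fit(reml=False)
        assert np.max(np.abs(fit.fixed_effects["estimate"].to_numpy() - ref.fe_params.values)) < 1e-4
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-3)
        # our optimum is never worse than the oracle's
        assert fit.loglik >= ref.llf - 1e-6

    def test_loglik_not_below_variances_pinned_to_zero(self):
        frame, _ = simulated_frame(5)
        design = build_design(frame, SPEC)
        fit = fit_lmm(design, SPEC)
        X = design[list(TERM_NAMES)].to_numpy()
        y = design["outcome"].to_numpy()
        n = len(y)
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta_ols
        sigma2 = resid @ resid / n  # ML residual variance of the nested model
        ll0 = -0.5 * (n * np.log(2 * np.pi * sigma2) + n)
        assert fit.loglik >= ll0 - 1e-6

    def test_wald_columns_are_internally_consistent(self):
        frame, _ = simulated_frame(6)
        fit = fit_lmm(build_design(frame, SPEC), SPEC)
        fe = fit.fixed_effects
        assert np.allclose(fe["z"] * fe["se"], fe["estimate"], atol=1e-8)
        assert ((fe["p"] > 0) & (fe["p"] <= 1)).all()
        assert fit.var_pedigree >= 0 and fit.var_site >= 0 and fit.var_resid > 0
        assert fit.converged

    def test_singular_design_names_aliased_columns(self):
        frame, _ = simulated_frame(7)
        frame["education"] = 12.0  # education constant -> aliased with intercept
        design = build_design(frame, SPEC)
        with pytest.raises(ValueError, match="aliased"):
            fit_lmm(design, SPEC)

    def test_requires_two_pedigrees_and_sites(self):
        frame, _ = simulated_frame(8)
        frame["site_id"] = "S01"
        with pytest.raises(ValueError, match="sites"):
            fit_lmm(build_design(frame, SPEC), SPEC)

    def test_reml_residual_variance_exceeds_ml(self):
        frame, _ = simulated_frame(9)
        design = build_design(frame, SPEC)
        ml = fit_lmm(design, SPEC)
        reml = fit_lmm(design, ModelSpec(outcome="latent", reml=True))
        # REML corrects the downward ML bias of the residual variance
        assert reml.var_resid > ml.var_resid


class TestEducationSlopes:
    def test_published_estimates_give_dose_ordered_slopes(self):
        fit = result_from_coefficients(PUBLISHED)
        assert education_slope(fit, gs=1, t_alleles=2) == pytest.approx(0.208, abs=1e-12)
        assert education_slope(fit, gs=1, t_alleles=1) == pytest.approx(0.0985, abs=1e-12)
        assert education_slope(fit, gs=1, t_alleles=0) == pytest.approx(-0.011, abs=1e-12)

    def test_noncarrier_slopes_are_nearly_flat_in_genotype(self):
        fit = result_from_coefficients(PUBLISHED)
        slopes = [education_slope(fit, gs=0, t_alleles=t) for t in (0, 1, 2)]
        assert slopes[0] == pytest.approx(0.035, abs=1e-12)
        assert max(slopes) - min(slopes) < 0.0011  # |b6| * 2

    def test_all_zero_coefficients_give_zero_slope(self):
        zero = result_from_coefficients({t: 0.0 for t in PUBLISHED})
        assert education_slope(zero, gs=1, t_alleles=2) == 0.0

    def test_slope_rejects_invalid_arguments(self):
        fit = result_from_coefficients(PUBLISHED)
        with pytest.raises(ValueError, match="t_alleles"):
            education_slope(fit, gs=1, t_alleles=3)
        with pytest.raises(ValueError, match="gs"):
            education_slope(fit, gs=2, t_alleles=1)

    def test_monotonicity_verdicts(self):
        assert slope_dose_monotonicity(result_from_coefficients(PUBLISHED)).attrs["verdict"] == "increasing"
        flat = dict(PUBLISHED, **{"Education x TMEM106B": 0.0, "GS x Education x TMEM106B": 0.0})
        assert slope_dose_monotonicity(result_from_coefficients(flat)).attrs["verdict"] == "constant"
        flipped = dict(PUBLISHED, **{"GS x Education x TMEM106B": -0.110})
        assert slope_dose_monotonicity(result_from_coefficients(flipped)).attrs["verdict"] == "decreasing"

    def test_centred_fit_reports_slopes_in_raw_allele_units(self):
        """A fit with a nonzero allele centring constant must give the same
        raw-unit slopes as the equivalent raw-coded coefficients."""
        centred = result_from_coefficients(PUBLISHED, tmem_center=1.268)
        raw_equivalent = dict(PUBLISHED)
        raw_equivalent["Education"] = PUBLISHED["Education"] - 1.268 * PUBLISHED["Education x TMEM106B"]
        raw_equivalent["GS x Education"] = (
            PUBLISHED["GS x Education"] - 1.268 * PUBLISHED["GS x Education x TMEM106B"]
        )
        raw = result_from_coefficients(raw_equivalent)
        for gs in (0, 1):
            for t in (0, 1, 2):
                assert education_slope(centred, gs, t) == pytest.approx(
                    education_slope(raw, gs, t), abs=1e-12
                )
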