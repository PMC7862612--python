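"""Design matrix, OLS fit, Wald contrasts and LOEC extraction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from leukotox import (ContrastResult, EffectParameters, ExperimentDesign,
                      build_design_matrix, determine_loec, fit_ols,
                      simulate_assay, standard_comparisons, wald_contrast)
from leukotox.immune_lm import DesignMatrix, contrast_vector
from leukotox.montecarlo import cell_table, true_beta
from leukotox.plate_qc import average_technical_replicates


def _averaged(design, params, seed):
    wells = simulate_assay(design, params, seed)
    return average_technical_replicates(wells)


class TestDesignMatrix:
    def test_degenerate_single_fish_no_concentration(self):
        design = ExperimentDesign(fish_ids=("F1",), concentrations=(0.0,))
        dm = build_design_matrix(cell_table(design))
        assert dm.columns == ["intercept", "time:19h", "lps:yes",
                              "time:19h|lps:yes"]

    def test_column_formula_seven_fish_three_concentrations(self):
        design = ExperimentDesign(fish_ids=tuple(f"F{i}" for i in range(7)),
                                  concentrations=(0.0, 1.0, 5.0, 10.0))
        dm = build_design_matrix(cell_table(design))
        # 1 + (|F|-1) + 1 + 1 + |C| + 1 + |C| + |C|
        assert len(dm.columns) == 1 + 6 + 1 + 1 + 3 + 1 + 3 + 3 == 19
        assert set(dm.X.ravel()) <= {0.0, 1.0}

    def test_complete_design_has_full_column_rank(self, design6):
        dm = build_design_matrix(cell_table(design6))
        assert np.linalg.matrix_rank(dm.X) == len(dm.columns)

    def test_duplicate_treatment_rows_rejected(self, design6):
        tbl = cell_table(design6)
        dup = pd.concat([tbl, tbl.iloc[:1]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            build_design_matrix(dup)


class TestFitOls:
    def test_noise_free_fit_recovers_parameters_exactly(self, design6,
                                                        noise_free):
        avg = _averaged(design6, noise_free, seed=1)
        dm = build_design_matrix(avg)
        fit = fit_ols(dm)
        np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-10)
        np.testing.assert_allclose(fit.beta, true_beta(noise_free, dm),
                                   atol=1e-10)

    def test_matches_normal_equations_oracle(self, design6, rich_params):
        avg = _averaged(design6, rich_params, seed=4)
        dm = build_design_matrix(avg)
        fit = fit_ols(dm)
        # independent brute-force solve of X'X beta = X'y
        beta_oracle = np.linalg.solve(dm.X.T @ dm.X, dm.X.T @ dm.y)
        np.testing.assert_allclose(fit.beta, beta_oracle, rtol=1e-8)
        resid = dm.y - dm.X @ beta_oracle
        sigma2_oracle = resid @ resid / (len(dm.y) - dm.X.shape[1])
        assert fit.sigma2 == pytest.approx(sigma2_oracle, rel=1e-8)

    def test_rank_deficient_aliasing_and_projection_invariance(self, design6,
                                                               rich_params):
        avg = _averaged(design6, rich_params, seed=5)
        dm = build_design_matrix(avg)
        X_dup = np.column_stack([dm.X, dm.X[:, 3]])
        dm_dup = DesignMatrix(X=X_dup, columns=dm.columns + ["dup"],
                              y=dm.y, meta=dm.meta,
                              concentrations=dm.concentrations,
                              time_levels=dm.time_levels,
                              lps_levels=dm.lps_levels)
        fit_dup = fit_ols(dm_dup)
        assert len(fit_dup.aliased) == 1
        fit_plain = fit_ols(dm)
        np.testing.assert_allclose(fit_dup.fitted, fit_plain.fitted,
                                   atol=1e-8)

    def test_saturated_model_rejected(self):
        dm = DesignMatrix(X=np.eye(3), columns=["a", "b", "c"],
                          y=np.arange(3.0), meta=pd.DataFrame(),
                          concentrations=(), time_levels=("3h",),
                          lps_levels=("no",))
        with pytest.raises(ValueError, match="saturated"):
            fit_ols(dm)

    def test_covariance_symmetric_psd(self, design6, rich_params):
        fit = fit_ols(build_design_matrix(_averaged(design6, rich_params,
                                                    seed=6)))
        np.testing.assert_allclose(fit.cov, fit.cov.T, atol=1e-12)
        eig = np.linalg.eigvalsh(fit.cov)
        assert eig.min() > -1e-10

    def test_constant_shift_moves_only_intercept(self, design6, rich_params):
        avg = _averaged(design6, rich_params, seed=7)
        fit0 = fit_ols(build_design_matrix(avg))
        shifted = avg.copy()
        shifted["mean"] = shifted["mean"] + 5.0
        fit1 = fit_ols(build_design_matrix(shifted))
        assert fit1.beta[0] == pytest.approx(fit0.beta[0] + 5.0)
        np.testing.assert_allclose(fit1.beta[1:], fit0.beta[1:], atol=1e-9)


class TestWaldContrast:
    def test_zero_contrast_rejected(self, design6, rich_params):
        fit = fit_ols(build_design_matrix(_averaged(design6, rich_params,
                                                    seed=8)))
        with pytest.raises(ValueError, match="non-estimable"):
            wald_contrast(fit, np.zeros(len(fit.columns)))

    def test_wrong_length_rejected(self, design6, rich_params):
        fit = fit_ols(build_design_matrix(_averaged(design6, rich_params,
                                                    seed=8)))
        with pytest.raises(ValueError, match="length"):
            wald_contrast(fit, np.ones(3))

    def test_two_group_contrast_equals_t_test(self):
        # balanced two-group design: single-coefficient Wald p equals the
        # classical equal-variance two-sample t-test p
        rng = np.random.default_rng(12)
        g1, g2 = rng.normal(0, 1, 8), rng.normal(0.8, 1, 8)
        X = np.column_stack([np.ones(16),
                             np.r_[np.zeros(8), np.ones(8)]])
        dm = DesignMatrix(X=X, columns=["intercept", "group2"],
                          y=np.r_[g1, g2], meta=pd.DataFrame(),
                          concentrations=(), time_levels=("3h",),
                          lps_levels=("no",))
        res = wald_contrast(fit_ols(dm), np.array([0.0, 1.0]))
        t, p = stats.ttest_ind(g2, g1, equal_var=True)
        assert res.t == pytest.approx(t, rel=1e-10)
        assert res.p == pytest.approx(p, rel=1e-10)


class TestStandardComparisons:
    def test_lps_comparison_coding(self, design6, rich_params):
        fit = fit_ols(build_design_matrix(_averaged(design6, rich_params,
                                                    seed=9)))
        results = {r.label: r for r in standard_comparisons(fit)}
        c3 = results["3h|LPS control vs non-stimulated control"].contrast
        # at 3 h the contrast selects the LPS main effect alone
        np.testing.assert_array_equal(
            c3, contrast_vector(fit, {"lps:yes": 1.0}))
        c19 = results["19h|LPS control vs non-stimulated control"].contrast
        np.testing.assert_array_equal(
            c19, contrast_vector(fit, {"lps:yes": 1.0,
                                       "time:19h|lps:yes": 1.0}))

    def test_estimates_match_cell_mean_differences_noise_free(
            self, design6, noise_free):
        avg = _averaged(design6, noise_free, seed=10)
        fit = fit_ols(build_design_matrix(avg))
        cells = avg.groupby(["time", "lps", "concentration"])["mean"].mean()
        for r in standard_comparisons(fit):
            time = r.meta["time"]
            if r.meta["comparison"] == "lps_vs_control":
                expected = cells[(time, "yes", 0.0)] - cells[(time, "no", 0.0)]
            else:
                lps, conc = r.meta["lps"], r.meta["concentration"]
                expected = cells[(time, lps, conc)] - cells[(time, lps, 0.0)]
            assert r.estimate == pytest.approx(expected, abs=1e-9)

    def test_comparison_count(self, design6, rich_params):
        fit = fit_ols(build_design_matrix(_averaged(design6, rich_params,
                                                    seed=11)))
        # per time point: 1 LPS comparison + |C| x 2 LPS levels
        assert len(standard_comparisons(fit)) == 2 * (1 + 3 * 2)


def _conc_contrast(conc, p, estimate=-1.0):
    return ContrastResult(label=f"c{conc}", contrast=np.zeros(1),
                          estimate=estimate, se=1.0, t=estimate, p=p,
                          meta={"concentration": conc})


class TestLoec:
    def test_lowest_significant_concentration(self):
        contrasts = [_conc_contrast(1, 0.2), _conc_contrast(5, 0.03),
                     _conc_contrast(10, 0.01)]
        res = determine_loec(contrasts)
        assert res.loec == 5 and res.determinable
        assert res.direction == "decrease"

    def test_all_nonsignificant_is_not_determinable(self):
        contrasts = [_conc_contrast(1, 0.2), _conc_contrast(5, 0.6)]
        res = determine_loec(contrasts)
        assert not res.determinable and res.loec is None
        assert str(res) == "n.d."

    def test_non_monotone_p_takes_minimum_concentration(self):
        contrasts = [_conc_contrast(1, 0.04), _conc_contrast(5, 0.5),
                     _conc_contrast(10, 0.01)]
        assert determine_loec(contrasts).loec == 1

    def test_boundary_p_equal_alpha_is_significant(self):
        assert determine_loec([_conc_contrast(2, 0.05)]).loec == 2

    def test_increase_direction(self):
        res = determine_loec([_conc_contrast(3, 0.01, estimate=2.0)])
        assert res.direction == "increase"


class TestStatsmodelsOracle:
    """Cross-validation against an independent reference implementation."""

    def test_random_designs_match_reference(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(2024)
        n_designs = 200
        for _ in range(n_designs):
            n_fish = int(rng.integers(3, 8))
            n_conc = int(rng.integers(0, 4))
            concs = tuple(np.sort(rng.uniform(0.5, 20, size=n_conc)))
            design = ExperimentDesign(
                fish_ids=tuple(f"F{i}" for i in range(n_fish)),
                concentrations=(0.0,) + concs, n_technical=1)
            tbl = cell_table(design)
            tbl["mean"] = rng.normal(0, 1, size=len(tbl))
            dm = build_design_matrix(tbl)
            fit = fit_ols(dm)
            ref = sm.OLS(dm.y, dm.X).fit()
            np.testing.assert_allclose(fit.beta, ref.params, rtol=1e-6,
                                       atol=1e-9)
            assert fit.sigma2 == pytest.approx(ref.scale, rel=1e-6)
            for r in standard_comparisons(fit):
                ref_p = float(ref.t_test(r.contrast).pvalue)
                assert r.p == pytest.approx(ref_p, rel=1e-6, abs=1e-12)
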