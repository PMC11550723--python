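"""Trajectory models: design construction, LRT machinery, period slopes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from clocktraj.models import (
    DesignSpec,
    build_design,
    chi_bar_square_p,
    fit_model,
)
from clocktraj.models import test_variance_component as variance_component_lrt
from clocktraj.simulate import SiteTruth, simulate_site


def site_frame(idx, ages, y, **covs):
    df = pd.DataFrame({"individual_id": idx, "visit_age_years": ages, "beta": y})
    for k, v in covs.items():
        df[k] = v
    return df


PLAIN_SPEC1 = DesignSpec(model=1, continuous=(), categorical=(), min_individuals=5)
PLAIN_SPEC2 = DesignSpec(model=2, continuous=(), categorical=(), min_individuals=5)


class TestBuildDesign:
    @pytest.mark.parametrize(
        "age,row",
        [(0.0, (1.0, 0.0, 0.0, 0.0)), (9.0, (1.0, 9.0, 3.0, 0.0)),
         (17.0, (1.0, 17.0, 11.0, 8.0))],
    )
    def test_truncated_basis_rows(self, age, row):
        ages = [age, 1.0, 3.0, 7.0, 12.0, 15.0]
        df = site_frame([0, 0, 1, 1, 2, 2], ages, [0.5] * 6)
        X, Z, names, _ = build_design(df, PLAIN_SPEC2)
        assert tuple(X[0]) == row
        assert names[:4] == ["intercept", "age", "age_m6", "age_m9"]

    def test_basis_continuous_at_knot(self):
        eps = 1e-9
        ages = [6.0 - eps, 6.0 + eps, 1.0, 3.0, 10.0, 12.0]
        df = site_frame([0, 0, 1, 1, 2, 2], ages, [0.5] * 6)
        X, *_ = build_design(df, PLAIN_SPEC2)
        assert abs(X[0, 2] - X[1, 2]) < 1e-8

    def test_model1_has_no_knot_columns(self):
        df = site_frame([0, 0, 1, 1], [0, 10, 0, 10], [0.5] * 4)
        X, Z, names, _ = build_design(df, PLAIN_SPEC1)
        assert names == ["intercept", "age"]
        assert Z.shape[1] == 2

    def test_continuous_covariate_z_scored(self):
        spec = DesignSpec(model=1, continuous=("gestational_age_z",), categorical=())
        df = site_frame([0, 0, 1, 1], [0, 10, 0, 10], [0.5] * 4,
                        gestational_age_z=[1.0, 1.0, 3.0, 3.0])
        X, _, names, _ = build_design(df, spec)
        col = X[:, names.index("gestational_age_z")]
        assert col.mean() == pytest.approx(0.0)
        assert col.std() == pytest.approx(1.0)

    def test_constant_covariate_dropped(self, caplog):
        spec = DesignSpec(model=1, continuous=("gestational_age_z",), categorical=())
        df = site_frame([0, 0, 1, 1], [0, 10, 0, 10], [0.5] * 4,
                        gestational_age_z=[2.0] * 4)
        with caplog.at_level("WARNING"):
            _, _, names, _ = build_design(df, spec)
        assert "gestational_age_z" not in names

    def test_collinear_column_named(self):
        spec = DesignSpec(model=1, continuous=("dup",), categorical=())
        df = site_frame([0, 0, 1, 1], [0, 10, 0, 10], [0.5] * 4)
        df["dup"] = df["visit_age_years"] * 2.0  # collinear with the age column
        with pytest.raises(ValueError, match="dup"):
            build_design(df, spec)

    def test_bad_knots_rejected(self):
        with pytest.raises(ValueError):
            DesignSpec(model=2, knots=(9.0, 6.0))


class TestChiBarSquare:
    def test_zero_statistic_gives_one(self):
        assert chi_bar_square_p(0.0, 1) == 1.0
        assert chi_bar_square_p(0.0, 2) == 1.0

    def test_q1_mixture_is_half_chi2_tail(self):
        lam = 3.84
        assert chi_bar_square_p(lam, 1) == pytest.approx(
            0.5 * stats.chi2.sf(lam, 1), rel=1e-12
        )

    def test_q2_mixture(self):
        lam = 5.0
        manual = 0.5 * (stats.chi2.sf(lam, 1) + stats.chi2.sf(lam, 2))
        assert chi_bar_square_p(lam, 2) == pytest.approx(manual, rel=1e-12)

    def test_equal_logliks_give_p_one(self):
        assert variance_component_lrt(-100.0, -100.0, 1) == 1.0

    def test_non_nested_inputs_raise(self):
        with pytest.raises(ValueError, match="non-nested"):
            variance_component_lrt(-101.0, -100.0, 1)


class TestFitModel:
    def test_min_individuals_enforced(self, balanced_design, simulate_y):
        idx, ages = balanced_design(10)
        truth = SiteTruth(cpg_id="c", mu0=0.5, sd_resid=0.01)
        df = site_frame(idx, ages, simulate_y(truth, idx, ages))
        with pytest.raises(ValueError, match="individuals"):
            fit_model(df, DesignSpec(model=1, continuous=(), categorical=()))

    def test_slope_recovery_within_3_se(self, jittered_design, simulate_y):
        truth = SiteTruth(cpg_id="c", mu0=0.5, beta_age=0.01,
                          sd_intercept=0.02, sd_slope=0.001, sd_resid=0.01)
        idx, ages = jittered_design(500, seed=11)
        df = site_frame(idx, ages, simulate_y(truth, idx, ages, seed=11))
        fit = fit_model(df, PLAIN_SPEC1, component_tests=False)
        est, se, p = fit.fixed["age"]
        assert abs(est - 0.01) < 3 * se
        assert p < 1e-7

    def test_variance_component_pvalues_sensible(self, jittered_design, simulate_y):
        truth = SiteTruth(cpg_id="c", mu0=0.5, sd_intercept=0.03, sd_resid=0.01)
        idx, ages = jittered_design(300, seed=12)
        df = site_frame(idx, ages, simulate_y(truth, idx, ages, seed=12))
        fit = fit_model(df, PLAIN_SPEC1)
        assert fit.p_random_intercept < 1e-10  # strong real intercept variance
        assert fit.p_random_slope > 1e-4  # absent slope variance

    def test_single_visit_flagged_degenerate(self, simulate_y):
        idx = np.arange(100)
        ages = np.random.default_rng(5).uniform(0, 17, 100)
        truth = SiteTruth(cpg_id="c", mu0=0.5, sd_intercept=0.02, sd_resid=0.01)
        df = site_frame(idx, ages, simulate_y(truth, idx, ages))
        fit = fit_model(df, PLAIN_SPEC1)
        assert fit.degenerate

    def test_rho_undefined_when_slope_variance_absent(self, balanced_design, simulate_y):
        truth = SiteTruth(cpg_id="c", mu0=0.5, sd_intercept=0.03, sd_resid=0.01)
        idx, ages = balanced_design(400)
        df = site_frame(idx, ages, simulate_y(truth, idx, ages, seed=13))
        fit = fit_model(df, PLAIN_SPEC1)
        assert not fit.rho_defined
        assert fit.rho_int_slope is None
        assert fit.p_rho == 1.0


class TestPeriodSlopes:
    def fit2(self, truth, seed, n=400, jitter=None):
        rng = np.random.default_rng(seed)
        base = np.tile([0.0, 6.0, 10.0, 17.0], n)
        idx = np.repeat(np.arange(n), 4)
        ages = base
        y, _ = simulate_site(truth, idx, ages, rng)
        df = site_frame(idx, ages, y)
        return fit_model(df, PLAIN_SPEC2, component_tests=False)

    def test_change_then_stable_contrasts(self):
        truth = SiteTruth(cpg_id="c", mu0=0.4, beta_age=0.02, delta6=-0.02,
                          sd_resid=0.005)
        fit = self.fit2(truth, 14)
        s = fit.period_slopes
        assert s["s1"][0] == pytest.approx(0.02, abs=5e-4)
        assert abs(s["s2"][0]) < 5e-4
        assert s["s2"][2] > 1e-7  # post-knot slope not significant

    def test_algebraic_identities(self):
        truth = SiteTruth(cpg_id="c", mu0=0.4, beta_age=0.005, delta6=-0.002,
                          delta9=-0.004, sd_resid=0.01)
        fit = self.fit2(truth, 15)
        b_age = fit.fixed["age"][0]
        d6 = fit.fixed["age_m6"][0]
        d9 = fit.fixed["age_m9"][0]
        assert fit.period_slopes["s1"][0] == pytest.approx(b_age, rel=1e-10)
        assert fit.period_slopes["s2"][0] == pytest.approx(b_age + d6, rel=1e-10)
        assert fit.period_slopes["s3"][0] == pytest.approx(b_age + d6 + d9, rel=1e-10)

    def test_contrast_se_matches_manual_delta_method(self):
        truth = SiteTruth(cpg_id="c", mu0=0.4, beta_age=0.005, delta6=-0.002,
                          delta9=-0.004, sd_resid=0.01)
        fit = self.fit2(truth, 16)
        names = fit.lmm.names
        cols = [names.index("age"), names.index("age_m6"), names.index("age_m9")]
        sub = fit.lmm.cov_beta[np.ix_(cols, cols)]
        w = np.ones(3)
        manual_se = float(np.sqrt(w @ sub @ w))
        assert fit.period_slopes["s3"][1] == pytest.approx(manual_se, rel=1e-10)


def test_fixed_effect_lrt_agrees_with_wald(jittered_design, simulate_y):
    """The LRT mode for fixed effects roughly tracks the Wald default and
    is decisive where the effect is strong."""
    from clocktraj.models import test_fixed_effect_lrt as fixed_effect_lrt

    truth = SiteTruth(cpg_id="c", mu0=0.5, beta_age=0.008,
                      sd_intercept=0.02, sd_slope=0.001, sd_resid=0.01)
    idx, ages = jittered_design(300, seed=21)
    df = site_frame(idx, ages, simulate_y(truth, idx, ages, seed=21))
    lam, p = fixed_effect_lrt(df, PLAIN_SPEC1, "age")
    assert lam > 30 and p < 1e-7
    with pytest.raises(KeyError):
        fixed_effect_lrt(df, PLAIN_SPEC1, "no_such_term")
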