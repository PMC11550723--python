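"""Per-site longitudinal trajectory models.

Two maximum-likelihood linear mixed models are fitted to each CpG site's
beta values across visits:

* **Model 1** — fixed intercept and age slope (plus covariates); random
  intercept and random age slope with a free correlation.  The random
  intercept captures inter-individual differences at birth, the random
  slope inter-individual differences in rate of change.
* **Model 2** — Model 1's fixed part plus truncated-linear slope-change
  terms (t-6)+ and (t-9)+ at knots 6 and 9 years, each with fixed and
  random components.  The random-effect covariance uses a block structure:
  the intercept and age slope are correlated, the slope-change effects are
  independent of each other and of the first block.

Random-effect significance is assessed by likelihood-ratio tests against
the fit with that term removed, referred to the 50:50 chi-bar-square
mixture of chi-square distributions with (q-1) and q degrees of freedom,
where q is the number of covariance parameters removed — the standard
boundary correction for variance components.  The intercept-slope
correlation is an interior parameter and is tested on a plain 1-df
chi-square.  Fixed-effect p-values are large-sample Wald tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .mixedlm import LMMResult, fit_lmm

logger = logging.getLogger(__name__)

__all__ = [
    "DesignSpec",
    "Model1Fit",
    "Model2Fit",
    "build_design",
    "fit_model",
    "fit_site",
    "test_variance_component",
    "test_intercept_slope_correlation",
    "period_slopes",
    "chi_bar_square_p",
]

DEFAULT_CONTINUOUS = ("gestational_age_z", "CD4T", "CD8T", "NK", "B", "mono", "gran")
DEFAULT_CATEGORICAL = ("sex", "batch", "cohort")


@dataclass(frozen=True)
class DesignSpec:
    """Design of the fixed and random parts of a trajectory model."""

    model: int = 1
    knots: tuple[float, float] = (6.0, 9.0)
    continuous: tuple[str, ...] = DEFAULT_CONTINUOUS
    categorical: tuple[str, ...] = DEFAULT_CATEGORICAL
    correlated: bool = True  # free intercept-slope correlation
    min_individuals: int = 50

    def __post_init__(self) -> None:
        if self.model not in (1, 2):
            raise ValueError("model must be 1 or 2")
        if not self.knots[0] < self.knots[1]:
            raise ValueError("knots must be strictly increasing")


def _truncated_basis(ages: np.ndarray, knots) -> np.ndarray:
    """Columns (1, t, (t-k1)+, (t-k2)+): a continuous piecewise-linear basis."""
    t = np.asarray(ages, float)
    return np.column_stack(
        [np.ones_like(t), t] + [np.maximum(0.0, t - k) for k in knots]
    )


def build_design(
    data: pd.DataFrame, spec: DesignSpec
) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    """Assemble fixed (X) and random (Z) design matrices for one site.

    Continuous covariates are z-scored over the analysis sample;
    categorical covariates are dummy-coded against their first (sorted)
    reference level.  Constant columns are dropped with a warning;
    remaining collinearity raises an error naming the offending columns.
    """
    ages = data["visit_age_years"].to_numpy(float)
    if not np.all(np.isfinite(ages)) or ages.min() < 0:
        raise ValueError("ages must be finite and >= 0")
    basis = _truncated_basis(ages, spec.knots)
    basis_names = ["intercept", "age", f"age_m{spec.knots[0]:g}", f"age_m{spec.knots[1]:g}"]
    n_basis = 4 if spec.model == 2 else 2
    cols = [basis[:, :n_basis]]
    names = basis_names[:n_basis]

    for c in spec.continuous:
        if c not in data.columns:
            continue
        v = data[c].to_numpy(float)
        sd = v.std()
        if sd == 0:
            logger.warning("dropping constant covariate column %r", c)
            continue
        cols.append(((v - v.mean()) / sd)[:, None])
        names.append(c)
    for c in spec.categorical:
        if c not in data.columns:
            continue
        levels = sorted(pd.unique(data[c].astype(str)))
        if len(levels) < 2:
            logger.warning("dropping constant covariate column %r", c)
            continue
        for lev in levels[1:]:
            cols.append((data[c].astype(str).to_numpy() == lev).astype(float)[:, None])
            names.append(f"{c}[{lev}]")

    X = np.hstack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify dependent columns by greedy QR elimination
        bad = []
        kept: list[int] = []
        for j in range(X.shape[1]):
            trial = X[:, kept + [j]]
            if np.linalg.matrix_rank(trial) == len(kept) + 1:
                kept.append(j)
            else:
                bad.append(names[j])
        raise ValueError(f"collinear design columns: {bad}")
    Z = basis[:, :n_basis]
    return X, Z, names, basis_names[:n_basis]


def chi_bar_square_p(lam: float, q: int) -> float:
    """Tail p of the 50:50 mixture of chi-square(q-1) and chi-square(q).

    chi-square(0) is a point mass at zero, so for q = 1 the mixture is
    0.5 * 1{lam = 0} + 0.5 * chi2(1).
    """
    lam = max(0.0, float(lam))
    if lam == 0.0:
        return 1.0
    lo = float(stats.chi2.sf(lam, q - 1)) if q > 1 else 0.0
    hi = float(stats.chi2.sf(lam, q))
    return 0.5 * (lo + hi)


def test_variance_component(full, reduced, n_removed_params: int, tol: float = 1e-3) -> float:
    """Boundary-corrected LRT p-value for removing one random term.

    ``full`` and ``reduced`` may be fits (anything with ``.loglik``) or
    plain log-likelihoods.  A likelihood-ratio statistic below ``-tol``
    indicates non-nested inputs and raises; small negative values are
    clamped to zero with a warning.
    """
    ll_full = getattr(full, "loglik", full)
    ll_red = getattr(reduced, "loglik", reduced)
    lam = 2.0 * (ll_full - ll_red)
    if lam < -tol:
        raise ValueError(
            f"non-nested fits: loglik of full model below reduced by {-lam / 2:g}"
        )
    if lam < 0:
        # optimizer-noise-sized deficits are routine; only larger ones are notable
        log = logger.warning if lam < -1e-6 else logger.debug
        log("clamping small negative LRT statistic %.3g to 0", lam)
        lam = 0.0
    return chi_bar_square_p(lam, n_removed_params)


@dataclass
class Model1Fit:
    """Model 1 per-site results."""

    fixed: dict[str, tuple[float, float, float]]  # name -> (est, se, p)
    sd_intercept: float
    sd_slope: float
    sd_resid: float
    rho_int_slope: float | None
    p_random_intercept: float
    p_random_slope: float
    p_rho: float
    rho_defined: bool
    loglik: float
    converged: bool
    n_obs: int
    n_individuals: int
    degenerate: bool = False
    lmm: LMMResult | None = field(default=None, repr=False)

    @property
    def age(self) -> tuple[float, float, float]:
        return self.fixed["age"]


@dataclass
class Model2Fit:
    """Model 2 per-site results (piecewise slopes at the knots)."""

    fixed: dict[str, tuple[float, float, float]]
    sd_intercept: float
    sd_slope: float
    sd_delta6: float
    sd_delta9: float
    sd_resid: float
    rho_int_slope: float | None
    p_random_intercept: float
    p_random_slope: float
    p_random_delta6: float
    p_random_delta9: float
    period_slopes: dict[str, tuple[float, float, float]]  # s1, s2, s3
    loglik: float
    converged: bool
    n_obs: int
    n_individuals: int
    degenerate: bool = False
    lmm: LMMResult | None = field(default=None, repr=False)


def _fit(y, X, Z, groups, names, correlated, theta0=None):
    return fit_lmm(y, X, Z, groups, x_names=names, correlated=correlated, theta0=theta0)


def _warm(full: LMMResult, cols: list[int], correlated: bool) -> np.ndarray:
    """Starting variance parameters for a nested refit, from the full fit."""
    th = [float(np.log(max(full.sd_random[c], 1e-9))) for c in cols]
    if correlated and len(cols) >= 2:
        r = full.rho if full.rho is not None else 0.0
        th.append(float(np.arctanh(np.clip(r, -0.999999, 0.999999))))
    th.append(float(np.log(full.sd_resid)))
    return np.array(th)


def _refine_full(y, X, Z, groups, names, correlated, full, reductions):
    """Restart the full fit from any nested solution that beat it.

    Guarantees (up to optimizer tolerance) the nesting invariant
    ll_full >= ll_reduced that the variance-component LRTs require.
    """
    best = full
    q = Z.shape[1]
    for red, cols in reductions:
        if red.loglik <= best.loglik + 1e-9:
            continue
        th = np.full(q, np.log(best.sd_resid) - 13.5)
        for i, c in enumerate(cols):
            th[c] = np.log(max(red.sd_random[i], 1e-9))
        tail = []
        if correlated and q >= 2:
            r = red.rho if red.rho is not None else 0.0
            tail.append(float(np.arctanh(np.clip(r, -0.999999, 0.999999))))
        tail.append(float(np.log(red.sd_resid)))
        cand = _fit(y, X, Z, groups, names, correlated, np.concatenate([th, tail]))
        if cand.loglik > best.loglik:
            best = cand
    return best


def fit_model(
    site_data: pd.DataFrame,
    spec: DesignSpec,
    component_tests: bool = True,
) -> Model1Fit | Model2Fit:
    """Fit Model 1 or Model 2 to one site by maximum likelihood.

    ``site_data`` needs columns ``individual_id``, ``visit_age_years``,
    ``beta`` and any covariates named in the spec.  ``component_tests``
    controls whether the nested refits behind the random-effect and
    correlation p-values are run (they dominate the cost).
    """
    n_ind = site_data["individual_id"].nunique()
    if n_ind < spec.min_individuals:
        raise ValueError(
            f"only {n_ind} individuals; minimum is {spec.min_individuals}"
        )
    y = site_data["beta"].to_numpy(float)
    groups = site_data["individual_id"].to_numpy()
    X, Z, names, znames = build_design(site_data, spec)
    max_grp = site_data.groupby("individual_id").size().max()
    degenerate = bool(max_grp < 2)  # intercept and residual variance confounded
    if degenerate:
        logger.warning("single observation per individual: variance components confounded")

    full = _fit(y, X, Z, groups, names, spec.correlated)
    nan = float("nan")

    if spec.model == 1:
        p_int = p_slope = p_rho = nan
        rho_defined = not (full.singular[0] or full.singular[1])
        if component_tests and not degenerate:
            red_slope = _fit(y, X, Z[:, [0]], groups, names, False, _warm(full, [0], False))
            red_int = _fit(y, X, Z[:, [1]], groups, names, False, _warm(full, [1], False))
            diag = _fit(y, X, Z, groups, names, False, _warm(full, [0, 1], False))
            full = _refine_full(
                y, X, Z, groups, names, spec.correlated, full,
                [(red_slope, [0]), (red_int, [1]), (diag, [0, 1])])
            rho_defined = not (full.singular[0] or full.singular[1])
            p_slope = test_variance_component(full, red_slope, 2)
            p_int = test_variance_component(full, red_int, 2)
            if rho_defined:
                lam = max(0.0, 2.0 * (full.loglik - diag.loglik))
                p_rho = float(stats.chi2.sf(lam, 1))
            else:
                p_rho = 1.0
        return Model1Fit(
            fixed={n: (float(b), float(s), float(p)) for n, b, s, p in
                   zip(full.names, full.beta, full.se, full.pvalues)},
            sd_intercept=float(full.sd_random[0]),
            sd_slope=float(full.sd_random[1]),
            sd_resid=full.sd_resid,
            rho_int_slope=full.rho if rho_defined else None,
            p_random_intercept=p_int,
            p_random_slope=p_slope,
            p_rho=p_rho,
            rho_defined=rho_defined,
            loglik=full.loglik,
            converged=full.converged,
            n_obs=full.n_obs,
            n_individuals=full.n_groups,
            degenerate=degenerate,
            lmm=full,
        )

    # Model 2
    p_int = p_slope = p_d6 = p_d9 = nan
    if component_tests and not degenerate:
        red_int2 = _fit(y, X, Z[:, [1, 2, 3]], groups, names, False,
                        _warm(full, [1, 2, 3], False))
        red_slope2 = _fit(y, X, Z[:, [0, 2, 3]], groups, names, False,
                          _warm(full, [0, 2, 3], False))
        red_d6 = _fit(y, X, Z[:, [0, 1, 3]], groups, names, spec.correlated,
                      _warm(full, [0, 1, 3], spec.correlated))
        red_d9 = _fit(y, X, Z[:, [0, 1, 2]], groups, names, spec.correlated,
                      _warm(full, [0, 1, 2], spec.correlated))
        full = _refine_full(
            y, X, Z, groups, names, spec.correlated, full,
            [(red_int2, [1, 2, 3]), (red_slope2, [0, 2, 3]),
             (red_d6, [0, 1, 3]), (red_d9, [0, 1, 2])])
        p_int = test_variance_component(full, red_int2, 2)
        p_slope = test_variance_component(full, red_slope2, 2)
        p_d6 = test_variance_component(full, red_d6, 1)
        p_d9 = test_variance_component(full, red_d9, 1)
    fit2 = Model2Fit(
        fixed={n: (float(b), float(s), float(p)) for n, b, s, p in
               zip(full.names, full.beta, full.se, full.pvalues)},
        sd_intercept=float(full.sd_random[0]),
        sd_slope=float(full.sd_random[1]),
        sd_delta6=float(full.sd_random[2]),
        sd_delta9=float(full.sd_random[3]),
        sd_resid=full.sd_resid,
        rho_int_slope=full.rho,
        p_random_intercept=p_int,
        p_random_slope=p_slope,
        p_random_delta6=p_d6,
        p_random_delta9=p_d9,
        period_slopes={},
        loglik=full.loglik,
        converged=full.converged,
        n_obs=full.n_obs,
        n_individuals=full.n_groups,
        degenerate=degenerate,
        lmm=full,
    )
    fit2.period_slopes = period_slopes(fit2)
    return fit2


def fit_site(
    site_data: pd.DataFrame,
    spec1: DesignSpec | None = None,
    spec2: DesignSpec | None = None,
    component_tests: bool = True,
) -> tuple[Model1Fit, Model2Fit]:
    """Fit both trajectory models to one site."""
    spec1 = spec1 or DesignSpec(model=1)
    spec2 = spec2 or DesignSpec(model=2)
    m1 = fit_model(site_data, spec1, component_tests)
    m2 = fit_model(site_data, spec2, component_tests)
    return m1, m2


def test_fixed_effect_lrt(
    site_data: pd.DataFrame, spec: DesignSpec, term: str
) -> tuple[float, float]:
    """Likelihood-ratio alternative to the Wald test for one fixed effect.

    Refits the model with the named design column removed and returns
    (statistic, p) on 1 df.  Several times the cost of the default Wald z;
    provided for users who prefer LRT-based fixed-effect inference.
    """
    y = site_data["beta"].to_numpy(float)
    groups = site_data["individual_id"].to_numpy()
    X, Z, names, _ = build_design(site_data, spec)
    if term not in names:
        raise KeyError(f"unknown fixed term {term!r}; have {names}")
    keep = [j for j, n in enumerate(names) if n != term]
    full = _fit(y, X, Z, groups, names, spec.correlated)
    red = _fit(y, X[:, keep], Z, groups, [names[j] for j in keep], spec.correlated)
    lam = max(0.0, 2.0 * (full.loglik - red.loglik))
    return lam, float(stats.chi2.sf(lam, 1))


def test_intercept_slope_correlation(
    site_data: pd.DataFrame, spec: DesignSpec | None = None
) -> tuple[float | None, float, bool]:
    """Estimate and test the Model 1 random intercept-slope correlation.

    Returns (rho_hat, p, defined).  When either variance component is at
    its boundary the correlation is undefined: rho is None, p is 1 and
    ``defined`` is False.
    """
    spec = spec or DesignSpec(model=1)
    fit = fit_model(site_data, spec, component_tests=True)
    if not fit.rho_defined:
        return None, 1.0, False
    return fit.rho_int_slope, fit.p_rho, True


def period_slopes(fit: Model2Fit) -> dict[str, tuple[float, float, float]]:
    """Period-specific slopes from the Model 2 fixed effects.

    s1 = beta_age (birth to first knot), s2 = beta_age + delta6, and
    s3 = beta_age + delta6 + delta9, with SEs from linear contrasts of the
    fixed-effect covariance and Wald p-values.
    """
    if fit.lmm is None or fit.lmm.cov_beta is None:
        raise ValueError("period_slopes requires the fixed-effect covariance")
    names = fit.lmm.names
    knot_names = [n for n in names if n.startswith("age_m")]
    idx = [names.index("age")] + [names.index(k) for k in knot_names]
    out = {}
    for k, label in enumerate(("s1", "s2", "s3")):
        w = np.zeros(len(names))
        w[idx[: k + 1]] = 1.0
        out[label] = fit.lmm.contrast(w)
    return out
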