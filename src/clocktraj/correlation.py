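"""Birth-to-adulthood correlation of residualised methylation.

For each site, methylation is residualised at each time point for batch,
estimated white-blood-cell proportions, gestational age and sex by
ordinary least squares, and the Pearson correlation of the residuals is
computed across individuals observed at both birth and the oldest visit
of the cohort that has a late-adolescence (>= 15-year) visit.  The squared
correlation is the share of adult variation already predictable at birth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationResult",
    "residualize",
    "birth_adulthood_correlation",
    "variance_explained",
    "correlate_all_sites",
]

RESID_CONTINUOUS = ("gestational_age_z", "CD4T", "CD8T", "NK", "B", "mono", "gran")
RESID_CATEGORICAL = ("batch", "sex")


def _design(cov: pd.DataFrame, continuous=RESID_CONTINUOUS, categorical=RESID_CATEGORICAL):
    cols = [np.ones(len(cov))]
    names = ["intercept"]
    for c in continuous:
        if c in cov.columns:
            v = cov[c].to_numpy(float)
            if v.std() > 0:
                cols.append(v)
                names.append(c)
    for c in categorical:
        if c in cov.columns:
            levels = sorted(pd.unique(cov[c].astype(str)))
            for lev in levels[1:]:
                cols.append((cov[c].astype(str) == lev).to_numpy(float))
                names.append(f"{c}[{lev}]")
    return np.column_stack(cols), names


def residualize(values: np.ndarray, covariates: pd.DataFrame) -> np.ndarray:
    """OLS residuals of one visit's beta values on the covariate design.

    Residuals are orthogonal to the fitted design.  A rank-deficient
    design raises, naming the redundant columns.
    """
    y = np.asarray(values, float)
    X, names = _design(covariates)
    if len(y) < X.shape[1] + 2:
        raise ValueError("too few samples to residualise against this design")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        kept: list[int] = []
        bad = []
        for j in range(X.shape[1]):
            if np.linalg.matrix_rank(X[:, kept + [j]]) == len(kept) + 1:
                kept.append(j)
            else:
                bad.append(names[j])
        raise ValueError(f"rank-deficient residualisation design; drop columns {bad}")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


@dataclass(frozen=True)
class CorrelationResult:
    cpg_id: str
    r: float
    p: float
    n: int
    significant: bool
    defined: bool = True


def birth_adulthood_correlation(
    birth_values: np.ndarray,
    adult_values: np.ndarray,
    birth_covariates: pd.DataFrame,
    adult_covariates: pd.DataFrame,
    cpg_id: str = "",
    alpha: float = 1e-7,
    min_pairs: int = 10,
) -> CorrelationResult:
    """Pearson correlation of residualised methylation at birth vs adulthood.

    Inputs are paired per individual (same order at both visits).  Returns
    r, its two-sided p, the pair count, and significance at ``alpha``.
    Zero variance at either time point yields an undefined result.
    """
    if len(birth_values) != len(adult_values):
        raise ValueError("birth and adult values must pair one-to-one")
    if len(birth_values) < min_pairs:
        raise ValueError(f"need >= {min_pairs} paired individuals")
    rb = residualize(birth_values, birth_covariates)
    ra = residualize(adult_values, adult_covariates)
    if rb.std() < 1e-12 or ra.std() < 1e-12:  # constant up to rounding
        logger.warning("site %s: zero variance at a time point; r undefined", cpg_id)
        return CorrelationResult(cpg_id, float("nan"), float("nan"), len(rb), False, False)
    r, p = stats.pearsonr(rb, ra)
    return CorrelationResult(cpg_id, float(r), float(p), len(rb), bool(p < alpha), True)


def variance_explained(r: float) -> float:
    """Proportion of variance shared between the two time points: r squared."""
    if abs(r) > 1:
        raise ValueError("|r| must be <= 1")
    return float(r) ** 2


def correlate_all_sites(
    table,
    covariates,
    alpha: float = 1e-7,
    min_adult_age: float = 15.0,
    min_pairs: int = 10,
) -> pd.DataFrame:
    """Per-site birth vs oldest-visit correlations in the late-visit cohort.

    "Adulthood" is each individual's oldest visit within the cohort whose
    schedule includes a visit of at least ``min_adult_age`` years; pairing
    requires the birth visit observed as well (no imputation).
    """
    samp = table.samples
    cov = covariates.sample_covariates
    elig = samp.groupby("cohort")["visit_age_years"].max()
    cohorts = elig[elig >= min_adult_age].index
    if len(cohorts) == 0:
        raise ValueError(f"no cohort has a visit at >= {min_adult_age} years")
    in_cohort = samp["cohort"].isin(cohorts).to_numpy()

    is_birth = in_cohort & (samp["visit_age_years"].to_numpy() < 1.0)
    oldest = samp[in_cohort].groupby("individual_id")["visit_age_years"].transform("max")
    is_adult = np.zeros(len(samp), bool)
    sel = samp.index[in_cohort]
    is_adult[sel] = (
        (samp.loc[sel, "visit_age_years"] == oldest)
        & (samp.loc[sel, "visit_age_years"] >= min_adult_age)
    )

    b_idx = pd.Series(samp.index[is_birth].to_numpy(),
                      index=samp.loc[is_birth, "individual_id"])
    a_idx = pd.Series(samp.index[is_adult].to_numpy(),
                      index=samp.loc[is_adult, "individual_id"])
    paired = b_idx.index.intersection(a_idx.index)
    bi = b_idx.loc[paired].to_numpy()
    ai = a_idx.loc[paired].to_numpy()
    cov_b = cov.iloc[bi].reset_index(drop=True)
    cov_a = cov.iloc[ai].reset_index(drop=True)

    rows = []
    for j, cpg in enumerate(table.site_ids):
        res = birth_adulthood_correlation(
            table.betas[bi, j], table.betas[ai, j], cov_b, cov_a,
            cpg_id=cpg, alpha=alpha, min_pairs=min_pairs,
        )
        rows.append(res.__dict__)
    return pd.DataFrame(rows)
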