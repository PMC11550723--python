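"""Synthetic longitudinal methylation cohorts with known per-site truth.

Generates beta-valued DNA methylation (bounded in [0, 1]) for two birth
cohorts measured at three visits each, with the generative structure the
trajectory models assume: per-site piecewise-linear mean trajectories with
knots at 6 and 9 years, correlated random intercepts and age slopes,
independent random slope changes at the knots, additive meQTL genotype
effects under Hardy-Weinberg, binary prenatal-exposure effects, covariate
effects (sex, gestational age, batch plate, cell proportions), jittered
visit ages and scheduled missing visits.

The default configuration reproduces the bookkeeping of the two-cohort
study design it emulates: 1399 + 949 = 2348 individuals contributing
2333 + 2686 = 5019 samples, with childhood visits at mean ages 6.0 (SD 0.5)
and 9.8 (SD 0.3) years in cohort A and 7.5 (SD 0.2) and 17.1 (SD 1.0)
years in cohort B.

For an individual i at age t the generated value is::

    beta = mu0 + b0_i + (beta_age + b1_i) * t
         + (delta6 + b2_i) * max(0, t - 6) + (delta9 + b3_i) * max(0, t - 9)
         + covariate terms + meqtl_beta * dosage_i + exposure_beta * E_i + eps

with (b0, b1) bivariate normal with correlation ``rho_int_slope``,
(b2, b3) independent normals, and eps ~ N(0, sd_resid).  Values are clipped
to [0, 1]; the clipping fraction is reported and defaults are chosen to
keep it below 1%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CohortArm",
    "CohortConfig",
    "SiteTruth",
    "LongMethylationTable",
    "CovariateTable",
    "assign_site_archetypes",
    "simulate_genotypes",
    "simulate_site",
    "generate_cohort",
    "trajectory_covariance",
    "trajectory_variance",
    "truths_to_frame",
]

ARCHETYPES = ("flat", "linear", "knee6", "knee9")

#: Default archetype mixture, motivated by array-wide prevalences of change
#: (~52% of sites change; ~8% change then stabilise at 6; ~3% change slope
#: at 9; the rest are flat).
DEFAULT_MIXTURE: Mapping[str, float] = {
    "flat": 0.48,
    "linear": 0.41,
    "knee6": 0.08,
    "knee9": 0.03,
}

CELL_TYPES = ("CD4T", "CD8T", "NK", "B", "mono", "gran")

#: Minimum-detectable-effect presets (beta-fraction change per year).
#: Both readings of the reported detectable effect are exposed: 0.0025%/yr
#: and 0.025%/yr on the beta scale.
DETECTABLE_SLOPE_PRESETS: Mapping[str, float] = {
    "per_mille_low": 0.000025,
    "per_mille_high": 0.00025,
}


@dataclass(frozen=True)
class CohortArm:
    """One cohort's design: visit schedule and sample bookkeeping."""

    name: str
    n_individuals: int
    visit_mean_ages: tuple[float, ...]
    visit_age_sds: tuple[float, ...]
    n_samples: int | None = None  # deterministic target; None = no missingness

    def __post_init__(self) -> None:
        if len(self.visit_mean_ages) != len(self.visit_age_sds):
            raise ValueError("visit_mean_ages and visit_age_sds differ in length")
        if any(a < 0 for a in self.visit_mean_ages):
            raise ValueError("visit ages must be >= 0")
        cap = self.n_individuals * len(self.visit_mean_ages)
        if self.n_samples is not None and not (
            self.n_individuals <= self.n_samples <= cap
        ):
            raise ValueError(
                f"cohort {self.name!r}: n_samples={self.n_samples} infeasible "
                f"(need between {self.n_individuals} and {cap})"
            )


def default_arms() -> tuple[CohortArm, CohortArm]:
    return (
        CohortArm("A", 1399, (0.0, 6.0, 9.8), (0.0, 0.5, 0.3), n_samples=2333),
        CohortArm("B", 949, (0.0, 7.5, 17.1), (0.0, 0.2, 1.0), n_samples=2686),
    )


@dataclass
class CohortConfig:
    """Configuration of the synthetic cohort generator."""

    arms: tuple[CohortArm, ...] = field(default_factory=default_arms)
    n_sites: int = 2000
    seed: int = 0
    mixture: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_MIXTURE))
    missing_visit_prob: float | None = None  # overrides per-arm n_samples targets
    # site-truth fractions and ranges
    var_birth_frac: float = 0.25
    slope_var_frac: float = 0.04
    d6_var_frac: float = 0.003
    d9_var_frac: float = 0.08
    rho_magnitude: float = 0.6
    meqtl_frac: float = 0.08
    exposure_frac: float = 0.01
    maf: float = 0.3
    exposure_prevalence: float = 0.15
    covariate_effect_sd: float = 0.0  # SD of per-site sex/GA/cell effects (beta units per z)
    batch_effect_sd: float = 0.0  # SD of per-plate shifts
    n_batches: int = 24
    female_prob: float = 0.51
    clip_warn_fraction: float = 0.01

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        for p in (self.exposure_prevalence, self.female_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.missing_visit_prob is not None and not 0 <= self.missing_visit_prob <= 1:
            raise ValueError("missing_visit_prob must lie in [0, 1]")


@dataclass
class SiteTruth:
    """Generative parameters of one CpG site."""

    cpg_id: str
    archetype: str = "flat"
    mu0: float = 0.5
    beta_age: float = 0.0
    delta6: float = 0.0
    delta9: float = 0.0
    sd_intercept: float = 0.0
    sd_slope: float = 0.0
    sd_delta6: float = 0.0
    sd_delta9: float = 0.0
    rho_int_slope: float = 0.0
    sd_resid: float = 0.01
    meqtl_beta: float = 0.0
    exposure_beta: float = 0.0
    sex_beta: float = 0.0
    ga_beta: float = 0.0
    cell_betas: tuple[float, ...] = (0.0,) * 6

    def __post_init__(self) -> None:
        for name in ("sd_intercept", "sd_slope", "sd_delta6", "sd_delta9", "sd_resid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.cpg_id}: {name} must be >= 0")
        if abs(self.rho_int_slope) > 1:
            raise ValueError(f"{self.cpg_id}: |rho_int_slope| must be <= 1")
        if not 0 < self.mu0 < 1:
            raise ValueError(f"{self.cpg_id}: mu0 must lie in (0, 1)")


class LongMethylationTable:
    """Long-format methylation table backed by a samples-by-sites matrix.

    Rows of the long view are (individual_id, cohort, visit_age_years,
    cpg_id, beta) with beta in [0, 1] and unique (individual, visit, site)
    keys.
    """

    def __init__(self, samples: pd.DataFrame, site_ids: Sequence[str], betas: np.ndarray):
        betas = np.asarray(betas, dtype=float)
        if betas.shape != (len(samples), len(site_ids)):
            raise ValueError("betas shape does not match samples x sites")
        if betas.size and (betas.min() < 0 or betas.max() > 1):
            raise ValueError("beta values must lie in [0, 1]")
        key = samples[["individual_id", "visit_index"]]
        if key.duplicated().any():
            raise ValueError("duplicate (individual, visit) rows")
        self.samples = samples.reset_index(drop=True)
        self.site_ids = list(site_ids)
        self.betas = betas

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_individuals(self) -> int:
        return self.samples["individual_id"].nunique()

    def site(self, cpg_id: str) -> np.ndarray:
        return self.betas[:, self.site_ids.index(cpg_id)]

    def to_long(self) -> pd.DataFrame:
        n, m = self.betas.shape
        rep = self.samples.loc[
            self.samples.index.repeat(m),
            ["individual_id", "cohort", "visit_age_years"],
        ].reset_index(drop=True)
        rep["cpg_id"] = np.tile(np.asarray(self.site_ids, dtype=object), n)
        rep["beta"] = self.betas.ravel()
        return rep

    def to_csv(self, path) -> None:
        self.to_long().to_csv(path, index=False, float_format="%.6g")

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "LongMethylationTable":
        df = df.copy()
        sites = sorted(df["cpg_id"].unique())
        df["visit_index"] = df.groupby("individual_id")["visit_age_years"].rank(
            method="dense"
        ).astype(int) - 1
        samp = (
            df[["individual_id", "cohort", "visit_age_years", "visit_index"]]
            .drop_duplicates(["individual_id", "visit_index"])
            .reset_index(drop=True)
        )
        wide = df.pivot_table(
            index=["individual_id", "visit_index"], columns="cpg_id", values="beta"
        )[sites]
        key = pd.MultiIndex.from_frame(samp[["individual_id", "visit_index"]])
        return cls(samp, sites, wide.loc[key].to_numpy())


@dataclass
class CovariateTable:
    """Per-sample covariates plus per-individual genotype/exposure data.

    ``sample_covariates`` aligns row-for-row with the methylation table's
    samples; ``genotypes`` is individuals x meQTL-linked sites with dosage
    in {0, 1, 2}; ``exposure`` is a per-individual binary indicator.
    """

    sample_covariates: pd.DataFrame
    genotypes: pd.DataFrame
    exposure: pd.Series

    def __post_init__(self) -> None:
        cells = self.sample_covariates[list(CELL_TYPES)].to_numpy()
        if cells.size and (cells.min() < 0 or cells.sum(axis=1).max() > 1 + 1e-9):
            raise ValueError("cell proportions must be >= 0 and sum to <= 1")
        if self.genotypes.size and not self.genotypes.isin([0, 1, 2]).all().all():
            raise ValueError("genotype dosages must lie in {0, 1, 2}")


def assign_site_archetypes(
    n_sites: int,
    mixture: Mapping[str, float] | None = None,
    seed: int = 0,
    config: CohortConfig | None = None,
) -> list[SiteTruth]:
    """Draw per-site generative truths with archetype counts matching the mixture.

    Counts follow the largest-remainder rounding of ``n_sites * proportion``
    (each within 1 of exact), and the assignment is deterministic given the
    seed.  Dynamic parameters are drawn from realistic beta-scale ranges;
    flat sites have all trajectory parameters exactly zero.
    """
    mixture = dict(DEFAULT_MIXTURE if mixture is None else mixture)
    unknown = set(mixture) - set(ARCHETYPES)
    if unknown:
        raise ValueError(f"unknown archetypes: {sorted(unknown)}")
    total = sum(mixture.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"mixture proportions sum to {total!r}, not 1")
    cfg = config or CohortConfig(n_sites=n_sites, seed=seed)

    quotas = {a: n_sites * mixture.get(a, 0.0) for a in ARCHETYPES}
    counts = {a: int(np.floor(q)) for a, q in quotas.items()}
    short = n_sites - sum(counts.values())
    for a in sorted(ARCHETYPES, key=lambda a: quotas[a] - counts[a], reverse=True)[:short]:
        counts[a] += 1

    rng = np.random.default_rng(seed)
    labels = np.repeat(
        [a for a in ARCHETYPES for _ in range(counts[a])], 1
    )
    rng.shuffle(labels)

    truths = []
    for i, arch in enumerate(labels):
        truths.append(_draw_truth(f"cg{i:08d}", str(arch), rng, cfg))
    return truths


def _draw_truth(cpg_id: str, arch: str, rng: np.random.Generator, cfg: CohortConfig) -> SiteTruth:
    sgn = lambda: rng.choice([-1.0, 1.0])
    mu0 = rng.uniform(0.15, 0.85)
    beta_age = delta6 = delta9 = 0.0
    if arch != "flat":
        beta_age = sgn() * rng.uniform(0.002, 0.010)
    if arch == "knee6":
        delta6 = -beta_age  # change until 6, stable after
    elif arch == "knee9":
        delta9 = -2.0 * beta_age  # direction reverses in late childhood

    varb = rng.random() < cfg.var_birth_frac
    vars_ = rng.random() < cfg.slope_var_frac
    sd_int = rng.uniform(0.010, 0.030) if varb else rng.uniform(0.0, 0.002)
    sd_slope = rng.uniform(0.0010, 0.0030) if vars_ else rng.uniform(0.0, 0.0002)
    sd_d6 = rng.uniform(0.0010, 0.0030) if rng.random() < cfg.d6_var_frac else 0.0
    sd_d9 = rng.uniform(0.0010, 0.0030) if rng.random() < cfg.d9_var_frac else 0.0
    rho = sgn() * cfg.rho_magnitude if (varb and vars_) else 0.0
    meqtl = sgn() * rng.uniform(0.01, 0.05) if rng.random() < cfg.meqtl_frac else 0.0
    expo = sgn() * rng.uniform(0.005, 0.020) if rng.random() < cfg.exposure_frac else 0.0
    ces = cfg.covariate_effect_sd
    return SiteTruth(
        cpg_id=cpg_id,
        archetype=arch,
        mu0=mu0,
        beta_age=beta_age,
        delta6=delta6,
        delta9=delta9,
        sd_intercept=sd_int,
        sd_slope=sd_slope,
        sd_delta6=sd_d6,
        sd_delta9=sd_d9,
        rho_int_slope=rho,
        sd_resid=rng.uniform(0.005, 0.015),
        meqtl_beta=meqtl,
        exposure_beta=expo,
        sex_beta=rng.normal(0, ces) if ces else 0.0,
        ga_beta=rng.normal(0, ces) if ces else 0.0,
        cell_betas=tuple(rng.normal(0, ces, 6)) if ces else (0.0,) * 6,
    )


def simulate_genotypes(n_individuals: int, maf: float, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Biallelic dosages as the sum of two Bernoulli(maf) draws (Hardy-Weinberg)."""
    if not 0 < maf < 1:
        raise ValueError(f"maf must lie in (0, 1), got {maf}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.binomial(2, maf, n_individuals)


def simulate_site(
    truth: SiteTruth,
    individual_index: np.ndarray,
    ages: np.ndarray,
    rng: np.random.Generator,
    dosage: np.ndarray | None = None,
    exposure: np.ndarray | None = None,
    covariate_effect: np.ndarray | None = None,
    clip_warn_fraction: float = 0.01,
) -> tuple[np.ndarray, float]:
    """Generate one site's beta values for all samples.

    ``individual_index`` maps each sample row to a 0..n_ind-1 individual;
    ``dosage``/``exposure`` are per-individual; ``covariate_effect`` is an
    optional precomputed per-sample additive term.  Returns the clipped
    values and the clipping fraction.
    """
    ages = np.asarray(ages, dtype=float)
    idx = np.asarray(individual_index)
    n_ind = int(idx.max()) + 1 if idx.size else 0

    # correlated (intercept, slope) pair via explicit Cholesky factors, which
    # also handles zero-variance components exactly
    z0 = rng.standard_normal(n_ind)
    z1 = rng.standard_normal(n_ind)
    rho = truth.rho_int_slope
    b0 = truth.sd_intercept * z0
    b1 = truth.sd_slope * (rho * z0 + np.sqrt(max(0.0, 1.0 - rho**2)) * z1)
    b2 = rng.normal(0.0, truth.sd_delta6, n_ind) if truth.sd_delta6 else np.zeros(n_ind)
    b3 = rng.normal(0.0, truth.sd_delta9, n_ind) if truth.sd_delta9 else np.zeros(n_ind)

    t6 = np.maximum(0.0, ages - 6.0)
    t9 = np.maximum(0.0, ages - 9.0)
    y = (
        truth.mu0
        + b0[idx]
        + (truth.beta_age + b1[idx]) * ages
        + (truth.delta6 + b2[idx]) * t6
        + (truth.delta9 + b3[idx]) * t9
        + rng.normal(0.0, truth.sd_resid, len(ages))
    )
    if dosage is not None and truth.meqtl_beta:
        y += truth.meqtl_beta * np.asarray(dosage)[idx]
    if exposure is not None and truth.exposure_beta:
        y += truth.exposure_beta * np.asarray(exposure)[idx]
    if covariate_effect is not None:
        y += covariate_effect

    clipped = np.clip(y, 0.0, 1.0)
    frac = float(np.mean(clipped != y)) if y.size else 0.0
    if frac > clip_warn_fraction:
        logger.warning(
            "site %s: clipping fraction %.3f exceeds %.3f",
            truth.cpg_id, frac, clip_warn_fraction,
        )
    return clipped, frac


def _schedule_missing(
    n_ind: int, n_visits: int, target: int, rng: np.random.Generator
) -> np.ndarray:
    """Boolean keep-mask (n_ind, n_visits) dropping slots until exactly
    ``target`` samples remain, never emptying an individual."""
    keep = np.ones((n_ind, n_visits), dtype=bool)
    to_drop = n_ind * n_visits - target
    order = rng.permutation(n_ind * n_visits)
    remaining = np.full(n_ind, n_visits)
    for slot in order:
        if to_drop == 0:
            break
        i, v = divmod(slot, n_visits)
        if remaining[i] > 1:
            keep[i, v] = False
            remaining[i] -= 1
            to_drop -= 1
    if to_drop:
        raise ValueError("infeasible missingness schedule")
    return keep


def generate_cohort(
    config: CohortConfig | None = None,
    truths: Sequence[SiteTruth] | None = None,
) -> tuple[LongMethylationTable, CovariateTable, list[SiteTruth]]:
    """Generate the full synthetic cohort.

    The default configuration yields exactly 2348 individuals contributing
    5019 samples.  All outputs are deterministic given ``config.seed``;
    supplying explicit ``truths`` overrides the drawn site parameters.
    """
    cfg = config or CohortConfig()
    rng = np.random.default_rng(cfg.seed)

    if truths is None:
        truths = assign_site_archetypes(cfg.n_sites, cfg.mixture, seed=cfg.seed + 1, config=cfg)
    truths = list(truths)

    rows = []
    ind_offset = 0
    for arm in cfg.arms:
        n_visits = len(arm.visit_mean_ages)
        ages = np.asarray(arm.visit_mean_ages) + rng.standard_normal(
            (arm.n_individuals, n_visits)
        ) * np.asarray(arm.visit_age_sds)
        ages = np.maximum(ages, 0.0)
        if cfg.missing_visit_prob is not None:
            keep = rng.random((arm.n_individuals, n_visits)) >= cfg.missing_visit_prob
            empt = ~keep.any(axis=1)
            keep[empt, 0] = True  # every individual keeps >= 1 visit
        elif arm.n_samples is not None:
            keep = _schedule_missing(arm.n_individuals, n_visits, arm.n_samples, rng)
        else:
            keep = np.ones((arm.n_individuals, n_visits), dtype=bool)
        for i in range(arm.n_individuals):
            for v in range(n_visits):
                if keep[i, v]:
                    rows.append(
                        (f"{arm.name}{i:05d}", arm.name, float(ages[i, v]), v, ind_offset + i)
                    )
        ind_offset += arm.n_individuals

    samples = pd.DataFrame(
        rows, columns=["individual_id", "cohort", "visit_age_years", "visit_index", "_ind"]
    )
    n_ind_total = ind_offset
    present = np.unique(samples["_ind"])
    # re-index individuals densely (all are present by construction)
    idx = samples["_ind"].to_numpy()

    # --- individual- and sample-level covariates -------------------------
    sex = rng.random(n_ind_total) < cfg.female_prob
    ga_z = rng.standard_normal(n_ind_total)
    exposure = rng.random(n_ind_total) < cfg.exposure_prevalence
    n = len(samples)
    batch = rng.integers(0, cfg.n_batches, n)
    # seven blood fractions (the seventh, nRBC-like, is generated but not
    # reported: it is cord-blood specific and excluded from analysis), so
    # the six analysed proportions do not sum exactly to one
    alpha = np.array([0.14, 0.08, 0.05, 0.08, 0.07, 0.53, 0.05]) * 60
    cells = rng.dirichlet(alpha, size=n)[:, :6]

    meqtl_sites = [t.cpg_id for t in truths if t.meqtl_beta != 0.0]
    geno = pd.DataFrame(
        {s: simulate_genotypes(n_ind_total, cfg.maf, rng) for s in meqtl_sites},
        index=pd.Index([_ind_id(cfg, k) for k in range(n_ind_total)], name="individual_id"),
        dtype=int,
    )

    cell_z = (cells - cells.mean(axis=0)) / np.where(cells.std(axis=0) > 0, cells.std(axis=0), 1.0)
    sex_s = sex[idx].astype(float)
    ga_s = ga_z[idx]
    batch_shift = {}

    betas = np.empty((n, len(truths)))
    clip_fracs = np.empty(len(truths))
    ages_s = samples["visit_age_years"].to_numpy()
    for j, t in enumerate(truths):
        cov_eff = None
        if t.sex_beta or t.ga_beta or any(t.cell_betas) or cfg.batch_effect_sd:
            cov_eff = t.sex_beta * sex_s + t.ga_beta * ga_s + cell_z @ np.asarray(t.cell_betas)
            if cfg.batch_effect_sd:
                shifts = rng.normal(0, cfg.batch_effect_sd, cfg.n_batches)
                cov_eff = cov_eff + shifts[batch]
        betas[:, j], clip_fracs[j] = simulate_site(
            t,
            idx,
            ages_s,
            rng,
            dosage=geno[t.cpg_id].to_numpy() if t.cpg_id in geno else None,
            exposure=exposure,
            covariate_effect=cov_eff,
            clip_warn_fraction=cfg.clip_warn_fraction,
        )
    logger.info(
        "generated %d samples x %d sites; mean clipping fraction %.4f",
        n, len(truths), float(clip_fracs.mean()) if len(truths) else 0.0,
    )

    sample_cov = pd.DataFrame(
        {
            "individual_id": samples["individual_id"],
            "visit_index": samples["visit_index"],
            "cohort": samples["cohort"],
            "visit_age_years": ages_s,
            "sex": np.where(sex_s > 0, "F", "M"),
            "gestational_age_z": ga_s,
            "batch": [f"plate{b:02d}" for b in batch],
        }
    )
    for k, ct in enumerate(CELL_TYPES):
        sample_cov[ct] = cells[:, k]

    table = LongMethylationTable(
        samples[["individual_id", "cohort", "visit_age_years", "visit_index"]],
        [t.cpg_id for t in truths],
        betas,
    )
    cov = CovariateTable(
        sample_covariates=sample_cov,
        genotypes=geno,
        exposure=pd.Series(exposure.astype(int), index=geno.index, name="exposure"),
    )
    return table, cov, truths


def _ind_id(cfg: CohortConfig, k: int) -> str:
    off = 0
    for arm in cfg.arms:
        if k < off + arm.n_individuals:
            return f"{arm.name}{k - off:05d}"
        off += arm.n_individuals
    raise IndexError(k)


# --- closed-form moments -------------------------------------------------

def trajectory_covariance(truth: SiteTruth, t1: float, t2: float) -> float:
    """Model-implied covariance of one individual's values at ages t1, t2.

    Includes the individual-level sources (random intercept/slope with
    correlation, random slope changes, meQTL and exposure effects under
    their default allele/prevalence frequencies is NOT included here —
    genetic terms are individual-constant and must be added by the caller
    when relevant).  Occasion-level residual variance is added only when
    ``t1 == t2``.
    """
    si, ss = truth.sd_intercept, truth.sd_slope
    c = (
        si**2
        + t1 * t2 * ss**2
        + (t1 + t2) * truth.rho_int_slope * si * ss
        + max(0.0, t1 - 6) * max(0.0, t2 - 6) * truth.sd_delta6**2
        + max(0.0, t1 - 9) * max(0.0, t2 - 9) * truth.sd_delta9**2
    )
    if t1 == t2:
        c += truth.sd_resid**2
    return c


def trajectory_variance(truth: SiteTruth, t: float) -> float:
    """Model-implied variance of the generated beta at age ``t`` (unclipped)."""
    return trajectory_covariance(truth, t, t)


def truths_to_frame(truths: Sequence[SiteTruth]) -> pd.DataFrame:
    recs = []
    for t in truths:
        d = asdict(t)
        cb = d.pop("cell_betas")
        for k, ct in enumerate(CELL_TYPES):
            d[f"cell_beta_{ct}"] = cb[k]
        recs.append(d)
    return pd.DataFrame(recs)
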