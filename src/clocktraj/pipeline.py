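"""End-to-end orchestration: simulate -> fit -> classify -> correlate ->
enrich -> match -> report.

Each stage reads and writes plain CSV/TSV files under an output directory
and records itself in a JSON run manifest (seed, config hash, outputs), so
a run is resumable stage by stage and fully reproducible from (config,
seed).  The stages are ordinary functions; the command-line interface in
:mod:`clocktraj.cli` is a thin wrapper over them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clocks as _clocks
from .clocks import Generation, SiteGroups, build_site_groups, make_mock_clock
from .correlation import correlate_all_sites
from .enrichment import direction_consistency, fisher_exact, make_contingency
from .features import FeatureFlags, flags_to_frame
from .matching import MatchResult, MatchSpec, match_background, matched_enrichment
from .models import DesignSpec, fit_site
from .simulate import CohortArm, CohortConfig, generate_cohort, truths_to_frame

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_simulate", "run_full", "load_config"]

ENRICH_FEATURES = (
    "changes",
    "nonlinear_at_6",
    "nonlinear_at_9",
    "change_then_stable_at_6",
    "var_at_birth",
    "rate_var_from_birth",
    "rate_var_from_6",
    "rate_var_from_9",
    "int_slope_corr_sig",
)


@dataclass
class PipelineConfig:
    """Everything a full run needs; defaults give a desk-scale synthetic run."""

    out_dir: str = "clocktraj_run"
    seed: int = 0
    # simulation
    n_sites: int = 500
    n_individuals: tuple[int, int] = (1399, 949)
    n_samples: tuple[int, int] | None = (2333, 2686)
    scale: float | None = None  # shrink the default cohort by this factor
    # synthetic clock construction: "random" draws clock sites uniformly,
    # "designed" over-samples high-intercept-variance sites
    clock_mode: str = "designed"
    n_clock_sites: tuple[int, int] = (60, 50)
    clock_bias_frac: float = 0.7  # designed: fraction drawn from high-variance pool
    # modelling
    knots: tuple[float, float] = (6.0, 9.0)
    alpha_site: float = 1e-7
    alpha_enrich: float = 0.05
    min_individuals: int = 50
    adjust_covariates: bool = True
    chunk_size: int = 200
    # matching
    match_feature: str = "sd_intercept_hat"
    match_ratio: int = 8
    n_batches: int | None = None  # None: ~one plate of 96 samples each
    threads: int = 1  # parallel workers for per-site fitting

    def cohort_config(self) -> CohortConfig:
        n_a, n_b = self.n_individuals
        s = self.n_samples
        if self.scale:
            n_a = max(2, int(round(n_a * self.scale)))
            n_b = max(2, int(round(n_b * self.scale)))
            s = None
        arms = (
            CohortArm("A", n_a, (0.0, 6.0, 9.8), (0.0, 0.5, 0.3),
                      n_samples=s[0] if s else None),
            CohortArm("B", n_b, (0.0, 7.5, 17.1), (0.0, 0.2, 1.0),
                      n_samples=s[1] if s else None),
        )
        expected = sum(
            a.n_samples if a.n_samples else a.n_individuals * len(a.visit_mean_ages)
            for a in arms
        )
        n_batches = self.n_batches or max(2, expected // 96)
        return CohortConfig(arms=arms, n_sites=self.n_sites, seed=self.seed,
                            n_batches=n_batches)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for key in ("n_individuals", "n_samples", "n_clock_sites", "knots"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    return PipelineConfig(**raw)


def _manifest_update(out: Path, cfg: PipelineConfig, stage: str, files: list[str]) -> None:
    path = out / "manifest.json"
    man = json.loads(path.read_text()) if path.exists() else {
        "seed": cfg.seed, "config_hash": cfg.config_hash(), "config": cfg.to_dict(),
        "stages": {},
    }
    man["stages"][stage] = {"files": files, "time": time.strftime("%Y-%m-%dT%H:%M:%S")}
    path.write_text(json.dumps(man, indent=2, sort_keys=True, default=str))


def _done(out: Path, files: list[str]) -> bool:
    return all((out / f).exists() for f in files)


# --------------------------------------------------------------------- stages

def run_simulate(cfg: PipelineConfig, resume: bool = False):
    """Generate the synthetic cohort and write its three tables."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = ["samples.csv", "betas.csv", "covariates.csv", "truth.csv", "exposure.csv"]
    table, cov, truths = generate_cohort(cfg.cohort_config())
    if not (resume and _done(out, files)):
        table.samples.to_csv(out / "samples.csv", index=False, float_format="%.6g")
        pd.DataFrame(table.betas, columns=table.site_ids).to_csv(
            out / "betas.csv", index=False, float_format="%.6g")
        cov.sample_covariates.to_csv(out / "covariates.csv", index=False, float_format="%.6g")
        truths_to_frame(truths).to_csv(out / "truth.csv", index=False, float_format="%.6g")
        pd.concat([cov.exposure, cov.genotypes], axis=1).to_csv(out / "exposure.csv")
        _manifest_update(out, cfg, "simulate", files)
    return table, cov, truths


def build_synthetic_clocks(cfg: PipelineConfig, truths) -> tuple[list, SiteGroups]:
    """Construct study clocks over the simulated sites.

    ``random`` mode draws clock sites uniformly (a global null for every
    enrichment); ``designed`` over-samples sites whose true random-intercept
    SD is in the top quartile, planting a var-at-birth enrichment.
    """
    rng = np.random.default_rng(cfg.seed + 1000)
    ids = np.array([t.cpg_id for t in truths], dtype=object)
    n1, n2 = cfg.n_clock_sites
    if cfg.clock_mode == "random":
        pick = rng.choice(ids, size=n1 + n2, replace=False)
        first, second = pick[:n1], pick[n1:]
    elif cfg.clock_mode == "designed":
        sd = np.array([t.sd_intercept for t in truths])
        hi = ids[sd >= np.quantile(sd, 0.75)]
        lo = ids[sd < np.quantile(sd, 0.75)]
        first, second = [], []
        for n, dest in ((n1, first), (n2, second)):
            k_hi = int(round(cfg.clock_bias_frac * n))
            hi_pool = np.setdiff1d(hi, np.concatenate([first, second]) if (len(first) or len(second)) else [])
            lo_pool = np.setdiff1d(lo, np.concatenate([first, second]) if (len(first) or len(second)) else [])
            dest.extend(rng.choice(hi_pool, size=min(k_hi, len(hi_pool)), replace=False))
            dest.extend(rng.choice(lo_pool, size=n - min(k_hi, len(hi_pool)), replace=False))
        first, second = np.array(first, dtype=object), np.array(second, dtype=object)
    else:
        raise ValueError(f"unknown clock_mode {cfg.clock_mode!r}")
    clock1 = make_mock_clock("sim_first", [str(s) for s in first], Generation.FIRST,
                             seed=cfg.seed + 1)
    clock2 = make_mock_clock("sim_second", [str(s) for s in second],
                             Generation.SECOND_THIRD, seed=cfg.seed + 2)
    groups = build_site_groups([clock1, clock2], [str(s) for s in ids])
    return [clock1, clock2], groups


def run_fit(cfg: PipelineConfig, table, cov, resume: bool = False) -> pd.DataFrame:
    """Fit both models per site; write the flat summary-statistics table."""
    out = Path(cfg.out_dir)
    if resume and (out / "model_fits.tsv").exists():
        return pd.read_csv(out / "model_fits.tsv", sep="\t")
    spec_kw = {} if cfg.adjust_covariates else {"continuous": (), "categorical": ()}
    spec1 = DesignSpec(model=1, knots=cfg.knots, min_individuals=cfg.min_individuals, **spec_kw)
    spec2 = DesignSpec(model=2, knots=cfg.knots, min_individuals=cfg.min_individuals, **spec_kw)
    base = cov.sample_covariates.copy()

    def fit_one(j, cpg):
        df = base.copy()
        df["beta"] = table.betas[:, j]
        try:
            m1, m2 = fit_site(df, spec1, spec2)
            return _fit_row(cpg, m1, m2)
        except Exception as exc:  # noqa: BLE001 - per-site failure is recorded, not fatal
            logger.warning("site %s failed: %s", cpg, exc)
            return {"cpg_id": cpg, "fit_ok": False}

    t0 = time.time()
    if cfg.threads > 1:
        from joblib import Parallel, delayed

        rows = Parallel(n_jobs=cfg.threads, batch_size=cfg.chunk_size)(
            delayed(fit_one)(j, cpg) for j, cpg in enumerate(table.site_ids))
    else:
        rows = []
        for j, cpg in enumerate(table.site_ids):
            rows.append(fit_one(j, cpg))
            if (j + 1) % cfg.chunk_size == 0:
                logger.info("fitted %d/%d sites (%.1fs)", j + 1,
                            len(table.site_ids), time.time() - t0)
    # sorted on write so the result is order-stable regardless of chunking
    fits = pd.DataFrame(rows).sort_values("cpg_id").reset_index(drop=True)
    fits.to_csv(out / "model_fits.tsv", sep="\t", index=False)
    _manifest_update(out, cfg, "fit", ["model_fits.tsv"])
    return fits


def _fit_row(cpg, m1, m2) -> dict:
    row = {"cpg_id": cpg, "fit_ok": bool(m1.converged and m2.converged
                                         and not (m1.degenerate or m2.degenerate))}
    e, s, p = m1.fixed["age"]
    row.update(m1_age=e, m1_age_se=s, m1_age_p=p,
               m1_sd_intercept=m1.sd_intercept, m1_sd_slope=m1.sd_slope,
               m1_sd_resid=m1.sd_resid,
               m1_rho=m1.rho_int_slope if m1.rho_defined else np.nan,
               m1_p_rand_int=m1.p_random_intercept, m1_p_rand_slope=m1.p_random_slope,
               m1_p_rho=m1.p_rho, m1_rho_defined=m1.rho_defined, m1_loglik=m1.loglik)
    for name, key in (("age", "m2_age"),):
        e, s, p = m2.fixed[name]
        row.update({key: e, key + "_se": s, key + "_p": p})
    knot_names = [n for n in m2.fixed if n.startswith("age_m")]
    for key, name in zip(("m2_d6", "m2_d9"), knot_names):
        e, s, p = m2.fixed[name]
        row.update({key: e, key + "_se": s, key + "_p": p})
    for lab in ("s1", "s2", "s3"):
        e, s, p = m2.period_slopes[lab]
        row.update({f"m2_{lab}": e, f"m2_{lab}_se": s, f"m2_{lab}_p": p})
    row.update(m2_sd_intercept=m2.sd_intercept, m2_sd_slope=m2.sd_slope,
               m2_sd_d6=m2.sd_delta6, m2_sd_d9=m2.sd_delta9,
               m2_p_rand_int=m2.p_random_intercept, m2_p_rand_slope=m2.p_random_slope,
               m2_p_rand_d6=m2.p_random_delta6, m2_p_rand_d9=m2.p_random_delta9,
               m2_loglik=m2.loglik)
    return row


def classify_from_fits(fits: pd.DataFrame, alpha: float) -> dict[str, FeatureFlags]:
    """Feature flags from the flat fit table (columns as written by run_fit)."""
    flags = {}
    sig = lambda p: bool(pd.notna(p) and p < alpha)
    for r in fits.itertuples(index=False):
        if not getattr(r, "fit_ok", False):
            flags[r.cpg_id] = FeatureFlags(cpg_id=r.cpg_id, fit_ok=False)
            continue
        changes = sig(r.m1_age_p)
        nl6, nl9 = sig(r.m2_d6_p), sig(r.m2_d9_p)
        flags[r.cpg_id] = FeatureFlags(
            cpg_id=r.cpg_id, fit_ok=True, changes=changes,
            change_direction=("increasing" if r.m1_age > 0 else "decreasing") if changes else "none",
            nonlinear_at_6=nl6, nonlinear_at_9=nl9, nonlinear_any=nl6 or nl9,
            change_then_stable_at_6=nl6 and sig(r.m2_s1_p) and not sig(r.m2_s2_p) and not nl9,
            var_at_birth=sig(r.m1_p_rand_int),
            rate_var_from_birth=sig(r.m2_p_rand_slope),
            rate_var_from_6=sig(r.m2_p_rand_d6),
            rate_var_from_9=sig(r.m2_p_rand_d9),
            int_slope_corr_sig=bool(r.m1_rho_defined) and sig(r.m1_p_rho),
        )
    return flags


def run_classify(cfg: PipelineConfig, fits: pd.DataFrame) -> dict[str, FeatureFlags]:
    out = Path(cfg.out_dir)
    flags = classify_from_fits(fits, cfg.alpha_site)
    flags_to_frame(flags).sort_values("cpg_id").to_csv(
        out / "site_features.tsv", sep="\t", index=False)
    _manifest_update(out, cfg, "classify", ["site_features.tsv"])
    return flags


def run_correlate(cfg: PipelineConfig, table, cov) -> pd.DataFrame:
    out = Path(cfg.out_dir)
    res = correlate_all_sites(table, cov, alpha=cfg.alpha_site)
    res.to_csv(out / "birth_adult_correlation.tsv", sep="\t", index=False,
               float_format="%.6g")
    _manifest_update(out, cfg, "correlate", ["birth_adult_correlation.tsv"])
    return res


def run_enrich(cfg: PipelineConfig, flags, site_groups, clocks,
               annotations: dict[str, set] | None = None) -> pd.DataFrame:
    """Clock-vs-background enrichment for every feature, the coefficient
    direction-consistency test, and any supplied annotation site sets
    (meQTL lists, exposure-associated CpGs, WBC panels)."""
    from .enrichment import annotation_enrichment

    out = Path(cfg.out_dir)
    rows = []
    for group in (Generation.FIRST, Generation.SECOND_THIRD):
        for feat in ENRICH_FEATURES:
            table = make_contingency(flags, site_groups, feat, group)
            res = fisher_exact(table, feature=feat, group=group.value)
            rows.append(_enrich_row(res))
        dirs = _clocks.site_coefficient_direction(clocks)
        res = direction_consistency(dirs, flags, set(site_groups.on_array(group)))
        res = dataclasses.replace(res, group=group.value)
        rows.append(_enrich_row(res))
        for name, ann in (annotations or {}).items():
            try:
                res = annotation_enrichment(ann, site_groups, group, feature=name)
            except ValueError as exc:
                logger.warning("annotation %s skipped for %s: %s", name, group.value, exc)
                continue
            rows.append(_enrich_row(res))
    df = pd.DataFrame(rows)
    df.to_csv(out / "enrichment.tsv", sep="\t", index=False, float_format="%.6g")
    _manifest_update(out, cfg, "enrich", ["enrichment.tsv"])
    return df


def _enrich_row(res) -> dict:
    t = res.table
    return dict(feature=res.feature, group=res.group, a=t.a, b=t.b, c=t.c, d=t.d,
                odds_ratio=res.odds_ratio, ci_low=res.ci_low, ci_high=res.ci_high,
                p=res.p, or_approximate=res.or_approximate, unstable=res.unstable)


def run_match(cfg: PipelineConfig, fits: pd.DataFrame, flags, site_groups
              ) -> dict[str, MatchResult]:
    """Match non-clock backgrounds to each clock group on a fitted scalar."""
    out = Path(cfg.out_dir)
    col = {"sd_intercept_hat": "m1_sd_intercept", "abs_change_hat": "m1_age"}[cfg.match_feature]
    vals = fits.set_index("cpg_id")[col]
    if cfg.match_feature == "abs_change_hat":
        vals = vals.abs()
    ok = fits.set_index("cpg_id")["fit_ok"]
    results = {}
    for group in (Generation.FIRST, Generation.SECOND_THIRD):
        treated_ids = [s for s in site_groups.on_array(group) if ok.get(s, False)]
        cand_ids = [s for s in site_groups.background(group) if ok.get(s, False)]
        spec = MatchSpec(feature=cfg.match_feature, ratio=cfg.match_ratio)
        mr = match_background(
            {s: float(vals[s]) for s in treated_ids},
            {s: float(vals[s]) for s in cand_ids},
            spec,
        )
        mr.pairs_frame().to_csv(out / f"matched_pairs_{group.value}.csv", index=False,
                                float_format="%.6g")
        results[group.value] = mr
    _manifest_update(out, cfg, "match",
                     [f"matched_pairs_{g}.csv" for g in results])
    return results


def run_matched_enrich(cfg: PipelineConfig, flags, site_groups,
                       match_results) -> pd.DataFrame:
    out = Path(cfg.out_dir)
    rows = []
    for group in (Generation.FIRST, Generation.SECOND_THIRD):
        mr = match_results[group.value]
        for feat in ENRICH_FEATURES:
            res = matched_enrichment(flags, site_groups, feat, group, mr)
            res = dataclasses.replace(res, group=group.value)
            rows.append(_enrich_row(res) | {"smd_before": mr.smd_before,
                                            "smd_after": mr.smd_after})
    df = pd.DataFrame(rows)
    df.to_csv(out / "matched_enrichment.tsv", sep="\t", index=False, float_format="%.6g")
    _manifest_update(out, cfg, "matched_enrich", ["matched_enrichment.tsv"])
    return df


def run_full(cfg: PipelineConfig, resume: bool = False) -> dict:
    """Execute every stage and return the summary report (also written as JSON)."""
    out = Path(cfg.out_dir)
    table, cov, truths = run_simulate(cfg, resume=resume)
    clocks, groups = build_synthetic_clocks(cfg, truths)
    fits = run_fit(cfg, table, cov, resume=resume)
    flags = run_classify(cfg, fits)
    corr = run_correlate(cfg, table, cov)
    annotations = {
        "meqtl": {t.cpg_id for t in truths if t.meqtl_beta != 0},
        "prenatal_exposure": {t.cpg_id for t in truths if t.exposure_beta != 0},
    }
    enrich = run_enrich(cfg, flags, groups, clocks, annotations=annotations)
    matches = run_match(cfg, fits, flags, groups)
    matched = run_matched_enrich(cfg, flags, groups, matches)

    from .features import feature_prevalence
    report = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "n_individuals": int(table.n_individuals),
        "n_samples": int(table.n_samples),
        "n_sites": len(table.site_ids),
        "prevalence": {
            "all": feature_prevalence(flags).to_dict(),
            "first": feature_prevalence(flags, set(groups.on_array("first"))).to_dict(),
            "second_third": feature_prevalence(
                flags, set(groups.on_array("second_third"))).to_dict(),
        },
        "significant_correlations": float((corr["significant"]).mean()),
        "enrichment": enrich.to_dict(orient="records"),
        "matched_enrichment": matched.to_dict(orient="records"),
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    _manifest_update(out, cfg, "report", ["report.json"])
    return report
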