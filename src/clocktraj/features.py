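"""Developmental-feature taxonomy of CpG sites.

Converts the per-site mixed-model results into boolean flags at a fixed
site-level significance threshold (default 1e-7, the Bonferroni-style
cutoff for an array-scale analysis): whether the site changes with age and
in which direction, whether the change is non-linear at the 6- and 9-year
knots, whether it changes then stabilises at 6, and whether individuals
differ at birth or in their rate of change from birth, 6 or 9 years.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import pandas as pd

from .models import Model1Fit, Model2Fit

__all__ = ["FeatureFlags", "classify_site", "feature_prevalence", "flags_to_frame"]

BOOL_FEATURES = (
    "changes",
    "nonlinear_at_6",
    "nonlinear_at_9",
    "nonlinear_any",
    "change_then_stable_at_6",
    "var_at_birth",
    "rate_var_from_birth",
    "rate_var_from_6",
    "rate_var_from_9",
    "int_slope_corr_sig",
)


@dataclass(frozen=True)
class FeatureFlags:
    """Per-site developmental features; all flags are False when fit_ok is."""

    cpg_id: str
    fit_ok: bool
    changes: bool = False
    change_direction: str = "none"  # increasing | decreasing | none
    nonlinear_at_6: bool = False
    nonlinear_at_9: bool = False
    nonlinear_any: bool = False
    change_then_stable_at_6: bool = False
    var_at_birth: bool = False
    rate_var_from_birth: bool = False
    rate_var_from_6: bool = False
    rate_var_from_9: bool = False
    int_slope_corr_sig: bool = False

    def __post_init__(self) -> None:
        if (self.change_direction == "none") == self.changes:
            raise ValueError("change_direction must be none iff changes is False")
        if not self.fit_ok and any(getattr(self, f) for f in BOOL_FEATURES):
            raise ValueError("failed fits must carry no feature flags")


def _sig(p: float, alpha: float) -> bool:
    return bool(p == p and p < alpha)  # NaN-safe


def classify_site(
    cpg_id: str, m1: Model1Fit | None, m2: Model2Fit | None, alpha: float = 1e-7
) -> FeatureFlags:
    """Apply the feature taxonomy to one site's Model 1/2 fits.

    A site *changes* if the Model 1 fixed age effect is significant, with
    direction from its sign.  Non-linearity at a knot requires the Model 2
    slope-change fixed effect there; *change-then-stable at 6* additionally
    requires a significant birth-to-6 period slope, a non-significant
    post-6 slope, and no slope change at 9.  Inter-individual variability
    flags come from the random-effect tests; the intercept-slope
    correlation is evaluated only where both components are estimable.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    ok = (
        m1 is not None and m2 is not None
        and m1.converged and m2.converged
        and not (m1.degenerate or m2.degenerate)
    )
    if not ok:
        return FeatureFlags(cpg_id=cpg_id, fit_ok=False)

    est_age, _, p_age = m1.fixed["age"]
    changes = _sig(p_age, alpha)
    direction = "none" if not changes else ("increasing" if est_age > 0 else "decreasing")

    knot6, knot9 = (n for n in m2.fixed if n.startswith("age_m"))
    nl6 = _sig(m2.fixed[knot6][2], alpha)
    nl9 = _sig(m2.fixed[knot9][2], alpha)
    s1_p = m2.period_slopes["s1"][2]
    s2_p = m2.period_slopes["s2"][2]
    cts6 = nl6 and _sig(s1_p, alpha) and not _sig(s2_p, alpha) and not nl9

    corr_sig = m1.rho_defined and _sig(m1.p_rho, alpha)
    return FeatureFlags(
        cpg_id=cpg_id,
        fit_ok=True,
        changes=changes,
        change_direction=direction,
        nonlinear_at_6=nl6,
        nonlinear_at_9=nl9,
        nonlinear_any=nl6 or nl9,
        change_then_stable_at_6=cts6,
        var_at_birth=_sig(m1.p_random_intercept, alpha),
        rate_var_from_birth=_sig(m2.p_random_slope, alpha),
        rate_var_from_6=_sig(m2.p_random_delta6, alpha),
        rate_var_from_9=_sig(m2.p_random_delta9, alpha),
        int_slope_corr_sig=corr_sig,
    )


def feature_prevalence(
    flags: dict[str, FeatureFlags] | list[FeatureFlags],
    group: set[str] | None = None,
) -> pd.Series:
    """Per-feature prevalence among successfully fitted sites of a group.

    Returns fractions plus the denominator under ``n``; failed fits are
    excluded from numerator and denominator alike.
    """
    if not isinstance(flags, dict):
        flags = {f.cpg_id: f for f in flags}
    ids = flags.keys() if group is None else group
    sel = [flags[i] for i in ids if i in flags and flags[i].fit_ok]
    if not sel:
        raise ValueError("empty group (or no successful fits in group)")
    out = {feat: sum(getattr(f, feat) for f in sel) / len(sel) for feat in BOOL_FEATURES}
    out["increasing"] = sum(f.change_direction == "increasing" for f in sel) / len(sel)
    out["decreasing"] = sum(f.change_direction == "decreasing" for f in sel) / len(sel)
    out["n"] = len(sel)
    return pd.Series(out)


def flags_to_frame(flags: dict[str, FeatureFlags] | list[FeatureFlags]) -> pd.DataFrame:
    if isinstance(flags, dict):
        flags = list(flags.values())
    return pd.DataFrame(
        [{f.name: getattr(x, f.name) for f in fields(FeatureFlags)} for x in flags]
    )
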