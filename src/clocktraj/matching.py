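"""Covariate-matched background selection for sensitivity analyses.

Array sites differ in how variable they are, and low-variability sites
are both less likely to enter a clock and less likely to show dynamic
features — so a raw clock-vs-rest enrichment can reflect variability
alone.  The sensitivity analysis therefore re-runs each enrichment
against a background of non-clock sites matched to the clock sites on a
scalar property (the estimated random-intercept SD for the
"inter-individual differences at birth" analysis; the absolute fixed age
effect for the "DNAm change" analysis), selecting ``ratio`` controls per
clock site by greedy nearest-neighbour Euclidean matching without
replacement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .enrichment import EnrichmentResult, fisher_exact

logger = logging.getLogger(__name__)

__all__ = ["MatchSpec", "MatchResult", "match_background", "matched_enrichment"]


@dataclass(frozen=True)
class MatchSpec:
    """How to match: scalar feature per site, controls-per-treated ratio,
    optional caliper (maximum accepted distance)."""

    feature: str = "sd_intercept"
    ratio: int = 100
    max_distance: float | None = None

    def __post_init__(self) -> None:
        if self.ratio < 1:
            raise ValueError("ratio must be >= 1")
        if self.max_distance is not None and self.max_distance <= 0:
            raise ValueError("max_distance must be positive")


@dataclass
class MatchResult:
    """Matched control ids per treated site, with balance diagnostics."""

    matches: dict[str, list[str]]
    distances: dict[str, list[float]]
    smd_before: float
    smd_after: float
    unmatched_treated: int
    spec: MatchSpec = field(default_factory=MatchSpec)

    @property
    def matched_ids(self) -> set[str]:
        return {c for cs in self.matches.values() for c in cs}

    def pairs_frame(self) -> pd.DataFrame:
        rows = [
            (t, c, d)
            for t in self.matches
            for c, d in zip(self.matches[t], self.distances[t])
        ]
        return pd.DataFrame(rows, columns=["treated_id", "control_id", "distance"])


def _smd(x: np.ndarray, y: np.ndarray) -> float:
    """Standardised mean difference with a pooled-SD denominator."""
    sp = np.sqrt((x.var(ddof=1) + y.var(ddof=1)) / 2) if len(x) > 1 and len(y) > 1 else 0.0
    if sp == 0:
        return 0.0
    return float(abs(x.mean() - y.mean()) / sp)


def match_background(
    treated: Mapping[str, float],
    candidates: Mapping[str, float],
    spec: MatchSpec | None = None,
) -> MatchResult:
    """Greedy nearest-neighbour matching without replacement.

    Treated sites are processed in deterministic order (descending feature
    value, ties broken by site id); each receives its ``ratio`` nearest
    unused candidates by absolute (Euclidean, scalar) distance.  If the
    candidate pool is too small a partial matching is returned with a
    warning.  Matching itself involves no randomness.
    """
    spec = spec or MatchSpec()
    if not candidates:
        raise ValueError("empty candidate set")
    missing = [k for k, v in list(treated.items()) + list(candidates.items())
               if v is None or not np.isfinite(v)]
    if missing:
        raise ValueError(f"missing feature values for sites: {sorted(set(missing))}")

    cand_ids = np.array(sorted(candidates, key=lambda k: (candidates[k], k)), dtype=object)
    cand_vals = np.array([candidates[k] for k in cand_ids], float)
    used = np.zeros(len(cand_ids), bool)
    n_unused = len(cand_ids)

    order = sorted(treated, key=lambda k: (-treated[k], k))
    if len(cand_ids) < spec.ratio * len(order):
        logger.warning(
            "candidate pool (%d) smaller than ratio x treated (%d); partial matching",
            len(cand_ids), spec.ratio * len(order),
        )

    matches: dict[str, list[str]] = {}
    dists: dict[str, list[float]] = {}
    unmatched = 0
    for t in order:
        v = treated[t]
        want = min(spec.ratio, n_unused)
        if want == 0:
            matches[t], dists[t] = [], []
            unmatched += 1
            continue
        pos = int(np.searchsorted(cand_vals, v))
        lo, hi = pos - 1, pos
        sel: list[int] = []
        while len(sel) < want:
            while lo >= 0 and used[lo]:
                lo -= 1
            while hi < len(cand_ids) and used[hi]:
                hi += 1
            take_lo = hi >= len(cand_ids) or (
                lo >= 0 and v - cand_vals[lo] <= cand_vals[hi] - v
            )
            k = lo if take_lo else hi
            dist = abs(cand_vals[k] - v)
            if spec.max_distance is not None and dist > spec.max_distance:
                break  # caliper: nothing closer remains on either side
            sel.append(k)
            used[k] = True
            if take_lo:
                lo -= 1
            else:
                hi += 1
        n_unused -= len(sel)
        matches[t] = [str(cand_ids[k]) for k in sel]
        dists[t] = [float(abs(cand_vals[k] - v)) for k in sel]
        if len(sel) < spec.ratio:
            unmatched += 1

    tv = np.array([treated[t] for t in order], float)
    all_cand = cand_vals
    matched_vals = np.array(
        [candidates[c] for cs in matches.values() for c in cs], float
    )
    return MatchResult(
        matches=matches,
        distances=dists,
        smd_before=_smd(tv, all_cand),
        smd_after=_smd(tv, matched_vals) if matched_vals.size else float("nan"),
        unmatched_treated=unmatched,
        spec=spec,
    )


def matched_enrichment(
    flags,
    site_groups,
    feature: str,
    group,
    match_result: MatchResult,
) -> EnrichmentResult:
    """Re-run an enrichment with the background restricted to matched controls."""
    from .enrichment import make_contingency

    table = make_contingency(
        flags, site_groups, feature, group, background=match_result.matched_ids
    )
    res = fisher_exact(table, feature=feature, group=str(group))
    return res
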