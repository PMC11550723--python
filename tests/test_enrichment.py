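"""Exact-test machinery against a brute-force hypergeometric oracle."""

import math

import numpy as np
import pytest
from scipy import stats

from clocktraj.clocks import build_site_groups, make_mock_clock
from clocktraj.enrichment import (
    ContingencyTable,
    annotation_enrichment,
    direction_consistency,
    fisher_exact,
    make_contingency,
)
from clocktraj.features import FeatureFlags


def enumeration_p(a, b, c, d):
    """Two-sided exact p by exhaustive enumeration over fixed margins.

    Sums the probabilities of all tables (with the observed margins) whose
    hypergeometric probability does not exceed the observed table's, up to
    the standard 1 + 1e-7 tie tolerance.
    """
    r1, n1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, r1 + n1 - n), min(r1, n1)
    ks = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(ks, n, n1, r1)
    if not np.all(np.isfinite(pmf)) or pmf.sum() == 0:  # degenerate (empty table)
        pmf = np.ones_like(pmf)
    p_obs = pmf[a - lo]
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


def flag(cpg, feature=False, ok=True, direction=None):
    changes = direction is not None
    return FeatureFlags(
        cpg_id=cpg, fit_ok=ok, changes=changes,
        change_direction=direction or "none", var_at_birth=feature,
    )


class TestFisherExact:
    def test_balanced_table_is_null(self):
        r = fisher_exact(ContingencyTable(5, 5, 5, 5))
        assert r.odds_ratio == pytest.approx(1.0, abs=1e-9)
        assert r.p == pytest.approx(1.0)

    def test_small_table_matches_enumeration(self):
        r = fisher_exact(ContingencyTable(3, 1, 1, 3))
        assert r.p == pytest.approx(enumeration_p(3, 1, 1, 3), abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_random_tables_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 12, 4)
            r = fisher_exact(ContingencyTable(int(a), int(b), int(c), int(d)))
            assert r.p == pytest.approx(
                enumeration_p(int(a), int(b), int(c), int(d)), abs=1e-12)

    def test_zero_cell_gives_infinite_or_with_finite_lower_bound(self):
        r = fisher_exact(ContingencyTable(12, 0, 40, 60))
        assert math.isinf(r.odds_ratio)
        assert r.ci_low > 1.0 and math.isinf(r.ci_high)

    def test_swap_invariance(self):
        t = ContingencyTable(7, 2, 4, 9)
        swapped = ContingencyTable(9, 4, 2, 7)  # swap rows and columns
        assert fisher_exact(t).p == pytest.approx(fisher_exact(swapped).p, abs=1e-12)

    def test_polarity_inversion_inverts_or(self):
        t = ContingencyTable(7, 2, 4, 9)
        inv = ContingencyTable(2, 7, 9, 4)
        r, ri = fisher_exact(t), fisher_exact(inv)
        assert r.odds_ratio == pytest.approx(1.0 / ri.odds_ratio, rel=1e-6)

    def test_large_table_uses_flagged_sample_or(self):
        t = ContingencyTable(2000, 1500, 1800, 2200)
        r = fisher_exact(t)
        assert r.or_approximate
        sample = (2000 * 2200) / (1500 * 1800)
        assert r.odds_ratio == pytest.approx(sample)

    def test_sample_or_close_to_cmle_when_cells_large(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            cells = rng.integers(500, 3000, 4)
            t = ContingencyTable(*map(int, cells))
            exact = fisher_exact(t, exact_or_margin_limit=10**9)
            approx = fisher_exact(t, exact_or_margin_limit=1)
            assert approx.odds_ratio == pytest.approx(exact.odds_ratio, rel=0.02)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 2, 3, 4)


class TestMakeContingency:
    def build(self):
        clock_ids = [f"k{i}" for i in range(4)]
        bg_ids = [f"b{i}" for i in range(6)]
        clock = make_mock_clock("c", clock_ids, "first")
        groups = build_site_groups([clock], set(clock_ids + bg_ids))
        flags = {s: flag(s, feature=True) for s in clock_ids[:3]}
        flags[clock_ids[3]] = flag(clock_ids[3], feature=False)
        flags.update({s: flag(s, feature=(s == "b0")) for s in bg_ids})
        return flags, groups

    def test_toy_counts(self):
        flags, groups = self.build()
        t = make_contingency(flags, groups, "var_at_birth", "first")
        assert (t.a, t.b, t.c, t.d) == (3, 1, 1, 5)

    def test_failed_fits_excluded(self):
        flags, groups = self.build()
        flags["b5"] = flag("b5", ok=False)
        t = make_contingency(flags, groups, "var_at_birth", "first")
        assert (t.c, t.d) == (1, 4)

    def test_unknown_feature_rejected(self):
        flags, groups = self.build()
        with pytest.raises(KeyError):
            make_contingency(flags, groups, "no_such_feature", "first")


class TestDirectionConsistency:
    def test_perfect_concordance_infinite_or(self):
        sites = [f"s{i}" for i in range(10)]
        dirs = {s: ("positive" if i < 5 else "negative") for i, s in enumerate(sites)}
        flags = {s: flag(s, direction="increasing" if i < 5 else "decreasing")
                 for i, s in enumerate(sites)}
        r = direction_consistency(dirs, flags, set(sites))
        assert math.isinf(r.odds_ratio)
        assert r.p < 0.05

    def test_toy_table_matches_enumeration(self):
        # 8 positive-increasing, 2 positive-decreasing, 3 negative-increasing,
        # 7 negative-decreasing
        sites, dirs, flags = [], {}, {}
        spec = [("positive", "increasing", 8), ("positive", "decreasing", 2),
                ("negative", "increasing", 3), ("negative", "decreasing", 7)]
        k = 0
        for sign, mot, cnt in spec:
            for _ in range(cnt):
                s = f"s{k}"; k += 1
                sites.append(s); dirs[s] = sign
                flags[s] = flag(s, direction=mot)
        r = direction_consistency(dirs, flags, set(sites))
        assert (r.table.a, r.table.b, r.table.c, r.table.d) == (8, 2, 3, 7)
        assert r.p == pytest.approx(enumeration_p(8, 2, 3, 7), abs=1e-12)

    def test_sparse_margin_flagged_unstable(self):
        dirs = {"a": "positive", "b": "positive"}
        flags = {s: flag(s, direction="increasing") for s in dirs}
        r = direction_consistency(dirs, flags, set(dirs))
        assert r.unstable


class TestAnnotationEnrichment:
    def test_toy_overlap_counts_and_p(self):
        uni = [f"u{i}" for i in range(100)]
        clock = make_mock_clock("c", uni[:10], "first")
        groups = build_site_groups([clock], set(uni))
        ann = set(uni[5:25])  # overlap 5 with the clock
        r = annotation_enrichment(ann, groups, "first")
        assert (r.table.a, r.table.b, r.table.c, r.table.d) == (5, 5, 15, 75)
        assert r.p == pytest.approx(enumeration_p(5, 5, 15, 75), abs=1e-12)

    def test_annotation_identical_to_clock(self):
        uni = [f"u{i}" for i in range(50)]
        clock = make_mock_clock("c", uni[:8], "first")
        groups = build_site_groups([clock], set(uni))
        r = annotation_enrichment(set(uni[:8]), groups, "first")
        assert math.isinf(r.odds_ratio)

    def test_random_annotation_is_null_on_average(self):
        rng = np.random.default_rng(10)
        uni = [f"u{i}" for i in range(400)]
        clock = make_mock_clock("c", uni[:40], "first")
        groups = build_site_groups([clock], set(uni))
        log_ors = []
        for _ in range(30):
            ann = set(rng.choice(uni, 80, replace=False))
            r = annotation_enrichment(ann, groups, "first")
            if np.isfinite(r.odds_ratio) and r.odds_ratio > 0:
                log_ors.append(np.log(r.odds_ratio))
        assert abs(np.mean(log_ors)) < 0.25

    def test_disjoint_annotation_rejected(self):
        uni = {f"u{i}" for i in range(20)}
        clock = make_mock_clock("c", list(uni)[:4], "first")
        groups = build_site_groups([clock], uni)
        with pytest.raises(ValueError):
            annotation_enrichment({"elsewhere"}, groups, "first")


def test_per_clock_enrichment_gives_one_result_per_clock():
    from clocktraj.enrichment import per_clock_enrichment

    uni = [f"u{i}" for i in range(200)]
    c1 = make_mock_clock("clockA", uni[:20], "first")
    c2 = make_mock_clock("clockB", uni[10:40], "first")
    # feature present in the low-index half of the universe
    flags = {s: flag(s, feature=int(s[1:]) < 100) for s in uni}
    res = per_clock_enrichment([c1, c2], flags, set(uni), "var_at_birth")
    assert set(res) == {"clockA", "clockB"}
    for name, r in res.items():
        assert r.table.a + r.table.b == len({"clockA": c1, "clockB": c2}[name])
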