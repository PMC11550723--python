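"""Greedy nearest-neighbour background matching."""

import numpy as np
import pytest

from clocktraj.clocks import build_site_groups, make_mock_clock
from clocktraj.features import FeatureFlags
from clocktraj.matching import MatchSpec, match_background, matched_enrichment


def as_map(prefix, values):
    return {f"{prefix}{i}": float(v) for i, v in enumerate(values)}


class TestMatchBackground:
    def test_exact_duplicates_matched_at_zero_distance(self):
        treated = as_map("t", [0.1, 0.5])
        cands = {**as_map("c", [0.1, 0.1, 0.5, 0.5]), **as_map("x", [9.0, 9.0])}
        res = match_background(treated, cands, MatchSpec(ratio=2))
        assert all(d == 0.0 for ds in res.distances.values() for d in ds)
        assert res.smd_after <= res.smd_before

    def test_greedy_takes_nearest_available(self):
        # one treated site, candidates at distances 0.1, 0.2, 5, 6
        treated = {"t0": 1.0}
        cands = {"c0": 1.1, "c1": 1.2, "c2": 6.0, "c3": 7.0}
        res = match_background(treated, cands, MatchSpec(ratio=2))
        assert sorted(res.matches["t0"]) == ["c0", "c1"]
        # brute force over all candidate pairs confirms this is optimal
        import itertools

        best = min(
            itertools.combinations(cands, 2),
            key=lambda pair: sum(abs(cands[c] - 1.0) for c in pair),
        )
        assert sorted(best) == sorted(res.matches["t0"])

    def test_descending_order_and_no_reuse(self):
        # the high-valued treated site is processed first and takes the
        # nearest candidate; the second must use the remaining one
        treated = {"lo": 0.0, "hi": 1.0}
        cands = {"c0": 0.9, "c1": 0.4}
        res = match_background(treated, cands, MatchSpec(ratio=1))
        assert res.matches["hi"] == ["c0"]
        assert res.matches["lo"] == ["c1"]
        assert len(res.matched_ids) == 2

    def test_ratio_times_treated_with_ample_candidates(self):
        rng = np.random.default_rng(0)
        treated = as_map("t", rng.normal(0, 1, 5))
        cands = as_map("c", rng.normal(0, 1, 600))
        res = match_background(treated, cands, MatchSpec(ratio=100))
        assert len(res.matched_ids) == 500
        assert res.unmatched_treated == 0

    def test_partial_when_pool_small(self, caplog):
        treated = as_map("t", [0.0, 1.0])
        cands = as_map("c", [0.5, 0.6, 0.7])
        with caplog.at_level("WARNING"):
            res = match_background(treated, cands, MatchSpec(ratio=2))
        assert len(res.matched_ids) == 3
        assert res.unmatched_treated >= 1

    def test_greedy_beats_random_assignment(self):
        rng = np.random.default_rng(1)
        tvals = rng.normal(0, 1, 20)
        cvals = rng.normal(0, 1, 200)
        treated, cands = as_map("t", tvals), as_map("c", cvals)
        res = match_background(treated, cands, MatchSpec(ratio=3))
        greedy_sum = sum(d for ds in res.distances.values() for d in ds)
        for rep in range(5):
            pick = rng.choice(cvals, size=60, replace=False)
            rand_sum = float(np.abs(np.repeat(tvals, 3) - pick).sum())
            assert greedy_sum <= rand_sum

    def test_smd_reduced_when_imbalanced(self):
        rng = np.random.default_rng(2)
        treated = as_map("t", rng.normal(2.0, 0.3, 15))
        cands = as_map("c", rng.normal(0.0, 1.0, 1000))
        res = match_background(treated, cands, MatchSpec(ratio=10))
        assert res.smd_before > 0.1
        assert res.smd_after < res.smd_before

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        treated = as_map("t", rng.normal(0, 1, 10))
        cands = as_map("c", rng.normal(0, 1, 100))
        a = match_background(treated, cands, MatchSpec(ratio=4))
        b = match_background(treated, cands, MatchSpec(ratio=4))
        assert a.matches == b.matches

    def test_errors(self):
        with pytest.raises(ValueError, match="empty"):
            match_background({"t": 1.0}, {})
        with pytest.raises(ValueError, match="missing"):
            match_background({"t": float("nan")}, {"c": 1.0})
        with pytest.raises(ValueError):
            MatchSpec(ratio=0)


class TestMatchedEnrichment:
    def build(self, n_clock=20, n_bg=400, seed=0, feature_rate_clock=0.5,
              feature_rate_bg=0.5):
        """Clock and background sites sharing one feature prevalence."""
        rng = np.random.default_rng(seed)
        clock_ids = [f"k{i}" for i in range(n_clock)]
        bg_ids = [f"b{i}" for i in range(n_bg)]
        clock = make_mock_clock("c", clock_ids, "first")
        groups = build_site_groups([clock], set(clock_ids + bg_ids))
        flags = {}
        feat_vals = {}
        for ids, rate, centre in ((clock_ids, feature_rate_clock, 1.0),
                                  (bg_ids, feature_rate_bg, 0.0)):
            for s in ids:
                has = bool(rng.random() < rate)
                flags[s] = FeatureFlags(cpg_id=s, fit_ok=True, var_at_birth=has,
                                        changes=False, change_direction="none")
                feat_vals[s] = float(rng.normal(centre, 0.5))
        return flags, groups, feat_vals, clock_ids, bg_ids

    def test_designed_null_gives_or_near_one(self):
        flags, groups, vals, clock_ids, bg_ids = self.build(
            feature_rate_clock=0.5, feature_rate_bg=0.5, n_clock=40, n_bg=800)
        mr = match_background({s: vals[s] for s in clock_ids},
                              {s: vals[s] for s in bg_ids}, MatchSpec(ratio=5))
        res = matched_enrichment(flags, groups, "var_at_birth", "first", mr)
        assert res.p > 0.01
        assert 0.4 < res.odds_ratio < 2.5

    def test_matching_on_confounded_feature_removes_signal(self):
        # the feature is a deterministic function of the matching scalar,
        # and the clock over-samples high values: raw enrichment is strong,
        # matched enrichment is null by construction
        rng = np.random.default_rng(5)
        clock_ids = [f"k{i}" for i in range(30)]
        bg_ids = [f"b{i}" for i in range(900)]
        clock = make_mock_clock("c", clock_ids, "first")
        groups = build_site_groups([clock], set(clock_ids + bg_ids))
        flags, vals = {}, {}
        for s in clock_ids:
            v = float(rng.normal(1.0, 0.5))
            vals[s] = v
            flags[s] = FeatureFlags(cpg_id=s, fit_ok=True, var_at_birth=v > 0.5,
                                    changes=False, change_direction="none")
        for s in bg_ids:
            v = float(rng.normal(0.0, 1.0))
            vals[s] = v
            flags[s] = FeatureFlags(cpg_id=s, fit_ok=True, var_at_birth=v > 0.5,
                                    changes=False, change_direction="none")
        from clocktraj.enrichment import make_contingency, fisher_exact

        raw = fisher_exact(make_contingency(flags, groups, "var_at_birth", "first"))
        assert raw.odds_ratio > 2 and raw.p < 0.01
        mr = match_background({s: vals[s] for s in clock_ids},
                              {s: vals[s] for s in bg_ids}, MatchSpec(ratio=8))
        matched = matched_enrichment(flags, groups, "var_at_birth", "first", mr)
        assert matched.p > 0.01


def test_caliper_limits_match_distance():
    treated = {"t0": 0.0}
    cands = {"c0": 0.05, "c1": 0.5, "c2": 5.0}
    res = match_background(treated, cands, MatchSpec(ratio=3, max_distance=1.0))
    assert sorted(res.matches["t0"]) == ["c0", "c1"]
    assert res.unmatched_treated == 1
    assert max(res.distances["t0"]) <= 1.0
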