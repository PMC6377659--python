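"""Tests for deviation statistics, rank tests, FDR and the selection rule.

The exact rank tests are checked against independent brute-force
enumeration oracles: all 2^n sign patterns for the signed-rank test,
all C(n1+n2, n1) group assignments for the rank-sum test.
"""

import itertools

import numpy as np
import pytest

from pde8a_editing.differential import (
    GROUP_AXIS,
    REGION_AXIS,
    ContrastError,
    ContrastSpec,
    all_deviations,
    delta_deviation,
    fdr_adjust,
    include_isoforms,
    median_variation,
    rank_sum_test,
    run_contrast,
    signed_rank_test,
)
from pde8a_editing.model import EditingProfile, SampleMeta
from pde8a_editing.synth import CohortSpec, default_isoform_means, simulate_cohort


# ---------------------------------------------------------------------------
# enumeration oracles
# ---------------------------------------------------------------------------

def signed_rank_oracle(devs):
    """Exact two-sided signed-rank p by enumerating all sign patterns."""
    d = np.asarray(devs, float)
    d = d[d != 0]
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    n = len(d)
    total = n * (n + 1) / 2.0
    stats = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ]
    stats = np.array(stats)
    lo = np.mean(stats <= min(w_obs, total - w_obs))
    hi = np.mean(stats >= max(w_obs, total - w_obs))
    return min(1.0, lo + hi)


def rank_sum_oracle(g1, g2):
    """Exact two-sided rank-sum p by enumerating all group assignments."""
    g1, g2 = list(g1), list(g2)
    pooled = g1 + g2
    n2 = len(g2)

    def u_stat(group2):
        rest = list(pooled)
        for v in group2:
            rest.remove(v)
        return sum((a > b) + 0.5 * (a == b) for a in group2 for b in rest)

    u_obs = u_stat(g2)
    n1n2 = n2 * len(g1)
    us = np.array([u_stat(list(c)) for c in itertools.combinations(pooled, n2)])
    lo = np.mean(us <= min(u_obs, n1n2 - u_obs))
    hi = np.mean(us >= max(u_obs, n1n2 - u_obs))
    return min(1.0, lo + hi)


class TestIncludeIsoforms:
    def _toy(self, props_by_sample):
        profiles, meta = [], []
        for i, props in enumerate(props_by_sample):
            sid = f"s{i}"
            profiles.append(EditingProfile(sid, props))
            meta.append(SampleMeta(sid, f"subj{i}", "control", "BA24", f"P{i}"))
        return profiles, meta

    def test_below_threshold_everywhere_excluded(self):
        profiles, meta = self._toy([{"B": 99.7, "D": 0.3}, {"B": 99.6, "D": 0.4}])
        assert include_isoforms(profiles, meta) == ["B"]

    def test_single_stratum_above_threshold_included(self):
        profiles, meta = self._toy([{"B": 99.4, "D": 0.6}, {"B": 99.4, "D": 0.6}])
        assert "D" in include_isoforms(profiles, meta)

    def test_default_cohort_includes_about_20_isoforms(self, cohort):
        profiles, meta = cohort
        included = include_isoforms(profiles, meta)
        assert 18 <= len(included) <= 23
        assert "M" not in included  # edited below 0.5% everywhere
        assert included[0] == "B"  # most abundant first in reference stratum


class TestDeviations:
    def test_signed_difference(self):
        p1 = EditingProfile("a", {"B": 20.0})
        p2 = EditingProfile("b", {"B": 30.0})
        assert delta_deviation(p1, p2, "B") == pytest.approx(10.0)
        assert delta_deviation(p2, p1, "B") == pytest.approx(-10.0)

    def test_identical_profiles_zero_everywhere(self):
        p = EditingProfile("a", {"B": 60.0, "NE": 40.0})
        assert all(delta_deviation(p, p, iso) == 0 for iso in ("B", "NE", "ABC"))

    def test_absent_isoform_counts_as_zero(self):
        p1 = EditingProfile("a", {"B": 100.0})
        p2 = EditingProfile("b", {"B": 99.0, "ABC": 1.0})
        assert delta_deviation(p1, p2, "ABC") == pytest.approx(1.0)

    def test_all_cross_pairs(self):
        devs = all_deviations([1.0, 2.0], [4.0, 6.0])
        assert sorted(devs) == [2.0, 3.0, 4.0, 5.0]


class TestMedianVariation:
    def test_reporting_convention(self):
        # medians 10 -> 25.6 is a +156% variation
        assert median_variation([10.0] * 3, [25.6] * 3) == pytest.approx(156.0)

    def test_equal_medians(self):
        assert median_variation([5.0, 7.0], [5.0, 7.0]) == 0.0

    def test_halved_median(self):
        assert median_variation([8.0] * 3, [4.0] * 3) == pytest.approx(-50.0)

    def test_zero_baseline_raises(self):
        with pytest.raises(ContrastError, match="zero"):
            median_variation([0.0, 0.0], [1.0, 2.0])


class TestSignedRank:
    def test_eight_concordant_deviations(self):
        # all positive signs: 2 of the 2^8 sign patterns are as extreme
        assert signed_rank_test([1, 2, 3, 4, 5, 6, 7, 8]) == pytest.approx(
            0.0078125, abs=1e-12
        )

    def test_antisymmetric_deviations(self):
        # exact x / -x pairs: the rank-sum splits evenly, no evidence either way
        assert signed_rank_test([3.0, -3.0, 1.0, -1.0]) == pytest.approx(1.0)

    def test_all_zero_degenerate(self):
        assert signed_rank_test([0.0, 0.0, 0.0]) == 1.0

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 11))
        d = rng.normal(0.4, 1.0, n)
        assert signed_rank_test(d) == pytest.approx(signed_rank_oracle(d), abs=1e-12)


class TestRankSum:
    def test_fully_separated_three_vs_three(self):
        assert rank_sum_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1, abs=1e-12)

    def test_identical_groups(self):
        assert rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_enumeration_oracle_8v8(self, seed):
        rng = np.random.default_rng(100 + seed)
        g1 = rng.normal(0, 1, 8)
        g2 = rng.normal(0.7, 1, 8)
        assert rank_sum_test(g1, g2) == pytest.approx(rank_sum_oracle(g1, g2), abs=1e-9)

    def test_too_small_groups_rejected(self):
        with pytest.raises(ContrastError):
            rank_sum_test([1.0], [2.0, 3.0])


class TestFdrAdjust:
    def test_single_p_unchanged(self):
        assert fdr_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_bh(self):
        q = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_boundary_all_ones(self):
        np.testing.assert_allclose(fdr_adjust([1.0, 1.0, 1.0]), 1.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_q_monotone_and_bounded_below_by_p(self, seed):
        p = np.sort(np.random.default_rng(seed).uniform(0, 1, 15))
        q = fdr_adjust(p)
        assert np.all(q >= p - 1e-12)
        assert np.all(np.diff(q) >= -1e-12)  # monotone in sorted p
        assert np.all(q <= 1.0)


class TestRunContrast:
    def test_group_contrast_detects_programmed_effect(self, cohort):
        profiles, meta = cohort
        spec = ContrastSpec(GROUP_AXIS, "control", "suicide", "BA24")
        results = run_contrast(profiles, meta, spec)
        by_iso = {r.isoform: r for r in results}
        # ABCEF is doubled in suicide BA24 under the default means
        assert by_iso["ABCEF"].selected
        assert by_iso["ABCEF"].median_variation_pct > 20
        # results ordered by significance
        ps = [r.p_value for r in results]
        assert ps == sorted(ps)

    def test_region_contrast_direction(self, cohort):
        profiles, meta = cohort
        spec = ContrastSpec(REGION_AXIS, "BA9", "BA24", "control")
        results = run_contrast(profiles, meta, spec)
        by_iso = {r.isoform: r for r in results}
        # AB is strongly BA24-enriched, ABG strongly BA9-enriched
        assert by_iso["AB"].median_variation_pct > 100
        assert by_iso["ABG"].median_variation_pct < -50

    def test_antisymmetry_under_condition_swap(self, cohort):
        profiles, meta = cohort
        fwd = ContrastSpec(GROUP_AXIS, "control", "suicide", "BA24")
        rev = ContrastSpec(GROUP_AXIS, "suicide", "control", "BA24")
        rf = {r.isoform: r for r in run_contrast(profiles, meta, fwd)}
        rr = {r.isoform: r for r in run_contrast(profiles, meta, rev)}
        for iso, f in rf.items():
            b = rr[iso]
            np.testing.assert_allclose(
                np.sort(b.delta_deviations), np.sort(-f.delta_deviations)
            )
            assert b.p_value == pytest.approx(f.p_value, rel=1e-9)
            expected = -f.median_variation_pct / (1 + f.median_variation_pct / 100.0)
            assert b.median_variation_pct == pytest.approx(expected, rel=1e-9)

    def test_signed_rank_mode_uses_design_pairing(self, cohort):
        profiles, meta = cohort
        spec = ContrastSpec(GROUP_AXIS, "control", "suicide", "BA24")
        results = run_contrast(profiles, meta, spec, test="signed-rank")
        assert all(0 <= r.p_value <= 1 for r in results)
        # n = 8 pairs: the exact signed-rank p cannot go below 2 / 2^8
        assert min(r.p_value for r in results) >= 0.0078125 - 1e-12

    def test_broken_pairing_raises(self, cohort):
        profiles, meta = cohort
        meta = [
            SampleMeta(m.sample_id, m.subject_id, m.group, m.region, "P99")
            if m.sample_id == meta[0].sample_id
            else m
            for m in meta
        ]
        spec = ContrastSpec(GROUP_AXIS, "control", "suicide", meta[0].region)
        with pytest.raises(ContrastError, match="bijection"):
            run_contrast(profiles, meta, spec, test="signed-rank")

    def test_null_cohort_selects_nothing(self):
        means = default_isoform_means()
        null = {
            (g, r): means[("control", r)] for g in ("control", "suicide") for r in ("BA9", "BA24")
        }
        profiles, meta = simulate_cohort(CohortSpec(isoform_means=null, seed=11))
        spec = ContrastSpec(GROUP_AXIS, "control", "suicide", "BA24")
        results = run_contrast(profiles, meta, spec)
        assert sum(r.selected for r in results) <= 1

    def test_selection_monotone_in_thresholds(self, cohort):
        profiles, meta = cohort
        spec = ContrastSpec(GROUP_AXIS, "control", "suicide", "BA24")
        loose = run_contrast(profiles, meta, spec, medvar_threshold=20, q_threshold=0.05)
        tight = run_contrast(profiles, meta, spec, medvar_threshold=40, q_threshold=0.01)
        sel_loose = {r.isoform for r in loose if r.selected}
        sel_tight = {r.isoform for r in tight if r.selected}
        assert sel_tight <= sel_loose
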