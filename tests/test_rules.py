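"""Composite-rule semantics, candidate selection, enumeration and ranking."""

from itertools import product

import pandas as pd
import pytest

import mnemoscreen as ms
from conftest import make_cohort
from mnemoscreen.metrics import EstimateWithCI

CANDIDATE_SECONDARIES = ("referred_pain", "sweating", "dyspnea", "palpitation")


def profile_from_points(or_, se, sp, n_sec_table=None) -> ms.DiagnosticProfile:
    """A DiagnosticProfile carrying given point estimates (for ranking inputs)."""
    def est(p, scale):
        return EstimateWithCI(p, p, p, scale, "given")

    table = n_sec_table or ms.TwoByTwo(1, 1, 1, 1)
    return ms.DiagnosticProfile(
        sensitivity=est(se, "proportion"), specificity=est(sp, "proportion"),
        ppv=est(0.3, "proportion"), npv=est(0.9, "proportion"),
        lr_pos=est(2.0, "ratio"), lr_neg=est(0.3, "ratio"),
        odds_ratio=est(or_, "ratio"), n_used=table.n, table=table,
    )


class TestSelection:
    def test_reference_candidates(self, reference_profiles):
        selected = ms.select_candidate_symptoms(reference_profiles, 1.0)
        assert selected == ["chest_pain", "referred_pain", "sweating",
                            "dyspnea", "palpitation"]

    def test_nothing_qualifies(self):
        profiles = {"a": profile_from_points(0.5, 0.2, 0.9),
                    "b": profile_from_points(0.9, 0.4, 0.8)}
        assert ms.select_candidate_symptoms(profiles, 1.0) == []

    def test_threshold_is_strict(self, reference_profiles):
        boundary = reference_profiles["sweating"].odds_ratio.point
        selected = ms.select_candidate_symptoms(reference_profiles, boundary)
        assert "sweating" not in selected
        assert "referred_pain" in selected  # 3.22 > 3.06

    def test_empty_profiles_rejected(self):
        with pytest.raises(ValueError):
            ms.select_candidate_symptoms({}, 1.0)


def oracle_rule_state(anchor_state, secondary_states, strict):
    """Brute-force three-valued rule semantics over explicit states.

    States: True (present), False (absent), None (unrecorded).
    """
    if strict:
        if anchor_state is None or any(s is None for s in secondary_states):
            return None
        return anchor_state and any(secondary_states)
    if anchor_state is None:
        return None
    if anchor_state is False:
        return False
    if any(s is True for s in secondary_states):
        return True
    if all(s is False for s in secondary_states):
        return False
    return None


class TestEvaluate:
    @pytest.mark.parametrize("n_sec", [1, 2, 3, 4])
    @pytest.mark.parametrize("strict", [False, True])
    def test_matches_exhaustive_truth_table(self, n_sec, strict):
        """Witness/strict semantics equal the brute-force oracle over all
        3^(1+k) symptom-state combinations."""
        secs = CANDIDATE_SECONDARIES[:n_sec]
        symptoms = ("chest_pain", *secs)
        combos = list(product([True, False, None], repeat=1 + n_sec))
        rows = [
            {"outcome": "ACS", **dict(zip(symptoms, combo))} for combo in combos
        ]
        cohort = make_cohort(rows, symptoms)
        rule = ms.CompositeRule("chest_pain", secs, strict=strict)
        got = rule.evaluate(cohort)
        for i, combo in enumerate(combos):
            expected = oracle_rule_state(combo[0], combo[1:], strict)
            value = got.iloc[i]
            if expected is None:
                assert pd.isna(value), combo
            else:
                assert value == expected, combo

    def test_singleton_rule_equals_direct_conjunction(self, fully_recorded_cohort):
        rule = ms.CompositeRule("chest_pain", ("sweating",))
        t_rule = ms.cross_tabulate(fully_recorded_cohort, rule)
        df = fully_recorded_cohort.df
        both = (df["chest_pain"] & df["sweating"]).fillna(False)
        acs = df["outcome"] == "ACS"
        assert t_rule.a == int((both & acs).sum())
        assert t_rule.b == int((both & ~acs).sum())

    def test_unknown_symptom_rejected(self, fully_recorded_cohort):
        rule = ms.CompositeRule("chest_pain", ("halitosis",))
        with pytest.raises(KeyError):
            rule.evaluate(fully_recorded_cohort)

    def test_anchor_cannot_be_secondary(self):
        with pytest.raises(ValueError):
            ms.CompositeRule("chest_pain", ("chest_pain", "sweating"))


class TestEnumerate:
    def test_sizes_three_to_four_give_five_rules(self):
        rules = ms.enumerate_mnemonics("chest_pain", CANDIDATE_SECONDARIES, 3, 4)
        assert len(rules) == 5
        sets = [set(r.secondaries) for r in rules]
        assert set(CANDIDATE_SECONDARIES) in sets
        assert {"dyspnea", "palpitation", "referred_pain"} in sets
        assert {"sweating", "palpitation", "referred_pain"} in sets
        # deterministic order: size descending, then lexicographic
        assert [len(r.secondaries) for r in rules] == [4, 3, 3, 3, 3]
        assert rules == ms.enumerate_mnemonics("chest_pain", CANDIDATE_SECONDARIES, 3, 4)

    def test_full_set_only(self):
        rules = ms.enumerate_mnemonics("chest_pain", CANDIDATE_SECONDARIES, 4, 4)
        assert len(rules) == 1

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            ms.enumerate_mnemonics("chest_pain", (), 1)


class TestRanking:
    def reference_rule_profiles(self):
        rules = ms.enumerate_mnemonics("chest_pain", CANDIDATE_SECONDARIES, 3, 4)
        by_set = {frozenset(r.secondaries): r for r in rules}
        # reported composite-rule performance in the original 3,400-visit cohort
        return [
            (by_set[frozenset(CANDIDATE_SECONDARIES)],
             profile_from_points(7.81, 0.81, 0.64)),
            (by_set[frozenset({"dyspnea", "palpitation", "referred_pain"})],
             profile_from_points(6.71, 0.77, 0.67)),
            (by_set[frozenset({"sweating", "palpitation", "referred_pain"})],
             profile_from_points(6.54, 0.71, 0.73)),
        ]

    def test_four_secondary_rule_ranks_first(self):
        ranked = ms.rank_mnemonics(self.reference_rule_profiles(), 0.5)
        top_rule, top_profile = ranked.entries[0]
        assert set(top_rule.secondaries) == set(CANDIDATE_SECONDARIES)
        assert top_profile.odds_ratio.point == 7.81
        assert top_profile.sensitivity.point == 0.81

    def test_high_floor_excludes_everything(self):
        ranked = ms.rank_mnemonics(self.reference_rule_profiles(), 0.99)
        assert ranked.all_excluded
        assert ranked.entries == ()

    def test_tie_break_by_size_then_label(self):
        r_small = ms.CompositeRule("chest_pain", ("sweating",))
        r_big = ms.CompositeRule("chest_pain", ("dyspnea", "sweating"))
        same = profile_from_points(5.0, 0.8, 0.7)
        ranked = ms.rank_mnemonics([(r_big, same), (r_small, same)], 0.5)
        assert ranked.entries[0][0] is r_small


@pytest.mark.parametrize("base", [("sweating",), ("sweating", "referred_pain"),
                                  ("sweating", "referred_pain", "dyspnea")])
def test_adding_a_secondary_is_monotone(fully_recorded_cohort, base):
    """On fully recorded data, widening the any-of set never lowers
    sensitivity and never raises specificity."""
    narrow = ms.CompositeRule("chest_pain", base)
    wide = ms.CompositeRule("chest_pain", base + ("palpitation",))
    p_narrow = ms.diagnostic_profile(ms.cross_tabulate(fully_recorded_cohort, narrow))
    p_wide = ms.diagnostic_profile(ms.cross_tabulate(fully_recorded_cohort, wide))
    assert p_wide.sensitivity.point >= p_narrow.sensitivity.point
    assert p_wide.specificity.point <= p_narrow.specificity.point
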