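"""Label codes, usability, deduplication-based confidentiality, final score."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from deidverify import (
    LabeledPolicy,
    MaskingPolicy,
    confidentiality_pct,
    confidentiality_value,
    distinct_groups,
    final_score,
    generate_cohort,
    label_code,
    label_policy,
    mask_cohort,
    score_policy,
    usability,
)
from tests.conftest import ALL_MASKED, TABLE5_POLICY, brute_force_distinct_groups

policies = st.builds(
    MaskingPolicy,
    name_level=st.integers(0, 3),
    age_level=st.integers(0, 2),
    phone_level=st.sampled_from(["none", "partial", "full"]),
    blood_mask=st.booleans(),
    region_mask=st.booleans(),
    illness_mask=st.booleans(),
    smoking_mask=st.booleans(),
)


class TestLabelCodes:
    @pytest.mark.parametrize(
        "field,level,expected",
        [
            ("name", 0, 3),
            ("name", 1, 12),
            ("name", 2, 21),
            ("name", 3, 30),
            ("age", 0, 2),
            ("age", 1, 11),
            ("age", 2, 20),
            ("phone", "none", 8),
            ("phone", "partial", 17),
            ("phone", "full", 80),
            ("blood", False, 1),
            ("blood", True, 0),
            ("region", False, 1),
            ("illness", True, 0),
            ("smoking", False, 1),
        ],
    )
    def test_label_code_table(self, field, level, expected):
        assert label_code(field, level) == expected

    def test_unknown_level_rejected(self):
        with pytest.raises(ValueError):
            label_code("age", 5)
        with pytest.raises(ValueError):
            label_code("phone", "half")
        with pytest.raises(ValueError):
            label_code("nickname", 0)

    def test_label_policy_worked_example(self):
        labels = label_policy(TABLE5_POLICY)
        assert labels == LabeledPolicy(12, 11, 17, 1, 1, 0, 1)


class TestUsability:
    def test_worked_example_equals_13(self):
        labels = LabeledPolicy(
            name_label=12, age_label=11, phone_label=17,
            blood_label=1, region_label=1, illness_label=0, smoking_label=1,
        )
        # (1x2) + (1x1) + (1x7) + 1 + 1 + 0 + 1
        assert usability(labels) == 13

    def test_everything_masked_scores_zero(self):
        labels = LabeledPolicy(30, 20, 80, 0, 0, 0, 0)
        assert usability(labels) == 0

    def test_fully_visible_policy_scores_only_categoricals(self):
        # digit products of 03, 02, 08 are all zero; 4 categorical points remain
        labels = LabeledPolicy(3, 2, 8, 1, 1, 1, 1)
        assert usability(labels) == 4

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(policy=policies)
    def test_depends_only_on_labels_and_is_bounded(self, policy):
        u = usability(label_policy(policy))
        assert 0 <= u <= 14  # max = (1x2)+(1x1)+(1x7)+4


class TestDistinctGroups:
    def test_all_rows_identical(self, cohort200):
        masked = mask_cohort(cohort200, ALL_MASKED)
        assert distinct_groups(masked) == 1

    def test_all_rows_distinct_with_unmasked_phones(self, cohort200):
        masked = mask_cohort(cohort200, MaskingPolicy())
        assert distinct_groups(masked) == len(cohort200)

    def test_six_row_fixture_with_two_duplicate_pairs(self):
        rows = [("a", "1"), ("b", "2"), ("a", "1"), ("c", "3"), ("b", "2"), ("d", "4")]
        frame = pd.DataFrame(rows)
        assert brute_force_distinct_groups(frame) == 4
        assert distinct_groups(frame) == 4

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            distinct_groups(pd.DataFrame())

    def test_matches_brute_force_oracle_on_random_policies(self, spec):
        rng = np.random.default_rng(42)
        for k in range(50):
            n = int(rng.integers(20, 201))
            cohort = generate_cohort(n, spec, seed=int(rng.integers(0, 2**31)))
            policy = MaskingPolicy(
                name_level=int(rng.integers(0, 4)),
                age_level=int(rng.integers(0, 3)),
                phone_level=["none", "partial", "full"][int(rng.integers(0, 3))],
                blood_mask=bool(rng.integers(0, 2)),
                region_mask=bool(rng.integers(0, 2)),
                illness_mask=bool(rng.integers(0, 2)),
                smoking_mask=bool(rng.integers(0, 2)),
            )
            masked = mask_cohort(cohort, policy)
            assert distinct_groups(masked) == brute_force_distinct_groups(masked)


class TestConfidentiality:
    def test_fully_masked_five_rows_is_20pct(self, fixtures):
        cohort = fixtures["cohort_5"]
        masked = mask_cohort(cohort, ALL_MASKED)
        assert confidentiality_pct(masked, len(cohort)) == pytest.approx(20.0)

    def test_unmasked_cohort_is_100pct(self, cohort200):
        masked = mask_cohort(cohort200, MaskingPolicy())
        assert confidentiality_pct(masked, len(cohort200)) == pytest.approx(100.0)

    def test_six_rows_four_groups_is_66_67pct(self):
        rows = [("a",), ("b",), ("a",), ("c",), ("b",), ("d",)]
        assert confidentiality_pct(pd.DataFrame(rows), 6) == pytest.approx(66.67, abs=0.01)

    def test_invalid_denominator(self):
        with pytest.raises(ValueError):
            confidentiality_pct(pd.DataFrame([("a",)]), 0)

    @pytest.mark.parametrize(
        "pct,expected",
        [
            (0.01, 15),
            (20.0, 15),
            (20.001, 12),
            (40.0, 12),
            (50.0, 9),
            (60.0, 9),
            (66.67, 6),
            (80.0, 6),
            (80.001, 3),
            (98.999, 3),
            (99.0, 1),
            (99.999, 1),
            (100.0, 0),
        ],
    )
    def test_banding(self, pct, expected):
        assert confidentiality_value(pct) == expected

    def test_out_of_range_pct_rejected(self):
        for pct in (0.0, -5.0, 100.001):
            with pytest.raises(ValueError):
                confidentiality_value(pct)

    def test_band_function_is_nonincreasing_with_exact_range(self):
        grid = np.linspace(1e-6, 100.0, 5000)
        vals = [confidentiality_value(p) for p in grid]
        assert all(a >= b for a, b in zip(vals, vals[1:]))
        assert set(vals) == {0, 1, 3, 6, 9, 12, 15}


class TestFinalScore:
    def test_usability_13_pct_20_gives_28(self):
        labels = LabeledPolicy(12, 11, 17, 1, 1, 0, 1)
        breakdown = final_score(labels, 20.0)
        assert breakdown.usability == 13
        assert breakdown.confidentiality_value == 15
        assert breakdown.final_score == 28

    def test_all_masked_useless_and_unprotected_extremes(self):
        assert final_score(LabeledPolicy(30, 20, 80, 0, 0, 0, 0), 100.0).final_score == 0
        assert final_score(LabeledPolicy(3, 2, 8, 1, 1, 1, 1), 100.0).final_score == 4

    def test_score_policy_is_deterministic(self, cohort200):
        a = score_policy(cohort200, TABLE5_POLICY)
        b = score_policy(cohort200, TABLE5_POLICY)
        assert a == b

    def test_confidentiality_monotone_under_nested_policies(self, spec):
        """Masking strictly more never increases the deduplicated-group count
        and never decreases the confidentiality band score."""
        rng = np.random.default_rng(7)
        cohort = generate_cohort(150, spec, seed=9)
        levels = ["none", "partial", "full"]
        checked = 0
        while checked < 100:
            weak = MaskingPolicy(
                name_level=int(rng.integers(0, 4)),
                age_level=int(rng.integers(0, 3)),
                phone_level=levels[int(rng.integers(0, 3))],
                blood_mask=bool(rng.integers(0, 2)),
                region_mask=bool(rng.integers(0, 2)),
                illness_mask=bool(rng.integers(0, 2)),
                smoking_mask=bool(rng.integers(0, 2)),
            )
            strong = MaskingPolicy(
                name_level=int(rng.integers(weak.name_level, 4)),
                age_level=int(rng.integers(weak.age_level, 3)),
                phone_level=levels[int(rng.integers(levels.index(weak.phone_level), 3))],
                blood_mask=bool(rng.integers(int(weak.blood_mask), 2)),
                region_mask=bool(rng.integers(int(weak.region_mask), 2)),
                illness_mask=bool(rng.integers(int(weak.illness_mask), 2)),
                smoking_mask=bool(rng.integers(int(weak.smoking_mask), 2)),
            )
            assert strong.covers(weak)
            g_weak = distinct_groups(mask_cohort(cohort, weak))
            g_strong = distinct_groups(mask_cohort(cohort, strong))
            assert g_strong <= g_weak
            v_weak = confidentiality_value(g_weak / len(cohort) * 100)
            v_strong = confidentiality_value(g_strong / len(cohort) * 100)
            assert v_strong >= v_weak
            checked += 1
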