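"""Letter bands, the 15% group rule, red flags, and group aggregation."""

import itertools
import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wag import (
    ConfigError,
    EmptyGroupError,
    IndividualGrade,
    aggregate,
    final_group_grade,
    grade_distribution,
    grade_of_score,
    red_flag,
    score_category,
)
from wag.grading import grade_group
from wag.schema import GRADE_LETTERS, default_grade_bands
from conftest import record_with_colors

BANDS = default_grade_bands()

# Printed two-group illustration of the 15% rule (per-letter % of animals).
GROUP_A = dict(zip(GRADE_LETTERS, [27, 39, 15, 9, 2, 5, 0, 2, 1, 0]))
GROUP_B = dict(zip(GRADE_LETTERS, [30, 39, 19, 3, 6, 2, 0, 1, 0, 0]))


def brute_force_group_grade(letters: list[str], threshold: float = 15.0) -> str:
    """Independent oracle: sort grades worst-to-best and scan for the
    first animal position at which the cumulative share reaches the
    threshold; the group grade is that animal's letter."""
    ordered = sorted(letters, key=GRADE_LETTERS.index, reverse=True)  # J first
    n = len(ordered)
    k = math.ceil(n * threshold / 100.0)
    return ordered[k - 1]


class TestGradeOfScore:
    @pytest.mark.parametrize(
        "score, letter",
        [
            (100, "A"),
            (95, "A"),
            (90, "A"),
            (89.9, "B"),
            (87.5, "B"),
            (80, "B"),
            (79, "C"),
            (62.5, "D"),
            (50, "E"),
            (49.9, "F"),
            (40, "F"),
            (12.5, "I"),
            (10, "I"),
            (9.9, "J"),
            (0, "J"),
        ],
    )
    def test_half_open_band_convention(self, score, letter):
        assert grade_of_score(score, BANDS) == letter

    @pytest.mark.parametrize("score", [-0.1, 100.1, 150])
    def test_out_of_range_rejected(self, score):
        with pytest.raises(ValueError):
            grade_of_score(score, BANDS)

    def test_achievable_letters_skip_f(self):
        """No sum of four values from {0, 12.5, 25} lands in [40, 50), so
        grade F is unreachable by real category scores."""
        points = (0.0, 12.5, 25.0)
        letters = {
            grade_of_score(sum(combo), BANDS)
            for combo in itertools.product(points, repeat=4)
        }
        assert letters == set("ABCDE") | set("GHIJ")


class TestGradeDistribution:
    def test_uniform_group(self):
        grades = [IndividualGrade(f"a{i}", "health", 100, "A") for i in range(4)]
        dist = grade_distribution(grades)
        assert dist["A"] == 100.0
        assert all(dist[let] == 0.0 for let in GRADE_LETTERS if let != "A")

    def test_matches_hand_tally_on_random_group(self):
        rng = np.random.default_rng(7)
        letters = rng.choice(list(GRADE_LETTERS), size=200)
        grades = [
            IndividualGrade(f"a{i}", "health", 0, let)
            for i, let in enumerate(letters)
        ]
        tally = Counter(letters)
        dist = grade_distribution(grades)
        for letter in GRADE_LETTERS:
            assert dist[letter] == pytest.approx(100 * tally[letter] / 200)
        assert sum(dist.values()) == pytest.approx(100)

    def test_empty_group_raises(self):
        with pytest.raises(EmptyGroupError):
            grade_distribution([])

    def test_mixed_categories_rejected(self):
        grades = [
            IndividualGrade("a", "health", 100, "A"),
            IndividualGrade("b", "behavior", 100, "A"),
        ]
        with pytest.raises(ValueError, match="categories"):
            grade_distribution(grades)


class TestFinalGroupGrade:
    def test_printed_group_a_selects_d_at_19(self):
        letter, cumulative = final_group_grade(GROUP_A, 15)
        assert letter == "D"
        assert cumulative["D"] == 19

    def test_printed_group_b_selects_c_at_31(self):
        letter, cumulative = final_group_grade(GROUP_B, 15)
        assert letter == "C"
        assert cumulative["C"] == 31

    def test_all_mass_at_a(self):
        dist = {letter: 0.0 for letter in GRADE_LETTERS} | {"A": 100.0}
        letter, cumulative = final_group_grade(dist, 15)
        assert letter == "A"
        assert cumulative["A"] == 100.0

    def test_cumulative_non_decreasing_worst_to_best(self):
        _, cumulative = final_group_grade(GROUP_A, 15)
        values = [cumulative[letter] for letter in reversed(GRADE_LETTERS)]
        assert values == sorted(values)
        assert cumulative["A"] == pytest.approx(100)

    def test_all_zero_distribution_raises(self):
        with pytest.raises(EmptyGroupError):
            final_group_grade({letter: 0 for letter in GRADE_LETTERS}, 15)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        letters=st.lists(
            st.sampled_from(GRADE_LETTERS), min_size=1, max_size=50
        )
    )
    def test_matches_sort_and_scan_oracle(self, letters):
        grades = [
            IndividualGrade(f"a{i}", "health", 0, let)
            for i, let in enumerate(letters)
        ]
        letter, _ = final_group_grade(grade_distribution(grades), 15)
        assert letter == brute_force_group_grade(letters, 15)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        letters=st.lists(
            st.sampled_from(GRADE_LETTERS), min_size=1, max_size=30
        ),
        animal=st.integers(min_value=0, max_value=29),
    )
    def test_improving_one_animal_never_worsens_group(self, letters, animal):
        """Weak monotonicity of the group grade."""
        animal %= len(letters)
        if letters[animal] == "A":
            return
        improved = list(letters)
        improved[animal] = GRADE_LETTERS[GRADE_LETTERS.index(letters[animal]) - 1]

        def final(ls):
            grades = [
                IndividualGrade(f"a{i}", "h", 0, l) for i, l in enumerate(ls)
            ]
            return final_group_grade(grade_distribution(grades), 15)[0]

        assert GRADE_LETTERS.index(final(improved)) <= GRADE_LETTERS.index(
            final(letters)
        )

    def test_final_letter_has_positive_share(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            letters = list(
                rng.choice(list(GRADE_LETTERS), size=rng.integers(1, 40))
            )
            grades = [
                IndividualGrade(f"a{i}", "h", 0, l)
                for i, l in enumerate(letters)
            ]
            dist = grade_distribution(grades)
            letter, _ = final_group_grade(dist, 15)
            assert dist[letter] > 0


class TestRedFlag:
    def _scores(self, config, tree, n_red, n_total):
        reds = [
            record_with_colors(tree, ("red", "green", "green", "green"), f"r{i}")
            for i in range(n_red)
        ]
        greens = [
            record_with_colors(tree, ("green",) * 4, f"g{i}")
            for i in range(n_total - n_red)
        ]
        return [score_category(r, tree, config) for r in reds + greens]

    def test_no_red_answers(self, config, behavior_tree):
        flagged, pct = red_flag(self._scores(config, behavior_tree, 0, 20), 15)
        assert (flagged, pct) == (False, 0.0)

    def test_exactly_fifteen_percent_is_inclusive(self, config, behavior_tree):
        flagged, pct = red_flag(self._scores(config, behavior_tree, 3, 20), 15)
        assert (flagged, pct) == (True, 15.0)

    def test_just_below_threshold(self, config, behavior_tree):
        scores = self._scores(config, behavior_tree, 149, 1000)
        flagged, pct = red_flag(scores, 15)
        assert (flagged, pct) == (False, 14.9)

    def test_empty_group_raises(self):
        with pytest.raises(EmptyGroupError):
            red_flag([], 15)


class TestAggregate:
    def _two_country_records(self, tree):
        records = []
        for country in ("np", "uk"):
            for i in range(10):
                records.append(
                    record_with_colors(
                        tree,
                        ("green",) * 4,
                        f"{country}{i}",
                        group_attrs={"country": country, "region": "all"},
                    )
                )
        return records

    def test_one_group_grade_per_country_and_category(self, config, behavior_tree):
        records = self._two_country_records(behavior_tree)
        grades = aggregate(records, config, ["country"])
        behavior = [g for g in grades if g.category == "behavior"]
        assert sorted(g.group_key["country"] for g in behavior) == ["np", "uk"]
        # the records answer no health questions: health groups carry no grade
        health = [g for g in grades if g.category == "health"]
        assert all(g.final_letter is None and g.render() == "no grade" for g in health)
        assert all(g.n_excluded == 10 for g in health)

    def test_uniform_three_green_one_red_group_renders_c_star(
        self, config, behavior_tree
    ):
        """Every animal (G, G, G, R) scores 75 -> grade C; every animal has a
        red answer, so the group grade carries the asterisk: C*."""
        records = [
            record_with_colors(
                behavior_tree,
                ("green", "green", "green", "red"),
                f"a{i}",
                group_attrs={"country": "x"},
            )
            for i in range(12)
        ]
        grades = [
            g
            for g in aggregate(records, config, ["country"])
            if g.category == "behavior"
        ]
        assert len(grades) == 1
        g = grades[0]
        assert g.final_letter == "C"
        assert g.red_flag and g.red_percent == 100.0
        assert g.render() == "C*"
        assert g.distribution["C"] == 100.0

    def test_constant_attribute_equals_whole_dataset(self, config, behavior_tree):
        records = self._two_country_records(behavior_tree)
        by_region = [
            g
            for g in aggregate(records, config, ["region"])
            if g.category == "behavior"
        ]
        whole = [
            g for g in aggregate(records, config, []) if g.category == "behavior"
        ]
        assert len(by_region) == len(whole) == 1
        assert by_region[0].final_letter == whole[0].final_letter
        assert by_region[0].distribution == whole[0].distribution

    def test_unknown_group_by_attribute_raises(self, config, behavior_tree):
        records = self._two_country_records(behavior_tree)
        with pytest.raises(ConfigError, match="continent"):
            aggregate(records, config, ["continent"])

    def test_grade_group_mixed_trees_rejected(self, config, behavior_tree, health_tree):
        b = score_category(
            record_with_colors(behavior_tree, ("green",) * 4), behavior_tree, config
        )
        h = score_category(
            record_with_colors(health_tree, ("green", "green", "green", "green")),
            health_tree,
            config,
        )
        with pytest.raises(ValueError, match="mixes"):
            grade_group([b, h], config, {})
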