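"""Aggregation Steps 2-4: letter grades, the 15% group rule, red flags.

Step 2 maps each 0-100 category score onto a letter band A (best) to J
(worst).  Step 3 assigns one grade to a whole group: percentages of animals
per letter are accumulated from the worst grade (J) towards the best (A),
and the group grade is the first letter at which the cumulative share
reaches the group-rule threshold (15% by default, inclusive).  Step 4
marks the grade with an asterisk when at least the red-flag threshold of
animals received one or more red answers, distinguishing a group of
uniformly mediocre animals from one mixing good and very poor ones.

Threshold comparisons use exact (unrounded) percentages; rounding happens
only at display time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .schema import (
    GRADE_LETTERS,
    ConfigError,
    EmptyGroupError,
    GradeBand,
    WagConfig,
)
from .scoring import AssessmentRecord, CategoryScore, score_records

__all__ = [
    "IndividualGrade",
    "GroupGrade",
    "grade_of_score",
    "grade_individual",
    "grade_distribution",
    "final_group_grade",
    "red_flag",
    "grade_group",
    "aggregate",
]


@dataclass(frozen=True)
class IndividualGrade:
    animal_id: str
    category: str
    score: float
    letter: str


@dataclass(frozen=True)
class GroupGrade:
    """One group's final letter grade with its full audit trail.

    ``final_letter`` is None for a group in which no animal could be
    scored — an explicit "no grade", never a default letter.  ``render()``
    formats the grade as ``"D*"`` when the red flag applies.
    """

    group_key: dict[str, str]
    category: str
    age_class: str
    n_animals: int
    n_excluded: int
    distribution: dict[str, float]  # letter -> % of scored animals
    cumulative: dict[str, float]  # letter -> cumulative %, worst (J) to best
    final_letter: Optional[str]
    red_flag: bool
    red_percent: float
    grades: tuple[IndividualGrade, ...] = field(default_factory=tuple)

    def render(self) -> str:
        if self.final_letter is None:
            return "no grade"
        return self.final_letter + ("*" if self.red_flag else "")


def grade_of_score(score: float, bands: Sequence[GradeBand]) -> str:
    """Map a category score to its letter band (A = [90,100] ... J = [0,10))."""
    if not (0 <= score <= 100):
        raise ValueError(f"score must lie in [0, 100], got {score}")
    for band in bands:
        if band.contains(score):
            return band.letter
    raise ValueError(f"no grade band contains score {score}")  # pragma: no cover


def grade_individual(score: CategoryScore, config: WagConfig) -> IndividualGrade:
    return IndividualGrade(
        animal_id=score.animal_id,
        category=score.category,
        score=score.total,
        letter=grade_of_score(score.total, config.grade_bands),
    )


def grade_distribution(grades: Iterable[IndividualGrade]) -> dict[str, float]:
    """Percentage of animals per letter, A..J, zero-count letters included."""
    grades = list(grades)
    if not grades:
        raise EmptyGroupError("cannot tabulate grades of an empty group")
    categories = {g.category for g in grades}
    if len(categories) > 1:
        raise ValueError(
            f"grade_distribution mixes categories {sorted(categories)}"
        )
    n = len(grades)
    counts = {letter: 0 for letter in GRADE_LETTERS}
    for g in grades:
        counts[g.letter] += 1
    return {letter: 100.0 * counts[letter] / n for letter in GRADE_LETTERS}


def final_group_grade(
    distribution: Mapping[str, float], threshold: float = 15.0
) -> tuple[str, dict[str, float]]:
    """Apply the 15% rule to a per-letter percentage distribution.

    Percentages are accumulated from the worst grade (J) to the best (A);
    the group grade is the first letter whose cumulative share reaches the
    threshold ("at least" — the comparison is inclusive).  Returns the
    letter and the full cumulative table keyed A..J.
    """
    total = sum(distribution.get(letter, 0.0) for letter in GRADE_LETTERS)
    if total <= 0:
        raise EmptyGroupError("distribution has no mass")
    if abs(total - 100.0) > 0.5:
        raise ValueError(f"distribution sums to {total}, expected 100")

    cumulative: dict[str, float] = {}
    running = 0.0
    final: Optional[str] = None
    for letter in reversed(GRADE_LETTERS):  # J -> A
        running += distribution.get(letter, 0.0)
        cumulative[letter] = running
        if final is None and running >= threshold:
            final = letter
    if final is None:  # threshold > 100 cannot be configured, but be safe
        final = "A"
    return final, {letter: cumulative[letter] for letter in GRADE_LETTERS}


def red_flag(
    category_scores: Sequence[CategoryScore], threshold: float = 15.0
) -> tuple[bool, float]:
    """Share of animals with >= 1 red answer, and whether it flags the group.

    The comparison is inclusive: exactly 15% of animals with a red answer
    raises the flag at the default threshold.
    """
    if not category_scores:
        raise EmptyGroupError("red_flag of an empty group")
    n = len(category_scores)
    n_red = sum(1 for s in category_scores if s.has_red)
    red_percent = 100.0 * n_red / n
    return red_percent >= threshold, red_percent


def grade_group(
    scores: Sequence[CategoryScore],
    config: WagConfig,
    group_key: Mapping[str, str],
    n_excluded: int = 0,
) -> GroupGrade:
    """Steps 2-4 for one group of already-scored animals."""
    if not scores:
        first = None
        return GroupGrade(
            group_key=dict(group_key),
            category="",
            age_class="",
            n_animals=0,
            n_excluded=n_excluded,
            distribution={},
            cumulative={},
            final_letter=first,
            red_flag=False,
            red_percent=0.0,
        )
    categories = {(s.category, s.age_class) for s in scores}
    if len(categories) > 1:
        raise ValueError(f"grade_group mixes trees {sorted(categories)}")
    category, age_class = next(iter(categories))

    grades = tuple(grade_individual(s, config) for s in scores)
    distribution = grade_distribution(grades)
    letter, cumulative = final_group_grade(
        distribution, config.thresholds.group_rule_percent
    )
    flagged, red_percent = red_flag(scores, config.thresholds.red_flag_percent)
    return GroupGrade(
        group_key=dict(group_key),
        category=category,
        age_class=age_class,
        n_animals=len(scores),
        n_excluded=n_excluded,
        distribution=distribution,
        cumulative=cumulative,
        final_letter=letter,
        red_flag=flagged,
        red_percent=red_percent,
        grades=grades,
    )


def _group_key_of(
    record: AssessmentRecord, group_by: Sequence[str]
) -> tuple[tuple[str, str], ...]:
    key = []
    for attr in group_by:
        if attr not in record.group_attrs:
            raise ConfigError(
                f"animal {record.animal_id!r} has no group attribute {attr!r}"
            )
        key.append((attr, record.group_attrs[attr]))
    return tuple(key)


def aggregate(
    records: Sequence[AssessmentRecord],
    config: WagConfig,
    group_by: Sequence[str] = (),
) -> list[GroupGrade]:
    """Run Steps 1-4 over a whole assessment table.

    Produces one :class:`GroupGrade` per (group x category x age class)
    combination present in the data; adult and foal animals are graded
    against their own trees and never pooled.  Excluded animals (incomplete
    trees) are counted per group.  An empty ``group_by`` grades the whole
    dataset as a single group.
    """
    results: list[GroupGrade] = []
    for tree in config.trees:
        subset = [r for r in records if r.age_class == tree.age_class]
        partitions: dict[tuple, list[AssessmentRecord]] = {}
        for record in subset:
            partitions.setdefault(_group_key_of(record, group_by), []).append(
                record
            )
        for key, members in sorted(partitions.items()):
            scores, excluded = score_records(members, tree, config)
            grade = grade_group(
                scores, config, dict(key), n_excluded=len(excluded)
            )
            if not scores:  # all excluded: keep tree identity on the result
                grade = GroupGrade(
                    group_key=dict(key),
                    category=tree.category,
                    age_class=tree.age_class,
                    n_animals=0,
                    n_excluded=len(excluded),
                    distribution={},
                    cumulative={},
                    final_letter=None,
                    red_flag=False,
                    red_percent=0.0,
                )
            results.append(grade)
    return results
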