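"""Aggregation Step 1: per-animal category scores.

Each welfare category is scored by a fixed decision tree of four questions.
Every selected answer carries a traffic-light color; a question's effective
color is the single answer's color (single choice), the worst selected
color (default multi-select rule: a poor-welfare indicator is never
outweighed by accompanying good ones), or the best selected color for the
two designated nutrition exception questions.  Per-color points
(green = 25, amber = 12.5, red = 0 by default) are summed over the four
questions into a 0-100 category score.

Animals are only scored when all four tree slots can be answered — either
by the primary question or by its configured replacement.  Anything less
raises :class:`~wag.schema.IncompleteAssessmentError` so callers can
exclude the animal explicitly rather than produce a partial score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from pydantic import BaseModel, ConfigDict, Field, field_validator

from .schema import (
    COLOR_RANK,
    AgeClass,
    CategoryTree,
    DataError,
    IncompleteAssessmentError,
    MissingAnswerError,
    QuestionSpec,
    WagConfig,
)

__all__ = [
    "AssessmentRecord",
    "QuestionScore",
    "CategoryScore",
    "effective_color",
    "score_question",
    "score_category",
    "score_records",
]


class AssessmentRecord(BaseModel):
    """One animal's assessment: answers plus grouping attributes.

    ``answers`` maps question_id to the set of selected answer_ids; a
    question the assessor could not answer is simply absent from the map.
    ``group_attrs`` holds the attributes used for group-level aggregation
    (region, country, role, species, sex, ...).
    """

    model_config = ConfigDict(extra="forbid")

    animal_id: str
    age_class: AgeClass
    group_attrs: dict[str, str] = Field(default_factory=dict)
    answers: dict[str, set[str]] = Field(default_factory=dict)

    @field_validator("answers")
    @classmethod
    def _no_empty_sets(cls, v: dict[str, set[str]]) -> dict[str, set[str]]:
        empty = [q for q, sel in v.items() if not sel]
        if empty:
            raise ValueError(f"empty answer set for question(s): {empty}")
        return v


@dataclass(frozen=True)
class QuestionScore:
    """The resolved color and points of one scored tree slot."""

    question_id: str
    effective_color: str
    points: float


@dataclass(frozen=True)
class CategoryScore:
    """A 0-100 category score with its per-question color trace."""

    animal_id: str
    category: str
    age_class: str
    question_scores: tuple[QuestionScore, ...]
    total: float
    has_red: bool
    uses_other: bool = False  # any scored answer was a free-text 'other'
    replacements_used: tuple[str, ...] = field(default_factory=tuple)

    def color_of(self, question_id: str) -> Optional[str]:
        for qs in self.question_scores:
            if qs.question_id == question_id:
                return qs.effective_color
        return None


def effective_color(question: QuestionSpec, selected: Iterable[str]) -> str:
    """Resolve a selection to the single color that determines the score.

    Colors are ordered by their points — red < amber < green — so the
    ``lowest`` rule returns the worst selected color and the ``highest``
    rule (nutrition exceptions) the best.  A single-choice question must
    carry exactly one selection.
    """
    selected = list(selected)
    if not selected:
        raise MissingAnswerError(
            f"question {question.question_id!r}: no answer selected"
        )
    if question.choice_mode == "single" and len(selected) != 1:
        raise DataError(
            f"question {question.question_id!r} is single-choice but "
            f"{len(selected)} answers were selected"
        )
    colors = [question.option(a).color for a in selected]
    pick = max if question.score_rule == "highest" else min
    return pick(colors, key=COLOR_RANK.__getitem__)


def score_question(
    question: QuestionSpec, selected: Iterable[str], config: WagConfig
) -> QuestionScore:
    color = effective_color(question, selected)
    return QuestionScore(
        question_id=question.question_id,
        effective_color=color,
        points=config.points_of(color),
    )


def _resolve_slot(
    record: AssessmentRecord, primary_id: str, tree: CategoryTree
) -> Optional[str]:
    """Return the question id answering this tree slot, or None."""
    if primary_id in record.answers:
        return primary_id
    repl_id = tree.replacements.get(primary_id)
    if repl_id is not None and repl_id in record.answers:
        return repl_id
    return None


def score_category(
    record: AssessmentRecord, tree: CategoryTree, config: WagConfig
) -> CategoryScore:
    """Score one animal on one category tree.

    The configured replacement question substitutes for a primary only
    when the primary is unanswered; when both are answered the primary
    wins.  If any of the four slots has neither primary nor replacement
    answered the animal cannot be scored and
    :class:`~wag.schema.IncompleteAssessmentError` is raised (the caller
    excludes the animal and reports the count).
    """
    if record.age_class != tree.age_class:
        raise DataError(
            f"animal {record.animal_id!r} has age class {record.age_class!r} "
            f"but the tree is for {tree.age_class!r}"
        )
    resolved: list[str] = []
    missing: list[str] = []
    for primary_id in tree.primary_questions:
        qid = _resolve_slot(record, primary_id, tree)
        if qid is None:
            missing.append(primary_id)
        else:
            resolved.append(qid)
    if missing:
        raise IncompleteAssessmentError(record.animal_id, missing)

    scores = []
    uses_other = False
    for qid in resolved:
        question = config.question(qid)
        selected = record.answers[qid]
        scores.append(score_question(question, selected, config))
        if any(question.option(a).is_other for a in selected):
            uses_other = True

    return CategoryScore(
        animal_id=record.animal_id,
        category=tree.category,
        age_class=tree.age_class,
        question_scores=tuple(scores),
        total=sum(qs.points for qs in scores),
        has_red=any(qs.effective_color == "red" for qs in scores),
        uses_other=uses_other,
        replacements_used=tuple(
            q for q in resolved if q not in tree.primary_questions
        ),
    )


def score_records(
    records: Iterable[AssessmentRecord], tree: CategoryTree, config: WagConfig
) -> tuple[list[CategoryScore], list[IncompleteAssessmentError]]:
    """Score every matching animal; collect exclusions instead of raising.

    Records of a different age class are ignored (they belong to another
    tree).  Returns the scores and the list of per-animal exclusions so
    incomplete assessments are counted, never silently dropped.
    """
    scores: list[CategoryScore] = []
    excluded: list[IncompleteAssessmentError] = []
    for record in records:
        if record.age_class != tree.age_class:
            continue
        try:
            scores.append(score_category(record, tree, config))
        except IncompleteAssessmentError as exc:
            excluded.append(exc)
    return scores, excluded
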