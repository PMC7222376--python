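"""Driver analysis: decompose a group's grade into its causes.

After aggregation, a poor group grade is traced back to (a) the share of
animals whose effective color on each tree question was green, amber or
red, and (b) within each (question, color) stratum, the share of animals
that selected each specific answer.  Breakdowns count every selected
answer, not only the one that determined the score, so overlapping signs
(e.g. nasal and eye discharge on the same animal) are both visible and the
within-stratum percentages of a multi-select question may sum to more
than 100.  Every table carries its denominator (the stratum n).

Percentages are computed exactly; rounding to whole percent is left to the
report renderer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Optional, Sequence

import pandas as pd

from .schema import (
    CategoryTree,
    DataError,
    EmptyGroupError,
    QuestionSpec,
    WagConfig,
)
from .scoring import AssessmentRecord, effective_color

__all__ = [
    "DriverReport",
    "color_frequencies",
    "answer_breakdown",
    "co_selection_rate",
    "build_driver_report",
]

GroupFilter = Optional[Callable[[AssessmentRecord], bool]]

_COLORS = ("green", "amber", "red")


def _filtered(
    records: Iterable[AssessmentRecord], group_filter: GroupFilter
) -> list[AssessmentRecord]:
    return [r for r in records if group_filter is None or group_filter(r)]


def _slot_question(
    record: AssessmentRecord, primary_id: str, tree: CategoryTree
) -> Optional[str]:
    if primary_id in record.answers:
        return primary_id
    repl = tree.replacements.get(primary_id)
    if repl is not None and repl in record.answers:
        return repl
    return None


def color_frequencies(
    records: Sequence[AssessmentRecord],
    tree: CategoryTree,
    config: WagConfig,
    group_filter: GroupFilter = None,
) -> pd.DataFrame:
    """Per-question percentages of animals by effective color.

    Replacement answers are tallied under the replacement question's own
    id, so the frame may carry more than four rows; the ``n`` column gives
    each question's denominator and per-slot denominators sum to the group
    size.  Rows are indexed by question_id with columns green/amber/red/n.
    """
    records = _filtered(records, group_filter)
    if not records:
        raise EmptyGroupError("no records in the filtered group")
    counts: dict[str, dict[str, int]] = {}
    for record in records:
        for primary_id in tree.primary_questions:
            qid = _slot_question(record, primary_id, tree)
            if qid is None:
                continue
            question = config.question(qid)
            color = effective_color(question, record.answers[qid])
            row = counts.setdefault(qid, {c: 0 for c in _COLORS})
            row[color] += 1

    rows = {}
    for qid, row in counts.items():
        n = sum(row.values())
        rows[qid] = {c: 100.0 * row[c] / n for c in _COLORS} | {"n": n}
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "question_id"
    frame["n"] = frame["n"].astype(int)
    return frame


def _color_stratum(
    records: Sequence[AssessmentRecord],
    question: QuestionSpec,
    color: str,
) -> list[AssessmentRecord]:
    stratum = []
    for record in records:
        selected = record.answers.get(question.question_id)
        if selected and effective_color(question, selected) == color:
            stratum.append(record)
    return stratum


def answer_breakdown(
    records: Sequence[AssessmentRecord],
    question: QuestionSpec,
    color: str,
    group_filter: GroupFilter = None,
) -> tuple[dict[str, float], int]:
    """Within one (question, color) stratum, % of animals per answer.

    The denominator is the stratum size (animals whose effective color on
    the question equals ``color``); each animal counts once per selected
    answer of that color.  An empty stratum returns ``({}, 0)`` — an
    explicit empty result, not an error.
    """
    if color not in _COLORS:
        raise ValueError(f"unknown color {color!r}")
    records = _filtered(records, group_filter)
    stratum = _color_stratum(records, question, color)
    if not stratum:
        return {}, 0
    option_ids = [o.answer_id for o in question.options if o.color == color]
    counts = {aid: 0 for aid in option_ids}
    for record in stratum:
        for aid in record.answers[question.question_id]:
            if question.option(aid).color == color:
                counts[aid] += 1
    n = len(stratum)
    return {aid: 100.0 * c / n for aid, c in counts.items()}, n


def co_selection_rate(
    records: Sequence[AssessmentRecord],
    question: QuestionSpec,
    answer_pair: tuple[str, str],
    group_filter: GroupFilter = None,
    color: Optional[str] = None,
) -> float:
    """Percentage of a stratum selecting both answers of a pair.

    The stratum is the animals that answered the question, optionally
    narrowed to those whose effective color equals ``color`` (matching the
    style of "of the red responders, X% displayed both signs").
    """
    a1, a2 = answer_pair
    question.option(a1)  # raise DataError on unknown ids
    question.option(a2)
    records = _filtered(records, group_filter)
    if color is None:
        stratum = [r for r in records if question.question_id in r.answers]
    else:
        stratum = _color_stratum(records, question, color)
    if not stratum:
        raise EmptyGroupError(
            f"no animals answered {question.question_id!r} in the stratum"
        )
    both = sum(
        1
        for r in stratum
        if {a1, a2} <= r.answers[question.question_id]
    )
    return 100.0 * both / len(stratum)


@dataclass(frozen=True)
class DriverReport:
    """All driver tables for one group and category tree."""

    group_key: dict[str, str]
    category: str
    age_class: str
    n_animals: int
    per_question: pd.DataFrame  # color_frequencies output
    breakdowns: dict[tuple[str, str], tuple[dict[str, float], int]]

    def to_frame(self) -> pd.DataFrame:
        """Flatten the breakdowns into one tidy table for CSV export."""
        rows = []
        for (qid, color), (pcts, n) in sorted(self.breakdowns.items()):
            for aid, pct in sorted(pcts.items()):
                rows.append(
                    {
                        "question_id": qid,
                        "color": color,
                        "answer_id": aid,
                        "percent_of_stratum": pct,
                        "stratum_n": n,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "question_id",
                "color",
                "answer_id",
                "percent_of_stratum",
                "stratum_n",
            ],
        )

    def to_markdown(self) -> str:
        """A compact human-readable report section for one group."""
        key = ", ".join(f"{k}={v}" for k, v in self.group_key.items()) or "all"
        lines = [
            f"### {self.category} ({self.age_class}) — {key} "
            f"(n = {self.n_animals})",
            "",
            "| question | % green | % amber | % red | n |",
            "|---|---|---|---|---|",
        ]
        for qid, row in self.per_question.iterrows():
            lines.append(
                f"| {qid} | {row['green']:.0f} | {row['amber']:.0f} "
                f"| {row['red']:.0f} | {int(row['n'])} |"
            )
        for (qid, color), (pcts, n) in sorted(self.breakdowns.items()):
            if not pcts or all(v == 0 for v in pcts.values()):
                continue
            parts = ", ".join(
                f"{aid} {pct:.0f}%" for aid, pct in sorted(pcts.items()) if pct > 0
            )
            lines.append("")
            lines.append(f"- {qid} / {color} (n = {n}): {parts}")
        return "\n".join(lines) + "\n"


def build_driver_report(
    records: Sequence[AssessmentRecord],
    tree: CategoryTree,
    config: WagConfig,
    group_key: Mapping[str, str] | None = None,
    group_filter: GroupFilter = None,
) -> DriverReport:
    """Assemble color frequencies plus every non-empty answer breakdown."""
    records = _filtered(records, group_filter)
    per_question = color_frequencies(records, tree, config)
    breakdowns: dict[tuple[str, str], tuple[dict[str, float], int]] = {}
    for qid in per_question.index:
        question = config.question(qid)
        for color in _COLORS:
            pcts, n = answer_breakdown(records, question, color)
            if n:
                breakdowns[(qid, color)] = (pcts, n)
    subset = [r for r in records if r.age_class == tree.age_class]
    return DriverReport(
        group_key=dict(group_key or {}),
        category=tree.category,
        age_class=tree.age_class,
        n_animals=len(subset),
        per_question=per_question,
        breakdowns=breakdowns,
    )
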