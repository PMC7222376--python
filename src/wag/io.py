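"""Assessment-table readers/writers and the end-to-end report pipeline.

Two CSV dialects are supported and round-trip losslessly:

* ``wide`` — one row per animal; one column per question holding the
  selected answer id(s), multi-selections joined by ``|`` (literal pipes
  and backslashes inside an answer id are backslash-escaped); empty cell =
  question not answered.
* ``long`` — one row per (animal, question, selected answer) with fixed
  columns ``animal_id, age_class, question_id, answer_id``.

Any column that is not a reserved column or a configured question id is
treated as a grouping attribute and carried through to aggregation.
Row-level problems are collected (and logged as warnings with counts),
never silently dropped.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import pandas as pd

from .drivers import build_driver_report
from .grading import GroupGrade, aggregate, grade_individual
from .schema import (
    GRADE_LETTERS,
    DataError,
    EmptyGroupError,
    WagConfig,
    load_config,
)
from .scoring import AssessmentRecord, score_records

__all__ = [
    "FormatError",
    "ReadResult",
    "read_assessments",
    "write_assessments",
    "run_pipeline",
]

logger = logging.getLogger("wag")

MULTI_DELIM = "|"
_RESERVED = ("animal_id", "age_class")
_LONG_COLUMNS = ("animal_id", "age_class", "question_id", "answer_id")


class FormatError(DataError):
    """An assessment table is missing required structure."""


def _escape(token: str) -> str:
    return token.replace("\\", "\\\\").replace(MULTI_DELIM, "\\" + MULTI_DELIM)


def _split_multi(cell: str) -> list[str]:
    """Split a wide-form cell on unescaped pipes, honouring backslash
    escapes for literal pipes and backslashes."""
    parts: list[str] = []
    buf: list[str] = []
    i = 0
    while i < len(cell):
        ch = cell[i]
        if ch == "\\" and i + 1 < len(cell) and cell[i + 1] in ("\\", MULTI_DELIM):
            buf.append(cell[i + 1])
            i += 2
        elif ch == MULTI_DELIM:
            parts.append("".join(buf))
            buf = []
            i += 1
        else:
            buf.append(ch)
            i += 1
    parts.append("".join(buf))
    return [p for p in parts if p != ""]


@dataclass
class ReadResult:
    """Parsed records plus the per-row problems that were rejected."""

    records: list[AssessmentRecord]
    problems: list[str] = field(default_factory=list)

    def __iter__(self) -> Iterator[AssessmentRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _require_columns(frame: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def _validate_answers(
    config: WagConfig, answers: dict[str, set[str]]
) -> str | None:
    for qid, selected in answers.items():
        if not config.has_question(qid):
            return f"unknown question {qid!r}"
        question = config.question(qid)
        known = {o.answer_id for o in question.options}
        bad = sorted(set(selected) - known)
        if bad:
            return f"question {qid!r}: unknown answer(s) {bad}"
        if question.choice_mode == "single" and len(selected) > 1:
            return f"question {qid!r} is single-choice, got {sorted(selected)}"
    return None


def read_assessments(
    path: str | Path, config: WagConfig, dialect: str = "wide"
) -> ReadResult:
    """Read an assessment CSV in either dialect into validated records."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"assessment file not found: {path}")
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: file is empty") from exc
    if dialect == "wide":
        result = _read_wide(frame, config, path)
    elif dialect == "long":
        result = _read_long(frame, config, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r} (use 'wide' or 'long')")
    if result.problems:
        logger.warning(
            "%s: rejected %d row(s)/animal(s); first problem: %s",
            path,
            len(result.problems),
            result.problems[0],
        )
    return result


def _read_wide(frame: pd.DataFrame, config: WagConfig, path) -> ReadResult:
    _require_columns(frame, _RESERVED, path)
    question_cols = [c for c in frame.columns if config.has_question(c)]
    attr_cols = [
        c
        for c in frame.columns
        if c not in _RESERVED and c not in question_cols
    ]
    records, problems = [], []
    seen_ids: set[str] = set()
    for idx, row in frame.iterrows():
        animal_id = row["animal_id"].strip()
        if not animal_id:
            problems.append(f"row {idx}: empty animal_id")
            continue
        if animal_id in seen_ids:
            problems.append(f"row {idx}: duplicate animal_id {animal_id!r}")
            continue
        answers = {
            q: set(_split_multi(row[q])) for q in question_cols if row[q] != ""
        }
        problem = _validate_answers(config, answers)
        if problem is None and row["age_class"] not in ("adult", "foal"):
            problem = f"unknown age_class {row['age_class']!r}"
        if problem is not None:
            problems.append(f"row {idx} (animal {animal_id!r}): {problem}")
            continue
        seen_ids.add(animal_id)
        records.append(
            AssessmentRecord(
                animal_id=animal_id,
                age_class=row["age_class"],
                group_attrs={a: row[a] for a in attr_cols},
                answers=answers,
            )
        )
    return ReadResult(records, problems)


def _read_long(frame: pd.DataFrame, config: WagConfig, path) -> ReadResult:
    _require_columns(frame, _LONG_COLUMNS, path)
    attr_cols = [c for c in frame.columns if c not in _LONG_COLUMNS]
    records, problems = [], []
    for (animal_id,), animal_rows in frame.groupby(["animal_id"], sort=False):
        age_classes = set(animal_rows["age_class"])
        if len(age_classes) > 1 or animal_rows[attr_cols].nunique().max() > 1:
            problems.append(
                f"animal {animal_id!r}: inconsistent age_class or attributes"
            )
            continue
        answers: dict[str, set[str]] = {}
        for _, row in animal_rows.iterrows():
            answers.setdefault(row["question_id"], set()).add(row["answer_id"])
        problem = _validate_answers(config, answers)
        age_class = next(iter(age_classes))
        if problem is None and age_class not in ("adult", "foal"):
            problem = f"unknown age_class {age_class!r}"
        if problem is not None:
            problems.append(f"animal {animal_id!r}: {problem}")
            continue
        first = animal_rows.iloc[0]
        records.append(
            AssessmentRecord(
                animal_id=str(animal_id),
                age_class=age_class,
                group_attrs={a: first[a] for a in attr_cols},
                answers=answers,
            )
        )
    return ReadResult(records, problems)


def write_assessments(
    records: Sequence[AssessmentRecord],
    path: str | Path,
    config: WagConfig,
    dialect: str = "wide",
) -> None:
    """Write records to CSV in either dialect (inverse of the reader)."""
    attr_cols = sorted({a for r in records for a in r.group_attrs})
    if dialect == "wide":
        question_cols = [
            q.question_id
            for q in config.questions
            if any(q.question_id in r.answers for r in records)
        ]
        rows = []
        for r in records:
            row = {"animal_id": r.animal_id, "age_class": r.age_class}
            row |= {a: r.group_attrs.get(a, "") for a in attr_cols}
            for q in question_cols:
                selected = sorted(r.answers.get(q, ()))
                row[q] = MULTI_DELIM.join(_escape(a) for a in selected)
            rows.append(row)
        columns = list(_RESERVED) + attr_cols + question_cols
    elif dialect == "long":
        rows = []
        for r in records:
            base = {"animal_id": r.animal_id, "age_class": r.age_class}
            base |= {a: r.group_attrs.get(a, "") for a in attr_cols}
            for qid in sorted(r.answers):
                for aid in sorted(r.answers[qid]):
                    rows.append(base | {"question_id": qid, "answer_id": aid})
        columns = ["animal_id", "age_class"] + attr_cols + [
            "question_id",
            "answer_id",
        ]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


# --------------------------------------------------------------------------
# Pipeline


def _group_grades_frame(grades: Sequence[GroupGrade]) -> pd.DataFrame:
    attr_cols = sorted({a for g in grades for a in g.group_key})
    rows = []
    for g in grades:
        row = {a: g.group_key.get(a, "") for a in attr_cols}
        row |= {
            "category": g.category,
            "age_class": g.age_class,
            "n_animals": g.n_animals,
            "n_excluded": g.n_excluded,
            "final_grade": g.render(),
            "red_percent": round(g.red_percent, 4),
        }
        for letter in GRADE_LETTERS:
            row[f"pct_{letter}"] = round(g.distribution.get(letter, 0.0), 4)
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(
    assessments_path: str | Path,
    config_path: str | Path,
    group_by: Sequence[str],
    out_dir: str | Path,
    dialect: str = "wide",
) -> dict[str, Path]:
    """Score, grade, and explain a whole assessment table.

    Writes, under ``out_dir``: ``animal_scores.csv`` (per-animal scores and
    letters), ``group_grades.csv`` (final letters with asterisks and the
    full grade distribution), ``driver_colors.csv`` and
    ``driver_breakdowns.csv`` (driver analysis per group),
    ``exclusions.csv`` (animals dropped for incomplete trees and why),
    ``report.md``, and ``run_metadata.json``.  Primary tables are
    deterministic for identical inputs; the timestamp lives only in the
    metadata file.  Partial outputs are removed on failure.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = load_config(config_path)
    result = read_assessments(assessments_path, config, dialect=dialect)
    if not result.records:
        raise EmptyGroupError(f"{assessments_path}: no valid assessment records")

    written: dict[str, Path] = {}
    try:
        score_rows, exclusion_rows = [], []
        color_frames, breakdown_frames, report_parts = [], [], []

        grades = aggregate(result.records, config, group_by)
        for tree in config.trees:
            subset = [
                r for r in result.records if r.age_class == tree.age_class
            ]
            scores, excluded = score_records(subset, tree, config)
            for s in scores:
                ig = grade_individual(s, config)
                score_rows.append(
                    {
                        "animal_id": s.animal_id,
                        "category": s.category,
                        "age_class": s.age_class,
                        "score": s.total,
                        "grade": ig.letter,
                        "has_red": s.has_red,
                        "uses_other": s.uses_other,
                        "replacements_used": MULTI_DELIM.join(
                            s.replacements_used
                        ),
                    }
                )
            for exc in excluded:
                exclusion_rows.append(
                    {
                        "animal_id": exc.animal_id,
                        "category": tree.category,
                        "age_class": tree.age_class,
                        "missing_questions": MULTI_DELIM.join(exc.missing),
                    }
                )

        for g in grades:
            if g.n_animals == 0:
                continue
            members = [
                r
                for r in result.records
                if r.age_class == g.age_class
                and all(r.group_attrs.get(k) == v for k, v in g.group_key.items())
            ]
            report = build_driver_report(
                members,
                config.tree(g.category, g.age_class),
                config,
                group_key=g.group_key,
            )
            colors = report.per_question.reset_index()
            for k, v in g.group_key.items():
                colors.insert(0, k, v)
            colors.insert(len(g.group_key), "category", g.category)
            color_frames.append(colors)
            bk = report.to_frame()
            for k, v in g.group_key.items():
                bk.insert(0, k, v)
            bk.insert(len(g.group_key), "category", g.category)
            breakdown_frames.append(bk)
            report_parts.append(
                f"**Group grade: {report.category} = {g.render()}** "
                f"(n = {g.n_animals}, excluded = {g.n_excluded}, "
                f"red answers in {g.red_percent:.0f}% of animals)\n\n"
                + report.to_markdown()
            )

        def _write(name: str, frame: pd.DataFrame) -> None:
            target = out_dir / name
            frame.to_csv(target, index=False)
            written[name] = target

        _write(
            "animal_scores.csv",
            pd.DataFrame(
                score_rows,
                columns=[
                    "animal_id",
                    "category",
                    "age_class",
                    "score",
                    "grade",
                    "has_red",
                    "uses_other",
                    "replacements_used",
                ],
            ).sort_values(["category", "age_class", "animal_id"], kind="stable"),
        )
        _write("group_grades.csv", _group_grades_frame(grades))
        _write(
            "driver_colors.csv",
            pd.concat(color_frames, ignore_index=True)
            if color_frames
            else pd.DataFrame(),
        )
        _write(
            "driver_breakdowns.csv",
            pd.concat(breakdown_frames, ignore_index=True)
            if breakdown_frames
            else pd.DataFrame(),
        )
        _write(
            "exclusions.csv",
            pd.DataFrame(
                exclusion_rows,
                columns=[
                    "animal_id",
                    "category",
                    "age_class",
                    "missing_questions",
                ],
            ),
        )

        report_path = out_dir / "report.md"
        report_path.write_text(
            "# Welfare aggregation report\n\n" + "\n\n".join(report_parts) + "\n"
        )
        written["report.md"] = report_path

        metadata_path = out_dir / "run_metadata.json"
        metadata_path.write_text(
            json.dumps(
                {
                    "assessments": str(assessments_path),
                    "config": str(config_path),
                    "group_by": list(group_by),
                    "n_records": len(result.records),
                    "n_rejected_rows": len(result.problems),
                    "rejected": result.problems,
                    "timestamp": pd.Timestamp.now().isoformat(),
                },
                indent=2,
            )
        )
        written["run_metadata.json"] = metadata_path
    except Exception:
        for target in written.values():
            target.unlink(missing_ok=True)
        raise
    return written
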