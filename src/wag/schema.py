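"""Question-tree configuration: domain types, loading, validation.

A WAG configuration bundles, for each welfare category and age class, the
four questions of the scoring decision tree, every question's answer
options with their colorimetric rank (green / amber / red), the per-color
point values, the letter grade bands, and the group-level thresholds.
All other modules consume a validated :class:`WagConfig`.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

# --------------------------------------------------------------------------
# Constants and errors

Color = Literal["green", "amber", "red"]
Category = Literal[
    "health", "behavior", "working_conditions", "living_environment", "nutrition"
]
AgeClass = Literal["adult", "foal"]

#: Ordering used by the lowest/highest multi-select rules; tied to the
#: point values (red scores least), not to option list position.
COLOR_RANK: dict[str, int] = {"red": 0, "amber": 1, "green": 2}

GRADE_LETTERS: tuple[str, ...] = tuple("ABCDEFGHIJ")

DEFAULT_SCORE_POINTS: dict[str, float] = {"green": 25.0, "amber": 12.5, "red": 0.0}


class WagError(Exception):
    """Base class for all errors raised by this package."""


class ConfigError(WagError):
    """A configuration file failed to parse or violates a guideline."""


class DataError(WagError):
    """An assessment record is inconsistent with the configuration."""


class MissingAnswerError(DataError):
    """A question was asked to score with no selected answer."""


class IncompleteAssessmentError(WagError):
    """An animal cannot be scored: one or more tree slots are unanswered.

    Carries the unanswerable question ids so callers can log the exclusion,
    as the method requires complete four-question data per animal.
    """

    def __init__(self, animal_id: str, missing: list[str]):
        self.animal_id = animal_id
        self.missing = list(missing)
        super().__init__(
            f"animal {animal_id!r}: no answer for question(s) {', '.join(missing)}"
        )


class EmptyGroupError(WagError):
    """A group-level operation was applied to an empty group."""


# --------------------------------------------------------------------------
# Domain types


class AnswerOption(BaseModel):
    """One selectable answer and its color rank on the traffic-light scale."""

    model_config = ConfigDict(extra="forbid")

    answer_id: str
    label: str = ""
    color: Color
    is_other: bool = False  # free-text option; its color is set per project


class QuestionSpec(BaseModel):
    """One welfare question: options, choice mode, and scoring rule.

    ``score_rule`` is ``lowest`` for every question except the designated
    exceptions (the two nutrition diet/milk questions), for which the best
    selected color wins; a positive indicator there supersedes a poor one.
    """

    model_config = ConfigDict(extra="forbid")

    question_id: str
    text: str = ""
    category: Category
    age_class: AgeClass = "adult"
    choice_mode: Literal["single", "multiple"] = "single"
    score_rule: Literal["lowest", "highest"] = "lowest"
    score_rule_exception: bool = False  # designates a highest-rule question
    replacement_for: Optional[str] = None
    options: list[AnswerOption] = Field(default_factory=list)

    @model_validator(mode="after")
    def _unique_answer_ids(self) -> "QuestionSpec":
        ids = [o.answer_id for o in self.options]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(
                f"question {self.question_id!r}: duplicate answer_id(s) {dupes}"
            )
        return self

    def option(self, answer_id: str) -> AnswerOption:
        for o in self.options:
            if o.answer_id == answer_id:
                return o
        raise DataError(
            f"question {self.question_id!r}: unknown answer_id {answer_id!r}"
        )

    def colors(self) -> set[str]:
        return {o.color for o in self.options}


class CategoryTree(BaseModel):
    """The four-question decision tree for one (category, age class)."""

    model_config = ConfigDict(extra="forbid")

    category: Category
    age_class: AgeClass = "adult"
    primary_questions: list[str]
    #: primary question_id -> fallback question_id, used when the primary
    #: cannot be answered (e.g. the owner is absent).
    replacements: dict[str, str] = Field(default_factory=dict)

    @property
    def key(self) -> tuple[str, str]:
        return (self.category, self.age_class)


class GradeBand(BaseModel):
    """A half-open score interval mapped to a letter grade.

    The band table partitions [0, 100]: A = [90, 100], B = [80, 90), ...,
    J = [0, 10).  Half-open intervals close the gaps the printed integer
    bands would leave at 0 and between adjacent letters.
    """

    model_config = ConfigDict(extra="forbid")

    letter: str
    lower: float
    upper: float

    def contains(self, score: float) -> bool:
        if self.letter == "A":  # top band is closed at 100
            return self.lower <= score <= self.upper
        return self.lower <= score < self.upper


def default_grade_bands() -> list[GradeBand]:
    """A=[90,100], B=[80,90), ..., J=[0,10) — best to worst."""
    return [
        GradeBand(letter=letter, lower=float(90 - 10 * i), upper=float(100 - 10 * i))
        for i, letter in enumerate(GRADE_LETTERS)
    ]


class Thresholds(BaseModel):
    model_config = ConfigDict(extra="forbid")

    group_rule_percent: float = 15.0  # 15% rule for the group grade
    red_flag_percent: float = 15.0  # asterisk when >= this % have a red answer

    @model_validator(mode="after")
    def _in_range(self) -> "Thresholds":
        for name in ("group_rule_percent", "red_flag_percent"):
            v = getattr(self, name)
            if not (0 < v <= 100):
                raise ValueError(f"thresholds.{name} must lie in (0, 100], got {v}")
        return self


class WagConfig(BaseModel):
    """A complete, self-contained WAG scoring configuration."""

    model_config = ConfigDict(extra="forbid")

    questions: list[QuestionSpec] = Field(default_factory=list)
    trees: list[CategoryTree] = Field(default_factory=list)
    score_points: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_SCORE_POINTS)
    )
    grade_bands: list[GradeBand] = Field(default_factory=default_grade_bands)
    thresholds: Thresholds = Field(default_factory=Thresholds)

    @model_validator(mode="after")
    def _points_decreasing(self) -> "WagConfig":
        pts = self.score_points
        missing = {"green", "amber", "red"} - set(pts)
        if missing:
            raise ValueError(f"score_points missing color(s): {sorted(missing)}")
        if not (pts["green"] > pts["amber"] > pts["red"]):
            raise ValueError(
                "score_points must be strictly decreasing green > amber > red, "
                f"got {pts}"
            )
        return self

    # -- lookups ---------------------------------------------------------
    def question(self, question_id: str) -> QuestionSpec:
        for q in self.questions:
            if q.question_id == question_id:
                return q
        raise ConfigError(f"unknown question_id {question_id!r}")

    def has_question(self, question_id: str) -> bool:
        return any(q.question_id == question_id for q in self.questions)

    def tree(self, category: str, age_class: str) -> CategoryTree:
        for t in self.trees:
            if t.category == category and t.age_class == age_class:
                return t
        raise ConfigError(f"no tree configured for ({category}, {age_class})")

    def points_of(self, color: str) -> float:
        return self.score_points[color]


# --------------------------------------------------------------------------
# Validation (guideline checks; violations are returned, never raised)


def _validate_bands(bands: list[GradeBand]) -> list[str]:
    violations: list[str] = []
    if [b.letter for b in bands] != list(GRADE_LETTERS):
        violations.append(
            "grade_bands must list the ten letters A..J in order best to worst"
        )
        return violations
    if bands[0].upper != 100 or bands[-1].lower != 0:
        violations.append("grade_bands must span [0, 100]")
    for hi, lo in zip(bands, bands[1:]):
        if hi.lower != lo.upper:
            violations.append(
                f"grade_bands: gap or overlap between {hi.letter} and {lo.letter}"
            )
        if lo.lower >= lo.upper:
            violations.append(f"grade_band {lo.letter}: lower must be < upper")
    return violations


def validate_config(config: WagConfig) -> list[str]:
    """Check every selection guideline; return human-readable violations.

    An empty list means the configuration is usable end to end: every tree
    has exactly four resolvable primary questions, every question offers at
    least one green and one red option, replacement links stay within the
    same category and age class, and the highest-scoring rule appears only
    on questions designated as exceptions.

    Deterministic and side-effect free.
    """
    violations: list[str] = []

    for q in config.questions:
        colors = q.colors()
        if "green" not in colors or "red" not in colors:
            violations.append(
                f"question {q.question_id!r} must contain at least one 'green' "
                "and one 'red' answer (amber is optional)"
            )
        if q.score_rule == "highest" and not q.score_rule_exception:
            violations.append(
                f"question {q.question_id!r} uses score_rule=highest but is not "
                "flagged as a designated exception question"
            )
        if q.choice_mode == "single" and len(q.options) < 2:
            violations.append(
                f"question {q.question_id!r}: a single-choice question needs "
                "at least two options"
            )

    seen_keys: set[tuple[str, str]] = set()
    for t in config.trees:
        name = f"tree ({t.category}, {t.age_class})"
        if t.key in seen_keys:
            violations.append(f"duplicate {name}")
        seen_keys.add(t.key)
        if len(t.primary_questions) != 4:
            violations.append(
                f"{name} must have exactly 4 primary questions, "
                f"found {len(t.primary_questions)}"
            )
        for qid in t.primary_questions:
            if not config.has_question(qid):
                violations.append(f"{name} references unknown question {qid!r}")
        for primary_id, repl_id in t.replacements.items():
            if primary_id not in t.primary_questions:
                violations.append(
                    f"{name}: replacement target {primary_id!r} is not a "
                    "primary member of the tree"
                )
            if not config.has_question(repl_id):
                violations.append(f"{name} references unknown question {repl_id!r}")
                continue
            if not config.has_question(primary_id):
                continue
            primary = config.question(primary_id)
            repl = config.question(repl_id)
            if (repl.category, repl.age_class) != (
                primary.category,
                primary.age_class,
            ):
                violations.append(
                    f"replacement {repl_id!r} must share category and age class "
                    f"with the question it replaces ({primary_id!r})"
                )

    violations.extend(_validate_bands(config.grade_bands))
    return violations


# --------------------------------------------------------------------------
# Loading / serialization


def load_config(path: str | Path) -> WagConfig:
    """Load and fully validate a WAG configuration from a YAML/JSON file.

    Defaults are applied for ``score_points``, ``grade_bands`` and
    ``thresholds`` when omitted.  Raises :class:`ConfigError` naming the
    offending key or guideline on any parse or validation failure.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:  # YAML errors carry line/column marks
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return parse_config(raw, source=str(path))


def parse_config(raw: dict, source: str = "<dict>") -> WagConfig:
    """Build a validated :class:`WagConfig` from already-parsed data."""
    try:
        config = WagConfig.model_validate(raw)
    except Exception as exc:
        raise ConfigError(f"{source}: {exc}") from exc
    violations = validate_config(config)
    if violations:
        joined = "; ".join(violations)
        raise ConfigError(f"{source}: {joined}")
    return config


def dump_config(config: WagConfig, path: str | Path) -> None:
    """Serialize a configuration back to YAML (round-trips losslessly)."""
    Path(path).write_text(
        yaml.safe_dump(config.model_dump(mode="json"), sort_keys=False)
    )


def default_config_path() -> Path:
    """Path of the shipped default configuration (health + behavior, adult)."""
    return Path(str(resources.files("wag").joinpath("configs/wag_default.yaml")))


def load_default_config() -> WagConfig:
    return load_config(default_config_path())
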