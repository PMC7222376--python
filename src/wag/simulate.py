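"""Synthetic assessment-data generator and its analytic grade oracle.

No public field dataset exists for this kind of assessment, so every
pipeline stage is exercised on simulated assessment tables with controlled
statistical structure.  Per animal and question, a color is drawn from a
per-question (green, amber, red) probability triple, then a concrete
answer of that color is drawn from per-color weights; multi-select
questions may co-select a second answer of the same color; questions go
missing with a configurable probability (falling back to the configured
replacement question when one exists).

Questions are independent by default.  An optional latent per-animal
welfare state (``latent_sd``) tilts all of an animal's color triples up or
down together, emulating the within-animal correlation real field data
would show.

``expected_grade`` is the analytic counterpart: the exact convolution of
the four per-question color distributions into the nine achievable scores
and their letters — an oracle for stochastic tests (valid for the
independent regime, ``latent_sd = 0``).
"""

from __future__ import annotations

import itertools
import math
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .schema import AgeClass, CategoryTree, ConfigError, WagConfig
from .grading import grade_of_score
from .scoring import AssessmentRecord

__all__ = [
    "GroupScenario",
    "SimulationScenario",
    "generate_population",
    "expected_grade",
]

_COLORS = ("green", "amber", "red")
_TILT = {"green": 1.0, "amber": 0.0, "red": -1.0}


class GroupScenario(BaseModel):
    """Generation parameters for one group of animals.

    ``color_probs`` maps each *primary* question id to its
    (p_green, p_amber, p_red) triple.  Replacement questions are generated
    only as fallback when the primary goes missing, reusing the primary's
    triple.  ``answer_weights`` optionally biases the within-color answer
    choice (default uniform over that color's options).
    """

    model_config = ConfigDict(extra="forbid")

    group_attrs: dict[str, str] = Field(default_factory=dict)
    n_animals: int = Field(gt=0)
    age_class: AgeClass = "adult"
    color_probs: dict[str, tuple[float, float, float]]
    answer_weights: dict[str, dict[str, dict[str, float]]] = Field(
        default_factory=dict
    )
    co_select_prob: float = 0.0
    missing_prob: dict[str, float] = Field(default_factory=dict)
    latent_sd: float = 0.0

    @model_validator(mode="after")
    def _probabilities_valid(self) -> "GroupScenario":
        for qid, triple in self.color_probs.items():
            if any(p < 0 or p > 1 for p in triple):
                raise ValueError(f"{qid}: probabilities must lie in [0, 1]")
            if not math.isclose(sum(triple), 1.0, abs_tol=1e-6):
                raise ValueError(
                    f"{qid}: color probabilities sum to {sum(triple)}, not 1"
                )
        if not (0 <= self.co_select_prob <= 1):
            raise ValueError("co_select_prob must lie in [0, 1]")
        for qid, p in self.missing_prob.items():
            if not (0 <= p <= 1):
                raise ValueError(f"missing_prob[{qid}] must lie in [0, 1]")
        if self.latent_sd < 0:
            raise ValueError("latent_sd must be non-negative")
        return self


class SimulationScenario(BaseModel):
    model_config = ConfigDict(extra="forbid")

    groups: list[GroupScenario]
    seed: int = 0


def _tilted(triple: tuple[float, float, float], s: float) -> dict[str, float]:
    """Exponentially tilt a color triple by latent welfare state s."""
    weights = {
        c: p * math.exp(s * _TILT[c]) for c, p in zip(_COLORS, triple)
    }
    z = sum(weights.values())
    return {c: w / z for c, w in weights.items()}


def _check_scenario(group: GroupScenario, config: WagConfig) -> None:
    for qid, triple in group.color_probs.items():
        question = config.question(qid)  # raises ConfigError when unknown
        available = question.colors()
        for color, p in zip(_COLORS, triple):
            if p > 0 and color not in available:
                raise ConfigError(
                    f"scenario gives p_{color} = {p} to question {qid!r}, "
                    f"which has no {color} option"
                )


def _replacement_of(
    qid: str, group: GroupScenario, config: WagConfig
) -> Optional[str]:
    for tree in config.trees:
        if tree.age_class != group.age_class:
            continue
        repl = tree.replacements.get(qid)
        if repl is not None:
            return repl
    return None


def _draw_answers(
    rng: np.random.Generator,
    question_id: str,
    color: str,
    group: GroupScenario,
    config: WagConfig,
) -> set[str]:
    """Draw one answer of the given color, plus an optional co-selection."""
    question = config.question(question_id)
    option_ids = [o.answer_id for o in question.options if o.color == color]
    weights = group.answer_weights.get(question_id, {}).get(color)
    if weights:
        w = np.array([weights.get(a, 0.0) for a in option_ids], dtype=float)
        if w.sum() <= 0:
            raise ConfigError(
                f"answer_weights for ({question_id}, {color}) give no mass "
                "to any option of that color"
            )
        p = w / w.sum()
    else:
        p = np.full(len(option_ids), 1.0 / len(option_ids))
    first = option_ids[int(rng.choice(len(option_ids), p=p))]
    selected = {first}
    # co-select a second answer of the SAME color so the drawn color stays
    # the effective color under both the lowest and highest rules
    if (
        question.choice_mode == "multiple"
        and len(option_ids) > 1
        and group.co_select_prob > 0
        and rng.random() < group.co_select_prob
    ):
        rest = [a for a in option_ids if a != first]
        pr = np.array(
            [p[option_ids.index(a)] for a in rest], dtype=float
        )
        if pr.sum() > 0:
            pr = pr / pr.sum()
            selected.add(rest[int(rng.choice(len(rest), p=pr))])
    return selected


def generate_population(
    scenario: SimulationScenario, config: WagConfig
) -> list[AssessmentRecord]:
    """Generate reproducible assessment records for every scenario group.

    Each animal draws from its own deterministic substream (spawned from
    the scenario seed by group and animal index), so inserting or removing
    animals never perturbs other animals' draws and the same seed always
    yields byte-identical populations.
    """
    records: list[AssessmentRecord] = []
    for gi, group in enumerate(scenario.groups):
        _check_scenario(group, config)
        for ai in range(group.n_animals):
            rng = np.random.default_rng(
                np.random.SeedSequence(scenario.seed, spawn_key=(gi, ai))
            )
            latent = (
                rng.normal(0.0, group.latent_sd) if group.latent_sd > 0 else 0.0
            )
            answers: dict[str, set[str]] = {}
            for qid, triple in group.color_probs.items():
                probs = (
                    _tilted(triple, latent)
                    if group.latent_sd > 0
                    else dict(zip(_COLORS, triple))
                )
                color = _COLORS[
                    int(rng.choice(3, p=[probs[c] for c in _COLORS]))
                ]
                missing = rng.random() < group.missing_prob.get(qid, 0.0)
                if not missing:
                    answers[qid] = _draw_answers(rng, qid, color, group, config)
                    continue
                repl = _replacement_of(qid, group, config)
                if repl is not None:
                    answers[repl] = _draw_answers(rng, repl, color, group, config)
            records.append(
                AssessmentRecord(
                    animal_id=f"g{gi}_a{ai:05d}",
                    age_class=group.age_class,
                    group_attrs=dict(group.group_attrs),
                    answers=answers,
                )
            )
    return records


def expected_grade(
    group: GroupScenario,
    config: WagConfig,
    tree: Optional[CategoryTree] = None,
) -> dict[str, float]:
    """Exact per-letter grade distribution implied by a group scenario.

    Convolves the four per-question color triples over the per-color
    points (3^4 = 81 color tuples) into the distribution over achievable
    scores, then maps scores to letters.  Assumes independent questions
    (``latent_sd = 0``) and no missingness bias: with the replacement
    fallback sharing the primary's triple, the distribution over complete
    assessments is unchanged.
    """
    if tree is None:
        if len(config.trees) != 1:
            raise ValueError("tree must be given when config has several trees")
        tree = config.trees[0]
    triples = []
    for qid in tree.primary_questions:
        if qid not in group.color_probs:
            raise ConfigError(f"scenario has no color_probs for {qid!r}")
        triples.append(group.color_probs[qid])

    result = {letter: 0.0 for letter in "ABCDEFGHIJ"}
    for combo in itertools.product(range(3), repeat=4):
        prob = 1.0
        score = 0.0
        for slot, ci in enumerate(combo):
            prob *= triples[slot][ci]
            score += config.points_of(_COLORS[ci])
        if prob == 0.0:
            continue
        result[grade_of_score(score, config.grade_bands)] += prob
    return result


def expected_red_percent(group: GroupScenario, config: WagConfig,
                         tree: Optional[CategoryTree] = None) -> float:
    """Probability (in %) that an animal gets >= 1 red answer in the tree."""
    if tree is None:
        tree = config.trees[0]
    p_no_red = 1.0
    for qid in tree.primary_questions:
        p_no_red *= 1.0 - group.color_probs[qid][2]
    return 100.0 * (1.0 - p_no_red)
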