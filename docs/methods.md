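# Methods

## The aggregation model

The package aggregates ordinal, color-ranked welfare indicators for
individual equids into group-level letter grades, one per welfare
category (health, behavior, working conditions, living environment,
nutrition) and age class (adult, foal). The model is deliberately simple
and fully traceable:

1. **Category score (Step 1).** Each (category, age class) has a fixed
   decision tree of four questions. Every answer option carries a color —
   green (best), amber, red (worst) — and colors carry points: green = 25,
   amber = 12.5, red = 0 by default (configurable, but required to be
   strictly decreasing). A question's *effective color* is the sole
   answer's color for single-choice questions; for multi-select questions
   it is the worst selected color, except on the two designated nutrition
   questions (main diet; foal milk access) where the best selected color
   wins. Color ordering is defined on the points, not on option list
   position. The four question points sum to a category score in
   {0, 12.5, 25, …, 100} — nine achievable values.
2. **Individual grade (Step 2).** Scores map to letters A–J via half-open
   bands A = [90, 100], B = [80, 90), …, I = [10, 20), J = [0, 10). The
   printed integer bands ("A = 100 to 90 … J = 10 to 1") leave score 0
   unassigned and make adjacent bands meet ambiguously; the half-open
   convention partitions [0, 100] exactly while preserving the letter of
   every printed integer boundary. Of the ten letters only
   {A, B, C, D, E, G, H, I, J} are reachable: no sum of four values from
   {0, 12.5, 25} lands in F's band [40, 50).
3. **Group grade (Step 3, the 15% rule).** Per-letter percentages of the
   group's scored animals are accumulated from J to A; the group grade is
   the first letter whose cumulative share is ≥ the group-rule threshold
   (default 15%, inclusive). Comparisons use exact, unrounded percentages;
   rounding to whole percent is display-only, since rounding before the
   comparison could flip the grade at a boundary.
4. **Red flag (Step 4).** The grade is rendered with an asterisk when the
   share of animals with at least one red effective color in the tree is
   ≥ the red-flag threshold (default 15%, inclusive).

### Key contracts and edge cases

- An animal is scored only if all four tree slots are answerable. A
  configured *replacement question* fills a slot when the primary question
  is unanswered (e.g. the owner-interaction question when no handler is
  present); when both are answered the primary wins. Animals with an
  unanswerable slot are excluded and counted — `aggregate` reports
  `n_excluded` per group, and the pipeline writes an exclusion log, so
  every input animal appears exactly once per category in either the
  scored table or the log.
- Replacement answers are reported under the replacement question's own
  id (in score traces and driver tables), with the substitution recorded
  on the score, rather than being silently folded into the primary.
- Adult and foal animals are graded against their own trees and never
  pooled; records with an unknown age class are rejected at parse time.
- Selected answers outside a question's option list fail loudly
  (`DataError`) instead of being coerced — silent coercion would corrupt
  driver analysis. 'Other' free-text options carry a project-assigned
  color (default amber) and animals using them are flagged on their
  scores.
- Empty groups, and groups whose animals were all excluded, yield an
  explicit "no grade" result, never a default letter.
- Region-level (multi-country) grades and flags are computed from the
  pooled animals of the region, not propagated from country results.

## Driver analysis

Per tree question, the share of animals by effective color; within each
(question, color) stratum, the share of animals selecting each answer of
that color. Breakdowns count *all* selected answers, not only the
score-determining one — overlapping signs on one animal (nasal and eye
discharge, say) must both be visible — so multi-select breakdowns can sum
past 100%. Every table carries its stratum denominator, and per-question
stratum sizes sum to the group size. `co_selection_rate` reports the share
of a stratum selecting both members of a stated answer pair, optionally
restricted to one color stratum. Percentages are computed exactly and
rounded only when rendered.

## Synthetic data generator

No public assessment dataset exists, so `wag.simulate` emulates one. Per
group, per animal and primary question: draw a color from a per-question
(p_green, p_amber, p_red) triple, then a concrete answer of that color
from per-color weights (uniform by default). Multi-select questions may
co-select a second answer of the *same* color with probability
`co_select_prob` — same-color co-selection keeps the drawn color equal to
the effective color, which is what makes the analytic oracle below exact.
Per-question missingness drops the primary answer; when the tree has a
replacement, the replacement is answered instead (from the primary's
triple), otherwise the animal becomes an exclusion downstream.

Randomness: one seed per scenario; each animal draws from its own
substream spawned by (group index, animal index), so populations are
byte-reproducible and growing a group never perturbs existing animals.

Questions are independent by default. Setting `latent_sd > 0` draws a
per-animal welfare state s ~ N(0, latent_sd) and exponentially tilts every
triple (green weight × e^s, red × e^-s, renormalized), inducing the
within-animal correlation across questions that real field data would
show. Tests exercise both regimes.

`expected_grade` is the analytic oracle for the independent regime: the
exact convolution of the four color triples over the points (81 color
tuples) into the nine achievable scores and their letters. Because
missingness is independent of the drawn colors and replacements reuse the
primary's triple, the distribution over *complete* assessments is
unchanged, so the oracle remains valid under missingness.

What the generator does **not** emulate: assessor effects, question
dependence beyond a single scalar latent state, answer-level correlation
structure within a question, temporal change, or realistic disease
co-occurrence. Passing recovery tests therefore demonstrates correctness
of the aggregation arithmetic under the stated sampling model, not
fidelity of any real population's welfare distribution.

## Validation strategy

- Worked desk-scale results are asserted exactly: the (green, green, red,
  amber) example scores 62.5; the two illustrative group distributions
  grade D (cumulative 19%) and C (cumulative 31%) under the 15% rule.
- The group rule is checked against an independent sort-and-scan oracle
  (sort grades worst→best; take the letter of the ⌈0.15 n⌉-th worst
  animal) on 1,000 random groups of ≤ 50 animals.
- Brute-force enumeration of all 3⁴ color tuples pins the nine achievable
  scores and the unreachability of grade F.
- Property tests (hypothesis, derandomized, plus seeded loops over random
  configurations) cover weak monotonicity: downgrading any selected
  answer never raises a category score, and improving any animal's grade
  never worsens the group letter.
- Monte-Carlo recovery: a fixed-seed population of 10,000 animals matches
  `expected_grade` within 3 binomial standard errors per letter. The
  boundary scenarios (all green → `A`; one question always red → every
  animal scores 75, rendering `C*`) are asserted through the full
  pipeline.

Problem sizes in the default test run (10,000-animal recovery, 1,000
oracle groups, 300 random-config monotonicity trials) keep the whole
suite under ~10 s while leaving the Monte-Carlo tolerances meaningful.

## Configuration dialect

One YAML/JSON file holds everything a project versions: `questions`
(options, colors, choice mode, scoring rule, replacement links), `trees`
(four primary question ids per category × age class, plus replacement
mapping), `score_points`, `grade_bands` and `thresholds` — the latter
three defaulted when omitted. `validate_config` returns guideline
violations (each question must offer ≥ 1 green and ≥ 1 red option; exactly
four primary questions per tree; replacements resolve within the same
category and age class; the highest-scoring rule only on designated
exception questions) as a list rather than raising, so authoring tools can
show all problems at once; `load_config` raises on any violation.

The shipped default configuration (packaged as `wag/configs/
wag_default.yaml`, path via `wag.default_config_path()`) carries the
published health and behavior trees for adults. The expert ranking procedure that selected
those questions is a design-time human process and is not modelled; only
its output ships. `wag/configs/wag_extras_synthetic.yaml` provides the
nutrition / working-conditions / living-environment trees with synthetic
placeholder option lists (the real option sheets for those categories are
not bundled); its structure — including the two highest-rule nutrition
questions — is real, and projects should substitute their own protocol
text before field use. One deliberate deviation from the printed health
sheet: nasal and eye discharge are stored as two separate red options of
the illness question (the sheet prints them in one cell) so that driver
analysis can report each sign and their co-occurrence; the color
assignment is unchanged.

## Known limitations

- Grades are ordinal; the package deliberately provides no cross-category
  composite score and no statistical inference on grade differences
  between groups.
- The 15% thresholds are conventions inherited from livestock welfare
  assessment, not fitted quantities; both are configurable.
- The wide CSV dialect relies on `|` as the multi-select delimiter
  (backslash-escapable); exports from other tools may need re-delimiting.
- Free-text 'other' answers must be color-classified in the config before
  scoring; per-record color overrides are not supported.
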