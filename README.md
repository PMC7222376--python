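# wag — Welfare Aggregation and Guidance

`wag` turns questionnaire-based equid welfare assessments (EARS-style:
per-animal 'yes/no' and ordinal questions with answers ranked on a
green / amber / red traffic-light scale) into concise per-category welfare
grades for groups of animals, and then decomposes poor grades into the
questions and answers that drive them. It is written for welfare charities
and researchers who must compare welfare across regions, countries, roles
or time, and decide where to send resources — without collapsing welfare
into a single number.

Five welfare categories are graded independently: health, behavior,
working conditions, living environment and nutrition. The shipped default
configuration carries the published health and behavior question trees for
adult equids; the other trees are configurable per project.

## The aggregation method

For each category and age class, four fixed questions form a decision
tree. Aggregation runs in four steps:

1. **Category score.** Each question's effective color maps to points —
   green = 25, amber = 12.5, red = 0. Multi-select questions score the
   *worst* selected color (a poor-welfare indicator is never outweighed by
   accompanying good ones); the two designated nutrition questions (main
   diet, foal milk access) instead score the *best* selected color. The
   four question points sum to a category score S ∈ {0, 12.5, …, 100}.
   Animals missing any of the four slots (after falling back to a
   configured replacement question) are excluded and counted.
2. **Individual grade.** S maps onto letter bands A (best) to J (worst):
   A = [90, 100], B = [80, 90), …, J = [0, 10).
3. **Group grade (15% rule).** Per-letter percentages are accumulated from
   the worst grade (J) to the best (A); the group grade is the first letter
   at which the cumulative share reaches at least 15%.
4. **Red flag.** The grade is marked with an asterisk (e.g. `D*`) when at
   least 15% of the group's animals received one or more red answers —
   distinguishing uniformly mediocre groups from ones mixing good and very
   poor animals.

Driver analysis then reports, per question, the share of animals by
effective color, and within each (question, color) stratum the share
selecting each specific answer (all selections counted, so multi-select
percentages may exceed 100%), plus co-selection rates for stated answer
pairs.

## Worked example

No public assessment dataset exists, so the bundled generator simulates
one. Two synthetic countries, 300 adult equids each, with per-question
color probabilities chosen so that `norland` has widespread behavioral
problems and `suthmark` mostly mild ones:

```python
import wag

config = wag.load_default_config()
scenario = wag.SimulationScenario(
    seed=11,
    groups=[
        {"group_attrs": {"country": "norland"}, "n_animals": 300,
         "color_probs": {
             "general_attitude": (0.55, 0.00, 0.45),
             "fear_distress": (0.70, 0.05, 0.25),
             "harmful_practices": (0.40, 0.00, 0.60),
             "owner_interaction": (0.45, 0.35, 0.20)},
         "co_select_prob": 0.3},
        {"group_attrs": {"country": "suthmark"}, "n_animals": 300,
         "color_probs": {
             "general_attitude": (0.90, 0.00, 0.10),
             "fear_distress": (0.95, 0.02, 0.03),
             "harmful_practices": (0.92, 0.00, 0.08),
             "owner_interaction": (0.80, 0.15, 0.05)}},
    ],
)
records = wag.generate_population(scenario, config)
for g in wag.aggregate(records, config, ["country"]):
    if g.category == "behavior":
        print(f"{g.group_key['country']:>9}: behavior = {g.render():3} "
              f"(n = {g.n_animals}, red answers in {g.red_percent:.0f}% of animals)")
```

prints

```
  norland: behavior = H*  (n = 300, red answers in 88% of animals)
 suthmark: behavior = C*  (n = 300, red answers in 20% of animals)
```

`norland` grades H with an asterisk: at least 15% of its animals sit at
grade H or worse, and 88% carry at least one red answer. Asking *why*:

```python
tree = config.tree("behavior", "adult")
worst = [r for r in records if r.group_attrs["country"] == "norland"]
print(wag.color_frequencies(worst, tree, config).round(0))
```

```
                   green  amber   red    n
question_id
general_attitude    54.0    0.0  46.0  300
fear_distress       71.0    5.0  24.0  300
harmful_practices   37.0    0.0  63.0  300
owner_interaction   44.0   31.0  25.0  300
```

so harmful practices (63% red) and general attitude (46% red) are the main
drivers; `wag.answer_breakdown(worst, config.question("fear_distress"),
"red")` then splits the 72 red fear/distress responders by specific sign
(startle responses 26%, trembling 25%, whites of the eyes 24%, …), and
`wag.co_selection_rate` reports how often two signs co-occur.

The same pipeline runs from the shell:

```bash
wag validate                               # check a config against the guidelines
wag simulate scenario.yaml --out sim.csv   # scenario file -> assessment CSV
wag score sim.csv                          # per-animal scores and letters
wag aggregate sim.csv --group-by country --out results/
wag drivers sim.csv --group-by country
```

`wag aggregate` writes `animal_scores.csv`, `group_grades.csv`,
`driver_colors.csv`, `driver_breakdowns.csv`, `exclusions.csv` and a
markdown report.

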