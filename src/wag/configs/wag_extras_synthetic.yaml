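# SYNTHETIC placeholder configuration for the nutrition, working-conditions
# and living-environment trees.  The published question sheet for these
# categories is not bundled here; the option lists below are synthetic
# stand-ins to be replaced with a project's real protocol before field use.
# The structure is real: four questions per tree, and the two designated
# diet/milk nutrition questions use the highest-scoring-answer rule (a
# positive nutrition indicator supersedes a poor one).

questions:
  # ---- nutrition (adult) -------------------------------------------------
  - question_id: main_diet
    text: "Describe the main diet of the equid"
    category: nutrition
    age_class: adult
    choice_mode: multiple
    score_rule: highest
    score_rule_exception: true
    options:
      - {answer_id: forage_adlib, label: "ad-lib forage", color: green}
      - {answer_id: restricted_forage, label: "restricted forage", color: amber}
      - {answer_id: scraps_only, label: "household scraps only", color: red}
  - question_id: body_condition
    text: "Body condition score band"
    category: nutrition
    age_class: adult
    choice_mode: single
    options:
      - {answer_id: ideal, label: "ideal", color: green}
      - {answer_id: thin_or_fat, label: "thin or overweight", color: amber}
      - {answer_id: emaciated_obese, label: "emaciated or obese", color: red}
  - question_id: water_access
    text: "Does the equid have access to clean water?"
    category: nutrition
    age_class: adult
    choice_mode: single
    options:
      - {answer_id: "yes", label: "yes", color: green}
      - {answer_id: limited, label: "limited", color: amber}
      - {answer_id: "no", label: "no", color: red}
  - question_id: feeding_frequency
    text: "How often is the equid fed?"
    category: nutrition
    age_class: adult
    choice_mode: single
    options:
      - {answer_id: adlib, label: "continuous access", color: green}
      - {answer_id: daily, label: "once daily", color: amber}
      - {answer_id: irregular, label: "irregularly", color: red}

  # ---- nutrition (foal) --------------------------------------------------
  - question_id: foal_milk_access
    text: "Describe the foal's access to milk"
    category: nutrition
    age_class: foal
    choice_mode: multiple
    score_rule: highest
    score_rule_exception: true
    options:
      - {answer_id: dam_adlib, label: "suckling dam freely", color: green}
      - {answer_id: supplemented, label: "milk replacer", color: amber}
      - {answer_id: none, label: "no milk access", color: red}
  - question_id: foal_body_condition
    text: "Foal body condition"
    category: nutrition
    age_class: foal
    choice_mode: single
    options:
      - {answer_id: ideal, label: "ideal", color: green}
      - {answer_id: thin, label: "thin", color: amber}
      - {answer_id: emaciated, label: "emaciated", color: red}
  - question_id: foal_water_access
    text: "Does the foal have access to clean water?"
    category: nutrition
    age_class: foal
    choice_mode: single
    options:
      - {answer_id: "yes", label: "yes", color: green}
      - {answer_id: "no", label: "no", color: red}
  - question_id: foal_creep_feed
    text: "Is suitable creep feed available?"
    category: nutrition
    age_class: foal
    choice_mode: single
    options:
      - {answer_id: "yes", label: "yes", color: green}
      - {answer_id: unsuitable, label: "unsuitable feed", color: amber}
      - {answer_id: "no", label: "no", color: red}

  # ---- working conditions (adult) ----------------------------------------
  - question_id: workload
    text: "Is the workload appropriate for the equid?"
    category: working_conditions
    age_class: adult
    choice_mode: single
    options:
      - {answer_id: appropriate, label: "appropriate", color: green}
      - {answer_id: heavy, label: "heavy", color: amber}
      - {answer_id: excessive, label: "excessive", color: red}
  - question_id: harness_fit
    text: "Is the harness or tack well fitted?"
    category: working_conditions
    age_class: adult
    choice_mode: single
    options:
      - {answer_id: well_fitted, label: "well fitted", color: green}
      - {answer_id: poorly_fitted, label: "poorly fitted", color: amber}
      - {answer_id: causing_injury, label: "causing injury", color: red}
  # rest_breaks stands in when no harness is worn and harness_fit is
  # unanswerable
  - question_id: rest_breaks
    text: "Does the equid receive rest breaks during work?"
    category: working_conditions
    age_class: adult
    choice_mode: single
    replacement_for: harness_fit
    options:
      - {answer_id: regular, label: "regular breaks", color: green}
      - {answer_id: occasional, label: "occasional breaks", color: amber}
      - {answer_id: none, label: "no breaks", color: red}
  - question_id: work_surface
    text: "What surface does the equid work on?"
    category: working_conditions
    age_class: adult
    choice_mode: single
    options:
      - {answer_id: suitable, label: "suitable surface", color: green}
      - {answer_id: hard, label: "hard or uneven", color: amber}
      - {answer_id: hazardous, label: "hazardous", color: red}
  - question_id: working_hours
    text: "How many hours does the equid work per day?"
    category: working_conditions
    age_class: adult
    choice_mode: single
    options:
      - {answer_id: under_6, label: "under 6 hours", color: green}
      - {answer_id: six_to_nine, label: "6-9 hours", color: amber}
      - {answer_id: over_9, label: "over 9 hours", color: red}

  # ---- living environment (adult) ----------------------------------------
  - question_id: shelter_access
    text: "Does the equid have access to shelter?"
    category: living_environment
    age_class: adult
    choice_mode: single
    options:
      - {answer_id: "yes", label: "yes", color: green}
      - {answer_id: partial, label: "partial", color: amber}
      - {answer_id: "no", label: "no", color: red}
  - question_id: space_allowance
    text: "Is the living space adequate?"
    category: living_environment
    age_class: adult
    choice_mode: single
    options:
      - {answer_id: adequate, label: "adequate", color: green}
      - {answer_id: restricted, label: "restricted", color: amber}
      - {answer_id: severely_confined, label: "severely confined", color: red}
  - question_id: bedding_ground
    text: "Condition of bedding or ground"
    category: living_environment
    age_class: adult
    choice_mode: single
    options:
      - {answer_id: clean_dry, label: "clean and dry", color: green}
      - {answer_id: damp, label: "damp or soiled", color: amber}
      - {answer_id: waterlogged, label: "waterlogged or hazardous", color: red}
  - question_id: environment_hazards
    text: "Are hazards present in the living environment?"
    category: living_environment
    age_class: adult
    choice_mode: multiple
    options:
      - {answer_id: none, label: "no hazards", color: green}
      - {answer_id: minor, label: "minor hazards", color: amber}
      - {answer_id: sharp_objects, label: "sharp objects or wire", color: red}
      - {answer_id: toxic_plants, label: "toxic plants or waste", color: red}

trees:
  - category: nutrition
    age_class: adult
    primary_questions: [main_diet, body_condition, water_access, feeding_frequency]
  - category: nutrition
    age_class: foal
    primary_questions:
      [foal_milk_access, foal_body_condition, foal_water_access, foal_creep_feed]
  - category: working_conditions
    age_class: adult
    primary_questions: [workload, harness_fit, work_surface, working_hours]
    replacements:
      harness_fit: rest_breaks
  - category: living_environment
    age_class: adult
    primary_questions:
      [shelter_access, space_allowance, bedding_ground, environment_hazards]
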