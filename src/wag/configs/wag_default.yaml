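# Default WAG configuration: the health and behavior decision trees for
# adult equids, with the published traffic-light color assignments.
#
# The "obvious signs of illness" question stores nasal and eye discharge as
# separate options (both red) so that driver analysis can report each sign
# and their co-occurrence; the printed question sheet groups them in one
# cell with the same color.
#
# 'Other' free-text options carry a project-assigned color, defaulting to
# amber (a free-text answer is evidence of something noteworthy but not
# automatically of the worst kind).

score_points: {green: 25, amber: 12.5, red: 0}

thresholds:
  group_rule_percent: 15
  red_flag_percent: 15

questions:
  # ---- health (adult) ----------------------------------------------------
  - question_id: skin_alterations
    text: "Are there any signs of skin system alterations?"
    category: health
    age_class: adult
    choice_mode: multiple
    options:
      - {answer_id: none, label: "no", color: green}
      - {answer_id: scars, label: "Scars", color: amber}
      - {answer_id: alopecia, label: "Alopecia", color: amber}
      - {answer_id: swellings, label: "Swellings", color: amber}
      - {answer_id: open_wounds, label: "Open wounds", color: red}
      - {answer_id: sarcoids, label: "Sarcoids", color: red}
      - {answer_id: other, label: "Other", color: amber, is_other: true}

  - question_id: lameness
    text: "Is the equid lame?"
    category: health
    age_class: adult
    choice_mode: single
    options:
      - {answer_id: no_lameness, label: "no lameness", color: green}
      - answer_id: lame
        label: "yes (intermittently or consistently lame)"
        color: amber
      - answer_id: non_weight_bearing
        label: "yes, non-weight bearing"
        color: red
      - answer_id: severely_lame
        label: "severely lame/unable to walk"
        color: red

  - question_id: illness_signs
    text: "Please indicate obvious signs of illness"
    category: health
    age_class: adult
    choice_mode: multiple
    options:
      - {answer_id: no_signs, label: "no signs present", color: green}
      - {answer_id: nasal_discharge, label: "nasal discharge", color: red}
      - {answer_id: eye_discharge, label: "eye discharge", color: red}
      - {answer_id: diarrhea, label: "signs of diarrhea", color: red}
      - answer_id: genital_discharge
        label: "significant discharge from penis or vulva"
        color: red
      - {answer_id: abdominal_pain, label: "abdominal pain", color: red}
      - {answer_id: other, label: "Other", color: amber, is_other: true}

  - question_id: coat_healthy
    text: "Is the equid's coat healthy?"
    category: health
    age_class: adult
    choice_mode: single
    options:
      - {answer_id: "yes", label: "Yes", color: green}
      - {answer_id: "no", label: "no", color: red}

  # ---- behavior (adult) --------------------------------------------------
  - question_id: general_attitude
    text: "General attitude of the equid at a distance?"
    category: behavior
    age_class: adult
    choice_mode: single
    options:
      - answer_id: at_ease
        label: "at ease-relaxed, calm and/or resting"
        color: green
      - answer_id: alert_interested
        label: "alert and actively interested in surroundings"
        color: green
      - answer_id: apathetic
        label: "apathetic, depressed, withdrawn"
        color: red
      - answer_id: agitated
        label: "agitated, aggressive, hyper-reactive/vigilant"
        color: red
      - {answer_id: other, label: "Other", color: amber, is_other: true}

  - question_id: fear_distress
    text: "Please indicate signs of fear and distress present"
    category: behavior
    age_class: adult
    choice_mode: multiple
    options:
      - answer_id: no_signs
        label: "no signs of fear and distress present"
        color: green
      - answer_id: whites_of_eyes
        label: "showing the whites of the eyes"
        color: red
      - answer_id: sudden_movements
        label: "unpredictable or sudden movements"
        color: red
      - answer_id: startle_responses
        label: "sudden startle responses"
        color: red
      - {answer_id: aggressive_behavior, label: "aggressive behavior", color: red}
      - {answer_id: trembling, label: "trembling", color: red}
      - {answer_id: head_shyness, label: "head shyness", color: red}
      - answer_id: withdrawn_shut_down
        label: "completely withdrawn/shut down"
        color: red
      - {answer_id: other, label: "Other", color: amber, is_other: true}

  - question_id: harmful_practices
    text: "Presence of signs of harmful practices?"
    category: behavior
    age_class: adult
    choice_mode: multiple
    options:
      - {answer_id: none, label: "no", color: green}
      - {answer_id: hot_brand_firing, label: "signs of hot brand, firing", color: red}
      - answer_id: limb_tethering
        label: "limb tethering or hobbling"
        color: red
      - answer_id: amputations
        label: "amputations or mutilations"
        color: red
      - answer_id: live_serreta
        label: "use of live serreta or similar"
        color: red
      - {answer_id: other, label: "Other", color: amber, is_other: true}

  - question_id: owner_interaction
    text: "Owner's/user's/handler's interaction when holding the equid?"
    category: behavior
    age_class: adult
    choice_mode: single
    options:
      - answer_id: relaxed_confident
        label: "relaxed and confident"
        color: green
      - answer_id: assertive_indifferent
        label: "assertive/indifferent"
        color: amber
      - {answer_id: cautious_fearful, label: "cautious/fearful", color: amber}
      - {answer_id: aggressive, label: "aggressive", color: red}
      - {answer_id: other, label: "Other", color: amber, is_other: true}

  # fallback for owner_interaction when no handler is present
  - question_id: with_other_animals
    text: "Is the equid with other animal(s)?"
    category: behavior
    age_class: adult
    choice_mode: single
    replacement_for: owner_interaction
    options:
      - answer_id: yes_physical_contact
        label: "yes, physical contact"
        color: green
      - answer_id: yes_visual_contact
        label: "yes, visual contact"
        color: amber
      - {answer_id: no_contact, label: "no", color: red}

trees:
  - category: health
    age_class: adult
    primary_questions: [skin_alterations, lameness, illness_signs, coat_healthy]
  - category: behavior
    age_class: adult
    primary_questions:
      [general_attitude, fear_distress, harmful_practices, owner_interaction]
    replacements:
      owner_interaction: with_other_animals
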