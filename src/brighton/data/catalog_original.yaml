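# Brighton Collaboration anaphylaxis case definition — original logical
# translation (negation-bearing minor criteria, compound terms as single
# expressions, Level-3 "other systems" excluding both cardiovascular and
# respiratory).  The catalog is data, not code, so corrections against the
# source case definition need no reprogramming.
variant: original
systems: [dermatologic_mucosal, cardiovascular, respiratory, gastrointestinal, laboratory]
temporal_atoms: [sudden_onset, rapid_progression]
atoms:
  sudden_onset: Sudden onset of signs and symptoms
  rapid_progression: Rapid progression of signs and symptoms
  generalized_urticaria: Generalized urticaria (hives)
  generalized_erythema: Generalized erythema
  angioedema: Angioedema (localized or generalized)
  generalized_pruritus: Generalized pruritus
  skin_rash: Skin rash
  generalized_prickle_sensation: Generalized prickle sensation
  localized_injection_site_urticaria: Localized injection-site urticaria
  red_itchy_eyes: Red and itchy eyes
  measured_hypotension: Measured hypotension
  tachycardia: Tachycardia
  capillary_refill_gt3s: Capillary refill time > 3 s
  reduced_central_pulse_volume: Reduced central pulse volume
  decreased_consciousness: Decreased or loss of consciousness
  bilateral_wheeze: Bilateral wheeze (bronchospasm)
  stridor: Stridor
  upper_airway_swelling: Upper airway swelling (lip, tongue, throat, uvula, larynx)
  tachypnoea: Tachypnoea
  accessory_muscle_use: Increased use of accessory respiratory muscles
  chest_wall_recession: Chest wall recession
  cyanosis: Cyanosis
  grunting: Grunting
  persistent_dry_cough: Persistent dry cough
  hoarse_voice: Hoarse voice
  difficulty_breathing: Difficulty breathing
  sensation_of_throat_closure: Sensation of throat closure
  sneezing_rhinorrhea: Sneezing or rhinorrhea
  diarrhea: Diarrhea
  abdominal_pain: Abdominal pain
  nausea: Nausea
  vomiting: Vomiting
  elevated_mast_cell_tryptase: Elevated mast-cell tryptase
criteria:
  - id: derm_major_urticaria_or_erythema
    system: dermatologic_mucosal
    weight: major
    expr: [or, [atom, generalized_urticaria], [atom, generalized_erythema]]
  - id: derm_major_angioedema
    system: dermatologic_mucosal
    weight: major
    expr: [atom, angioedema]
  - id: derm_major_pruritus_with_rash
    system: dermatologic_mucosal
    weight: major
    expr: [and, [atom, generalized_pruritus], [atom, skin_rash]]
  - id: derm_minor_pruritus_without_rash
    system: dermatologic_mucosal
    weight: minor
    expr: [and, [atom, generalized_pruritus], [not, [atom, skin_rash]]]
  - id: derm_minor_prickle_sensation
    system: dermatologic_mucosal
    weight: minor
    expr: [atom, generalized_prickle_sensation]
  - id: derm_minor_injection_site_urticaria
    system: dermatologic_mucosal
    weight: minor
    expr: [atom, localized_injection_site_urticaria]
  - id: derm_minor_red_itchy_eyes
    system: dermatologic_mucosal
    weight: minor
    expr: [atom, red_itchy_eyes]
  - id: cardio_major_measured_hypotension
    system: cardiovascular
    weight: major
    expr: [atom, measured_hypotension]
  - id: cardio_major_uncompensated_shock
    system: cardiovascular
    weight: major
    expr:
      - at_least
      - 3
      - [atom, tachycardia]
      - [atom, capillary_refill_gt3s]
      - [atom, reduced_central_pulse_volume]
      - [atom, decreased_consciousness]
  - id: cardio_minor_reduced_peripheral_circulation
    system: cardiovascular
    weight: minor
    expr:
      - at_least
      - 2
      - [atom, tachycardia]
      - [and, [atom, capillary_refill_gt3s], [not, [atom, measured_hypotension]]]
      - [atom, reduced_central_pulse_volume]
      - [atom, decreased_consciousness]
  - id: resp_major_bilateral_wheeze
    system: respiratory
    weight: major
    expr: [atom, bilateral_wheeze]
  - id: resp_major_stridor
    system: respiratory
    weight: major
    expr: [atom, stridor]
  - id: resp_major_upper_airway_swelling
    system: respiratory
    weight: major
    expr: [atom, upper_airway_swelling]
  - id: resp_major_respiratory_distress
    system: respiratory
    weight: major
    expr:
      - at_least
      - 2
      - [atom, tachypnoea]
      - [atom, accessory_muscle_use]
      - [atom, chest_wall_recession]
      - [atom, cyanosis]
      - [atom, grunting]
  - id: resp_minor_persistent_dry_cough
    system: respiratory
    weight: minor
    expr: [atom, persistent_dry_cough]
  - id: resp_minor_hoarse_voice
    system: respiratory
    weight: minor
    expr: [atom, hoarse_voice]
  - id: resp_minor_difficulty_breathing_no_wheeze_stridor
    system: respiratory
    weight: minor
    expr:
      - and
      - [atom, difficulty_breathing]
      - [not, [atom, bilateral_wheeze]]
      - [not, [atom, stridor]]
  - id: resp_minor_throat_closure
    system: respiratory
    weight: minor
    expr: [atom, sensation_of_throat_closure]
  - id: resp_minor_sneezing_rhinorrhea
    system: respiratory
    weight: minor
    expr: [atom, sneezing_rhinorrhea]
  - id: gi_minor_diarrhea
    system: gastrointestinal
    weight: minor
    expr: [atom, diarrhea]
  - id: gi_minor_abdominal_pain
    system: gastrointestinal
    weight: minor
    expr: [atom, abdominal_pain]
  - id: gi_minor_nausea
    system: gastrointestinal
    weight: minor
    expr: [atom, nausea]
  - id: gi_minor_vomiting
    system: gastrointestinal
    weight: minor
    expr: [atom, vomiting]
  - id: lab_minor_elevated_tryptase
    system: laboratory
    weight: minor
    expr: [atom, elevated_mast_cell_tryptase]
level_rules:
  # Level 1: >=1 major dermatologic AND (>=1 major cardiovascular OR
  # >=1 major respiratory).
  1:
    - and
    - [major_ge, dermatologic_mucosal, 1]
    - [or, [major_ge, cardiovascular, 1], [major_ge, respiratory, 1]]
  # Level 2: both non-dermatologic majors, or one of them plus a minor
  # from another system, or a dermatologic major plus a cardiovascular or
  # respiratory minor.
  2:
    - or
    - [and, [major_ge, cardiovascular, 1], [major_ge, respiratory, 1]]
    - - and
      - [or, [major_ge, cardiovascular, 1], [major_ge, respiratory, 1]]
      - - or
        - [and, [major_ge, cardiovascular, 1], [systems_with_minor_ge, [cardiovascular], 1]]
        - [and, [major_ge, respiratory, 1], [systems_with_minor_ge, [respiratory], 1]]
    - - and
      - [major_ge, dermatologic_mucosal, 1]
      - [or, [minor_ge, cardiovascular, 1], [minor_ge, respiratory, 1]]
  # Level 3: >=1 minor cardiovascular or respiratory criterion AND >=1
  # minor criterion from each of >=2 systems that are neither
  # cardiovascular nor respiratory (this catalog's reading).
  3:
    - and
    - [or, [minor_ge, cardiovascular, 1], [minor_ge, respiratory, 1]]
    - [systems_with_minor_ge, [cardiovascular, respiratory], 2]
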