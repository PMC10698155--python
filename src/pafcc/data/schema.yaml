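# Data dictionary for subject-level case-control CSVs.
# Maps CSV column name -> record field.  The default is the identity
# mapping; rename keys to adapt a differently-headed CSV.
#
# Coding conventions:
#   status: case | control
#   sex: male | female
#   tri-state exposures/features: yes | no | (empty = missing)
#   family_history: positive | negative | unknown | (empty = missing)
#   ages in years; calendar years as 4-digit integers; empty cell = missing.
columns:
  subject_id: subject_id            # opaque unique identifier
  status: status                    # disease status
  sex: sex
  age_years: age_years              # age at survey
  onset_age_years: onset_age_years  # cases only; <= age_years
  survey_year: survey_year          # used to reconstruct calendar years from ages
  onset_year: onset_year            # cases only; overrides age-based reconstruction
  family_history: family_history    # >=1 first/second-degree relative affected
  mtbi_event: mtbi_event            # head injury with concussion/hospitalization
  mtbi_event_year: mtbi_event_year
  repeated_blows_head: repeated_blows_head  # sports/combat, sub-clinical
  pesticide_exposure: pesticide_exposure
  pesticide_start_year: pesticide_start_year
  pesticide_duration_years: pesticide_duration_years  # only if exposed
  military_chemical_exposure: military_chemical_exposure
  constipation: constipation
  rbd: rbd                          # REM sleep behavior disorder
  weight_loss: weight_loss
  ethnicity_hispanic: ethnicity_hispanic
  race: race
  spousal_pair_id: spousal_pair_id  # links one case to one control
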