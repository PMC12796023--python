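# Synthetic EHR bundle: file and column schemas

All tables are CSV with a header row; notes are JSON Lines (one object
per note). Dates are ISO `YYYY-MM-DD`, timestamps ISO-8601.

## demographics.csv
| column | meaning |
|---|---|
| patient_id | unique patient key (`P#####`) |
| age | age in years at admission |
| sex | Male / Female |
| race | seven-level category |
| ethnicity | three-level category |
| insurance | Medicare / Medicaid / Private / Self-Pay |
| adi_state_rank | area deprivation index, state rank 1–10 |
| adi_national_rank | area deprivation index, national rank 1–100 |
| height_m, weight_kg | for BMI; empty when BMI is unknown |
| sepsis_score | passthrough integer severity input; empty when N/A |
| admission_date | hospital admission date |

## vitals.csv
patient_id, timestamp, measure (`sbp` mmHg, `heart_rate` beats/min), value.

## labs.csv
Long-format SOFA component observations: patient_id, date, measure,
value. Measures: `pao2_fio2` (mmHg ratio), `resp_support` (0/1),
`platelets` (10^3/uL), `bilirubin` (mg/dL), `map` (mmHg),
`vasopressor_<drug>` (ug/kg/min), `gcs` (3–15), `creatinine` (mg/dL),
`urine_output` (mL/day).

## icd.csv
patient_id, icd_code (ICD-10, may carry dots).

## events.csv
patient_id, event (`iv_fluid_bolus`, `arterial_line`,
`central_venous_catheter`, `continuous_renal_replacement`,
`cardiac_catheterization`, `interventional_radiology`), timestamp.

## outcomes.csv
patient_id, in_hospital_death (0/1), icu_death (0/1),
discharge_disposition (six-level category).

## notes.jsonl
Fields per record: note_id, patient_id, clinician_id, clinician_type,
specialty, note_type (`history_and_physical` / `progress` / `consult`),
timestamp, text.

## truth.json
Ground-truth ledger: `patients` maps patient_id to {eligible,
exclusion_kind, never_agreement, onset_day, died, n_clinicians,
base_vector}; `note_vectors` maps note_id to the planted 9-dimensional
binary etiology vector (canonical order: septic, cardiogenic,
hypovolemic, adrenal, neurogenic, undifferentiated, obstructive,
anaphylactic, post_procedural).
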