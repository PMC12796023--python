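# Methods

## Agreement model

Each clinician note is reduced to a 9-dimensional binary vector over a
fixed etiology order (septic, cardiogenic, hypovolemic, adrenal,
neurogenic, undifferentiated, obstructive, anaphylactic,
post-procedural). A dimension is 1 when the note carries at least one
non-negated lexicon term for that etiology; repeat or overlapping
mentions of distinct etiologies each set their own bit ("mixed septic
and cardiogenic shock" sets two). Ambiguous phrases ("distributive
shock", "shock of unclear etiology") are lexicon aliases of the
undifferentiated dimension.

Within a patient-day, one clinician's notes are merged by set union
into a single daily diagnosis vector. This makes "each clinician
compared to every other clinician" well defined and removes self-pairs;
the alternative reading — scoring every cross-clinician *note* pair —
is implemented behind `daily_agreement_table(mode="note_pairs")` for
sensitivity analysis and changes nothing qualitatively on synthetic
data.

Pairwise agreement is cosine similarity, for binary vectors
|u∩v| / √(|u|·|v|) ∈ [0,1]. Zero vectors (a note documenting "shock"
with no etiology term) are excluded from pairing rather than scored as
disagreement — cosine is undefined at zero — and are tallied in QC. The
daily score is the unweighted mean over all pairs; days with fewer than
two nonzero clinician vectors are undefined and skipped (not
zero-filled). A patient "ever agrees" at threshold τ when the maximum
defined daily mean over study days 0–4 reaches τ − 1e−9 (float guard);
the primary outcome is never-agreement at τ = 1.0, with τ = 0.95 and
0.90 as sensitivity labels. Never-agreement rates are monotone
non-increasing as τ relaxes, by construction.

## Cohort definition

Day 0 is the earliest calendar day with (a) any systolic blood pressure
reading strictly below 90 mmHg and (b) a SOFA total strictly above the
last previously recorded total. When no prior SOFA exists the baseline
is taken as 0, so admission-day shock is detectable; these patients are
flagged in QC. Calendar days, not rolling 24-hour windows, define the
study window (days 0–4 inclusive, five days; the day count is surfaced
as `cohort.STUDY_DAYS`). Eligibility further requires a shock-word note
on day 0 from an allow-listed note type (history & physical, progress,
consult), not all etiology mentions negated across the window, two or
more *distinct* clinicians with shock notes on at least one single
study day (same-clinician note pairs can never establish
inter-clinician agreement), and age ≥ 18. Excluded patients receive
exactly one terminal reason, the first failing rule in the order:
no-structured-shock, no-shock-note-day0, negation-only-notes,
fewer-than-two-clinician-notes, under-18.

## Note NLP

Matching is literal, case-insensitive, on word boundaries; within an
etiology the longest term wins ("septic shock" is one mention). There
is no stemming, abbreviation expansion, section segmentation or
copy-forward handling. Negation is a NegEx-style pre-trigger rule: a
mention is negated when a trigger ("no", "without", "ruled out",
"no evidence of", ...) lies within a 6-token window before it with no
scope terminator (sentence punctuation, "but", "however") in between;
pseudo-triggers ("cannot rule out") are checked first and suppress the
triggers they contain. Trigger lists, pseudo-triggers, the window and
the lexicon ship as editable YAML (`data/lexicon.yaml`,
`data/negation.yaml`). "Sepsis" alone, without the word "shock", sets
the septic dimension — the lexicon is taken at face value.

## Severity scores

SOFA uses the canonical six-organ threshold table (stored data-driven
in `severity.SOFA_THRESHOLDS`): respiration caps at 2 without
respiratory support; cardiovascular uses the vasopressor dose ladder;
renal takes the worse of creatinine and urine-output criteria. A
missing component scores 0 and is flagged; a patient-day with all six
components missing maps to the "No SOFA score" band. Bands are 0–6,
7–12, 13–15, 16–24.

The Elixhauser index defaults to an unweighted count of distinct
comorbidity categories matched by a bundled 31-category ICD-10 prefix
map (a prefix-level adaptation of the Quan coding algorithm); weights
are editable in `data/elixhauser_icd10.yaml`. Printed overlapping band
edges are resolved left-closed/right-open: Elixhauser 0–4 / 5–6 / 7–10 /
≥ 11 (displayed with the conventional labels "0–5" etc.); shock index
< 0.5 / [0.5, 0.7) / [0.7, 1.0] / > 1.0, where 1.0 sits in the third
band; time-to-event hours [0,24) / [24,48) / [48,72) / [72,96) / ≥ 96.
Every binning scheme is total over finite inputs, with an explicit
"Unknown"/"N/A" label for missing values. The "sepsis score" is a
passthrough integer input, binned but never computed.

## Synthetic data generator

The generator emulates the study conditions, not clinical language: it
is the test bed for every downstream stage, with a ground-truth ledger
of planted note vectors, patient labels and outcomes.

Defaults (all `SimulationConfig` fields, one seeded generator, no
global state):

- **Never-agreement rate** 0.182; labels drawn per patient, then
  *planted mechanistically*: a designated dissenting clinician
  documents one extra (or, if all nine are present, one fewer) etiology
  and co-writes on every study day any colleague writes, so every
  defined daily mean sits strictly below 1 and the label emerges from
  the agreement module. For agreement patients all clinicians share one
  vector.
- **Clinicians per patient**: mean 4.85, SD 2.7, support ≥ 2, realised
  as a *shifted* negative binomial on {2, 3, ...} with moments matched
  exactly (truncating a negative binomial at 2 would bias the mean up
  by ~0.25 and break the moment checks; shifting keeps them exact).
- **Etiology prevalences** (multi-label, per patient): septic 0.646,
  cardiogenic 0.232, hypovolemic 0.126, adrenal 0.075, obstructive
  0.090, undifferentiated 0.023, anaphylactic 0.006, neurogenic 0.004,
  post-procedural 0.0005; an empty draw defaults to septic.
- **Notes**: one note per clinician per study day written (day 0 always
  has ≥ 2 writers; other days join with probability 0.15–0.25); 25% of
  notes carry a negated distractor mention, 5% are etiology-free
  "shock" notes (never the day-0 anchors or the dissenter, so planted
  labels stay exact even with zero-vector noise). A stress mode
  (`multi_note_per_clinician_day`) emits occasional same-clinician
  duplicates; the per-day multiplicity distribution is a free choice
  (30% chance of a second note) since no empirical distribution is
  available.
- **Structured data**: one sub-90 systolic reading on the planted onset
  day (admission + offset drawn from {0:0.4, 1:0.3, 2:0.2, 3:0.1});
  SOFA component panels are planted by inverting the threshold table so
  the day-0 total lands in a target band (band mixture shifted toward
  higher severity for never-agreement patients), with a lower baseline
  the day before and a day-4 panel that improves with probability 0.419
  (agreement) vs 0.347 (never-agreement). ICD codes hit a planted
  number of comorbidity categories with the same label shift. The
  "No SOFA score" stratum is not planted for eligible patients: onset
  detection requires a scored day 0, so a no-score eligible patient
  would be self-contradictory; the band itself is exercised in unit
  tests.
- **Outcomes**: in-hospital death with baseline probability 0.276 and a
  disagreement odds ratio of 1.86 (≈ 41.5% vs 27.6%).
- **Ineligible patients** (5%) are planted across the five exclusion
  kinds so every exclusion path is exercised and recoverable from the
  ledger.

What passing tests on this generator do *not* show: robustness to real
clinical language (abbreviations, section headers, copy-forward
duplication, misspellings), to irregular note timing, to ICD coding
incompleteness, or to confounding structures absent from the planted
feature–label model. The round-trip guarantee (extraction reproduces
every planted vector exactly, verified exhaustively over all 512
vectors and on 1000 mixed rendered notes) is a property of the
template–lexicon pair, not of free text.

## Descriptive statistics

Chi-squared tests of independence without continuity correction are the
default (a Yates flag exists); 2×2 tables with any expected cell below
5 fall back to the two-sided Fisher exact test (summation of
hypergeometric probabilities no larger than the observed table's).
Multi-flag families (etiology flags, procedures) are one independent
2×2 comparison per row. The continuous clinician count uses a Welch
two-sample t-test. Display percentages are within-group, half-up
rounded to one decimal; raw values are retained. No multiple-testing
adjustment is applied, and the report footer says so. The suite
verifies the 2×2 chi-squared against its closed form
n(ad−bc)²/((a+b)(c+d)(a+c)(b+d)), Fisher against exhaustive
enumeration, and type-I error calibration (≈5% rejections on null
bundles).

## Prediction

Stratified 80/20 split (deterministic under the master seed), fivefold
cross-validated grid search per family, refit on the full training set,
metrics on the untouched holdout. Default grids are small and
documented in `prediction.default_model_specs`: logistic C over five
log-spaced values; tree depths {3, 5, 10, none}; forest depths
{5, 10, none} at 200 trees; gradient-boosting depth {2, 3}; k ∈
{5, 15, 51}; SVM C ∈ {0.5, 2}. Ties in the CV objective (AUC-ROC by
default, F1 selectable) resolve to the earliest grid entry. Categorical
features are one-hot encoded with unknown levels mapping to all-zeros;
continuous features are standardized with training-set statistics only.

Because never-agreement has ~18% prevalence, an F1 score computed on
the *majority* (agreement) class exceeds accuracy while the
positive-class F1 is much lower; the report therefore carries all three
variants (`f1_positive`, `f1_negative`, `f1_macro`) explicitly
labelled. Calibration uses 10 equal-width probability bins (bin counts
sum to the holdout size). SVMs are fit without Platt scaling; their
probabilities are a sigmoid-squashed decision function, flagged via
`probability_source`. Random-forest importances are impurity-based,
sum to 1, and break ties alphabetically. Outcome columns (death,
disposition) are excluded from the predictor set.

## Problem sizes and numerical choices

The acceptance script uses a 2000-patient cohort with a logistic and a
random-forest model; the test suite's heaviest checks use 2000 patients
for planted-rate recovery (exact binomial 95% interval), 5000 for the
random-forest sanity bound (holdout AUC ≥ 0.85, fixed from a pilot run
before the main build), 200 simulations for type-I calibration, and
the full 511×511 vector grid for the cosine oracle. These sizes are the
package's chosen defaults for a laptop-scale run; larger cohorts only
tighten the stochastic checks. Threshold comparisons use an absolute
guard of 1e−9; exclusion ordering, bin edge conventions and tie-breaks
are fixed as described above so every run is deterministic under its
seed.

## Known limitations

- The lexicon-and-negation extractor is intentionally literal; recall
  on real notes would be bounded by lexicon coverage.
- First shock episode only; multi-episode hospitalizations and
  inter-hospital transfers are out of scope.
- The Elixhauser implementation is a category count by default; the
  weighted (van Walraven) variant requires editing the YAML weights.
- ADI ranks and the sepsis score are passthrough inputs, never derived.
- Synthetic demographics/outcome associations are planted marginals,
  not a causal model; adjusted (multivariable) association analysis is
  out of scope.
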