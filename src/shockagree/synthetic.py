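"""Self-contained synthetic EHR bundle generator with known ground truth.

Emulates the structured-plus-notes data the analysis consumes: per
patient a planted shock-onset day (one SBP reading below 90 mmHg plus a
same-day SOFA elevation over baseline), a clinician team whose size
follows an overdispersed count distribution (mean ~4.85, SD ~2.7),
template-rendered clinician notes embedding the exact lexicon terms
(with optional negated distractor mentions and etiology-free "shock"
notes), ICD codes hitting a planted number of comorbidity categories,
treatment events, and outcomes with elevated mortality in the
never-agreement stratum.

Disagreement is planted *mechanistically*: a designated dissenting
clinician documents one extra (or one fewer) etiology on every study
day they share with a colleague, so the never-agreement label emerges
from the agreement module rather than being stamped on. The returned
GroundTruth ledger records every planted note vector and patient label,
making each downstream stage testable by exact recovery.

All randomness flows from a single seeded ``numpy`` generator; the same
config and seed reproduce the bundle byte for byte.
"""
from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .etiologies import ETIOLOGIES, N_ETIOLOGIES, vector_from_names
from .note_nlp import default_lexicon

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "EhrBundle",
    "ConfigurationError",
    "GenerationError",
    "generate_bundle",
    "render_note",
    "write_bundle",
    "load_bundle",
    "DEFAULT_ETIOLOGY_PREVALENCE",
]


class ConfigurationError(ValueError):
    """Invalid simulation configuration; the message names the field."""


class GenerationError(RuntimeError):
    """Internal inconsistency while rendering synthetic data."""


# Multi-label etiology prevalences in the complete-agreement stratum
# (the bulk of the cohort); a patient may carry several etiologies.
DEFAULT_ETIOLOGY_PREVALENCE: dict[str, float] = {
    "septic": 0.646,
    "cardiogenic": 0.232,
    "hypovolemic": 0.126,
    "adrenal": 0.075,
    "neurogenic": 0.004,
    "undifferentiated": 0.023,
    "obstructive": 0.090,
    "anaphylactic": 0.006,
    "post_procedural": 0.0005,
}

_PROPORTION_FIELDS = (
    "target_disagreement_rate", "negated_mention_rate",
    "zero_vector_note_rate", "ineligible_rate",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic bundle."""

    n_patients: int = 500
    seed: int = 0
    target_disagreement_rate: float = 0.182
    clinician_count_mean: float = 4.85
    clinician_count_sd: float = 2.7
    etiology_prevalence: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ETIOLOGY_PREVALENCE))
    negated_mention_rate: float = 0.25
    zero_vector_note_rate: float = 0.05
    mortality_odds_ratio_disagreement: float = 1.86
    baseline_mortality: float = 0.276
    onset_day_offset_distribution: dict[int, float] = field(
        default_factory=lambda: {0: 0.4, 1: 0.3, 2: 0.2, 3: 0.1})
    ineligible_rate: float = 0.05
    feature_effect_scale: float = 1.0
    multi_note_per_clinician_day: bool = False

    def __post_init__(self) -> None:
        if not isinstance(self.n_patients, (int, np.integer)) or self.n_patients <= 0:
            raise ConfigurationError(f"n_patients must be a positive integer, got {self.n_patients}")
        for name in _PROPORTION_FIELDS:
            v = getattr(self, name)
            if not np.isfinite(v) or not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be a proportion in [0, 1], got {v}")
        for name in ("clinician_count_mean", "clinician_count_sd",
                     "mortality_odds_ratio_disagreement", "baseline_mortality"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ConfigurationError(f"{name} must be a positive finite real, got {v}")
        if set(self.etiology_prevalence) != set(ETIOLOGIES):
            raise ConfigurationError(
                "etiology_prevalence must have exactly the nine etiology keys; "
                f"got {sorted(self.etiology_prevalence)}")
        for k, v in self.etiology_prevalence.items():
            if not np.isfinite(v) or not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"etiology_prevalence[{k!r}] must lie in [0, 1], got {v}")
        probs = np.array(list(self.onset_day_offset_distribution.values()), float)
        if (probs < 0).any() or not np.isclose(probs.sum(), 1.0):
            raise ConfigurationError("onset_day_offset_distribution must be a probability distribution")
        if self.clinician_count_mean <= 2:
            raise ConfigurationError("clinician_count_mean must exceed 2 (eligible patients need >= 2 clinicians)")
        excess = self.clinician_count_mean - 2
        if self.clinician_count_sd ** 2 <= excess:
            raise ConfigurationError(
                "clinician_count_sd^2 must exceed clinician_count_mean - 2 "
                "(overdispersed count model)")


@dataclass
class GroundTruth:
    """Planted truth ledger for one bundle."""

    patients: dict[str, dict] = field(default_factory=dict)
    note_vectors: dict[str, list[int]] = field(default_factory=dict)

    def eligible_ids(self) -> list[str]:
        return [p for p, rec in self.patients.items() if rec["eligible"]]

    def to_json(self) -> str:
        return json.dumps(
            {"patients": self.patients, "note_vectors": self.note_vectors},
            sort_keys=True, indent=1, default=str)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        raw = json.loads(text)
        return cls(patients=raw["patients"], note_vectors=raw["note_vectors"])


@dataclass
class EhrBundle:
    """In-memory synthetic EHR tables plus the note set."""

    demographics: pd.DataFrame
    vitals: pd.DataFrame
    labs: pd.DataFrame
    icd: pd.DataFrame
    events: pd.DataFrame
    outcomes: pd.DataFrame
    notes: list[dict]


# --- note rendering --------------------------------------------------------

OPENER_TEMPLATES = (
    "ICU progress note.",
    "Critical care evaluation.",
    "Overnight events reviewed.",
    "Patient seen and examined at bedside.",
)
SHOCK_TEMPLATES = (
    "Patient remains in shock.",
    "Clinical picture is consistent with shock.",
    "Shock requiring ongoing resuscitation.",
)
POSITIVE_TEMPLATES = (
    "Assessment significant for {term}.",
    "{term} remains the leading working diagnosis.",
    "Findings are most consistent with {term}.",
    "Ongoing management of {term}.",
)
NEGATED_TEMPLATES = (
    "No evidence of {term}.",
    "Without evidence of {term}.",
    "Negative for {term} on current assessment.",
)
CLOSER_TEMPLATES = (
    "Will continue to monitor closely.",
    "Plan discussed with the team.",
    "Continue current supportive care.",
)


def render_note(
    planted_vector: np.ndarray,
    distractors: list[tuple[str, bool]] | None = None,
    template_pool: tuple[str, ...] = POSITIVE_TEMPLATES,
    rng: np.random.Generator | None = None,
    zero_vector_note: bool = False,
) -> str:
    """Render note text whose extraction reproduces ``planted_vector``.

    For each set dimension the text carries one lexicon term of that
    etiology in non-negated position; each ``(etiology, True)``
    distractor adds a term under a pre-positioned negation trigger; the
    bare word "shock" appears whenever any dimension is set or the
    zero-vector-note flag is. An all-zero vector without that flag is a
    generation error.
    """
    if not template_pool:
        raise GenerationError("template pool must be non-empty")
    rng = rng or np.random.default_rng(0)
    vec = np.asarray(planted_vector)
    if vec.sum() == 0 and not zero_vector_note:
        raise GenerationError(
            "planted vector is all-zero but the zero-vector-note flag is unset")
    lex = default_lexicon()
    sentences = [str(rng.choice(OPENER_TEMPLATES))]
    if vec.sum() > 0 or zero_vector_note:
        sentences.append(str(rng.choice(SHOCK_TEMPLATES)))
    for i, name in enumerate(ETIOLOGIES):
        if vec[i]:
            term = str(rng.choice(lex.terms[name]))
            sentences.append(str(rng.choice(template_pool)).format(term=term))
    for etiology, negated in (distractors or []):
        term = str(rng.choice(lex.terms[etiology]))
        tpl = NEGATED_TEMPLATES if negated else template_pool
        sentences.append(str(rng.choice(tpl)).format(term=term))
    sentences.append(str(rng.choice(CLOSER_TEMPLATES)))
    return " ".join(sentences)


# --- clinician pool --------------------------------------------------------

_CLINICIAN_TYPES = (
    ("Physician", 0.471), ("Resident/Fellow", 0.293),
    ("Advanced Practice Provider", 0.145), ("Nurse", 0.018),
    ("Medical Student", 0.012), ("Non-shock Clinician", 0.004),
    ("Other", 0.049), ("Other student/trainee", 0.002), ("Unknown", 0.006),
)
_SPECIALTIES = (
    ("Critical Care Medicine", 0.077), ("Internal Medicine", 0.437),
    ("Cardiology", 0.089), ("Surgery", 0.092),
    ("Neurology/Neurological Surgery", 0.049), ("Infectious Disease", 0.049),
    ("Anesthesiology", 0.031), ("Emergency Medicine", 0.027),
    ("Gastroenterology", 0.022), ("Obstetrics and Gynecology", 0.009),
    ("Non-shock Specialty", 0.030), ("Other", 0.043), ("Unknown", 0.045),
)
_NOTE_TYPES = (("progress", 0.6), ("history_and_physical", 0.2), ("consult", 0.2))


def _categorical(rng, pairs):
    names = [p[0] for p in pairs]
    probs = np.array([p[1] for p in pairs], float)
    probs /= probs.sum()
    return str(rng.choice(names, p=probs))


def _sample_clinician_count(rng: np.random.Generator, cfg: SimulationConfig) -> int:
    # Shifted negative binomial on {2, 3, ...} with mean and SD exactly at
    # the configured values (shifting, not truncating, keeps the moments).
    m = cfg.clinician_count_mean - 2
    var = cfg.clinician_count_sd ** 2
    r = m * m / (var - m)
    p = r / (r + m)
    return 2 + int(rng.negative_binomial(r, p))


# --- SOFA component planting -----------------------------------------------

_SOFA_LEVEL_VALUES = {
    "respiration": (450.0, 350.0, 250.0, 150.0, 80.0),
    "coagulation": (250.0, 120.0, 75.0, 35.0, 15.0),
    "liver": (0.5, 1.5, 3.0, 8.0, 13.0),
    "cns": (15, 13, 11, 7, 4),
    "renal": (0.8, 1.5, 2.5, 4.0, 5.5),
}
_ORGANS = ("respiration", "coagulation", "liver", "cardiovascular", "cns", "renal")

# First-SOFA band mixture by planted label (no-score band not planted:
# onset detection needs a scored day 0).
_SOFA_BAND_PROBS = {
    False: (0.4254, 0.3870, 0.1088, 0.0788),  # complete agreement
    True: (0.3998, 0.3543, 0.1194, 0.1265),   # never agreement
}
_SOFA_BAND_RANGES = ((1, 6), (7, 12), (13, 15), (16, 20))

_ELIX_BAND_PROBS = {
    False: (0.139, 0.188, 0.357, 0.316),
    True: (0.069, 0.151, 0.388, 0.391),
}
_ELIX_BAND_RANGES = ((0, 4), (5, 6), (7, 10), (11, 14))

_SOFA_IMPROVE_PROB = {False: 0.419, True: 0.347}

_RACES = ("White", "Black or African American", "Asian",
          "Native Hawaiian or Other Pacific Islander",
          "American Indian or Alaska Native", "Other", "Unknown")
_RACE_PROBS = {
    False: (0.700, 0.162, 0.037, 0.002, 0.002, 0.069, 0.028),
    True: (0.657, 0.205, 0.032, 0.002, 0.004, 0.068, 0.032),
}
_ETHNICITIES = (("Hispanic, Latino, or Spanish origin", 0.090),
                ("Not Hispanic, Latino, or Spanish origin", 0.877),
                ("Unknown", 0.033))
_INSURANCE = (("Medicare", 0.613), ("Medicaid", 0.120),
              ("Private", 0.248), ("Self-Pay", 0.018))

_PROCEDURES = {
    # event name -> (P | agreement, P | never-agreement)
    "arterial_line": (0.345, 0.404),
    "central_venous_catheter": (0.419, 0.490),
    "continuous_renal_replacement": (0.125, 0.215),
    "cardiac_catheterization": (0.068, 0.081),
    "interventional_radiology": (0.001, 0.001),
}


def _blend(base: tuple, shifted: tuple, scale: float) -> np.ndarray:
    probs = (1 - scale) * np.array(base) + scale * np.array(shifted)
    return probs / probs.sum()


def _plant_sofa_levels(rng, total: int) -> dict[str, int]:
    levels = {o: 0 for o in _ORGANS}
    budget = total
    while budget > 0:
        open_organs = [o for o in _ORGANS if levels[o] < 4]
        if not open_organs:
            break
        levels[str(rng.choice(open_organs))] += 1
        budget -= 1
    return levels


def _sofa_rows(pid: str, date: dt.date, levels: dict[str, int]) -> list[dict]:
    rows = []

    def add(measure, value):
        rows.append({"patient_id": pid, "date": date.isoformat(),
                     "measure": measure, "value": float(value)})

    add("pao2_fio2", _SOFA_LEVEL_VALUES["respiration"][levels["respiration"]])
    add("resp_support", 1.0 if levels["respiration"] >= 3 else 0.0)
    add("platelets", _SOFA_LEVEL_VALUES["coagulation"][levels["coagulation"]])
    add("bilirubin", _SOFA_LEVEL_VALUES["liver"][levels["liver"]])
    cv = levels["cardiovascular"]
    if cv == 0:
        add("map", 80.0)
    elif cv == 1:
        add("map", 65.0)
    elif cv == 2:
        add("map", 65.0)
        add("vasopressor_dopamine", 3.0)
    elif cv == 3:
        add("map", 62.0)
        add("vasopressor_norepinephrine", 0.08)
    else:
        add("map", 55.0)
        add("vasopressor_norepinephrine", 0.3)
    add("gcs", _SOFA_LEVEL_VALUES["cns"][levels["cns"]])
    add("creatinine", _SOFA_LEVEL_VALUES["renal"][levels["renal"]])
    return rows


# --- patient generation ----------------------------------------------------

_INELIGIBLE_KINDS = ("under_18", "single_clinician", "negation_only",
                     "no_day0_note", "no_structured_shock")


def _sample_base_vector(rng, cfg: SimulationConfig) -> np.ndarray:
    draws = rng.random(N_ETIOLOGIES)
    vec = np.array([1 if draws[i] < cfg.etiology_prevalence[name] else 0
                    for i, name in enumerate(ETIOLOGIES)], dtype=np.int8)
    if vec.sum() == 0:
        vec = vector_from_names(["septic"])
    return vec


def _dissent_vector(rng, base: np.ndarray) -> np.ndarray:
    vec = base.copy()
    zeros = np.flatnonzero(vec == 0)
    if zeros.size:
        vec[rng.choice(zeros)] = 1
    else:
        vec[rng.choice(np.flatnonzero(vec == 1))] = 0
    return vec


def generate_bundle(config: SimulationConfig) -> tuple[EhrBundle, GroundTruth]:
    """Generate a full synthetic EHR bundle and its truth ledger."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    base_date = dt.date(2023, 1, 1)

    pool_size = max(40, cfg.n_patients // 3)
    clinicians = [{
        "clinician_id": f"C{i:05d}",
        "clinician_type": _categorical(rng, _CLINICIAN_TYPES),
        "specialty": _categorical(rng, _SPECIALTIES),
    } for i in range(pool_size)]

    offsets = sorted(cfg.onset_day_offset_distribution)
    offset_probs = np.array([cfg.onset_day_offset_distribution[o] for o in offsets])

    demo_rows, vitals_rows, labs_rows, icd_rows = [], [], [], []
    event_rows, outcome_rows, notes = [], [], []
    truth = GroundTruth()
    note_counter = 0

    for idx in range(cfg.n_patients):
        pid = f"P{idx:05d}"
        ineligible = rng.random() < cfg.ineligible_rate
        kind = str(rng.choice(_INELIGIBLE_KINDS)) if ineligible else None
        label = bool(rng.random() < cfg.target_disagreement_rate)

        age = 16 if kind == "under_18" else int(np.clip(rng.normal(68, 15), 18, 100))
        admission = base_date + dt.timedelta(days=int(rng.integers(0, 300)))
        offset = int(rng.choice(offsets, p=offset_probs))
        day0 = admission + dt.timedelta(days=offset)
        study_days = [day0 + dt.timedelta(days=i) for i in range(5)]

        # demographics ------------------------------------------------------
        race = str(rng.choice(_RACES, p=_blend(
            _RACE_PROBS[False], _RACE_PROBS[label], cfg.feature_effect_scale)))
        bmi = float(np.clip(rng.normal(28, 6), 15, 55))
        bmi_known = rng.random() > 0.18
        height_m = float(np.clip(rng.normal(1.70, 0.10), 1.45, 2.05))
        sepsis_known = rng.random() > 0.196
        sepsis_score = int(rng.choice([0, 1, 2, 3, 4, 5, 6],
                                      p=[0.075, 0.058, 0.074, 0.125, 0.40, 0.17, 0.098])) \
            if sepsis_known else None
        demo_rows.append({
            "patient_id": pid, "age": age,
            "sex": "Male" if rng.random() < 0.56 else "Female",
            "race": race,
            "ethnicity": _categorical(rng, _ETHNICITIES),
            "insurance": _categorical(rng, _INSURANCE),
            "adi_state_rank": int(rng.integers(1, 11)),
            "adi_national_rank": int(rng.integers(1, 101)),
            "height_m": round(height_m, 2) if bmi_known else None,
            "weight_kg": round(bmi * height_m ** 2, 1) if bmi_known else None,
            "sepsis_score": sepsis_score,
            "admission_date": admission.isoformat(),
        })

        # vitals ------------------------------------------------------------
        n_days = (day0 - admission).days + 5
        for d in range(n_days):
            date = admission + dt.timedelta(days=d)
            ts = dt.datetime.combine(date, dt.time(8, 0))
            sbp = float(np.clip(rng.normal(115, 8), 95, None))
            hr = float(np.clip(rng.normal(95, 15), 45, 170))
            if date == day0 and kind != "no_structured_shock":
                sbp = float(rng.uniform(70, 88))
                hr = float(np.clip(rng.normal(105, 18), 55, 175))
            vitals_rows.append({"patient_id": pid, "timestamp": ts.isoformat(),
                                "measure": "sbp", "value": round(sbp, 1)})
            vitals_rows.append({"patient_id": pid, "timestamp": ts.isoformat(),
                                "measure": "heart_rate", "value": round(hr, 1)})

        # SOFA labs ---------------------------------------------------------
        band = int(rng.choice(4, p=_blend(_SOFA_BAND_PROBS[False],
                                          _SOFA_BAND_PROBS[label],
                                          cfg.feature_effect_scale)))
        lo, hi = _SOFA_BAND_RANGES[band]
        day0_total = int(rng.integers(lo, hi + 1))
        if offset > 0:
            baseline_total = int(rng.integers(0, min(2, day0_total)))
            labs_rows.extend(_sofa_rows(
                pid, day0 - dt.timedelta(days=1),
                _plant_sofa_levels(rng, baseline_total)))
        day0_levels = _plant_sofa_levels(rng, day0_total)
        labs_rows.extend(_sofa_rows(pid, day0, day0_levels))
        improved = rng.random() < _SOFA_IMPROVE_PROB[label]
        delta = int(rng.integers(1, 4))
        day4_total = max(0, day0_total - delta) if improved \
            else min(24, day0_total + int(rng.integers(0, 3)))
        labs_rows.extend(_sofa_rows(pid, study_days[4],
                                    _plant_sofa_levels(rng, day4_total)))

        # ICD codes ---------------------------------------------------------
        eband = int(rng.choice(4, p=_blend(_ELIX_BAND_PROBS[False],
                                           _ELIX_BAND_PROBS[label],
                                           cfg.feature_effect_scale)))
        elo, ehi = _ELIX_BAND_RANGES[eband]
        n_cat = int(rng.integers(elo, ehi + 1))
        cmap_names = _comorbidity_prefixes()
        chosen = rng.choice(len(cmap_names), size=min(n_cat, len(cmap_names)),
                            replace=False)
        for ci in sorted(chosen):
            icd_rows.append({"patient_id": pid, "icd_code": cmap_names[ci]})
        if rng.random() < 0.3:
            icd_rows.append({"patient_id": pid, "icd_code": "Z99.9"})

        # events ------------------------------------------------------------
        for event, (p_agree, p_dis) in _PROCEDURES.items():
            p = p_dis if label else p_agree
            if rng.random() < p:
                ts = dt.datetime.combine(
                    day0 + dt.timedelta(days=int(rng.integers(0, 5))), dt.time(12, 0))
                event_rows.append({"patient_id": pid, "event": event,
                                   "timestamp": ts.isoformat()})
        bolus_hours = float(rng.gamma(1.2, 9.0))
        event_rows.append({
            "patient_id": pid, "event": "iv_fluid_bolus",
            "timestamp": (dt.datetime.combine(day0, dt.time(0, 0))
                          + dt.timedelta(hours=bolus_hours)).isoformat()})

        # outcomes ----------------------------------------------------------
        base_odds = cfg.baseline_mortality / (1 - cfg.baseline_mortality)
        odds = base_odds * (cfg.mortality_odds_ratio_disagreement if label else 1.0)
        p_death = odds / (1 + odds)
        died = bool(rng.random() < p_death)
        icu_death = died and rng.random() < 0.97
        if died:
            dispo = "Death"
        else:
            dispo = str(rng.choice(
                ["Home", "Long-term Facility", "Acute Inpatient Rehabilitation",
                 "Acute Care Hospital", "Unknown"],
                p=[0.508, 0.323, 0.134, 0.028, 0.007]))
        outcome_rows.append({"patient_id": pid, "in_hospital_death": int(died),
                             "icu_death": int(icu_death),
                             "discharge_disposition": dispo})

        # clinician team and notes -----------------------------------------
        k = 1 if kind == "single_clinician" else _sample_clinician_count(rng, cfg)
        team_idx = rng.choice(pool_size, size=min(k, pool_size), replace=False)
        team = [clinicians[i] for i in team_idx]

        base_vec = _sample_base_vector(rng, cfg)
        dis_vec = _dissent_vector(rng, base_vec) if label else base_vec
        dissenter = team[0]["clinician_id"] if label else None

        # which clinician writes on which study day
        write_days: dict[str, set[int]] = {c["clinician_id"]: set() for c in team}
        anchors = [c["clinician_id"] for c in team[:2]]
        for cid in anchors:
            write_days[cid].add(0)
        for c in team:
            cid = c["clinician_id"]
            if cid not in anchors and rng.random() < 0.25:
                write_days[cid].add(0)
            for d in range(1, 5):
                if rng.random() < 0.15:
                    write_days[cid].add(d)
            if not write_days[cid]:
                write_days[cid].add(int(rng.integers(0, 5)))
        if label and dissenter is not None:
            # the dissenter shares every day on which anyone else writes,
            # so no defined day can reach a mean of 1
            others = set().union(*(ds for cid, ds in write_days.items()
                                   if cid != dissenter)) if len(team) > 1 else set()
            write_days[dissenter] |= others

        if kind == "no_day0_note":
            for cid in write_days:
                write_days[cid] = {max(1, d) for d in write_days[cid]} or {1}
            for cid in anchors:
                write_days[cid].add(1)
        if kind == "single_clinician":
            write_days = {team[0]["clinician_id"]: {0}}

        def emit_note(cid, cinfo, date, day_idx, vec, zero_note, distractors):
            nonlocal note_counter
            note_id = f"N{note_counter:07d}"
            note_counter += 1
            text = render_note(vec, distractors, rng=rng, zero_vector_note=zero_note)
            notes.append({
                "note_id": note_id, "patient_id": pid,
                "clinician_id": cid,
                "clinician_type": cinfo["clinician_type"],
                "specialty": cinfo["specialty"],
                "note_type": _categorical(rng, _NOTE_TYPES),
                "timestamp": dt.datetime.combine(
                    date, dt.time(9 + day_idx % 8, int(rng.integers(0, 60)))).isoformat(),
                "text": text,
            })
            truth.note_vectors[note_id] = [int(x) for x in np.asarray(vec)]

        cinfo_by_id = {c["clinician_id"]: c for c in team}
        for cid in sorted(write_days):
            cinfo = cinfo_by_id[cid]
            for d in sorted(write_days[cid]):
                date = study_days[d]
                if kind == "negation_only":
                    distractor = str(rng.choice(ETIOLOGIES[:4]))
                    emit_note(cid, cinfo, date, d,
                              np.zeros(N_ETIOLOGIES, dtype=np.int8), True,
                              [(distractor, True)])
                    continue
                vec = dis_vec if cid == dissenter else base_vec
                protected = (cid == dissenter) or (d == 0 and cid in anchors)
                zero_note = (not protected
                             and rng.random() < cfg.zero_vector_note_rate)
                if zero_note:
                    vec = np.zeros(N_ETIOLOGIES, dtype=np.int8)
                distractors = []
                if not zero_note and rng.random() < cfg.negated_mention_rate:
                    candidates = np.flatnonzero(np.asarray(vec) == 0)
                    if candidates.size:
                        distractors.append(
                            (ETIOLOGIES[int(rng.choice(candidates))], True))
                emit_note(cid, cinfo, date, d, vec, zero_note, distractors)
                if (cfg.multi_note_per_clinician_day and not zero_note
                        and rng.random() < 0.3):
                    emit_note(cid, cinfo, date, d, vec, False, [])
        if kind == "single_clinician":
            # a second same-clinician note on day 0: pairs from one
            # clinician never establish agreement
            emit_note(team[0]["clinician_id"], team[0], day0, 0, base_vec, False, [])

        truth.patients[pid] = {
            "eligible": not ineligible,
            "exclusion_kind": kind,
            "never_agreement": (label if not ineligible else None),
            "onset_day": day0.isoformat(),
            "died": died,
            "n_clinicians": len(team),
            "base_vector": [int(x) for x in base_vec],
        }

    bundle = EhrBundle(
        demographics=pd.DataFrame(demo_rows),
        vitals=pd.DataFrame(vitals_rows),
        labs=pd.DataFrame(labs_rows),
        icd=pd.DataFrame(icd_rows),
        events=pd.DataFrame(event_rows),
        outcomes=pd.DataFrame(outcome_rows),
        notes=notes,
    )
    return bundle, truth


_CMAP_CODES: list[str] | None = None


def _comorbidity_prefixes() -> list[str]:
    """One representative ICD-10 code per bundled comorbidity category.

    Picks, per category, a prefix that no other category's prefix
    covers, so each planted code contributes exactly one category.
    """
    global _CMAP_CODES
    if _CMAP_CODES is None:
        from .severity import default_comorbidity_map
        cats = default_comorbidity_map().categories
        codes = []
        for name, prefixes, _w in cats:
            others = [q for other, qs, _ in cats if other != name for q in qs]
            unique = [p for p in prefixes
                      if not any(p.startswith(q) for q in others)]
            if not unique:
                raise GenerationError(f"no unambiguous prefix for category {name!r}")
            codes.append(unique[0])
        _CMAP_CODES = codes
    return _CMAP_CODES


# --- serialization ---------------------------------------------------------

_TABLES = ("demographics", "vitals", "labs", "icd", "events", "outcomes")


def write_bundle(bundle: EhrBundle, truth: GroundTruth | None, out_dir: str | Path) -> None:
    """Write the bundle as CSVs + notes.jsonl (+ truth.json)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in _TABLES:
        getattr(bundle, name).to_csv(out / f"{name}.csv", index=False)
    with open(out / "notes.jsonl", "w") as fh:
        for rec in bundle.notes:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")
    if truth is not None:
        (out / "truth.json").write_text(truth.to_json())


def load_bundle(in_dir: str | Path) -> EhrBundle:
    """Read a bundle directory written by :func:`write_bundle`."""
    p = Path(in_dir)
    frames = {name: pd.read_csv(p / f"{name}.csv") for name in _TABLES}
    notes = [json.loads(line) for line in
             (p / "notes.jsonl").read_text().splitlines() if line.strip()]
    return EhrBundle(notes=notes, **frames)
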