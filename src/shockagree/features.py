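"""Assembly of the per-patient predictor table.

Joins demographics, day-0 severity scores, comorbidity burden,
extracted etiology mentions and clinician counts into one row per
included patient, with every categorical predictor binned through the
registered schemes and an explicit "Unknown"/"N/A" level for missing
values. The etiology-mention block (nine flags plus the count of
distinct etiologies documented across clinicians) is the signal the
prediction stage leans on.
"""
from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd

from .cohort import ShockEpisode
from .etiologies import ETIOLOGIES
from .severity import bin_value, elixhauser_index, shock_index

__all__ = ["assemble_features", "FEATURE_COLUMNS"]

FEATURE_COLUMNS = (
    ["age_band", "sex", "race", "ethnicity", "insurance",
     "adi_state_band", "adi_national_band", "sofa_band", "sepsis_score_band",
     "shock_index_band", "elixhauser_band", "bmi_band",
     "icu_admission_weekend", "shock_onset_weekend", "n_clinicians",
     "n_distinct_etiologies"]
    + [f"etiology_{e}" for e in ETIOLOGIES]
)


def _is_weekend(date: dt.date) -> int:
    return int(date.weekday() >= 5)


def _day0_shock_index(vitals: pd.DataFrame, episode: ShockEpisode) -> float | None:
    v = vitals.copy()
    v["timestamp"] = pd.to_datetime(v["timestamp"])
    v["date"] = v["timestamp"].dt.date
    day0 = v[v["date"] == episode.day0]
    hr_rows = day0[day0["measure"] == "heart_rate"]
    if hr_rows.empty:
        return None
    ratio, _ = shock_index(float(hr_rows["value"].iloc[0]), episode.qualifying_sbp)
    return ratio


def assemble_features(
    demographics: pd.DataFrame,
    vitals: pd.DataFrame,
    icd: pd.DataFrame,
    sofa_daily: pd.DataFrame,
    note_vectors: pd.DataFrame,
    episodes: dict[str, ShockEpisode],
    labels: pd.DataFrame,
) -> pd.DataFrame:
    """One predictor row per included patient, merged with the labels.

    ``note_vectors`` carries per-note rows (patient_id, clinician_id,
    day_index, nine etiology columns); ``labels`` is the agreement
    module's per-patient table.
    """
    demo = demographics.set_index("patient_id")
    icd_by_pid = {pid: list(grp["icd_code"]) for pid, grp in icd.groupby("patient_id")}
    sofa_by_pid_day = {
        (r.patient_id, str(r.date)): (r.sofa_total, r.sofa_band)
        for r in sofa_daily.itertuples()
    }
    vitals_by_pid = {pid: grp for pid, grp in vitals.groupby("patient_id")}
    notes_by_pid = {pid: grp for pid, grp in note_vectors.groupby("patient_id")}

    rows = []
    for pid, episode in episodes.items():
        d = demo.loc[pid]
        age = float(d["age"])
        bmi = None
        if pd.notna(d.get("height_m")) and pd.notna(d.get("weight_kg")):
            bmi = float(d["weight_kg"]) / float(d["height_m"]) ** 2
        elix, elix_band, _ = elixhauser_index(icd_by_pid.get(pid, []))
        sofa_total, sofa_band = sofa_by_pid_day.get(
            (pid, episode.day0.isoformat()), (None, "No SOFA score"))
        si = _day0_shock_index(vitals_by_pid.get(pid, vitals.iloc[0:0]), episode)
        admission = dt.date.fromisoformat(str(d["admission_date"])) \
            if "admission_date" in d else episode.day0

        pat_notes = notes_by_pid.get(pid)
        etio_flags = {f"etiology_{e}": 0 for e in ETIOLOGIES}
        n_clin = 0
        if pat_notes is not None:
            union = pat_notes[list(ETIOLOGIES)].max(axis=0)
            for e in ETIOLOGIES:
                etio_flags[f"etiology_{e}"] = int(union[e])
            n_clin = int(pat_notes["clinician_id"].nunique())
        n_etio = int(sum(etio_flags.values()))

        rows.append({
            "patient_id": pid,
            "age_band": bin_value(age, "age"),
            "sex": str(d["sex"]),
            "race": str(d["race"]),
            "ethnicity": str(d["ethnicity"]),
            "insurance": str(d["insurance"]),
            "adi_state_band": bin_value(d.get("adi_state_rank"), "adi_state"),
            "adi_national_band": bin_value(d.get("adi_national_rank"), "adi_national"),
            "sofa_band": sofa_band,
            "sepsis_score_band": bin_value(
                d.get("sepsis_score") if pd.notna(d.get("sepsis_score")) else None,
                "sepsis_score"),
            "shock_index_band": bin_value(si, "shock_index"),
            "elixhauser_band": elix_band,
            "elixhauser_index": elix,
            "bmi_band": bin_value(bmi, "bmi"),
            "icu_admission_weekend": _is_weekend(admission),
            "shock_onset_weekend": _is_weekend(episode.day0),
            "n_clinicians": n_clin,
            "n_distinct_etiologies": n_etio,
            **etio_flags,
        })
    feats = pd.DataFrame.from_records(rows)
    return feats.merge(labels, on="patient_id", how="inner")
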