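"""Inter-clinician agreement via cosine similarity of etiology vectors.

Each clinician's notes on one patient-day collapse (by set union) into
one 9-dimensional binary diagnosis vector. For every patient-day with
at least two clinicians carrying a nonzero vector, all pairwise cosine
similarities are computed and averaged; a patient "ever agrees" at
threshold tau when some daily average reaches tau. The primary outcome
label is *never* reaching a daily average of 1.0 on study days 0-4.

Cosine similarity of binary vectors u, v is |u & v| / sqrt(|u| * |v|):
1 exactly when the two label sets coincide, 0 when they are disjoint.
Zero vectors (shock documented without an etiology term) are excluded
from pairing — cosine is undefined at zero — and counted in QC.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .etiologies import ETIOLOGIES, validate_vector

__all__ = [
    "DEFAULT_THRESHOLDS",
    "DailyAgreement",
    "PatientAgreementLabel",
    "cosine_similarity",
    "clinician_day_vector",
    "daily_average_agreement",
    "classify_patient",
    "daily_agreement_table",
    "label_table",
]

DEFAULT_THRESHOLDS = (1.0, 0.95, 0.90)
_EPS = 1e-9  # float guard when comparing daily means against a threshold


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity of two nonzero binary etiology vectors."""
    u = validate_vector(u)
    v = validate_vector(v)
    nu = int(u.sum())
    nv = int(v.sum())
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity is undefined for a zero vector; "
                         "callers must filter zero vectors upstream")
    inter = int((u & v).sum())
    return inter / float(np.sqrt(nu * nv))


def clinician_day_vector(note_vectors: list[np.ndarray]) -> np.ndarray:
    """Union (component-wise OR) of one clinician's same-day note vectors."""
    if not note_vectors:
        raise ValueError("clinician_day_vector requires at least one note vector")
    stacked = np.stack([validate_vector(v) for v in note_vectors])
    return stacked.max(axis=0).astype(np.int8)


@dataclass(frozen=True)
class DailyAgreement:
    """All pairwise cosine scores among one patient-day's clinicians."""

    patient_id: str
    day_index: int
    clinicians: tuple[str, ...]          # contributors with nonzero vectors
    pair_scores: tuple[float, ...]
    mean_score: float
    n_zero_vectors: int = 0

    @property
    def pair_count(self) -> int:
        return len(self.pair_scores)


def daily_average_agreement(
    clinician_vectors: dict[str, np.ndarray],
    patient_id: str = "",
    day_index: int = 0,
) -> DailyAgreement | None:
    """Mean pairwise cosine score for one patient-day.

    Zero vectors are dropped first; with fewer than two nonzero
    clinician vectors the day is undefined (None).
    """
    nonzero = {c: validate_vector(v) for c, v in clinician_vectors.items()
               if np.asarray(v).sum() > 0}
    n_zero = len(clinician_vectors) - len(nonzero)
    if len(nonzero) < 2:
        return None
    clinicians = tuple(sorted(nonzero))
    scores = tuple(
        cosine_similarity(nonzero[a], nonzero[b])
        for a, b in itertools.combinations(clinicians, 2)
    )
    return DailyAgreement(
        patient_id=patient_id,
        day_index=day_index,
        clinicians=clinicians,
        pair_scores=scores,
        mean_score=float(np.mean(scores)),
        n_zero_vectors=n_zero,
    )


@dataclass(frozen=True)
class PatientAgreementLabel:
    """Ever-agreement flags per threshold; primary label at tau = 1.0."""

    patient_id: str
    max_daily_mean: float
    ever_agreement: dict[float, bool]

    @property
    def never_agreement(self) -> bool:
        """The primary outcome: never reached a daily mean of 1.0."""
        return not self.ever_agreement[1.0]


def classify_patient(
    daily_means: list[float | None],
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    patient_id: str = "",
) -> PatientAgreementLabel:
    """Ever-agreement classification from the study-window daily means.

    Undefined days (None) are skipped, not zero-filled; at least one
    defined mean is required (cohort eligibility guarantees it).
    """
    defined = [m for m in daily_means if m is not None]
    if not defined:
        raise ValueError(f"patient {patient_id!r} has no defined daily agreement mean; "
                         "should have been excluded upstream")
    best = max(defined)
    ever = {float(t): bool(best >= t - _EPS) for t in thresholds}
    return PatientAgreementLabel(patient_id=patient_id, max_daily_mean=best,
                                 ever_agreement=ever)


# --- table-level drivers ---------------------------------------------------

def daily_agreement_table(
    note_vectors: pd.DataFrame,
    mode: str = "union",
) -> pd.DataFrame:
    """Per patient-day agreement from a note-vector table.

    ``note_vectors`` columns: patient_id, clinician_id, day_index plus
    the nine etiology columns. ``mode='union'`` (default) collapses each
    clinician-day to one vector by set union; ``mode='note_pairs'``
    scores every cross-clinician note pair instead (sensitivity mode).
    Days with fewer than two nonzero vectors are omitted.
    """
    if mode not in ("union", "note_pairs"):
        raise ValueError(f"unknown agreement mode {mode!r}")
    cols = list(ETIOLOGIES)
    records = []
    for (pid, day), grp in note_vectors.groupby(["patient_id", "day_index"], sort=True):
        if mode == "union":
            vecs = {
                cid: clinician_day_vector([row.to_numpy() for _, row in sub[cols].iterrows()])
                for cid, sub in grp.groupby("clinician_id")
            }
            agg = daily_average_agreement(vecs, patient_id=pid, day_index=int(day))
            if agg is None:
                continue
            records.append({
                "patient_id": pid, "day_index": int(day), "k": len(agg.clinicians),
                "pair_count": agg.pair_count, "mean_score": agg.mean_score,
                "n_zero_vectors": agg.n_zero_vectors,
            })
        else:
            rows = [(cid, np.array([rec[c] for c in cols], dtype=np.int8))
                    for cid, rec in zip(grp["clinician_id"], grp.to_dict("records"))]
            nonzero = [(cid, v) for cid, v in rows if v.sum() > 0]
            pairs = [
                cosine_similarity(u, v)
                for (ca, u), (cb, v) in itertools.combinations(nonzero, 2)
                if ca != cb
            ]
            if not pairs:
                continue
            records.append({
                "patient_id": pid, "day_index": int(day),
                "k": len({cid for cid, _ in nonzero}),
                "pair_count": len(pairs), "mean_score": float(np.mean(pairs)),
                "n_zero_vectors": len(rows) - len(nonzero),
            })
    return pd.DataFrame.from_records(
        records,
        columns=["patient_id", "day_index", "k", "pair_count", "mean_score",
                 "n_zero_vectors"],
    )


def label_table(
    daily: pd.DataFrame,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Per-patient never-agreement flags at each threshold.

    Patients absent from ``daily`` (no defined day) are absent here too.
    Column names encode the threshold, e.g. ``never_agreement_100``.
    """
    records = []
    for pid, grp in daily.groupby("patient_id", sort=True):
        lab = classify_patient(list(grp["mean_score"]), thresholds, patient_id=pid)
        rec = {"patient_id": pid, "max_daily_mean": lab.max_daily_mean}
        for t in thresholds:
            rec[threshold_column(t)] = not lab.ever_agreement[float(t)]
        records.append(rec)
    return pd.DataFrame.from_records(records)


def threshold_column(tau: float) -> str:
    """Label column name for a threshold, e.g. 0.95 -> never_agreement_095."""
    return f"never_agreement_{int(round(tau * 100)):03d}"
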