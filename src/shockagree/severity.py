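"""Clinical severity scores and categorical binnings.

Implements the SOFA score (six organ subscores, 0-4 each, total 0-24)
from component measurements, the shock index (heart rate / systolic
blood pressure), an Elixhauser comorbidity index as a count of distinct
comorbidity categories matched by ICD-10 code prefixes, and the named
categorical binning schemes used as analysis predictors (age, BMI,
SOFA band, shock index, sepsis score, ADI ranks, time-to-event hours).

SOFA thresholds follow the canonical published criteria and live in a
data-driven table (`SOFA_THRESHOLDS`) so alternates can be swapped.
A missing component scores 0 and is flagged; a patient-day with no
observed component at all maps to the "No SOFA score" band.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SofaComponents",
    "SofaResult",
    "ComorbidityMap",
    "score_sofa",
    "shock_index",
    "elixhauser_index",
    "default_comorbidity_map",
    "bin_value",
    "BIN_SCHEMES",
    "daily_sofa_totals",
]

_MISSING = object()


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass(frozen=True)
class SofaComponents:
    """Raw inputs to a SOFA score; any field may be missing (None)."""

    pao2_fio2: float | None = None          # mmHg ratio
    respiratory_support: bool = False       # mechanical ventilation / CPAP
    platelets: float | None = None          # 10^3 / uL
    bilirubin: float | None = None          # mg/dL
    mean_arterial_pressure: float | None = None  # mmHg
    vasopressors: dict[str, float] = field(default_factory=dict)  # drug -> dose ug/kg/min
    gcs: int | None = None                  # Glasgow Coma Scale 3-15
    creatinine: float | None = None         # mg/dL
    urine_output: float | None = None       # mL/day

    def __post_init__(self) -> None:
        for name in ("pao2_fio2", "platelets", "bilirubin",
                     "mean_arterial_pressure", "creatinine", "urine_output"):
            v = getattr(self, name)
            if v is not None and not _is_missing(v) and v < 0:
                raise ValueError(f"SOFA component {name} must be non-negative, got {v}")
        if self.gcs is not None and not _is_missing(self.gcs) and not 3 <= self.gcs <= 15:
            raise ValueError(f"GCS must lie in [3, 15], got {self.gcs}")
        for drug, dose in self.vasopressors.items():
            if dose < 0:
                raise ValueError(f"vasopressor dose for {drug} must be non-negative")


SOFA_BANDS = ("0–6", "7–12", "13–15", "16–24")
SOFA_NO_SCORE = "No SOFA score"

# Data-driven subscore thresholds (value -> points). Respiration points
# 3-4 additionally require respiratory support; cardiovascular uses the
# vasopressor ladder below.
SOFA_THRESHOLDS: dict[str, list[tuple[float, int]]] = {
    # (exclusive upper bound, points) scanned in order
    "respiration": [(100.0, 4), (200.0, 3), (300.0, 2), (400.0, 1)],
    "coagulation": [(20.0, 4), (50.0, 3), (100.0, 2), (150.0, 1)],
    # (inclusive lower bound, points) scanned in order
    "liver": [(12.0, 4), (6.0, 3), (2.0, 2), (1.2, 1)],
    "renal_creatinine": [(5.0, 4), (3.5, 3), (2.0, 2), (1.2, 1)],
}


@dataclass(frozen=True)
class SofaResult:
    """Six subscores, their total, the band, and missingness flags."""

    subscores: dict[str, int]
    total: int
    band: str
    missing: tuple[str, ...]

    def __post_init__(self) -> None:
        assert self.total == sum(self.subscores.values())


def _respiration_score(pf: float | None, support: bool) -> int:
    if _is_missing(pf):
        return 0
    for bound, pts in SOFA_THRESHOLDS["respiration"]:
        if pf < bound:
            if pts >= 3 and not support:
                return 2  # capped without respiratory support
            return pts
    return 0


def _coagulation_score(platelets: float | None) -> int:
    if _is_missing(platelets):
        return 0
    for bound, pts in SOFA_THRESHOLDS["coagulation"]:
        if platelets < bound:
            return pts
    return 0


def _liver_score(bilirubin: float | None) -> int:
    if _is_missing(bilirubin):
        return 0
    for bound, pts in SOFA_THRESHOLDS["liver"]:
        if bilirubin >= bound:
            return pts
    return 0


def _cardiovascular_score(map_: float | None, vaso: dict[str, float]) -> int:
    doses = {k.lower(): v for k, v in vaso.items() if v > 0}
    dopamine = doses.get("dopamine", 0.0)
    dobutamine = doses.get("dobutamine", 0.0)
    epi = doses.get("epinephrine", 0.0)
    norepi = doses.get("norepinephrine", 0.0)
    if dopamine > 15 or epi > 0.1 or norepi > 0.1:
        return 4
    if dopamine > 5 or epi > 0 or norepi > 0:
        return 3
    if dopamine > 0 or dobutamine > 0:
        return 2
    if not _is_missing(map_) and map_ < 70:
        return 1
    return 0


def _cns_score(gcs: int | None) -> int:
    if _is_missing(gcs):
        return 0
    if gcs < 6:
        return 4
    if gcs <= 9:
        return 3
    if gcs <= 12:
        return 2
    if gcs <= 14:
        return 1
    return 0


def _renal_score(creatinine: float | None, urine_output: float | None) -> int:
    score = 0
    if not _is_missing(creatinine):
        for bound, pts in SOFA_THRESHOLDS["renal_creatinine"]:
            if creatinine >= bound:
                score = pts
                break
    if not _is_missing(urine_output):
        if urine_output < 200:
            score = max(score, 4)
        elif urine_output < 500:
            score = max(score, 3)
    return score


def score_sofa(components: SofaComponents) -> SofaResult:
    """Compute the six SOFA organ subscores, the total and its band.

    Missing components score 0 and are listed in ``missing``; when every
    component is missing the band is "No SOFA score".
    """
    missing = []
    if _is_missing(components.pao2_fio2):
        missing.append("respiration")
    if _is_missing(components.platelets):
        missing.append("coagulation")
    if _is_missing(components.bilirubin):
        missing.append("liver")
    if _is_missing(components.mean_arterial_pressure) and not components.vasopressors:
        missing.append("cardiovascular")
    if _is_missing(components.gcs):
        missing.append("cns")
    if _is_missing(components.creatinine) and _is_missing(components.urine_output):
        missing.append("renal")

    subs = {
        "respiration": _respiration_score(components.pao2_fio2, components.respiratory_support),
        "coagulation": _coagulation_score(components.platelets),
        "liver": _liver_score(components.bilirubin),
        "cardiovascular": _cardiovascular_score(
            components.mean_arterial_pressure, components.vasopressors
        ),
        "cns": _cns_score(components.gcs),
        "renal": _renal_score(components.creatinine, components.urine_output),
    }
    total = sum(subs.values())
    if len(missing) == 6:
        band = SOFA_NO_SCORE
    else:
        band = bin_value(total, "sofa")
    return SofaResult(subscores=subs, total=total, band=band, missing=tuple(missing))


def shock_index(heart_rate: float, sbp: float) -> tuple[float, str]:
    """Heart rate over systolic blood pressure, with its category.

    Bands: < 0.5, [0.5, 0.7), [0.7, 1.0], > 1.0; non-positive SBP
    yields NaN with the "Unknown" band and a warning.
    """
    if heart_rate < 0:
        raise ValueError(f"heart rate must be non-negative, got {heart_rate}")
    if sbp <= 0:
        warnings.warn("non-positive systolic blood pressure; shock index unknown")
        return float("nan"), "Unknown"
    ratio = heart_rate / sbp
    return ratio, bin_value(ratio, "shock_index")


@dataclass(frozen=True)
class ComorbidityMap:
    """Ordered comorbidity categories with ICD-10 prefixes and weights."""

    categories: tuple[tuple[str, tuple[str, ...], int], ...]

    def __post_init__(self) -> None:
        names = [c[0] for c in self.categories]
        if len(set(names)) != len(names):
            raise ValueError("comorbidity category names must be unique")
        for name, prefixes, _weight in self.categories:
            for p in prefixes:
                if not p.isalnum() or p != p.upper():
                    raise ValueError(
                        f"prefix {p!r} in category {name!r} must be uppercase alphanumeric"
                    )


_DEFAULT_CMAP: ComorbidityMap | None = None


def default_comorbidity_map() -> ComorbidityMap:
    """The bundled 31-category ICD-10 prefix map (cached)."""
    global _DEFAULT_CMAP
    if _DEFAULT_CMAP is None:
        with resources.files("shockagree.data").joinpath("elixhauser_icd10.yaml").open() as fh:
            raw = yaml.safe_load(fh)
        cats = tuple(
            (c["name"], tuple(str(p).upper() for p in c["prefixes"]), int(c["weight"]))
            for c in raw["categories"]
        )
        _DEFAULT_CMAP = ComorbidityMap(cats)
    return _DEFAULT_CMAP


def elixhauser_index(
    icd_codes: list[str], cmap: ComorbidityMap | None = None
) -> tuple[int, str, dict]:
    """Comorbidity index from ICD-10 codes.

    A category contributes its weight once when at least one code
    matches one of its prefixes (dots stripped, case-insensitive).
    With the default unit weights the index is the number of distinct
    matched categories. Returns (index, band, diagnostics) where
    diagnostics carry the matched category names and unmatched codes.
    """
    cmap = cmap or default_comorbidity_map()
    normalized = [str(c).upper().replace(".", "").strip() for c in icd_codes]
    matched: list[str] = []
    matched_codes: set[str] = set()
    index = 0
    for name, prefixes, weight in cmap.categories:
        hit = False
        for code in normalized:
            if any(code.startswith(p) for p in prefixes):
                hit = True
                matched_codes.add(code)
        if hit:
            matched.append(name)
            index += weight
    unmatched = [c for c in normalized if c not in matched_codes]
    band = bin_value(index, "elixhauser")
    return index, band, {"matched_categories": matched, "unmatched_codes": unmatched}


def _half_up(x: float, digits: int = 1) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0." + "0" * digits), rounding=ROUND_HALF_UP))


# --- named binning schemes -------------------------------------------------
# Each scheme is (binning function, unknown label). Conventions:
# left-closed / right-open except where a printed boundary dictates
# otherwise (shock index includes 1.0 in "0.7-1.0").

def _bin_age(v: float) -> str:
    if v <= 50:
        return "50 and under"
    if v <= 60:
        return "51–60"
    if v <= 70:
        return "61–70"
    if v <= 80:
        return "71–80"
    return "81 and older"


def _bin_bmi(v: float) -> str:
    if v < 18.5:
        return "< 18.5"
    if v < 25.0:
        return "18.5–24.9"
    if v < 30.0:
        return "25.0–29.9"
    if v < 35.0:
        return "30.0–34.9"
    return "35 and above"


def _bin_sofa(v: float) -> str:
    if v <= 6:
        return SOFA_BANDS[0]
    if v <= 12:
        return SOFA_BANDS[1]
    if v <= 15:
        return SOFA_BANDS[2]
    return SOFA_BANDS[3]


def _bin_shock_index(v: float) -> str:
    if v < 0.5:
        return "< 0.5"
    if v < 0.7:
        return "0.5–0.7"
    if v <= 1.0:
        return "0.7–1.0"
    return "> 1.0"


def _bin_sepsis_score(v: float) -> str:
    iv = int(v)
    if iv <= 3:
        return str(iv)
    return ">= 4"


def _bin_elixhauser(v: float) -> str:
    # printed "0-5, 5-6" edges disambiguated to 0-4 / 5-6 / 7-10 / >= 11,
    # displayed with the printed labels
    if v <= 4:
        return "0–5"
    if v <= 6:
        return "5–6"
    if v <= 10:
        return "7–10"
    return "> 10"


def _bin_adi_state(v: float) -> str:
    if v <= 2:
        return "1–2"
    if v <= 5:
        return "3–5"
    return "6–10"


def _bin_adi_national(v: float) -> str:
    if v < 25:
        return "< 25"
    if v < 50:
        return "25–49"
    if v < 75:
        return "50–74"
    return "75–100"


def _bin_time_hours(v: float) -> str:
    if v < 24:
        return "< 24 h"
    if v < 48:
        return "24–48 h"
    if v < 72:
        return "49–72 h"
    if v < 96:
        return "73–96 h"
    return "> 96 h"


BIN_SCHEMES: dict[str, tuple] = {
    "age": (_bin_age, "Unknown"),
    "bmi": (_bin_bmi, "Unknown"),
    "sofa": (_bin_sofa, SOFA_NO_SCORE),
    "shock_index": (_bin_shock_index, "Unknown"),
    "sepsis_score": (_bin_sepsis_score, "N/A"),
    "elixhauser": (_bin_elixhauser, "Unknown"),
    "adi_state": (_bin_adi_state, "Unknown"),
    "adi_national": (_bin_adi_national, "Unknown"),
    "time_hours": (_bin_time_hours, "N/A"),
}


def bin_value(value, scheme: str) -> str:
    """Map a value to the single label of a registered binning scheme.

    Missing input (None/NaN) maps to the scheme's unknown label; an
    unregistered scheme name raises ``KeyError``.
    """
    if scheme not in BIN_SCHEMES:
        raise KeyError(f"unregistered binning scheme {scheme!r}; "
                       f"known: {sorted(BIN_SCHEMES)}")
    fn, unknown = BIN_SCHEMES[scheme]
    if _is_missing(value):
        return unknown
    return fn(float(value))


# --- labs table -> per-day SOFA totals -------------------------------------

_NUMERIC_MEASURES = {
    "pao2_fio2": "pao2_fio2",
    "platelets": "platelets",
    "bilirubin": "bilirubin",
    "map": "mean_arterial_pressure",
    "gcs": "gcs",
    "creatinine": "creatinine",
    "urine_output": "urine_output",
}


def _components_from_rows(rows: pd.DataFrame) -> SofaComponents:
    kwargs: dict = {}
    vaso: dict[str, float] = {}
    for measure, grp in rows.groupby("measure"):
        val = float(grp["value"].iloc[-1])
        if measure in _NUMERIC_MEASURES:
            if measure == "gcs":
                kwargs["gcs"] = int(val)
            else:
                kwargs[_NUMERIC_MEASURES[measure]] = val
        elif measure == "resp_support":
            kwargs["respiratory_support"] = bool(val)
        elif measure.startswith("vasopressor_"):
            vaso[measure.removeprefix("vasopressor_")] = val
    return SofaComponents(vasopressors=vaso, **kwargs)


def daily_sofa_totals(labs: pd.DataFrame) -> pd.DataFrame:
    """Score SOFA per patient-day from a long labs table.

    ``labs`` columns: patient_id, date, measure, value. Returns one row
    per patient-day with the total, band and per-organ subscores.
    """
    records = []
    for (pid, date), rows in labs.groupby(["patient_id", "date"], sort=True):
        comp = _components_from_rows(rows)
        res = score_sofa(comp)
        rec = {"patient_id": pid, "date": date, "sofa_total": res.total,
               "sofa_band": res.band}
        rec.update({f"sofa_{k}": v for k, v in res.subscores.items()})
        records.append(rec)
    return pd.DataFrame.from_records(records)
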