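"""End-to-end orchestration: bundle -> cohort -> agreement -> stats -> models.

`extract_note_vectors` turns the note set into per-note etiology
vectors; `analyze_bundle` runs the whole analysis in memory and is the
workhorse behind both the CLI and the acceptance script. `run_pipeline`
adds on-disk inputs/outputs and a reproducibility manifest (seed, row
counts, output checksums).
"""
from __future__ import annotations

import datetime as dt
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import agreement as agr
from . import stats as st
from .cohort import build_cohort
from .etiologies import ETIOLOGIES
from .features import assemble_features
from .note_nlp import vectorize_note
from .prediction import default_model_specs, run_model_battery
from .severity import daily_sofa_totals
from .synthetic import EhrBundle, SimulationConfig, generate_bundle, load_bundle, write_bundle

__all__ = ["PipelineConfig", "PipelineResult", "extract_note_vectors",
           "analyze_bundle", "run_pipeline"]


def extract_note_vectors(notes: list[dict]) -> pd.DataFrame:
    """Vectorize every note: nine etiology columns plus QC flags."""
    records = []
    for note in notes:
        vec, diag = vectorize_note(note["text"])
        ts = dt.datetime.fromisoformat(note["timestamp"])
        rec = {
            "note_id": note["note_id"],
            "patient_id": note["patient_id"],
            "clinician_id": note["clinician_id"],
            "note_type": note.get("note_type", "progress"),
            "date": ts.date(),
        }
        rec.update({e: int(vec[i]) for i, e in enumerate(ETIOLOGIES)})
        rec["shock_word"] = diag.shock_word
        rec["negated_only"] = diag.negated_only
        rec["has_matches"] = bool(diag.matches)
        records.append(rec)
    return pd.DataFrame.from_records(records)


NOTE_TYPE_ALLOWLIST = ("history_and_physical", "progress", "consult")


@dataclass
class PipelineResult:
    """All intermediate and final frames of one analysis run."""

    note_vectors: pd.DataFrame
    sofa_daily: pd.DataFrame
    cohort: pd.DataFrame
    exclusions: pd.DataFrame
    daily_agreement: pd.DataFrame
    labels: pd.DataFrame
    features: pd.DataFrame
    report: st.ReportTables | None = None
    eval_reports: dict = field(default_factory=dict)
    models: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)

    def never_agreement_rate(self, tau: float = 1.0) -> float:
        col = agr.threshold_column(tau)
        return float(self.labels[col].mean())


def analyze_bundle(
    bundle: EhrBundle,
    thresholds: tuple[float, ...] = agr.DEFAULT_THRESHOLDS,
    agreement_mode: str = "union",
    run_stats: bool = True,
    run_prediction: bool = False,
    model_specs: list | None = None,
    seed: int = 0,
    note_type_allowlist: tuple[str, ...] = NOTE_TYPE_ALLOWLIST,
) -> PipelineResult:
    """Run extraction, cohort, agreement, stats and (optionally) models."""
    note_vectors = extract_note_vectors(bundle.notes)
    note_vectors = note_vectors[note_vectors["note_type"].isin(note_type_allowlist)]
    sofa_daily = daily_sofa_totals(bundle.labs)
    sofa_daily["date"] = sofa_daily["date"].astype(str)

    vitals = bundle.vitals.copy()
    sofa_for_cohort = sofa_daily.copy()
    sofa_for_cohort["date"] = sofa_for_cohort["date"].map(dt.date.fromisoformat)
    cohort, exclusions, episodes = build_cohort(
        vitals, sofa_for_cohort, note_vectors, bundle.demographics)

    # agreement over the study window of each included patient
    day_index = {}
    for pid, ep in episodes.items():
        for i, d in enumerate(ep.study_days):
            day_index[(pid, d)] = i
    nv = note_vectors[note_vectors["patient_id"].isin(episodes)].copy()
    nv["day_index"] = [
        day_index.get((pid, d), -1) for pid, d in zip(nv["patient_id"], nv["date"])]
    nv = nv[nv["day_index"] >= 0]

    daily = agr.daily_agreement_table(nv, mode=agreement_mode)
    labels = agr.label_table(daily, thresholds)

    scorable = set(labels["patient_id"])
    unscorable = sorted(set(episodes) - scorable)
    episodes = {pid: ep for pid, ep in episodes.items() if pid in scorable}
    cohort = cohort[cohort["patient_id"].isin(scorable)]

    feats = assemble_features(
        bundle.demographics, bundle.vitals, bundle.icd, sofa_daily,
        nv, episodes, labels)
    feats = feats.merge(bundle.outcomes, on="patient_id", how="left")

    result = PipelineResult(
        note_vectors=note_vectors, sofa_daily=sofa_daily, cohort=cohort,
        exclusions=exclusions, daily_agreement=daily, labels=labels,
        features=feats,
        qc={
            "n_patients_input": int(bundle.demographics.shape[0]),
            "n_included": int(cohort.shape[0]),
            "n_excluded": int(exclusions.shape[0]),
            "exclusion_reasons": exclusions["reason"].value_counts().to_dict(),
            "n_no_scorable_day": len(unscorable),
            "n_zero_vector_notes": int(
                (note_vectors[list(ETIOLOGIES)].sum(axis=1) == 0).sum()),
        },
    )
    if run_stats:
        stat_feats = feats.copy()
        events = bundle.events
        for event in sorted(events["event"].unique()):
            if event == "iv_fluid_bolus":
                continue
            pids = set(events.loc[events["event"] == event, "patient_id"])
            stat_feats[f"proc_{event}"] = stat_feats["patient_id"].isin(pids).astype(int)
        stat_feats["icu_death"] = stat_feats["icu_death"].astype(bool)
        stat_feats["in_hospital_death"] = stat_feats["in_hospital_death"].astype(bool)
        result.report = st.build_report(stat_feats)
    if run_prediction:
        pred_feats = feats.drop(columns=[
            c for c in ("in_hospital_death", "icu_death", "discharge_disposition")
            if c in feats])
        reports, models = run_model_battery(
            pred_feats, specs=model_specs, seed=seed)
        result.eval_reports = {k: v.to_dict() for k, v in reports.items()}
        result.models = models
    return result


@dataclass
class PipelineConfig:
    """Configuration of an on-disk end-to-end run."""

    out_dir: str
    seed: int = 0
    bundle_dir: str | None = None          # read an existing bundle
    simulate: SimulationConfig | None = None  # or generate one
    thresholds: tuple[float, ...] = agr.DEFAULT_THRESHOLDS
    agreement_mode: str = "union"
    run_prediction: bool = True
    model_families: tuple[str, ...] | None = ("logistic_regression", "random_forest")

    def __post_init__(self) -> None:
        for t in self.thresholds:
            if not 0 < t <= 1:
                raise ValueError(f"agreement thresholds must lie in (0, 1], got {t}")
        if self.bundle_dir is None and self.simulate is None:
            raise ValueError("either bundle_dir or a simulate config is required")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline on disk; returns the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.simulate is not None:
        bundle, truth = generate_bundle(config.simulate)
        write_bundle(bundle, truth, out / "bundle")
    else:
        bundle = load_bundle(config.bundle_dir)

    specs = None
    if config.model_families is not None:
        specs = [s for s in default_model_specs()
                 if s.family in config.model_families]
    result = analyze_bundle(
        bundle, thresholds=config.thresholds,
        agreement_mode=config.agreement_mode,
        run_prediction=config.run_prediction, model_specs=specs,
        seed=config.seed)

    result.note_vectors.to_csv(out / "note_vectors.csv", index=False)
    result.cohort.to_csv(out / "cohort.csv", index=False)
    result.exclusions.to_csv(out / "exclusions.csv", index=False)
    result.daily_agreement.to_csv(out / "daily_agreement.csv", index=False)
    result.labels.to_csv(out / "labels.csv", index=False)
    result.features.to_csv(out / "features.csv", index=False)
    if result.report is not None:
        (out / "report.md").write_text(st.render_report(result.report))
        (out / "report.json").write_text(
            json.dumps(st.report_to_records(result.report), indent=1))
    if result.eval_reports:
        (out / "eval_report.json").write_text(
            json.dumps(result.eval_reports, indent=1))

    outputs = sorted(p for p in out.rglob("*") if p.is_file())
    manifest = {
        "seed": config.seed,
        "thresholds": list(config.thresholds),
        "qc": result.qc,
        "never_agreement_rates": {
            agr.threshold_column(t): result.never_agreement_rate(t)
            for t in config.thresholds},
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in outputs},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
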