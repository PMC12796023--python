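"""Descriptive comparison of cohort features by agreement label.

Every categorical feature is cross-tabulated against the binary
never-agreement label and tested with a chi-squared test of
independence (no continuity correction by default); 2x2 tables with
any expected cell below a configurable threshold fall back to Fisher's
exact test. Multi-flag families (etiology flags, procedures) are
tested row by row, each row a separate 2x2 comparison. The continuous
clinician count is compared with a Welch two-sample t-test. Display
percentages are within-group, half-up rounded to one decimal.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CrosstabResult",
    "crosstab_compare",
    "percent_within_group",
    "two_by_two_from_counts",
    "continuous_compare",
    "build_report",
    "render_report",
]


@dataclass(frozen=True)
class CrosstabResult:
    """One feature's contingency comparison between the two groups."""

    feature: str
    categories: tuple[str, ...]
    groups: tuple[str, ...]
    counts: tuple[tuple[int, ...], ...]       # [category][group]
    percentages: tuple[tuple[float, ...], ...]
    test: str                                  # "chi-squared" | "fisher" | "none"
    statistic: float | None
    p_value: float | None
    dof: int | None = None
    note: str = ""


def percent_within_group(count: int, total: int) -> float:
    """100 * count / total, half-up rounded to one decimal for display."""
    if total <= 0:
        raise ValueError("group total must be positive")
    if not 0 <= count <= total:
        raise ValueError(f"count {count} outside [0, {total}]")
    raw = 100.0 * count / total
    return float(Decimal(repr(raw)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _fisher_two_sided(table: np.ndarray) -> tuple[float, float]:
    """Two-sided Fisher exact p by summing hypergeometric probabilities
    no larger than the observed table's."""
    odds, p = sps.fisher_exact(table, alternative="two-sided")
    return float(odds), float(min(p, 1.0))


def crosstab_compare(
    categories: pd.Series,
    groups: pd.Series,
    feature: str = "",
    category_order: list[str] | None = None,
    fisher_expected_threshold: float = 5.0,
    yates: bool = False,
) -> CrosstabResult:
    """Chi-squared (or Fisher) comparison of a categorical feature.

    ``groups`` must be binary. Fisher's exact test replaces the
    chi-squared test for 2x2 tables with any expected count below
    ``fisher_expected_threshold``.
    """
    tab = pd.crosstab(categories, groups)
    if tab.shape[1] != 2 or (tab.sum(axis=0) == 0).any():
        raise ValueError(f"feature {feature!r}: need two non-empty groups, "
                         f"got shape {tab.shape}")
    if category_order:
        present = [c for c in category_order if c in tab.index]
        tab = tab.loc[present]
    tab = tab[tab.sum(axis=1) > 0]
    group_names = tuple(str(g) for g in tab.columns)
    totals = tab.sum(axis=0)
    counts = tuple(tuple(int(x) for x in row) for row in tab.to_numpy())
    pcts = tuple(
        tuple(percent_within_group(int(c), int(totals.iloc[j]))
              for j, c in enumerate(row))
        for row in tab.to_numpy()
    )
    cat_names = tuple(str(c) for c in tab.index)

    if tab.shape[0] < 2:
        return CrosstabResult(feature, cat_names, group_names, counts, pcts,
                              test="none", statistic=None, p_value=None,
                              note="single category; no test performed")

    observed = tab.to_numpy()
    expected = sps.contingency.expected_freq(observed)
    if observed.shape == (2, 2) and (expected < fisher_expected_threshold).any():
        odds, p = _fisher_two_sided(observed)
        return CrosstabResult(feature, cat_names, group_names, counts, pcts,
                              test="fisher", statistic=odds, p_value=p)
    if (expected < fisher_expected_threshold).any():
        warnings.warn(f"feature {feature!r}: expected cell < "
                      f"{fisher_expected_threshold} in a non-2x2 table; "
                      "chi-squared approximation may be poor")
    chi2, p, dof, _ = sps.chi2_contingency(observed, correction=yates)
    return CrosstabResult(feature, cat_names, group_names, counts, pcts,
                          test="chi-squared", statistic=float(chi2),
                          p_value=float(p), dof=int(dof))


def two_by_two_from_counts(
    feature: str,
    a_yes: int, a_total: int,
    b_yes: int, b_total: int,
    group_names: tuple[str, str] = ("group_a", "group_b"),
    **kwargs,
) -> CrosstabResult:
    """Comparison of one dichotomous row given printed group counts."""
    cats = pd.Series(["yes"] * a_yes + ["no"] * (a_total - a_yes)
                     + ["yes"] * b_yes + ["no"] * (b_total - b_yes))
    grp = pd.Series([group_names[0]] * a_total + [group_names[1]] * b_total)
    return crosstab_compare(cats, grp, feature=feature,
                            category_order=["yes", "no"], **kwargs)


@dataclass(frozen=True)
class ContinuousResult:
    feature: str
    groups: tuple[str, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]
    statistic: float
    p_value: float
    test: str = "welch-t"


def continuous_compare(values: pd.Series, groups: pd.Series,
                       feature: str = "") -> ContinuousResult:
    """Welch two-sample t-test on a continuous feature."""
    names = sorted(groups.dropna().unique(), key=str)
    if len(names) != 2:
        raise ValueError(f"feature {feature!r}: need exactly two groups")
    a = values[groups == names[0]].astype(float)
    b = values[groups == names[1]].astype(float)
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return ContinuousResult(
        feature=feature, groups=tuple(str(n) for n in names),
        means=(float(a.mean()), float(b.mean())),
        sds=(float(a.std(ddof=1)), float(b.std(ddof=1))),
        statistic=float(t), p_value=float(p),
    )


# Layout of the descriptive report: (table name, feature columns).
# Flag features (0/1 columns, tested row-wise) are marked with "*".
REPORT_LAYOUT: dict[str, list[str]] = {
    "demographics": ["age_band", "sex", "race", "ethnicity", "insurance",
                     "adi_national_band", "adi_state_band"],
    "clinical_features": ["sofa_band", "sepsis_score_band", "shock_index_band",
                          "*etiology_flags", "elixhauser_band", "bmi_band",
                          "icu_admission_weekend", "shock_onset_weekend",
                          "~n_clinicians"],
    "clinical_course": ["sofa_change", "*procedure_flags", "icu_death",
                        "in_hospital_death", "discharge_disposition"],
}


@dataclass
class ReportTables:
    """Per-feature comparison results grouped into report tables."""

    tables: dict[str, list] = field(default_factory=dict)
    footnotes: list[str] = field(default_factory=list)

    def all_pvalues(self) -> list[float]:
        out = []
        for rows in self.tables.values():
            for r in rows:
                if getattr(r, "p_value", None) is not None:
                    out.append(r.p_value)
        return out


def build_report(
    features: pd.DataFrame,
    label_col: str = "never_agreement_100",
    layout: dict[str, list[str]] | None = None,
    **test_kwargs,
) -> ReportTables:
    """Descriptive comparison tables of every feature by agreement label.

    Features absent from ``features`` are skipped silently so the same
    layout serves bundles of different richness. Flag families expand
    to one independent 2x2 comparison per flag column.
    """
    layout = layout or REPORT_LAYOUT
    grp = features[label_col].map({True: "never_agreement", False: "agreement"})
    report = ReportTables()
    for table_name, cols in layout.items():
        rows: list = []
        for col in cols:
            if col.startswith("*"):
                prefix = {"*etiology_flags": "etiology_", "*procedure_flags": "proc_"}.get(
                    col, col[1:])
                flag_cols = [c for c in features.columns if c.startswith(prefix)]
                for fc in flag_cols:
                    rows.append(crosstab_compare(
                        features[fc].map({1: "yes", 0: "no", True: "yes", False: "no"}),
                        grp, feature=fc, category_order=["yes", "no"], **test_kwargs))
                continue
            if col.startswith("~"):
                name = col[1:]
                if name in features:
                    rows.append(continuous_compare(features[name], grp, feature=name))
                continue
            if col not in features:
                continue
            series = features[col]
            if series.dtype == bool or set(series.dropna().unique()) <= {0, 1, True, False}:
                series = series.map({1: "yes", 0: "no", True: "yes", False: "no"})
            rows.append(crosstab_compare(series.astype(str), grp, feature=col,
                                         **test_kwargs))
        report.tables[table_name] = rows
    report.footnotes = [
        "Each flag row is a separate statistical comparison.",
        "Chi-squared tests are uncorrected; Fisher's exact test is used for "
        "2x2 tables with an expected cell count below 5.",
        "Printed bin edges with overlapping labels are resolved "
        "left-closed/right-open (Elixhauser 0-4/5-6/7-10/>=11).",
        "No multiple-testing adjustment is applied.",
    ]
    return report


def render_report(report: ReportTables) -> str:
    """Human-readable markdown rendering of the comparison tables."""
    lines: list[str] = []
    for table_name, rows in report.tables.items():
        lines.append(f"## {table_name}")
        for r in rows:
            if isinstance(r, ContinuousResult):
                lines.append(
                    f"- {r.feature}: mean (SD) "
                    f"{r.means[0]:.2f} ({r.sds[0]:.2f}) vs "
                    f"{r.means[1]:.2f} ({r.sds[1]:.2f}), "
                    f"{r.test} p = {r.p_value:.3f}")
                continue
            ptxt = ("" if r.p_value is None
                    else ("p < 0.001" if r.p_value < 0.001 else f"p = {r.p_value:.3f}"))
            lines.append(f"- {r.feature} ({r.test}) {ptxt}")
            for cat, cnts, pcts in zip(r.categories, r.counts, r.percentages):
                cells = ", ".join(
                    f"{g}: {c} ({p})" for g, c, p in zip(r.groups, cnts, pcts))
                lines.append(f"    - {cat}: {cells}")
        lines.append("")
    lines.append("### Footnotes")
    lines.extend(f"- {fn}" for fn in report.footnotes)
    return "\n".join(lines)


def report_to_records(report: ReportTables) -> list[dict]:
    """Machine-readable flat records (for JSON/CSV export)."""
    records = []
    for table_name, rows in report.tables.items():
        for r in rows:
            if isinstance(r, ContinuousResult):
                records.append({
                    "table": table_name, "feature": r.feature, "category": None,
                    "test": r.test, "statistic": r.statistic, "p_value": r.p_value,
                    "means": list(r.means), "sds": list(r.sds),
                })
                continue
            for cat, cnts, pcts in zip(r.categories, r.counts, r.percentages):
                records.append({
                    "table": table_name, "feature": r.feature, "category": cat,
                    "test": r.test, "statistic": r.statistic,
                    "p_value": r.p_value,
                    "counts": list(cnts), "percentages": list(pcts),
                })
    return records
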