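"""SOFA scoring, shock index, comorbidity index and binning schemes."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from shockagree.severity import (SofaComponents, bin_value,
                                 default_comorbidity_map, elixhauser_index,
                                 score_sofa, shock_index)


class TestSofa:
    def test_all_normal_scores_zero(self):
        res = score_sofa(SofaComponents(
            pao2_fio2=450, platelets=250, bilirubin=0.5,
            mean_arterial_pressure=80, gcs=15, creatinine=0.8))
        assert res.total == 0
        assert res.band == "0–6"

    def test_moderate_derangement(self):
        # PF 180 without support caps respiration at 2
        res = score_sofa(SofaComponents(
            pao2_fio2=180, respiratory_support=False, platelets=90,
            bilirubin=2.5, mean_arterial_pressure=65, gcs=12, creatinine=2.2))
        assert res.subscores == {
            "respiration": 2, "coagulation": 2, "liver": 2,
            "cardiovascular": 1, "cns": 2, "renal": 2}
        assert res.total == 11
        assert res.band == "7–12"

    def test_all_missing_is_no_score(self):
        res = score_sofa(SofaComponents())
        assert res.band == "No SOFA score"
        assert res.total == 0
        assert len(res.missing) == 6

    def test_respiratory_support_unlocks_high_scores(self):
        low = score_sofa(SofaComponents(pao2_fio2=80, respiratory_support=False))
        high = score_sofa(SofaComponents(pao2_fio2=80, respiratory_support=True))
        assert low.subscores["respiration"] == 2
        assert high.subscores["respiration"] == 4

    def test_vasopressor_ladder(self):
        assert score_sofa(SofaComponents(
            vasopressors={"dobutamine": 2.0})).subscores["cardiovascular"] == 2
        assert score_sofa(SofaComponents(
            vasopressors={"norepinephrine": 0.05})).subscores["cardiovascular"] == 3
        assert score_sofa(SofaComponents(
            vasopressors={"norepinephrine": 0.3})).subscores["cardiovascular"] == 4

    def test_urine_output_floors_renal(self):
        res = score_sofa(SofaComponents(creatinine=0.8, urine_output=150))
        assert res.subscores["renal"] == 4

    @pytest.mark.parametrize("kwargs", [
        {"platelets": -1.0},
        {"gcs": 2},
        {"gcs": 16},
        {"bilirubin": -0.5},
    ])
    def test_impossible_values_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SofaComponents(**kwargs)

    @settings(max_examples=80, derandomize=True)
    @given(
        pf=hst.floats(50, 500), plt=hst.floats(5, 400), bili=hst.floats(0, 20),
        map_=hst.floats(40, 110), gcs=hst.integers(3, 15), cr=hst.floats(0.2, 8),
        organ=hst.sampled_from(["pf", "plt", "bili", "map_", "gcs", "cr"]),
    )
    def test_worsening_one_component_never_lowers_total(
            self, pf, plt, bili, map_, gcs, cr, organ):
        base = dict(pao2_fio2=pf, respiratory_support=True, platelets=plt,
                    bilirubin=bili, mean_arterial_pressure=map_, gcs=gcs,
                    creatinine=cr)
        worse = dict(base)
        key = {"pf": "pao2_fio2", "plt": "platelets", "bili": "bilirubin",
               "map_": "mean_arterial_pressure", "gcs": "gcs",
               "cr": "creatinine"}[organ]
        if key in ("bilirubin", "creatinine"):
            worse[key] = base[key] * 2  # higher is worse
        elif key == "gcs":
            worse[key] = max(3, base[key] - 4)
        else:
            worse[key] = base[key] / 2  # lower is worse
        t0 = score_sofa(SofaComponents(**base)).total
        t1 = score_sofa(SofaComponents(**worse)).total
        assert t1 >= t0


class TestShockIndex:
    @pytest.mark.parametrize("hr, sbp, ratio, band", [
        (60, 120, 0.5, "0.5–0.7"),
        (100, 100, 1.0, "0.7–1.0"),
        (110, 88, 1.25, "> 1.0"),
        (40, 120, 1 / 3, "< 0.5"),
    ])
    def test_ratio_and_band(self, hr, sbp, ratio, band):
        r, b = shock_index(hr, sbp)
        assert r == pytest.approx(ratio)
        assert b == band

    def test_nonpositive_sbp_is_unknown(self):
        with pytest.warns(UserWarning):
            r, b = shock_index(80, 0)
        assert np.isnan(r)
        assert b == "Unknown"


class TestElixhauser:
    def test_empty_codes(self):
        idx, band, _ = elixhauser_index([])
        assert idx == 0
        assert band == "0–5"

    def test_distinct_category_counting(self):
        # three categories, one hit twice -> index 3
        idx, _, diag = elixhauser_index(["I50.9", "I50.1", "I48", "E66.9"])
        assert idx == 3
        assert len(diag["matched_categories"]) == 3

    def test_many_categories_top_band(self):
        codes = ["I50", "I48", "I05", "I26", "I70", "I10", "I11", "G81",
                 "G20", "J44", "E119", "E112"]
        idx, band, _ = elixhauser_index(codes)
        assert idx == 12
        assert band == "> 10"

    def test_unmatched_codes_reported(self):
        _, _, diag = elixhauser_index(["Z99.9", "I50"])
        assert diag["unmatched_codes"] == ["Z999"]

    @settings(max_examples=40, derandomize=True)
    @given(hst.lists(hst.sampled_from(
        ["I50", "I48", "I10", "E66", "F32", "N18", "J44", "Z999", "XYZ"]),
        max_size=12))
    def test_matches_brute_force_set_oracle(self, codes):
        cmap = default_comorbidity_map()
        norm = [c.upper().replace(".", "") for c in codes]
        expected = sum(
            1 for _name, prefixes, _w in cmap.categories
            if any(code.startswith(p) for code in norm for p in prefixes))
        idx, _, _ = elixhauser_index(codes, cmap)
        assert idx == expected


class TestBinValue:
    @pytest.mark.parametrize("value, scheme, label", [
        (50, "age", "50 and under"),
        (51, "age", "51–60"),
        (81, "age", "81 and older"),
        (24.9, "bmi", "18.5–24.9"),
        (25.0, "bmi", "25.0–29.9"),
        (24.0, "time_hours", "24–48 h"),
        (96.0, "time_hours", "> 96 h"),
        (None, "time_hours", "N/A"),
        (0, "elixhauser", "0–5"),
        (5, "elixhauser", "5–6"),
        (11, "elixhauser", "> 10"),
        (4, "sepsis_score", ">= 4"),
        (None, "sepsis_score", "N/A"),
        (2, "adi_state", "1–2"),
        (24.9, "adi_national", "< 25"),
        (6, "sofa", "0–6"),
        (16, "sofa", "16–24"),
    ])
    def test_examples(self, value, scheme, label):
        assert bin_value(value, scheme) == label

    def test_unregistered_scheme(self):
        with pytest.raises(KeyError):
            bin_value(1.0, "nonesuch")

    @settings(max_examples=100, derandomize=True)
    @given(v=hst.floats(min_value=-1e6, max_value=1e6,
                        allow_nan=False, allow_infinity=False),
           scheme=hst.sampled_from(["age", "bmi", "sofa", "shock_index",
                                    "elixhauser", "adi_national", "time_hours"]))
    def test_total_function_over_finite_inputs(self, v, scheme):
        label = bin_value(v, scheme)
        assert isinstance(label, str) and label
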