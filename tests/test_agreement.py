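"""Cosine similarity, daily averages and never-agreement labels."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from shockagree.agreement import (classify_patient, clinician_day_vector,
                                  cosine_similarity, daily_average_agreement,
                                  threshold_column)
from shockagree.etiologies import ETIOLOGIES, vector_from_names

V = vector_from_names


class TestCosine:
    def test_identity(self):
        assert cosine_similarity(V(["septic"]), V(["septic"])) == 1.0

    def test_disjoint(self):
        assert cosine_similarity(V(["septic"]), V(["cardiogenic"])) == 0.0

    def test_subset(self):
        got = cosine_similarity(V(["septic"]), V(["septic", "cardiogenic"]))
        assert got == pytest.approx(1 / np.sqrt(2), abs=1e-12)

    def test_symmetric(self):
        u, v = V(["septic", "obstructive"]), V(["septic", "adrenal", "neurogenic"])
        assert cosine_similarity(u, v) == cosine_similarity(v, u)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity(V([]), V(["septic"]))

    def test_nonbinary_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity(np.full(9, 2), V(["septic"]))

    def test_one_iff_equal_sets(self):
        u, v = V(["septic", "cardiogenic"]), V(["septic", "cardiogenic"])
        assert cosine_similarity(u, v) == 1.0
        w = V(["septic", "hypovolemic"])
        assert cosine_similarity(u, w) < 1.0


class TestClinicianDayVector:
    def test_single_note_identity(self):
        assert (clinician_day_vector([V(["septic"])]) == V(["septic"])).all()

    def test_union_of_same_day_notes(self):
        got = clinician_day_vector([V(["septic"]), V(["septic", "cardiogenic"])])
        assert (got == V(["septic", "cardiogenic"])).all()

    def test_zero_notes_union_to_zero(self):
        assert clinician_day_vector([V([]), V([])]).sum() == 0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            clinician_day_vector([])


class TestDailyAverage:
    def test_two_identical(self):
        agg = daily_average_agreement({"A": V(["septic"]), "B": V(["septic"])})
        assert agg.pair_scores == (1.0,)
        assert agg.mean_score == 1.0

    def test_three_clinicians_brute_force(self):
        agg = daily_average_agreement({
            "A": V(["septic"]), "B": V(["septic"]),
            "C": V(["septic", "cardiogenic"])})
        assert agg.pair_count == 3
        assert sorted(agg.pair_scores) == pytest.approx(
            sorted([1.0, 1 / np.sqrt(2), 1 / np.sqrt(2)]))
        assert agg.mean_score == pytest.approx(0.80474, abs=1e-5)

    def test_single_nonzero_is_undefined(self):
        assert daily_average_agreement({"A": V(["septic"]), "B": V([])}) is None

    def test_zero_vectors_dropped_not_scored(self):
        agg = daily_average_agreement(
            {"A": V(["septic"]), "B": V(["septic"]), "C": V([])})
        assert agg.mean_score == 1.0
        assert agg.n_zero_vectors == 1

    @settings(max_examples=50, derandomize=True)
    @given(hst.lists(hst.sets(hst.sampled_from(ETIOLOGIES), min_size=1, max_size=4),
                     min_size=2, max_size=5),
           hst.randoms(use_true_random=False))
    def test_permutation_invariance(self, vec_sets, rnd):
        vecs = {f"C{i}": V(sorted(s)) for i, s in enumerate(vec_sets)}
        base = daily_average_agreement(vecs)
        ids = list(vecs)
        rnd.shuffle(ids)
        relabeled = {f"R{j}": vecs[cid] for j, cid in enumerate(ids)}
        perm = daily_average_agreement(relabeled)
        assert perm.mean_score == pytest.approx(base.mean_score, abs=1e-12)
        assert sorted(perm.pair_scores) == pytest.approx(sorted(base.pair_scores))


class TestClassifyPatient:
    def test_ever_agreement(self):
        lab = classify_patient([0.71, 1.0, None, 0.9, 0.71])
        assert lab.ever_agreement[1.0] is True
        assert lab.never_agreement is False

    def test_near_agreement_thresholds(self):
        lab = classify_patient([0.96, 0.96])
        assert lab.ever_agreement[1.0] is False
        assert lab.ever_agreement[0.95] is True
        assert lab.ever_agreement[0.90] is True

    def test_never_anywhere(self):
        lab = classify_patient([0.5, None, 0.5])
        assert not any(lab.ever_agreement.values())

    def test_float_noise_near_one_counts(self):
        lab = classify_patient([1.0 - 1e-12])
        assert lab.ever_agreement[1.0] is True

    def test_all_undefined_is_an_error(self):
        with pytest.raises(ValueError):
            classify_patient([None, None])

    @settings(max_examples=50, derandomize=True)
    @given(hst.lists(hst.floats(0, 1), min_size=1, max_size=5))
    def test_threshold_monotonicity(self, means):
        lab = classify_patient(means)
        assert lab.ever_agreement[1.0] <= lab.ever_agreement[0.95] \
            <= lab.ever_agreement[0.90]

    def test_threshold_column_names(self):
        assert threshold_column(1.0) == "never_agreement_100"
        assert threshold_column(0.95) == "never_agreement_095"
        assert threshold_column(0.9) == "never_agreement_090"


class TestPlantedLabelRecovery:
    def test_pipeline_labels_match_ledger(self, small_result):
        result, truth = small_result
        lab = result.labels.set_index("patient_id")["never_agreement_100"]
        for pid, rec in truth.patients.items():
            if not rec["eligible"]:
                continue
            assert bool(lab.loc[pid]) == rec["never_agreement"], pid

    def test_rates_monotone_in_threshold(self, small_result):
        result, _ = small_result
        r100 = result.never_agreement_rate(1.0)
        r095 = result.never_agreement_rate(0.95)
        r090 = result.never_agreement_rate(0.90)
        assert r100 >= r095 >= r090
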