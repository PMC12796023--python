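"""Synthetic bundle generation: determinism, planted truth, round-trips."""
import itertools

import numpy as np
import pytest

from shockagree.etiologies import ETIOLOGIES, N_ETIOLOGIES
from shockagree.note_nlp import vectorize_note
from shockagree.pipeline import analyze_bundle
from shockagree.synthetic import (ConfigurationError, GenerationError,
                                  SimulationConfig, generate_bundle,
                                  render_note)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs, field_name", [
        ({"n_patients": 0}, "n_patients"),
        ({"target_disagreement_rate": 1.5}, "target_disagreement_rate"),
        ({"target_disagreement_rate": float("nan")}, "target_disagreement_rate"),
        ({"clinician_count_mean": -1}, "clinician_count_mean"),
        ({"zero_vector_note_rate": -0.1}, "zero_vector_note_rate"),
        ({"mortality_odds_ratio_disagreement": 0}, "mortality_odds_ratio_disagreement"),
        ({"etiology_prevalence": {"septic": 0.5}}, "etiology_prevalence"),
        ({"onset_day_offset_distribution": {0: 0.5, 1: 0.2}},
         "onset_day_offset_distribution"),
    ])
    def test_errors_name_the_field(self, kwargs, field_name):
        with pytest.raises(ConfigurationError, match=field_name):
            SimulationConfig(**kwargs)


class TestDeterminism:
    def test_identical_config_and_seed_reproduces_bundle(self):
        cfg = SimulationConfig(n_patients=60, seed=9)
        b1, t1 = generate_bundle(cfg)
        b2, t2 = generate_bundle(cfg)
        for name in ("demographics", "vitals", "labs", "icd", "events", "outcomes"):
            assert getattr(b1, name).equals(getattr(b2, name)), name
        assert b1.notes == b2.notes
        assert t1.to_json() == t2.to_json()

    def test_different_seed_differs(self):
        b1, _ = generate_bundle(SimulationConfig(n_patients=60, seed=9))
        b2, _ = generate_bundle(SimulationConfig(n_patients=60, seed=10))
        assert b1.notes != b2.notes


class TestRenderNote:
    def test_zero_vector_without_flag_is_error(self):
        with pytest.raises(GenerationError):
            render_note(np.zeros(N_ETIOLOGIES, dtype=int))

    def test_empty_template_pool_is_error(self):
        vec = np.zeros(N_ETIOLOGIES, dtype=int)
        vec[0] = 1
        with pytest.raises(GenerationError):
            render_note(vec, template_pool=())

    def test_planted_septic_only(self):
        rng = np.random.default_rng(1)
        vec = np.zeros(N_ETIOLOGIES, dtype=int)
        vec[ETIOLOGIES.index("septic")] = 1
        got, _ = vectorize_note(render_note(vec, rng=rng))
        assert (got == vec).all()

    def test_negated_distractor_stays_off(self):
        rng = np.random.default_rng(2)
        vec = np.zeros(N_ETIOLOGIES, dtype=int)
        vec[ETIOLOGIES.index("septic")] = 1
        text = render_note(vec, distractors=[("cardiogenic", True)], rng=rng)
        got, diag = vectorize_note(text)
        assert (got == vec).all()
        assert any(m.etiology == "cardiogenic" and m.negated for m in diag.matches)

    def test_exhaustive_round_trip_all_nonzero_vectors(self):
        # all 2^9 - 1 nonzero planted vectors plus the zero-vector note
        rng = np.random.default_rng(7)
        for bits in itertools.product((0, 1), repeat=N_ETIOLOGIES):
            vec = np.array(bits, dtype=np.int8)
            zero = vec.sum() == 0
            text = render_note(vec, rng=rng, zero_vector_note=zero)
            got, diag = vectorize_note(text)
            assert (got == vec).all(), bits
            if zero:
                assert diag.shock_word

    def test_shock_word_present_whenever_required(self):
        rng = np.random.default_rng(3)
        vec = np.zeros(N_ETIOLOGIES, dtype=int)
        vec[ETIOLOGIES.index("adrenal")] = 1  # terms lack the bare word
        text = render_note(vec, rng=rng)
        _, diag = vectorize_note(text)
        assert diag.shock_word


class TestPlantedStructure:
    def test_clinician_count_moments(self):
        from shockagree.synthetic import _sample_clinician_count
        cfg = SimulationConfig(n_patients=1, seed=0)
        rng = np.random.default_rng(2024)
        draws = np.array([_sample_clinician_count(rng, cfg) for _ in range(3000)])
        assert draws.min() >= 2
        se_mean = cfg.clinician_count_sd / np.sqrt(draws.size)
        assert abs(draws.mean() - cfg.clinician_count_mean) < 3 * se_mean
        assert abs(draws.std(ddof=1) - cfg.clinician_count_sd) < 0.25

    def test_note_ids_unique_and_ledgered(self, small_bundle):
        bundle, truth = small_bundle
        ids = [n["note_id"] for n in bundle.notes]
        assert len(ids) == len(set(ids))
        assert set(ids) == set(truth.note_vectors)

    def test_planted_note_vectors_recovered_by_extraction(self, small_bundle):
        bundle, truth = small_bundle
        for note in bundle.notes:
            got, _ = vectorize_note(note["text"])
            assert list(map(int, got)) == truth.note_vectors[note["note_id"]], \
                note["note_id"]

    def test_eligible_patients_have_day0_pair(self, small_bundle):
        bundle, truth = small_bundle
        by_pid = {}
        for n in bundle.notes:
            by_pid.setdefault(n["patient_id"], []).append(n)
        for pid, rec in truth.patients.items():
            if not rec["eligible"]:
                continue
            day0 = rec["onset_day"]
            writers = {n["clinician_id"] for n in by_pid[pid]
                       if n["timestamp"].startswith(day0)}
            assert len(writers) >= 2, pid

    def test_zero_disagreement_config_yields_full_agreement(self):
        cfg = SimulationConfig(n_patients=80, seed=13,
                               target_disagreement_rate=0.0,
                               zero_vector_note_rate=0.0)
        bundle, _ = generate_bundle(cfg)
        result = analyze_bundle(bundle, run_stats=False)
        assert result.labels["never_agreement_100"].sum() == 0

    def test_mortality_differential_planted(self):
        cfg = SimulationConfig(n_patients=1500, seed=77, ineligible_rate=0.0)
        bundle, truth = generate_bundle(cfg)
        died = bundle.outcomes.set_index("patient_id")["in_hospital_death"]
        rates = {True: [], False: []}
        for pid, rec in truth.patients.items():
            rates[rec["never_agreement"]].append(died.loc[pid])
        assert np.mean(rates[True]) > np.mean(rates[False])
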