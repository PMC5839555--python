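"""Synthetic study generator: determinism, truth model, exact-count planting."""

from datetime import date

import numpy as np
import pytest

from cannaphen.classify import Label, classify_cohort
from cannaphen.ehr import CohortSpec, read_notes, read_patients, select_cohort
from cannaphen.exposure import Mode, read_exposures
from cannaphen.lexicon import default_lexicon
from cannaphen.simulate import (
    PlantedCounts,
    SimulationConfig,
    generate_interviews,
    generate_planted_study,
    generate_study,
    read_truth,
)
from cannaphen.validation import disposition_from_interviews, read_interviews

INDEX = date(2015, 12, 31)


def classify_study(study):
    cohort = select_cohort(study.patients, CohortSpec())
    return classify_cohort(cohort, study.notes, default_lexicon(), INDEX)


class TestProbabilisticMode:
    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError, match="probability"):
            SimulationConfig(p_ever_use=1.2)

    def test_registry_passes_cohort_filters(self):
        study = generate_study(SimulationConfig(n_patients=50, seed=3))
        assert len(select_cohort(study.patients, CohortSpec())) == 50

    def test_noiseless_limit_recovers_truth_exactly(self):
        """With perfect documentation and no false-positive terms, the
        classifier arms partition past-year users vs everyone else."""
        cfg = SimulationConfig(
            n_patients=150,
            p_documented_given_past_year_use=1.0,
            p_term_given_no_past_year_use=0.0,
            seed=9,
        )
        study = generate_study(cfg)
        got_users = {
            c.patient_id
            for c in classify_study(study)
            if c.label is Label.PRELIMINARY_USER
        }
        true_users = {t.patient_id for t in study.truths if t.past_year}
        assert got_users == true_users

    def test_classifier_recovers_documented_flag(self):
        """In-window mentions occur iff the truth record says documented;
        historical mentions and confounders never flip a label."""
        study = generate_study(SimulationConfig(n_patients=200, seed=4))
        labels = {c.patient_id: c.label for c in classify_study(study)}
        for t in study.truths:
            expected = Label.PRELIMINARY_USER if t.documented else Label.PRELIMINARY_NONUSER
            assert labels[t.patient_id] is expected

    def test_same_seed_identical_study(self):
        a = generate_study(SimulationConfig(n_patients=40, seed=12))
        b = generate_study(SimulationConfig(n_patients=40, seed=12))
        assert a.patients == b.patients
        assert a.notes == b.notes
        assert a.truths == b.truths

    def test_truth_nesting_holds(self):
        study = generate_study(SimulationConfig(n_patients=300, seed=2))
        for t in study.truths:
            assert (not t.past_30d or t.past_year) and (not t.past_year or t.ever)

    def test_negated_false_positive_contribution_monotone(self):
        """Negated mentions are detected by design: as the negation-phrasing
        rate rises, more of the false-positive patients owe their label to a
        negation-phrased sentence (the method's documented limitation)."""
        cues = ("denies", "no current", "quit")
        counts = []
        for rate in (0.0, 0.5, 1.0):
            cfg = SimulationConfig(n_patients=400, negated_mention_rate=rate, seed=21)
            study = generate_study(cfg)
            fp_ids = {t.patient_id for t in study.truths if t.documented and not t.past_year}
            negated_fp = {
                n.patient_id
                for n in study.notes
                if n.patient_id in fp_ids
                and any(c in n.text.lower() for c in cues)
            }
            counts.append(len(negated_fp))
        assert counts[0] == 0
        assert counts[0] <= counts[1] <= counts[2]
        assert counts[2] > 0


class TestGenerateInterviews:
    def test_misreport_zero_equals_truth(self):
        study = generate_study(SimulationConfig(n_patients=60, seed=8))
        ivs = generate_interviews(study.truths, completion_rate=1.0, misreport_rate=0.0, seed=8)
        for t, iv in zip(study.truths, ivs):
            assert (iv.used_past_30d, iv.used_past_year, iv.ever_used) == (
                t.past_30d, t.past_year, t.ever,
            )

    def test_zero_completion_rate(self):
        study = generate_study(SimulationConfig(n_patients=30, seed=8))
        ivs = generate_interviews(study.truths, completion_rate=0.0, seed=8)
        assert not any(iv.completed for iv in ivs)

    def test_completion_count_matches_binomial_expectation(self):
        """97 contactable at completion rate 0.71: mean completions over many
        seeds approximates 97 x 0.71 = 68.87 within 3 standard errors."""
        study = generate_study(SimulationConfig(n_patients=97, seed=1))
        n_seeds, p = 200, 0.71
        totals = [
            sum(iv.completed for iv in generate_interviews(study.truths, p, seed=s))
            for s in range(n_seeds)
        ]
        se_mean = np.sqrt(97 * p * (1 - p) / n_seeds)
        assert abs(np.mean(totals) - 97 * p) < 3 * se_mean

    def test_nesting_reimposed_after_flips(self):
        study = generate_study(SimulationConfig(n_patients=100, seed=5))
        ivs = generate_interviews(study.truths, 1.0, misreport_rate=0.4, seed=5)
        for iv in ivs:
            assert (not iv.used_past_30d or iv.used_past_year)
            assert (not iv.used_past_year or iv.ever_used)

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            generate_interviews([], completion_rate=1.5)


class TestPlantedMode:
    def test_planted_counts_are_exact(self, planted_study):
        counts = PlantedCounts()
        patients = read_patients(planted_study / "patients.csv")
        cohort = select_cohort(patients, CohortSpec())
        assert len(cohort) == counts.n_cohort
        assert len(patients) == counts.n_cohort + counts.n_decoys

        cls = classify_cohort(
            cohort, read_notes(planted_study / "notes.jsonl"), default_lexicon(), INDEX
        )
        n_users = sum(c.label is Label.PRELIMINARY_USER for c in cls)
        assert n_users == counts.n_term_positive

        responses, frame = read_interviews(planted_study / "interviews.csv")
        completed = [iv for iv in responses if iv.completed]
        assert len(completed) == 69
        d = disposition_from_interviews(frame)
        assert (d.contacted, d.completed, d.refused_by_message,
                d.refused_on_call, d.unreachable) == (97, 69, 1, 20, 7)

    def test_truth_consistent_with_interviews(self, planted_study):
        truth = {t.patient_id: t for t in read_truth(planted_study / "truth.csv")}
        responses, _ = read_interviews(planted_study / "interviews.csv")
        for iv in responses:
            if iv.completed:
                t = truth[iv.patient_id]
                assert (t.past_30d, t.past_year, t.ever) == (
                    iv.used_past_30d, iv.used_past_year, iv.ever_used,
                )

    def test_exposures_cover_current_users(self, planted_study):
        records = read_exposures(planted_study / "exposures.csv")
        counts = PlantedCounts()
        assert len(records) == counts.n_current_users
        smokers = [r for r in records if r.primary_mode is Mode.SMOKED]
        assert len(smokers) == counts.n_predominantly_smoked
        responses, _ = read_interviews(planted_study / "interviews.csv")
        current = {iv.patient_id for iv in responses if iv.completed and iv.used_past_30d}
        assert {r.patient_id for r in records} == current

    def test_fixed_seed_byte_identical(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        generate_planted_study(a, seed=13)
        generate_planted_study(b, seed=13)
        for name in ("patients.csv", "notes.jsonl", "truth.csv",
                     "interviews.csv", "exposures.csv"):
            assert (a / name).read_bytes() == (b / name).read_bytes()

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError, match="nesting"):
            PlantedCounts(cells_term_positive=(20, 17, 2, 33))
        with pytest.raises(ValueError, match="absorb"):
            PlantedCounts(refused_on_call=19)
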