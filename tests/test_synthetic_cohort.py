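"""Fixture margins, simulator behaviour and reproducibility."""

from collections import Counter

import pytest
from pydantic import ValidationError

from lynchtriage import (
    GermlineOutcome,
    MethylationStatus,
    MsiStatus,
    SimulationParams,
    call_ihc_pattern,
    call_methylation,
    call_msi,
    cascade_summary,
    default_params,
    expected_prevalence,
    paper_fixture,
    simulate_cohort,
    triage_cohort,
)
from lynchtriage.triage import TriageLabel


class TestPaperFixture:
    def test_cohort_size(self, fixture_cohort):
        assert len(fixture_cohort) == 173
        assert len({p.patient_id for p in fixture_cohort}) == 173

    def test_assay_margins(self, fixture_cohort):
        patterns = [call_ihc_pattern(p.ihc) for p in fixture_cohort]
        msi = [call_msi(p.msi) for p in fixture_cohort]
        n_loss = sum(bool(pt.lost) for pt in patterns)
        n_msi = sum(m.status is MsiStatus.MSI for m in msi)
        assert n_loss == 58
        assert n_msi == 47
        n_loss_mss = sum(
            bool(pt.lost) and m.status is MsiStatus.MSS
            for pt, m in zip(patterns, msi)
        )
        n_msi_intact = sum(
            not pt.lost and m.status is MsiStatus.MSI
            for pt, m in zip(patterns, msi)
        )
        assert n_loss_mss == 14
        assert n_msi_intact == 3
        assert sum("MLH1" in pt.lost for pt in patterns) == 44

    def test_methylation_margins(self, fixture_cohort):
        mlh1_loss = [
            p for p in fixture_cohort if "MLH1" in call_ihc_pattern(p.ihc).lost
        ]
        assert all(p.meth_tumor is not None for p in mlh1_loss)
        methylated = [
            p for p in mlh1_loss
            if call_methylation(p.meth_tumor) is MethylationStatus.METHYLATED
        ]
        assert len(methylated) == 34
        with_blood = [p for p in methylated if p.meth_blood is not None]
        assert len(with_blood) == 9
        assert all(
            call_methylation(p.meth_blood) is MethylationStatus.UNMETHYLATED
            for p in with_blood
        )

    def test_suspected_pattern_counts(self, fixture_summary):
        assert fixture_summary.pattern_counts == {
            "mlh1_unmethylated": 10,
            "msh2_msh6": 5,
            "msh6": 7,
            "pms2": 1,
            "msh6_pms2": 1,
            "msi_normal_ihc": 3,
        }
        assert fixture_summary.n_suspected == 27

    def test_germline_margins(self, fixture_cohort):
        tested = [
            p for p in fixture_cohort
            if any(r.outcome is not GermlineOutcome.NOT_DONE for r in p.germline)
        ]
        carriers = [
            p for p in fixture_cohort
            if any(r.outcome is GermlineOutcome.PATHOGENIC for r in p.germline)
        ]
        assert len(tested) == 19
        assert len(carriers) == 8
        genes = Counter(
            r.gene for p in carriers for r in p.germline
            if r.outcome is GermlineOutcome.PATHOGENIC
        )
        assert genes == {"MLH1": 1, "MSH2": 3, "MSH6": 3, "PMS2": 1}
        assert sorted(p.age for p in carriers) == [40, 41, 44, 45, 45, 56, 60, 61]

    def test_carrier_records_verbatim(self, fixture_cohort):
        end131 = fixture_cohort.by_id("End131")
        assert call_ihc_pattern(end131.ihc).lost == {"MLH1", "PMS2"}
        assert call_msi(end131.msi).status is MsiStatus.MSI
        assert end131.age == 41 and end131.rbg is True
        end088 = fixture_cohort.by_id("End088")
        assert call_ihc_pattern(end088.ihc).lost == {"MSH6"}
        assert call_msi(end088.msi).status is MsiStatus.MSS
        end137 = fixture_cohort.by_id("End137")
        assert call_ihc_pattern(end137.ihc).lost == frozenset()
        assert call_msi(end137.msi).status is MsiStatus.MSI
        assert end137.synchronous_ovarian is False

    def test_family_history_margins(self, fixture_cohort):
        known = [p for p in fixture_cohort if p.family_history_known]
        assert len(known) == 87
        assert sum(bool(p.rbg) for p in known) == 38
        assert sum(bool(p.amii) for p in known) == 4
        assert all(p.rbg is None for p in fixture_cohort
                   if not p.family_history_known)

    def test_pathology_margins(self, fixture_cohort):
        stage = Counter(p.stage for p in fixture_cohort)
        assert stage == {"I": 119, "II": 6, "III": 31, "IV": 2, None: 15}
        hist = Counter(p.histology for p in fixture_cohort)
        assert hist["endometrioid"] == 137
        myo = Counter(p.myometrial_invasion for p in fixture_cohort)
        assert myo == {"none": 15, "<=50%": 93, ">50%": 38, None: 27}
        assert sum(bool(p.til) for p in fixture_cohort) == 47
        assert sum(p.til is None for p in fixture_cohort) == 13
        assert sum(bool(p.lvi) for p in fixture_cohort) == 24
        assert sum(bool(p.lus) for p in fixture_cohort) == 16
        ovarian = Counter(p.synchronous_ovarian for p in fixture_cohort)
        assert ovarian == {False: 126, True: 26, None: 21}

    def test_deterministic_and_idempotent(self, fixture_cohort):
        again = paper_fixture()
        assert again.patients == fixture_cohort.patients
        d1 = triage_cohort(fixture_cohort)
        d2 = triage_cohort(again)
        assert d1 == d2


class TestSimulationParams:
    def test_defaults_are_the_observed_frequencies(self):
        p = default_params()
        assert p.p_pathogenic_given_tested == pytest.approx(8 / 19)
        assert p.p_tested_given_suspected == pytest.approx(19 / 27)
        assert p.p_methylated_given_mlh1_loss == pytest.approx(34 / 44)
        assert p.p_deficient == pytest.approx(61 / 173)
        assert sum(p.pattern_weights.values()) == pytest.approx(1.0)

    def test_invalid_probability_lists_field(self):
        with pytest.raises(ValidationError, match="p_deficient"):
            SimulationParams(p_deficient=1.4)

    def test_bad_pattern_weights_rejected(self):
        with pytest.raises(ValidationError, match="sum to 1"):
            SimulationParams(pattern_weights={"msh6": 0.5, "pms2": 0.2})
        with pytest.raises(ValidationError, match="unknown pattern"):
            SimulationParams(pattern_weights={"braf": 1.0})

    def test_expected_prevalence_matches_observed_rate_at_defaults(self):
        assert expected_prevalence(default_params()) == pytest.approx(8 / 173)


class TestSimulateCohort:
    def test_seed_determinism(self):
        p = default_params().model_copy(update={"seed": 11})
        assert simulate_cohort(p).patients == simulate_cohort(p).patients
        other = simulate_cohort(default_params().model_copy(update={"seed": 12}))
        assert other.patients != simulate_cohort(p).patients

    def test_no_deficiency_means_no_cascade(self):
        p = default_params().model_copy(update={"p_deficient": 0.0, "seed": 1})
        cohort = simulate_cohort(p)
        s = cascade_summary(triage_cohort(cohort), [x.germline for x in cohort])
        assert s.n_mmr_deficient == 0
        assert s.n_suspected == 0
        assert s.n_pathogenic == 0

    def test_assays_reproduce_the_simulated_category(self):
        """Triage over raw simulated assays never mislabels a sporadic case."""
        for seed in range(10):
            p = default_params().model_copy(update={"seed": seed})
            cohort = simulate_cohort(p)
            decisions = triage_cohort(cohort)
            for patient, d in zip(cohort, decisions):
                assert d.label is not TriageLabel.PENDING_METHYLATION
                assert d.label is not TriageLabel.UNRESOLVABLE
                if (
                    patient.meth_tumor is not None
                    and call_methylation(patient.meth_tumor)
                    is MethylationStatus.METHYLATED
                ):
                    assert d.label is TriageLabel.SPORADIC_METHYLATED

    def test_ages_respect_the_truncation_range(self):
        cohort = simulate_cohort(default_params().model_copy(update={"seed": 5}))
        assert all(29 <= p.age <= 90 for p in cohort)

    def test_full_testing_uptake_equates_prevalence_and_suspected_yield(self):
        p = default_params().model_copy(
            update={"p_tested_given_suspected": 1.0,
                    "p_pathogenic_given_tested": 1.0, "seed": 2}
        )
        cohort = simulate_cohort(p)
        s = cascade_summary(triage_cohort(cohort), [x.germline for x in cohort])
        assert s.n_pathogenic == s.n_suspected
        assert s.prevalence_observed == pytest.approx(s.n_suspected / s.n_total)
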