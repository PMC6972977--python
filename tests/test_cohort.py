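"""Severity stratification, spectrum counts and diagnostic yield."""

import pandas as pd
import pytest

from myh9rd.cohort import (
    PatientRecord,
    attribute_domain,
    domain_phenotype_table,
    new_diagnosis_count,
    severity_group,
    spectrum_summary,
    thrombocytopenia_flag,
)


class TestSeverity:
    @pytest.mark.parametrize(
        "count, expected",
        [(8, "severe_moderate"), (50, "severe_moderate"), (51, "mild"), (220, "mild")],
    )
    def test_split_at_50(self, count, expected):
        assert severity_group(count) == expected

    def test_missing_count_excluded(self):
        assert severity_group(None) is None

    @pytest.mark.parametrize(
        "count, expected", [(54, True), (149, True), (150, False), (187, False)]
    )
    def test_thrombocytopenia_strictly_below_150(self, count, expected):
        assert thrombocytopenia_flag(count) is expected


def _patient(pid, fam, vids, status="unclassified_platelet_disorder", **kwargs):
    return PatientRecord(
        patient_id=pid, family_id=fam, variant_ids=vids, enrollment_status=status,
        **kwargs,
    )


class TestSpectrum:
    def _table(self):
        return pd.DataFrame(
            [
                {"patient_id": "1", "family_id": "F1", "hgvs_c": "c.97T>G",
                 "hgvs_p": "p.(Trp33Gly)", "exon": 2},
                {"patient_id": "2", "family_id": "F1", "hgvs_c": "c.97T>G",
                 "hgvs_p": "p.(Trp33Gly)", "exon": 2},
                {"patient_id": "3", "family_id": "F2", "hgvs_c": "c.97T>G",
                 "hgvs_p": "p.(Trp33Gly)", "exon": 2},
                {"patient_id": "4", "family_id": "F2", "hgvs_c": "c.97T>G",
                 "hgvs_p": "p.(Trp33Gly)", "exon": 2},
                {"patient_id": "5", "family_id": "F3", "hgvs_c": "c.5797C>T",
                 "hgvs_p": "p.(Arg1933*)", "exon": 41},
            ]
        )

    def test_variant_shared_by_relatives_counts_once(self):
        summary = spectrum_summary(self._table(), known_hgvs_p=["p.(Arg1933*)"])
        assert summary["n_unique_variants"] == 2
        assert summary["n_novel"] == 1
        assert summary["n_patients"] == 5
        assert summary["distinct_families"] == 3
        assert summary["consequence_counts"] == {"missense": 1, "stop_gain": 1}
        assert summary["domain_counts"] == {"HD": 1, "NHTD": 1}

    def test_invariant_under_row_order_and_duplication(self):
        table = self._table()
        shuffled = table.sample(frac=1, random_state=3)
        duplicated = pd.concat([table, table.iloc[[0]]], ignore_index=True)
        base = spectrum_summary(table, known_hgvs_p=[])
        assert spectrum_summary(shuffled, known_hgvs_p=[]) == base
        assert spectrum_summary(duplicated, known_hgvs_p=[]) == base

    def test_planted_registry_overlap_sets_novel_count(self):
        summary = spectrum_summary(
            self._table(), known_hgvs_p=["p.(Trp33Gly)", "p.(Arg1933*)"]
        )
        assert summary["n_novel"] == 0

    def test_missing_columns_raise(self):
        with pytest.raises(ValueError):
            spectrum_summary(pd.DataFrame({"hgvs_c": []}), known_hgvs_p=[])


class TestDiagnosticYield:
    def _cohort(self):
        return [
            _patient("1", "F1", ["V1"], "unclassified_platelet_disorder"),
            _patient("2", "F2", ["V2"], "suspected_MYH9RD"),
            _patient("3", "F3", ["V3"], "known_MYH9RD_unconfirmed"),
            _patient("4", "F4", ["V4"], "unclassified_platelet_disorder"),
        ]

    def test_counts_only_new_diagnoses(self):
        classes = {"1": "pathogenic", "2": "likely_pathogenic",
                   "3": "pathogenic", "4": "VUS"}
        assert new_diagnosis_count(self._cohort(), classes) == 2

    def test_known_only_cohort_yields_zero(self):
        cohort = [_patient(str(i), f"F{i}", ["V"], "known_MYH9RD_unconfirmed")
                  for i in range(5)]
        assert new_diagnosis_count(cohort, {str(i): "pathogenic" for i in range(5)}) == 0

    def test_monotone_under_vus_upgrades(self):
        cohort = self._cohort()
        classes = {"1": "VUS", "2": "VUS", "3": "VUS", "4": "VUS"}
        baseline = new_diagnosis_count(cohort, classes)
        for pid in classes:
            upgraded = dict(classes, **{pid: "likely_pathogenic"})
            assert new_diagnosis_count(cohort, upgraded) >= baseline

    def test_missing_class_skipped(self):
        assert new_diagnosis_count(self._cohort(), {}) == 0


class TestDomainAttribution:
    def test_higher_class_wins(self):
        patient = _patient("39", "F34", ["Va", "Vb"])
        vid, dom = attribute_domain(
            patient,
            variant_domains={"Va": "HD", "Vb": "TD"},
            variant_residues={"Va": 921, "Vb": 100},
            final_classes={"Va": "VUS", "Vb": "pathogenic"},
        )
        assert (vid, dom) == ("Vb", "TD")

    def test_tie_breaks_toward_higher_residue(self):
        patient = _patient("39", "F34", ["Va", "Vb"])
        vid, dom = attribute_domain(
            patient,
            variant_domains={"Va": "TD", "Vb": "TD"},
            variant_residues={"Va": 921, "Vb": 1649},
            final_classes={"Va": "VUS", "Vb": "VUS"},
        )
        assert vid == "Vb"


class TestDomainPhenotypeTable:
    def test_single_patient_fractions_and_partition(self):
        patients = [
            _patient("1", "F1", ["V1"], platelet_count=30.0, hearing_impairment=True),
            _patient("2", "F2", ["V2"], platelet_count=80.0, hearing_impairment=False),
            _patient("3", "F3", ["V3"], platelet_count=40.0),  # hearing unknown
        ]
        domains = {"V1": "HD", "V2": "TD", "V3": "TD"}
        residues = {"V1": 100, "V2": 1000, "V3": 1200}
        classes = {"V1": "pathogenic", "V2": "VUS", "V3": "VUS"}
        pheno, severity = domain_phenotype_table(patients, domains, residues, classes)
        assert pheno["hearing_impairment"]["HD"] == (1, 1)
        # patient 2 is an observed negative; patient 3's unknown flag drops
        # out of the denominator entirely
        assert pheno["hearing_impairment"]["TD"] == (0, 1)
        # severity strata partition the patients with known counts
        for group, row in severity.items():
            total = sum(num for num, _ in row.values())
            dens = {den for _, den in row.values()}
            assert dens == {total}
        assert severity["severe_moderate"] == {"HD": (1, 2), "TD": (1, 2)}
        assert severity["mild"] == {"TD": (1, 1)}


class TestPatientRecordValidation:
    def test_requires_a_variant(self):
        with pytest.raises(ValueError):
            _patient("1", "F1", [])

    def test_rejects_unknown_status(self):
        with pytest.raises(ValueError):
            _patient("1", "F1", ["V1"], status="walk_in")

    def test_thrombocytopenia_derived_from_count(self):
        assert _patient("1", "F1", ["V1"], platelet_count=54.0).thrombocytopenia is True
        assert _patient("2", "F1", ["V1"], platelet_count=187.0).thrombocytopenia is False
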