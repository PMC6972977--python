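"""Evidence parsing, combining, policy and per-variant evidence assignment."""

import pytest

from myh9rd.acmg import (
    DESCRIPTIVE,
    MODERATE,
    STRONG,
    SUPPORTING,
    EnginePolicy,
    EvidenceCode,
    KnownVariantRegistry,
    apply_policy,
    assign_evidence,
    classify_benign_counts,
    combine_evidence,
    contribution_assignment,
    format_evidence_code,
    parse_evidence_string,
    parse_evidence_token,
    Classification,
)
from myh9rd.cohort import PatientRecord
from myh9rd.hgvs import (
    PopulationFrequency,
    VariantAnnotations,
    VariantRecord,
    parse_hgvs_c,
    parse_hgvs_p,
)


def _codes(text):
    return parse_evidence_string(text)


class TestEvidenceParsing:
    def test_modulated_tokens(self):
        ps4s = parse_evidence_token("PS4_supporting")
        assert (ps4s.base, ps4s.level, ps4s.modulated) == ("PS4", SUPPORTING, True)
        pp1s = parse_evidence_token("PP1_strong")
        assert (pp1s.base, pp1s.level, pp1s.modulated) == ("PP1", STRONG, True)

    def test_pm4_substitution_marker(self):
        code = parse_evidence_token("#PM4")
        assert code.base == "PM4"
        assert code.level == MODERATE
        assert code.substituted_for == "PVS1"
        assert format_evidence_code(code) == "#PM4"

    def test_descriptive_codes(self):
        assert parse_evidence_token("A").level == DESCRIPTIVE
        assert parse_evidence_token("B").side == "descriptive"

    @pytest.mark.parametrize("bad", ["PX9", "#PS4", "PM2_gigantic", "pm2", ""])
    def test_malformed_tokens_raise(self, bad):
        with pytest.raises(ValueError):
            parse_evidence_token(bad)

    def test_printed_string_roundtrip(self):
        text = "PS4, #PM4, PM2, PM1, PP4, A"
        codes = _codes(text)
        assert ", ".join(format_evidence_code(c) for c in codes) == text


class TestCombining:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("PS4, PS3, PM1, PM2, PP4, PP3", "pathogenic"),
            ("PM2, PM5, PP3, PP4", "likely_pathogenic"),
            ("PM2", "VUS"),
            ("", "VUS"),
            ("PS4, PM2, PP1_strong, PP4, PP3", "pathogenic"),  # two strong codes
            ("PS4_supporting, PM2, PP4, PP3", "VUS"),  # modulation demotes PS4
            ("PVS1, PM2", "likely_pathogenic"),
            ("PVS1, PM2, PP4", "pathogenic"),
            ("PS4, #PM4, PM2, PM1, PP4", "pathogenic"),  # 1 strong + 3 moderate
            ("PM2, PM4, PP4", "VUS"),  # 2 moderate + 1 supporting falls short
            ("PM2, A, B", "VUS"),  # descriptive codes never count
        ],
    )
    def test_printed_evidence_combinations(self, text, expected):
        assert combine_evidence(_codes(text)) == expected

    def test_symmetry_under_reordering(self):
        text = "PS4, PM2, PP1_strong, PP4, PP3"
        codes = _codes(text)
        assert combine_evidence(codes) == combine_evidence(list(reversed(codes)))

    def test_conflicting_sides_resolve_to_vus(self):
        codes = _codes("PVS1, PM2, PP4") + [
            EvidenceCode("BS1", STRONG), EvidenceCode("BS2", STRONG)
        ]
        assert combine_evidence(codes) == "VUS"

    def test_benign_side_rules(self):
        assert classify_benign_counts(1, 0, 0) == "benign"
        assert classify_benign_counts(0, 2, 0) == "benign"
        assert classify_benign_counts(0, 1, 1) == "likely_benign"
        assert classify_benign_counts(0, 0, 2) == "likely_benign"
        assert classify_benign_counts(0, 1, 0) == "VUS"


class TestConservativeNovelPolicy:
    def test_novel_truncation_without_corroboration_is_capped(self):
        codes = _codes("PM2, PVS1, PP4, A")
        strict = combine_evidence(codes)
        assert strict == "pathogenic"
        result = apply_policy(strict, codes, novel=True)
        assert result.klass == "VUS"
        assert result.policy_applied == "conservative_novel_cap"
        assert any(rule == "conservative_novel_cap" for rule, _ in result.audit)

    def test_novel_missense_with_de_novo_support_is_capped(self):
        codes = _codes("PM6, PM2, PP3, PP4, A")
        assert combine_evidence(codes) == "likely_pathogenic"
        assert apply_policy("likely_pathogenic", codes, novel=True).klass == "VUS"

    @pytest.mark.parametrize(
        "text",
        [
            "PM2, PM5, PP3, PP4, A",   # same-residue pathogenic precedent
            "PM2, PM4, PM1, PP4, A",   # mutational hotspot
            "PS3, PM2, PM4, PP4",      # functional evidence
            "PS4, PM2, PM4, PP4",      # strong-level code
        ],
    )
    def test_corroboration_lifts_the_cap(self, text):
        codes = _codes(text)
        strict = combine_evidence(codes)
        assert strict == "likely_pathogenic"
        result = apply_policy(strict, codes, novel=True)
        assert result.klass == strict
        assert result.policy_applied is None

    def test_known_variants_are_never_capped(self):
        codes = _codes("PVS1, PM2, PP4")
        assert apply_policy("pathogenic", codes, novel=False).klass == "pathogenic"

    def test_policy_toggle(self):
        codes = _codes("PM2, PVS1, PP4")
        policy = EnginePolicy(conservative_novel_cap=False)
        assert apply_policy("pathogenic", codes, True, policy).klass == "pathogenic"


def _patient(**kwargs):
    defaults = dict(
        patient_id="P1", family_id="F1", variant_ids=["V1"],
        enrollment_status="unclassified_platelet_disorder",
        macrothrombocytes=True,
    )
    defaults.update(kwargs)
    return PatientRecord(**defaults)


class TestContribution:
    def test_macrothrombocytopenia_gives_full(self):
        c = Classification(klass="VUS")
        assert contribution_assignment(c, _patient(platelet_count=54.0)) == "full"

    def test_normal_count_with_inclusions_only_is_uncertain(self):
        patient = _patient(platelet_count=220.0, dohle_bodies="reported")
        assert contribution_assignment(Classification("VUS"), patient) == "uncertain"

    def test_normal_count_rescued_by_family_history(self):
        patient = _patient(platelet_count=187.0, family_history_myh9rd=True)
        assert contribution_assignment(Classification("pathogenic"), patient) == "full"

    def test_no_phenotype_data_is_uncertain(self):
        patient = _patient(macrothrombocytes=None)
        assert contribution_assignment(Classification("VUS"), patient) == "uncertain"
        assert contribution_assignment(Classification("VUS"), None) == "uncertain"


def _variant(hgvs_c, hgvs_p, exon, novel=True, **ann):
    return VariantRecord(
        id="test",
        coding_change=parse_hgvs_c(hgvs_c),
        protein_change=parse_hgvs_p(hgvs_p),
        exon=exon,
        novel_flag=novel,
        annotations=VariantAnnotations(**ann),
        frequencies=PopulationFrequency(),
    )


FULL_PREDICTOR_SUPPORT = dict(
    nucleotide_conserved=True, aminoacid_conserved=True, protein_effect_predicted=True,
    gvgd_class="C65", sift_call="deleterious", polyphen_call="deleterious",
    mutation_taster_call="deleterious",
)


class TestAssignEvidence:
    def test_early_truncation_gets_pvs1(self):
        variant = _variant("c.2668delC", "p.(Gln890Arg*)", 22)
        patient = _patient(phenotype_specific=True, dohle_bodies="reported")
        bases = {c.base for c in assign_evidence(variant, patient)}
        assert bases == {"PVS1", "PM2", "PP4", "A"}

    def test_last50_truncation_gets_pm4_substitution_and_hotspot(self):
        variant = _variant(
            "c.5770_5779delGGGGACCTGC", "p.(Gly1924Argfs*21)", 41,
            novel=False, prevalence_evidence="strong",
        )
        patient = _patient(phenotype_specific=True, dohle_bodies="reported")
        codes = assign_evidence(variant, patient)
        rendered = {format_evidence_code(c) for c in codes}
        assert rendered == {"PS4", "#PM4", "PM1", "PM2", "PP4", "A"}

    def test_registry_hit_and_full_predictor_concordance(self):
        registry = KnownVariantRegistry([("p.(Trp33Cys)", 33, "pathogenic")])
        variant = _variant("c.97T>G", "p.(Trp33Gly)", 2, **FULL_PREDICTOR_SUPPORT)
        patient = _patient(phenotype_specific=True, dohle_bodies="reported")
        bases = {c.base for c in assign_evidence(variant, patient, registry=registry)}
        assert bases == {"PM2", "PM5", "PP3", "PP4", "A"}

    def test_pp3_withheld_when_any_predictor_is_missing(self):
        ann = dict(FULL_PREDICTOR_SUPPORT)
        ann["polyphen_call"] = None
        variant = _variant("c.97T>G", "p.(Trp33Gly)", 2, **ann)
        bases = {c.base for c in assign_evidence(variant, _patient())}
        assert "PP3" not in bases

    def test_pp3_conjunction_fails_on_disagreement(self):
        ann = dict(FULL_PREDICTOR_SUPPORT)
        ann["gvgd_class"] = "C0"
        variant = _variant("c.97T>G", "p.(Trp33Gly)", 2, **ann)
        assert "PP3" not in {c.base for c in assign_evidence(variant, _patient())}

    def test_inframe_change_gets_pm4(self):
        variant = _variant("c.108_116delCGACAAGAG", "p.(Asp37_Ser39del)", 2)
        bases = {c.base for c in assign_evidence(variant, _patient())}
        assert "PM4" in bases and "PVS1" not in bases

    def test_de_novo_tiers(self):
        confirmed = _variant("c.97T>G", "p.(Trp33Gly)", 2, de_novo_status="confirmed")
        assumed = _variant("c.97T>G", "p.(Trp33Gly)", 2, de_novo_status="assumed")
        assert "PS2" in {c.base for c in assign_evidence(confirmed)}
        assert "PM6" in {c.base for c in assign_evidence(assumed)}

    @pytest.mark.parametrize(
        "meioses, level", [(0, None), (2, SUPPORTING), (4, MODERATE), (7, STRONG)]
    )
    def test_cosegregation_strength_tiers(self, meioses, level):
        variant = _variant("c.97T>G", "p.(Trp33Gly)", 2)
        codes = assign_evidence(variant, informative_meioses=meioses)
        pp1 = [c for c in codes if c.base == "PP1"]
        if level is None:
            assert not pp1
        else:
            assert pp1[0].level == level

    def test_common_variant_gets_no_pm2(self):
        variant = _variant("c.97T>G", "p.(Trp33Gly)", 2)
        variant.frequencies.af_gnomad = 0.01
        assert "PM2" not in {c.base for c in assign_evidence(variant)}
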