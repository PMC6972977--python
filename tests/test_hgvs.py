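"""Variant-notation parsing, formatting and truncation arithmetic."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from myh9rd.hgvs import (
    CodingKind,
    Consequence,
    HgvsParseError,
    ProteinChange,
    ProteinKind,
    classify_consequence,
    format_hgvs_c,
    format_hgvs_p,
    parse_hgvs_c,
    parse_hgvs_p,
    residues_removed,
    termination_position,
    truncated_length,
)

REF_LEN = 1960


def translation_oracle(change: ProteinChange, ref_len: int = REF_LEN) -> int:
    """Independent string-level oracle: build a mock protein and apply the edit.

    The mock reference is a run of ``ref_len`` residues; truncating edits cut
    it and append the altered tail a frameshift produces before its new stop.
    """
    native = "M" * ref_len
    if change.kind is ProteinKind.STOP_GAIN:
        product = native[: change.residue_start - 1]
    elif change.kind is ProteinKind.NONSENSE_AFTER_SUBSTITUTION:
        product = native[: change.residue_start - 1] + "X"
    elif change.kind is ProteinKind.FRAMESHIFT and change.stop_offset is not None:
        product = native[: change.residue_start - 1] + "x" * (change.stop_offset - 1)
    else:
        product = native
    return len(product)


class TestCodingParsing:
    @pytest.mark.parametrize(
        "text, kind, start, end, ref, alt",
        [
            ("c.97T>G", CodingKind.SUBSTITUTION, 97, 97, "T", "G"),
            ("c.108_116delCGACAAGAG", CodingKind.DELETION, 108, 116, "CGACAAGAG", ""),
            ("c.5808delG", CodingKind.DELETION, 5808, 5808, "G", ""),
            (
                "c.3202_3222dupCAGGCCCAGATCGCGGAGCTC",
                CodingKind.DUPLICATION,
                3202,
                3222,
                "CAGGCCCAGATCGCGGAGCTC",
                "CAGGCCCAGATCGCGGAGCTC" * 2,
            ),
            ("c.2761 G>A", CodingKind.SUBSTITUTION, 2761, 2761, "G", "A"),
        ],
    )
    def test_parses_study_notation_forms(self, text, kind, start, end, ref, alt):
        change = parse_hgvs_c(text)
        assert change.kind is kind
        assert (change.position_start, change.position_end) == (start, end)
        assert change.ref_bases == ref
        assert change.alt_bases == alt

    @pytest.mark.parametrize(
        "bad",
        ["97T>G", "c.", "c.abcT>G", "c.97T>Z", "c.116_108delC", "c.10_12delAA"],
    )
    def test_malformed_input_raises_with_token(self, bad):
        with pytest.raises(HgvsParseError):
            parse_hgvs_c(bad)

    def test_roundtrip_is_idempotent_on_fixture(self, fixture_cohort):
        for text in fixture_cohort.variants["hgvs_c"]:
            once = format_hgvs_c(parse_hgvs_c(text))
            assert format_hgvs_c(parse_hgvs_c(once)) == once
            assert once == text.replace(" ", "")


class TestProteinParsing:
    @pytest.mark.parametrize(
        "text, kind, start, end, offset",
        [
            ("p.(Trp33Gly)", ProteinKind.MISSENSE, 33, 33, None),
            ("p.(Gln890Arg*)", ProteinKind.NONSENSE_AFTER_SUBSTITUTION, 890, 890, None),
            ("p.(Arg1933*)", ProteinKind.STOP_GAIN, 1933, 1933, None),
            ("p.(Gly1938Alafs*10)", ProteinKind.FRAMESHIFT, 1938, 1938, 10),
            ("p.(Asp37_Ser39del)", ProteinKind.INFRAME_DELETION, 37, 39, None),
            ("p.(Gln1068_Leu1074dup)", ProteinKind.INFRAME_DUPLICATION, 1068, 1074, None),
            ("p.Arg702Cys", ProteinKind.MISSENSE, 702, 702, None),
        ],
    )
    def test_parses_protein_forms(self, text, kind, start, end, offset):
        change = parse_hgvs_p(text)
        assert change.kind is kind
        assert (change.residue_start, change.residue_end) == (start, end)
        assert change.stop_offset == offset

    @pytest.mark.parametrize("bad", ["Trp33Gly", "p.(Xyz33Gly)", "p.(Trp33Zzz)", "p.()"])
    def test_unknown_codes_raise(self, bad):
        with pytest.raises(HgvsParseError):
            parse_hgvs_p(bad)

    def test_roundtrip_is_idempotent_on_fixture(self, fixture_cohort):
        for text in fixture_cohort.variants["hgvs_p"]:
            once = format_hgvs_p(parse_hgvs_p(text))
            assert format_hgvs_p(parse_hgvs_p(once)) == once
            assert once == text


class TestConsequences:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("p.(Asp37_Ser39del)", Consequence.INFRAME_DELETION),
            ("p.(Met1934Trpfs*14)", Consequence.FRAMESHIFT),
            ("p.(Arg702Cys)", Consequence.MISSENSE),
            ("p.(Gln890Arg*)", Consequence.STOP_GAIN),
            ("p.(Gln1068_Leu1074dup)", Consequence.INFRAME_INSERTION),
        ],
    )
    def test_examples(self, text, expected):
        assert classify_consequence(parse_hgvs_p(text)) is expected

    def test_fixture_types_match_transcribed_column(self, fixture_cohort):
        printed_map = {
            "Missense": Consequence.MISSENSE,
            "Frameshift": Consequence.FRAMESHIFT,
            "Stop-gain": Consequence.STOP_GAIN,
            "In-frame deletion": Consequence.INFRAME_DELETION,
            "In-frame insertion": Consequence.INFRAME_INSERTION,
        }
        for row in fixture_cohort.variants.itertuples():
            assert classify_consequence(parse_hgvs_p(row.hgvs_p)) is printed_map[
                row.variant_type
            ], row.hgvs_p


class TestTruncationArithmetic:
    @pytest.mark.parametrize(
        "text, retained, removed, termination",
        [
            ("p.(Gln890Arg*)", 890, 1070, 891),
            ("p.(Arg1933*)", 1932, 28, 1933),
            ("p.(Arg702Cys)", 1960, 0, None),
            ("p.(Gly1924Argfs*21)", 1943, 17, 1944),
            ("p.(Gly1938Alafs*10)", 1946, 14, 1947),
            ("p.(Met1934Trpfs*14)", 1946, 14, 1947),
        ],
    )
    def test_against_translation_oracle(self, text, retained, removed, termination):
        change = parse_hgvs_p(text)
        assert truncated_length(change, REF_LEN) == retained
        assert truncated_length(change, REF_LEN) == translation_oracle(change)
        assert residues_removed(change, REF_LEN) == removed
        assert termination_position(change) == termination

    def test_invalid_reference_length(self):
        with pytest.raises(ValueError):
            truncated_length(parse_hgvs_p("p.(Arg1933*)"), 0)

    def test_unknown_stop_offset_yields_no_termination(self):
        change = parse_hgvs_p("p.(Gly1938Alafs*?)")
        assert change.stop_offset is None
        assert termination_position(change) is None

    def test_fixture_truncations_partition_reference(self, fixture_cohort):
        truncating = 0
        for row in fixture_cohort.variants.itertuples():
            change = parse_hgvs_p(row.hgvs_p)
            assert truncated_length(change, REF_LEN) + residues_removed(change, REF_LEN) == REF_LEN
            if termination_position(change) is not None:
                truncating += 1
        assert truncating == 5  # two stop gains + three frameshifts

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        residue=st.integers(1, 1940),
        offset=st.integers(1, 20),
        kind=st.sampled_from(
            [ProteinKind.STOP_GAIN, ProteinKind.NONSENSE_AFTER_SUBSTITUTION,
             ProteinKind.FRAMESHIFT, ProteinKind.MISSENSE]
        ),
    )
    def test_oracle_agreement_property(self, residue, offset, kind):
        change = ProteinChange(
            residue_start=residue,
            residue_end=residue,
            ref_aa="Ala",
            alt_aa="Ter" if kind is ProteinKind.STOP_GAIN else "Gly",
            kind=kind,
            stop_offset=offset if kind is ProteinKind.FRAMESHIFT else None,
        )
        assert truncated_length(change, REF_LEN) == translation_oracle(change)
        assert 0 <= residues_removed(change, REF_LEN) <= REF_LEN
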