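"""tRNA reference model: parsing, loop location, motif scan, decoding."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from m7gflow.errors import (
    DegenerateInputError,
    EmptyInputError,
    PatternError,
    StructureError,
)
from m7gflow.reference import (
    DecodingPolicy,
    Interval,
    IUPAC,
    MotifPattern,
    TRNAGene,
    decoded_codons,
    load_trna_reference,
    locate_variable_loop,
    m7g_codon_set,
    parse_gtrnadb_header,
    revcomp,
    scan_motif,
)


class TestLoadReference:
    def test_gtrnadb_header_grammar(self):
        assert parse_gtrnadb_header("Homo_sapiens_tRNA-Val-AAC-1-1") == (
            "Val", "AAC",
        )
        assert parse_gtrnadb_header("no-trna-here") is None

    def test_load_parses_and_normalises_u(self, tmp_path):
        fa = tmp_path / "ref.fa"
        fa.write_text(
            ">Homo_sapiens_tRNA-Val-AAC-1-1\n" + "ACGU" * 19 + "\n"
            ">weird_header\n" + "ACGT" * 19 + "\n"
        )
        genes = load_trna_reference(fa)
        assert genes[0].amino_acid == "Val"
        assert genes[0].anticodon == "AAC"
        assert "U" not in genes[0].sequence
        assert genes[0].variable_loop == Interval(49, 64)
        # unparseable header flagged, not dropped
        assert genes[1].flag is not None

    def test_empty_fasta_is_an_error(self, tmp_path):
        fa = tmp_path / "empty.fa"
        fa.write_text("")
        with pytest.raises(EmptyInputError):
            load_trna_reference(fa)

    def test_structure_length_mismatch(self, tmp_path):
        fa = tmp_path / "ref.fa"
        fa.write_text(">Homo_sapiens_tRNA-Val-AAC-1-1\n" + "ACGT" * 19 + "\n")
        ann = tmp_path / "ref.struct"
        ann.write_text(">Homo_sapiens_tRNA-Val-AAC-1-1\n....\n")
        with pytest.raises(Exception):
            load_trna_reference(fa, annotation_path=ann)


def _cloverleaf():
    """Hand-built structure whose variable loop is exactly [44, 49)."""
    acceptor5 = "(" * 7                      # 0..6
    d_arm = "(" * 6 + "." * 4 + ")" * 6      # 7..22
    ac_arm = "(" * 7 + "." * 7 + ")" * 7     # 23..43, loop at [30, 37)
    var_loop = "." * 5                       # 44..48
    t_arm = "(" * 4 + "." * 4 + ")" * 4      # 49..60
    acceptor3 = ")" * 7                      # 61..67
    db = acceptor5 + d_arm + ac_arm + var_loop + t_arm + acceptor3
    seq = list("A" * len(db))
    seq[32:35] = list("AAC")                 # anticodon inside its loop
    return "".join(seq), db


class TestVariableLoop:
    def test_structural_location_matches_construction(self):
        seq, db = _cloverleaf()
        gene = TRNAGene(id="g", amino_acid="Val", anticodon="AAC", sequence=seq)
        assert locate_variable_loop(gene, dot_bracket=db) == Interval(44, 49)

    def test_structural_location_invariant_to_cca(self):
        seq, db = _cloverleaf()
        gene = TRNAGene(id="g", amino_acid="Val", anticodon="AAC",
                        sequence=seq + "CCA")
        loop = locate_variable_loop(gene, dot_bracket=db + "...",
                                    cca_appended=True)
        assert loop == Interval(44, 49)

    def test_fallback_window_default(self, loop_gene):
        assert locate_variable_loop(loop_gene) == Interval(49, 64)

    def test_fallback_excludes_cca_when_flagged(self):
        gene = TRNAGene(id="g", amino_acid="Val", anticodon="AAC",
                        sequence="A" * 73 + "CCA")
        loop = locate_variable_loop(gene, cca_appended=True)
        assert loop == Interval(73 - 27, 73 - 12)

    def test_short_sequence_degenerate(self):
        gene = TRNAGene(id="g", amino_acid="Val", anticodon="AAC",
                        sequence="ACGTACGTAC")
        with pytest.raises(DegenerateInputError):
            locate_variable_loop(gene)

    def test_unbalanced_structure_raises(self):
        gene = TRNAGene(id="g", amino_acid="Val", anticodon="AAC",
                        sequence="ACGTA")
        with pytest.raises(StructureError):
            locate_variable_loop(gene, dot_bracket="((..)")


class TestScanMotif:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("ACGAC", [2]),   # A, C in B, G, A in W, C in Y
            ("AAGTC", []),    # second base violates B
            ("AGGAT", [2]),
            ("ACGGC", []),    # fourth base violates W
        ],
    )
    def test_examples(self, seq, expected):
        assert scan_motif(seq, Interval(0, len(seq))) == expected

    def test_window_shorter_than_pattern_no_overhang(self):
        assert scan_motif("ACGAC", Interval(0, 3), allow_overhang=False) == []

    def test_overhang_allows_g_in_window(self):
        # match starts at 0 inside [0, 3); G at 2 is inside; tail overhangs
        assert scan_motif("ACGAC", Interval(0, 3), allow_overhang=True) == [2]

    def test_invalid_pattern_character(self):
        with pytest.raises(PatternError):
            MotifPattern(iupac="AXGWY")

    def test_modified_offset_must_match_g(self):
        with pytest.raises(PatternError):
            MotifPattern(iupac="ABGWY", modified_offset=0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=0, max_size=200))
    def test_equals_literal_expansion_oracle(self, seq):
        """The scan agrees with substring search over all 12 literal 5-mers."""
        pattern = MotifPattern()
        expected = set()
        for lit in pattern.literal_expansions():
            start = seq.find(lit)
            while start != -1:
                expected.add(start + pattern.modified_offset)
                start = seq.find(lit, start + 1)
        got = scan_motif(seq, Interval(0, len(seq)), pattern)
        assert sorted(expected) == got
        assert len(pattern.literal_expansions()) == 12


ALL_ANTICODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]


class TestDecoding:
    @pytest.mark.parametrize(
        "anticodon,mode,expected",
        [
            ("CTT", "strict_wc", {"AAG"}),
            ("AAC", "crick_wobble_inosine", {"GTT", "GTC", "GTA"}),
            ("GAA", "crick_wobble", {"TTC", "TTT"}),
            ("TAC", "crick_wobble", {"GTA", "GTG"}),
            ("CCA", "crick_wobble", {"TGG"}),
        ],
    )
    def test_examples(self, anticodon, mode, expected):
        assert decoded_codons(anticodon, DecodingPolicy(mode)) == expected

    @pytest.mark.parametrize("anticodon", ALL_ANTICODONS)
    def test_nesting_and_wc_core(self, anticodon):
        strict = decoded_codons(anticodon, DecodingPolicy("strict_wc"))
        wobble = decoded_codons(anticodon, DecodingPolicy("crick_wobble"))
        inosine = decoded_codons(anticodon, DecodingPolicy("crick_wobble_inosine"))
        assert strict <= wobble <= inosine
        assert 1 <= len(inosine) <= 3
        for codon in inosine:
            assert codon[:2] == revcomp(anticodon)[:2]

    def test_codon_set_union_and_dedup(self):
        genes = [
            TRNAGene(id=f"g{i}", amino_acid=aa, anticodon=ac, sequence="ACGT")
            for i, (aa, ac) in enumerate(
                [("Val", "AAC"), ("Lys", "CTT"), ("Val", "AAC")]
            )
        ]
        got = m7g_codon_set(genes)
        assert got == {"GTT", "GTC", "GTA", "AAG"}
        assert got == m7g_codon_set(genes[:2])

    def test_empty_collection_is_an_error(self):
        with pytest.raises(EmptyInputError):
            m7g_codon_set([])
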