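"""Mature-N-terminus rules, semi-specific digestion and dipeptidyl arithmetic."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from tailskit.nterm import (
    IMET_EXCISION_RESIDUES,
    DigestParams,
    NtermRule,
    OriginClass,
    PeptideSpan,
    ProteinRecord,
    classify_origin,
    digest_semi,
    dipeptidyl_cleave,
    mature_nterm,
    p_positions,
)

from oracles import brute_force_semi_digest

AA = "ACDEFGHIKLMNPQRSTVWY"
protein_seqs = st.text(alphabet=AA, min_size=2, max_size=30)


class TestMatureNterm:
    @pytest.mark.parametrize("seq, start, rule", [
        ("MVTAQ", 2, NtermRule.IMET_EXCISION),    # small residue 2 -> Met excised
        ("MDEAA", 1, NtermRule.NONE),             # Asp does not trigger excision
        ("MXTAQ", 1, NtermRule.NONE),             # ambiguous residue never fires
        ("AVTAQ", 1, NtermRule.NONE),             # fragment without Met1
    ])
    def test_imet_rule(self, seq, start, rule):
        m = mature_nterm(ProteinRecord("p", seq))
        assert (m.start, m.rule) == (start, rule)

    def test_signal_peptide_sets_start_after_annotated_end(self):
        p = ProteinRecord("p", "M" + "A" * 30, signal_peptide_end=20)
        m = mature_nterm(p)
        assert m.start == 21 and m.rule == NtermRule.SIGNAL_PEPTIDE

    def test_signal_peptide_takes_precedence_over_imet(self):
        p = ProteinRecord("p", "MV" + "A" * 30, signal_peptide_end=18)
        assert mature_nterm(p).rule == NtermRule.SIGNAL_PEPTIDE

    def test_length1_protein_with_signal_annotation_rejected(self):
        with pytest.raises(ValueError):
            ProteinRecord("p", "M", signal_peptide_end=1)

    @given(protein_seqs)
    def test_exactly_one_rule_fires_and_is_idempotent(self, seq):
        p = ProteinRecord("p", seq)
        m1 = mature_nterm(p)
        assert m1 == mature_nterm(p)
        if m1.rule == NtermRule.IMET_EXCISION:
            assert m1.start == 2 and seq[0] == "M" and seq[1] in IMET_EXCISION_RESIDUES
        elif m1.rule == NtermRule.NONE:
            assert m1.start == 1


class TestDigestSemi:
    def test_full_specific_toy(self):
        p = ProteinRecord("p", "MKRAAAR")
        spans = digest_semi(p, DigestParams(max_missed_cleavages=0, min_length=1,
                                            max_length=40, semi_specific=False))
        assert {(s.start, s.end) for s in spans} == {(1, 3), (4, 7)}
        assert {s.sequence for s in spans} == {"MKR", "AAAR"}

    def test_missed_cleavage_adds_readthrough_peptide(self):
        p = ProteinRecord("p", "MKRAAAR")
        spans = digest_semi(p, DigestParams(max_missed_cleavages=1, min_length=1,
                                            max_length=40, semi_specific=False))
        assert (1, 7) in {(s.start, s.end) for s in spans}

    @pytest.mark.parametrize("semi", [False, True])
    @pytest.mark.parametrize("max_missed", [0, 1, 2])
    @pytest.mark.parametrize("proline_block", [False, True])
    def test_matches_brute_force_oracle(self, semi, max_missed, proline_block):
        rng = np.random.default_rng(42)
        for _ in range(25):
            seq = "".join(rng.choice(list(AA), size=rng.integers(2, 31)))
            p = ProteinRecord("p", seq)
            params = DigestParams(max_missed_cleavages=max_missed, min_length=2,
                                  max_length=12, semi_specific=semi,
                                  proline_block=proline_block)
            got = {(s.start, s.end) for s in digest_semi(p, params)}
            want = brute_force_semi_digest(seq, {"R"}, max_missed, 2, 12, semi,
                                           proline_block)
            assert got == want

    def test_spans_carry_matching_subsequences(self):
        p = ProteinRecord("p", "MVRAPTKLLRAEDF")
        for s in digest_semi(p, DigestParams(min_length=3, max_length=10)):
            assert s.sequence == p.sequence[s.start - 1 : s.end]


class TestDipeptidylCleave:
    def test_single_cycle_shifts_start_by_two(self, mep1_like):
        span = PeptideSpan.from_protein(mep1_like, 2, 17)
        prod = dipeptidyl_cleave(span)
        assert prod.start == 4 and prod.end == 17
        assert len(span) - len(prod) == 2

    def test_thirteen_cycles_reach_position_28(self, mep1_like):
        span = PeptideSpan("w", 2, 40, "A" * 39)
        assert dipeptidyl_cleave(span, cycles=13).start == 28

    def test_two_single_cycles_equal_one_double(self, mep1_like):
        span = PeptideSpan.from_protein(mep1_like, 2, 17)
        assert dipeptidyl_cleave(dipeptidyl_cleave(span)) == dipeptidyl_cleave(span, 2)

    def test_too_short_span_rejected(self):
        with pytest.raises(ValueError):
            dipeptidyl_cleave(PeptideSpan("p", 1, 2, "MV"))


class TestClassifyOrigin:
    def test_start_at_mature_nterm_is_substrate(self, mep1_like):
        m = mature_nterm(mep1_like)
        span = PeptideSpan.from_protein(mep1_like, 2, 17)
        assert classify_origin(span, m).kind == OriginClass.NTERM_SUBSTRATE

    def test_even_offset_is_product_with_cycle_count(self, mep1_like):
        m = mature_nterm(mep1_like)
        span = PeptideSpan.from_protein(mep1_like, 4, 17)
        o = classify_origin(span, m)
        assert o == OriginClass(OriginClass.NTERM_PRODUCT, 1)

    def test_odd_offset_is_internal(self, mep1_like):
        m = mature_nterm(mep1_like)  # start 2; 33 - 2 = 31 is odd
        span = PeptideSpan.from_protein(mep1_like, 33, 40)
        assert classify_origin(span, m).kind == OriginClass.INTERNAL

    def test_offset_beyond_max_cycles_is_internal(self, mep1_like):
        m = mature_nterm(mep1_like)
        span = PeptideSpan.from_protein(mep1_like, 36, 40)  # 17 cycles
        assert classify_origin(span, m, max_cycles=15).kind == OriginClass.INTERNAL

    @given(st.integers(1, 12))
    def test_cleaving_a_substrate_yields_matching_product_class(self, k):
        protein = ProteinRecord("p", "MV" + "A" * 60)
        m = mature_nterm(protein)
        span = PeptideSpan.from_protein(protein, m.start, 60)
        assert classify_origin(span, m).kind == OriginClass.NTERM_SUBSTRATE
        prod = dipeptidyl_cleave(span, cycles=k)
        assert classify_origin(prod, m, max_cycles=15) == \
            OriginClass(OriginClass.NTERM_PRODUCT, k)


class TestPPositions:
    def test_worked_example_vta(self, mep1_like):
        span = PeptideSpan.from_protein(mep1_like, 2, 17)
        assert p_positions(span, mep1_like) == ("V", "T", "A")

    def test_positional_lookup(self):
        p = ProteinRecord("p", "APGKLLM")
        span = PeptideSpan.from_protein(p, 1, 7)
        assert p_positions(span, p) == ("A", "P", "G")

    def test_span_shorter_than_three_rejected(self):
        p = ProteinRecord("p", "APGKLLM")
        with pytest.raises(ValueError):
            p_positions(PeptideSpan.from_protein(p, 1, 2), p)
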