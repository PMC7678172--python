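"""Codon arithmetic, strand handling, and coding-effect annotation."""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings, strategies as st

from coatscan import (
    EffectClass,
    GENETIC_CODE,
    GeneModel,
    Variant,
    annotate,
    cds_position,
    codon_arithmetic,
    genomic_position,
    infer_strand,
    verify_candidates,
)
from coatscan.annotate import AnnotationError, reverse_complement


class TestCdsPosition:
    def test_plus_strand_first_base(self):
        m = GeneModel("G", "a", "1", "+", ((1000, 1998),), "A" * 996 + "TGA")
        assert cds_position(m, "1", 1000) == 1
        assert cds_position(m, "1", 1998) == 999  # last base

    def test_minus_strand_mirror(self):
        m = GeneModel("G", "a", "1", "-", ((1000, 1998),), "A" * 996 + "TGA")
        assert cds_position(m, "1", 1998) == 1
        assert cds_position(m, "1", 1000) == 999

    def test_two_segment_walk(self):
        # brute-force oracle: walk genomic bases in transcription order
        segments = ((100, 199), (300, 400))
        m = GeneModel("G", "a", "1", "+", segments, "A" * 201)
        walk = [p for start, end in segments for p in range(start, end + 1)]
        assert walk.index(300) + 1 == 101
        assert cds_position(m, "1", 300) == 101
        # every position agrees with the brute-force walk
        for cdna, pos in enumerate(walk, start=1):
            assert cds_position(m, "1", pos) == cdna

    def test_noncoding_and_wrong_chromosome_return_none(self):
        m = GeneModel("G", "a", "1", "+", ((1000, 1998),), "A" * 996 + "TGA")
        assert cds_position(m, "1", 999) is None
        assert cds_position(m, "1", 2500) is None
        assert cds_position(m, "2", 1500) is None

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(cdna=st.integers(min_value=1, max_value=300), minus=st.booleans())
    def test_genomic_position_inverts_cds_position(self, cdna, minus):
        segments = ((100, 199), (300, 399), (500, 599))
        ordered = segments[::-1] if minus else segments
        m = GeneModel("G", "a", "7", "-" if minus else "+", ordered, "A" * 297 + "TGA")
        pos = genomic_position(m, cdna)
        assert cds_position(m, "7", pos) == cdna


class TestCodonArithmetic:
    @pytest.mark.parametrize(
        "cdna,expected",
        [
            (143, (48, 2)),   # the causal site: middle base of residue 48
            (1, (1, 1)),
            (9260, (3087, 2)),
            (3, (1, 3)),
            (4, (2, 1)),
        ],
    )
    def test_examples(self, cdna, expected):
        assert codon_arithmetic(cdna) == expected

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            codon_arithmetic(0)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(cdna=st.integers(min_value=1, max_value=10**7))
    def test_reconstruction_is_exact(self, cdna):
        index, offset = codon_arithmetic(cdna)
        assert 3 * (index - 1) + offset == cdna
        assert 1 <= offset <= 3


class TestInferStrand:
    @pytest.mark.parametrize(
        "g_ref,g_alt,c_ref,c_alt,offset,expected",
        [
            ("T", "C", "cTg", "cCg", 2, "+"),   # causal MC1R-style site
            ("C", "T", "Gat", "Aat", 1, "-"),   # ATRN-style
            ("G", "T", "gCc", "gAc", 2, "-"),   # SHROOM2-style
            ("A", "C", "ttA", "ttC", 3, "+"),   # LYST-style
        ],
    )
    def test_orientations(self, g_ref, g_alt, c_ref, c_alt, offset, expected):
        assert infer_strand(g_ref, g_alt, c_ref, c_alt, offset) == expected

    def test_inconsistent_orientation_is_an_error(self):
        # genomic A>C matches coding T>C neither directly nor complemented
        with pytest.raises(AnnotationError, match="neither orientation"):
            infer_strand("A", "C", "cTg", "cCg", 2)

    def test_misplaced_capital_rejected(self):
        with pytest.raises(ValueError, match="capital"):
            infer_strand("T", "C", "Ctg", "cCg", 2)


class TestGeneticCode:
    def test_agrees_with_independent_translation_for_all_64_codons(self):
        assert len(GENETIC_CODE) == 64
        for codon, aa in GENETIC_CODE.items():
            assert aa == str(Seq(codon).translate())


class TestAnnotate:
    def test_causal_missense_annotation(self, mc1r_model):
        effect = annotate(Variant("18", 14705518, "T", "C", 842.0), mc1r_model)
        assert effect.hgvs_c == "c.143T>C"
        assert (effect.codon_ref, effect.codon_alt) == ("cTg", "cCg")
        assert effect.hgvs_p == "p.L48P"
        assert effect.effect_class is EffectClass.MISSENSE

    def test_synonymous_third_position(self, mc1r_model):
        # c.144 G>A turns CTG into CTA: still leucine
        effect = annotate(Variant("18", 14705519, "G", "A", 10.0), mc1r_model)
        assert effect.cdna_pos == 144
        assert effect.effect_class is EffectClass.SYNONYMOUS
        assert effect.hgvs_p == "p.L48="

    def test_minus_strand_complements_alleles(self, atrn_model):
        pos = genomic_position(atrn_model, 1573)
        effect = annotate(Variant("13", pos, "C", "T", 99.0), atrn_model)
        assert effect.hgvs_c == "c.1573G>A"
        assert (effect.codon_ref, effect.codon_alt) == ("Gat", "Aat")
        assert effect.hgvs_p == "p.D525N"
        assert effect.effect_class is EffectClass.MISSENSE

    def test_noncoding_returns_none(self, mc1r_model):
        start = mc1r_model.cds_segments[0][0]
        assert annotate(Variant("18", start - 10, "A", "G", 5.0), mc1r_model) is None

    def test_reference_mismatch_is_an_error(self, mc1r_model):
        # c.143 is T in the model; claiming ref A contradicts the CDS
        with pytest.raises(AnnotationError, match="c.143"):
            annotate(Variant("18", 14705518, "A", "G", 5.0), mc1r_model)

    def test_nonsense_classification(self):
        # CAA (Gln) -> TAA (stop) at codon 2 via c.4 C>T
        m = GeneModel("G", "a", "1", "+", ((100, 108),), "ATGCAATGA")
        effect = annotate(Variant("1", 103, "C", "T", 50.0), m)
        assert effect.effect_class is EffectClass.NONSENSE
        assert effect.aa_alt == "*"

    def test_start_lost_classification(self):
        m = GeneModel("G", "a", "1", "+", ((100, 108),), "ATGCAATGA")
        effect = annotate(Variant("1", 100, "A", "G", 50.0), m)
        assert effect.effect_class is EffectClass.START_LOST

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=10**6))
    def test_strand_symmetry(self, seed):
        """A minus-strand annotation must equal the annotation of the
        same coding change on a plus-strand model carrying the identical
        coding sequence (the genomic alleles being complements)."""
        rng = np.random.default_rng(seed)
        n_codons = int(rng.integers(4, 40))
        length = 3 * n_codons
        cds = "".join(rng.choice(list("ACGT"), size=length))
        minus = GeneModel("M", "a", "9", "-", ((10_000, 10_000 + length - 1),), cds)
        plus = GeneModel("P", "a", "9", "+", ((50_000, 50_000 + length - 1),), cds)
        cdna = int(rng.integers(1, length + 1))
        ref_coding = cds[cdna - 1]
        alt_coding = str(rng.choice([b for b in "ACGT" if b != ref_coding]))
        v_minus = Variant("9", genomic_position(minus, cdna),
                          reverse_complement(ref_coding),
                          reverse_complement(alt_coding), 50.0)
        v_plus = Variant("9", genomic_position(plus, cdna), ref_coding, alt_coding, 50.0)
        e_minus = annotate(v_minus, minus)
        e_plus = annotate(v_plus, plus)
        assert e_minus == e_plus
        assert e_minus.cdna_pos == cdna


class TestVerifyCandidates:
    def test_all_published_rows_recompute(self, candidate_rows):
        n, checks = verify_candidates(candidate_rows)
        assert n == 19
        assert all(c.matches for c in checks)

    def test_single_row(self, candidate_rows):
        mc1r = [r for r in candidate_rows if r.gene == "MC1R"]
        n, checks = verify_candidates(mc1r)
        assert n == 1
        assert checks[0].recomputed == "p.L48P"
        assert checks[0].strand == "+"

    def test_corrupted_row_counts_as_mismatch(self, candidate_rows):
        import dataclasses

        bad = dataclasses.replace(candidate_rows[9], aa_sub="p.L48A")
        n, checks = verify_candidates([bad])
        assert n == 0 and not checks[0].matches

    def test_strands_match_published_orientation(self, candidate_rows):
        _, checks = verify_candidates(candidate_rows)
        by_gene = {(c.gene, c.cdna_pos): c.strand for c in checks}
        assert by_gene[("MC1R", 143)] == "+"
        assert by_gene[("ATRN", 1573)] == "-"
        assert by_gene[("SHROOM2", 3176)] == "-"
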