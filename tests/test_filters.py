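"""The filtering cascade: QC, gene subsetting, recessive trio filter,
panel refinement, and the stage-by-stage report."""

from __future__ import annotations

import itertools

import pytest

from coatscan import (
    AnimalRecord,
    EffectClass,
    GeneModel,
    Genotype,
    GenotypeCall,
    Origin,
    Phenotype,
    Variant,
    filter_near_indels,
    nonsynonymous_only,
    recessive_trio_filter,
    refine_with_panel,
    run_cascade,
    subset_to_genes,
)
from coatscan.filters import Candidate, annotate_candidates


def _snv(pos, qual, chrom="1"):
    return Variant(chrom, pos, "A", "G", qual=qual)


def _indel(pos, qual, chrom="1"):
    return Variant(chrom, pos, "AT", "A", qual=qual)


class TestFilterNearIndels:
    @pytest.mark.parametrize(
        "snv_qual,indel_pos,indel_qual,kept",
        [
            (30, 102, 50, False),  # within 3 bp, lower QUAL: removed
            (60, 102, 50, True),   # within 3 bp but higher QUAL: kept
            (50, 102, 50, True),   # equal QUAL is not "lower": kept
            (30, 103, 50, False),  # distance exactly 3: inside window
            (30, 104, 50, True),   # distance 4 > window
            (30, 105, 50, True),   # distance 5 > window
        ],
    )
    def test_window_and_qual_rule(self, snv_qual, indel_pos, indel_qual, kept):
        snv = _snv(100, snv_qual)
        out = filter_near_indels([snv, _indel(indel_pos, indel_qual)])
        assert (snv in out) is kept

    def test_indels_never_removed(self):
        variants = [_indel(100, 10), _indel(101, 90)]
        assert filter_near_indels(variants) == variants

    def test_different_chromosome_ignored(self):
        snv = _snv(100, 10)
        out = filter_near_indels([snv, _indel(101, 90, chrom="2")])
        assert snv in out

    def test_exhaustive_distance_scan_matches_window(self):
        # derived oracle: scan distances 1..6 around a low-QUAL SNV
        for dist in range(1, 7):
            snv = _snv(100, 10)
            out = filter_near_indels([snv, _indel(100 + dist, 90)], window=3)
            assert (snv in out) is (dist > 3)


@pytest.fixture(scope="module")
def toy_model():
    return GeneModel("MC1R", "a", "18", "+", ((1000, 1929),), "ATG" + "CAA" * 308 + "TGA")


class TestSubsetToGenes:
    def test_listed_gene_retained(self, toy_model):
        v = _snv(1100, 50, chrom="18")
        assert subset_to_genes([v], [toy_model], {"MC1R"}) == [(v, toy_model)]

    def test_unlisted_gene_removed(self, toy_model):
        v = _snv(1100, 50, chrom="18")
        with pytest.warns(UserWarning):  # TYR is listed but has no model
            assert subset_to_genes([v], [toy_model], {"TYR"}) == []

    def test_intergenic_removed(self, toy_model):
        assert subset_to_genes([_snv(5000, 50, chrom="18")], [toy_model], {"MC1R"}) == []

    def test_listed_gene_without_model_warns(self, toy_model):
        with pytest.warns(UserWarning, match="TYR"):
            subset_to_genes([], [toy_model], {"MC1R", "TYR"})


class TestNonsynonymousOnly:
    def test_mixture_count(self, toy_model):
        # c.5 A>T: CAA->CTA (Q2L missense); c.6 A>G: CAA->CAG (synonymous)
        missense = [Variant("18", 1004, "A", "T", 50.0), Variant("18", 1007, "A", "T", 50.0)]
        synonymous = [Variant("18", 1005, "A", "G", 50.0), Variant("18", 1008, "A", "G", 50.0),
                      Variant("18", 1011, "A", "G", 50.0)]
        cands = annotate_candidates([(v, toy_model) for v in missense + synonymous])
        kept = nonsynonymous_only(cands)
        assert len(kept) == 2
        assert all(c.effect.effect_class is EffectClass.MISSENSE for c in kept)
        dropped = [c for c in cands if c not in kept]
        assert all(c.effect.effect_class is EffectClass.SYNONYMOUS for c in dropped)


def _cand(toy_model, pos=1004):
    v = Variant("18", pos, "A", "T", 50.0)
    return Candidate(v, toy_model, None)


class TestRecessiveTrioFilter:
    def test_matches_nine_case_brute_force_oracle(self, toy_model):
        """Only (affected hom-alt, carrier het) may pass, by exhaustive
        scan over all nine genotype pairs."""
        for a_gt, c_gt in itertools.product(Genotype, Genotype):
            cand = _cand(toy_model)
            affected = {cand.key: GenotypeCall.make("dam", cand.key, a_gt)}
            carrier = {cand.key: GenotypeCall.make("calf", cand.key, c_gt)}
            out = recessive_trio_filter([cand], affected, carrier)
            expected = (a_gt, c_gt) == (Genotype.HOM_ALT, Genotype.HET)
            assert (out == [cand]) is expected

    def test_missing_genotype_removes(self, toy_model):
        cand = _cand(toy_model)
        carrier = {cand.key: GenotypeCall.make("calf", cand.key, Genotype.HET)}
        assert recessive_trio_filter([cand], {cand.key: None}, carrier) == []


def _animal(i, phenotype, key, gt):
    genotypes = {key: None if gt is None else GenotypeCall.make(f"P{i}", key, gt)}
    return AnimalRecord(f"P{i}", "loc", Origin.G, phenotype, genotypes)


class TestRefineWithPanel:
    def test_concordant_panel_passes(self, toy_model):
        cand = _cand(toy_model)
        panel = [
            *(_animal(i, Phenotype.WHITE, cand.key, Genotype.HOM_ALT) for i in range(3)),
            _animal(3, Phenotype.PIGMENTED, cand.key, Genotype.HOM_REF),
            _animal(4, Phenotype.PIGMENTED, cand.key, Genotype.HET),
            _animal(5, Phenotype.PIGMENTED, cand.key, Genotype.HOM_REF),
        ]
        assert refine_with_panel([cand], panel) == [cand]

    def test_homalt_pigmented_eliminates(self, toy_model):
        cand = _cand(toy_model)
        panel = [_animal(0, Phenotype.PIGMENTED, cand.key, Genotype.HOM_ALT)]
        assert refine_with_panel([cand], panel) == []

    def test_nonhomalt_white_eliminates(self, toy_model):
        cand = _cand(toy_model)
        panel = [_animal(0, Phenotype.WHITE, cand.key, Genotype.HET)]
        assert refine_with_panel([cand], panel) == []

    def test_empty_panel_is_vacuous(self, toy_model):
        cands = [_cand(toy_model), _cand(toy_model, pos=1007)]
        assert refine_with_panel(cands, []) == cands

    def test_missing_genotype_reported_not_disqualifying(self, toy_model):
        cand = _cand(toy_model)
        panel = [
            _animal(0, Phenotype.WHITE, cand.key, None),
            _animal(1, Phenotype.WHITE, cand.key, Genotype.HOM_ALT),
        ]
        log = []
        assert refine_with_panel([cand], panel, log) == [cand]
        assert log == [("P0", "18:1004")]


class TestRunCascade:
    def test_empty_vcf_gives_all_zero_report(self, toy_model):
        report = run_cascade([], [toy_model], {"MC1R"}, "dam", "calf", panels=[])
        assert report.final == []
        assert all(s.n_in == 0 and s.n_out == 0 for s in report.stages)

    def test_unknown_sample_id_is_configuration_error(self, toy_model):
        v = Variant("18", 1004, "A", "T", 50.0)
        rec = (v, {"dam": GenotypeCall.make("dam", v.key, Genotype.HOM_ALT)})
        with pytest.raises(ValueError, match="calf"):
            run_cascade([rec], [toy_model], {"MC1R"}, "dam", "calf")

    def test_counts_monotone_and_attribution_complete(self, toy_model):
        # mixed bag: causal-style SNV, synonymous SNV, indel, near-indel SNV
        def rec(v, a_gt, c_gt):
            return (v, {"dam": GenotypeCall.make("dam", v.key, a_gt),
                        "calf": GenotypeCall.make("calf", v.key, c_gt)})

        records = [
            rec(Variant("18", 1004, "A", "T", 50.0), Genotype.HOM_ALT, Genotype.HET),
            rec(Variant("18", 1005, "A", "G", 50.0), Genotype.HOM_ALT, Genotype.HET),
            rec(Variant("18", 1010, "AT", "A", 90.0), Genotype.HET, Genotype.HET),
            rec(Variant("18", 1012, "A", "G", 10.0), Genotype.HOM_ALT, Genotype.HET),
            rec(Variant("18", 1100, "A", "T", 50.0), Genotype.HET, Genotype.HET),
        ]
        report = run_cascade(records, [toy_model], {"MC1R"}, "dam", "calf")
        for prev, nxt in zip(report.stages, report.stages[1:]):
            assert nxt.n_in == prev.n_out  # removals attributed to one stage
        assert all(s.n_out <= s.n_in for s in report.stages)
        total_removed = sum(s.n_removed for s in report.stages)
        assert total_removed + len(report.final) == len(records)
        assert [c.variant.pos for c in report.final] == [1004]
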