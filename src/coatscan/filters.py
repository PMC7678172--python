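"""The candidate-variant filtering cascade.

Stages, in the order they run:

1. indel-proximity QC — drop SNVs within 3 bp of an indel when the SNV's
   QUAL is below that indel's;
2. candidate-gene subsetting — keep variants inside CDS segments of
   listed genes;
3. coding-effect annotation;
4. non-synonymous restriction;
5. recessive trio filter — affected homozygous-alt, obligate-carrier
   heterozygous;
6. iterative panel refinement — exact genotype-phenotype concordance on
   successively larger validation panels.

Each stage's in/out counts are recorded in a :class:`CascadeReport` so a
run is auditable stage by stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .annotate import annotate
from .models import (
    AnimalRecord,
    CodingEffect,
    GeneModel,
    Genotype,
    GenotypeCall,
    NONSYNONYMOUS,
    Phenotype,
    Variant,
    VariantClass,
)
from .io import VcfRecord


@dataclass(frozen=True)
class Candidate:
    """A variant that has reached (at least) the annotation stage."""

    variant: Variant
    gene: GeneModel
    effect: CodingEffect | None = None

    @property
    def key(self):
        return self.variant.key


@dataclass
class StageCount:
    stage: str
    n_in: int
    n_out: int
    genes: tuple[str, ...] = ()

    @property
    def n_removed(self) -> int:
        return self.n_in - self.n_out


@dataclass
class CascadeReport:
    """Stage-by-stage audit of one cascade run."""

    stages: list[StageCount] = field(default_factory=list)
    final: list[Candidate] = field(default_factory=list)
    missing_panel_genotypes: list[tuple[str, str]] = field(default_factory=list)

    def add(self, stage: str, n_in: int, n_out: int, genes: tuple[str, ...] = ()) -> None:
        if n_out > n_in:
            raise ValueError(f"stage {stage}: output {n_out} exceeds input {n_in}")
        self.stages.append(StageCount(stage, n_in, n_out, genes))

    @property
    def final_keys(self):
        return [c.key for c in self.final]

    def as_dict(self) -> dict:
        return {
            "stages": [
                {
                    "stage": s.stage,
                    "n_in": s.n_in,
                    "n_out": s.n_out,
                    "n_removed": s.n_removed,
                    "genes": list(s.genes),
                }
                for s in self.stages
            ],
            "final_candidates": [
                {
                    "chrom": c.variant.chrom,
                    "pos": c.variant.pos,
                    "ref": c.variant.ref,
                    "alt": c.variant.alt,
                    "gene": c.gene.symbol,
                    "hgvs_c": c.effect.hgvs_c if c.effect else None,
                    "hgvs_p": c.effect.hgvs_p if c.effect else None,
                    "codon": c.effect.codon_display if c.effect else None,
                }
                for c in self.final
            ],
        }


def filter_near_indels(variants: list[Variant], window: int = 3) -> list[Variant]:
    """Indel-proximity QC: an SNV is removed iff an indel on the same
    chromosome lies within ``window`` bp (inclusive POS distance) *and*
    the SNV's QUAL is strictly below that indel's. Indels themselves are
    never removed here."""
    indels = [v for v in variants if v.vclass is VariantClass.INDEL]
    by_chrom: dict[str, list[Variant]] = {}
    for indel in indels:
        by_chrom.setdefault(indel.chrom, []).append(indel)
    kept = []
    for v in variants:
        if v.vclass is VariantClass.INDEL:
            kept.append(v)
            continue
        doomed = any(
            abs(v.pos - indel.pos) <= window and v.qual < indel.qual
            for indel in by_chrom.get(v.chrom, ())
        )
        if not doomed:
            kept.append(v)
    return kept


def subset_to_genes(
    variants: list[Variant],
    gene_models: list[GeneModel],
    gene_list: set[str],
) -> list[tuple[Variant, GeneModel]]:
    """Keep variants whose position falls in a CDS segment of a listed
    gene; returns each with its containing model. Listed genes lacking a
    model are warned about and skipped."""
    models = {m.symbol.upper(): m for m in gene_models}
    missing = sorted(gene_list - set(models))
    if missing:
        warnings.warn(f"no gene model for listed genes: {missing}", stacklevel=2)
    active = [models[sym] for sym in sorted(gene_list & set(models))]
    by_chrom: dict[str, list[GeneModel]] = {}
    for m in active:
        by_chrom.setdefault(m.chrom, []).append(m)
    out = []
    for v in variants:
        for m in by_chrom.get(v.chrom, ()):
            if m.contains(v.chrom, v.pos):
                out.append((v, m))
                break
    return out


def annotate_candidates(pairs: list[tuple[Variant, GeneModel]]) -> list[Candidate]:
    """Annotate coding effects; non-SNVs and non-coding positions drop out."""
    out = []
    for variant, model in pairs:
        if not variant.is_snv:
            continue
        effect = annotate(variant, model)
        if effect is not None:
            out.append(Candidate(variant, model, effect))
    return out


def nonsynonymous_only(candidates: list[Candidate]) -> list[Candidate]:
    """Retain missense/nonsense/start-lost effects; synonymous (and
    unannotated) candidates are excluded from further processing."""
    return [
        c for c in candidates
        if c.effect is not None and c.effect.effect_class in NONSYNONYMOUS
    ]


def recessive_trio_filter(
    candidates: list[Candidate],
    affected_gt: dict[tuple, GenotypeCall | None],
    carrier_gt: dict[tuple, GenotypeCall | None],
) -> list[Candidate]:
    """Recessive-model filter on the sequenced pair: under full
    penetrance the affected dam must be homozygous for the alternative
    allele and her unaffected calf — an obligate carrier — heterozygous.
    A missing genotype at either sample removes the candidate."""
    out = []
    for c in candidates:
        a = affected_gt.get(c.key)
        b = carrier_gt.get(c.key)
        if a is not None and b is not None and (a.gt, b.gt) == (Genotype.HOM_ALT, Genotype.HET):
            out.append(c)
    return out


def refine_with_panel(
    candidates: list[Candidate],
    panel: list[AnimalRecord],
    missing_log: list[tuple[str, str]] | None = None,
) -> list[Candidate]:
    """Exact-concordance screen against a validation panel.

    A candidate survives iff every WHITE animal is homozygous-alt and
    every PIGMENTED animal is not. Missing genotypes neither confirm nor
    eliminate; they are appended to ``missing_log`` as
    ``(animal_id, variant)`` pairs for the report.
    """
    out = []
    for c in candidates:
        ok = True
        for animal in panel:
            gt = animal.genotype_at(c.key)
            if gt is None:
                if missing_log is not None:
                    missing_log.append((animal.animal_id, f"{c.variant.chrom}:{c.variant.pos}"))
                continue
            if animal.phenotype is Phenotype.WHITE and gt is not Genotype.HOM_ALT:
                ok = False
                break
            if animal.phenotype is Phenotype.PIGMENTED and gt is Genotype.HOM_ALT:
                ok = False
                break
        if ok:
            out.append(c)
    return out


def run_cascade(
    vcf_records: list[VcfRecord],
    gene_models: list[GeneModel],
    gene_list: set[str],
    affected_id: str,
    carrier_id: str,
    panels: list[list[AnimalRecord]] | None = None,
    window: int = 3,
) -> CascadeReport:
    """Run the full cascade and return the stage-by-stage report.

    ``panels`` are applied in order (the study design was 1+1, then 3+3,
    then the full cohort). Sample ids absent from the VCF records raise
    a configuration error before any filtering.
    """
    report = CascadeReport()
    if vcf_records:
        present = set(vcf_records[0][1])
        for sid in (affected_id, carrier_id):
            if sid not in present:
                raise ValueError(f"sample {sid!r} not among VCF samples {sorted(present)}")
    variants = [v for v, _ in vcf_records]
    calls = {v.key: gts for v, gts in vcf_records}

    qc = filter_near_indels(variants, window=window)
    report.add("indel_proximity_qc", len(variants), len(qc))

    in_genes = subset_to_genes(qc, gene_models, gene_list)
    report.add(
        "candidate_gene_subset", len(qc), len(in_genes),
        tuple(sorted({m.symbol for _, m in in_genes})),
    )

    annotated = annotate_candidates(in_genes)
    report.add("coding_annotation", len(in_genes), len(annotated))

    nonsyn = nonsynonymous_only(annotated)
    report.add(
        "nonsynonymous_only", len(annotated), len(nonsyn),
        tuple(sorted({c.gene.symbol for c in nonsyn})),
    )

    affected = {key: gts.get(affected_id) for key, gts in calls.items()}
    carrier = {key: gts.get(carrier_id) for key, gts in calls.items()}
    trio = recessive_trio_filter(nonsyn, affected, carrier)
    report.add(
        "recessive_trio", len(nonsyn), len(trio),
        tuple(sorted({c.gene.symbol for c in trio})),
    )

    survivors = trio
    for i, panel in enumerate(panels or [], start=1):
        n_white = sum(a.phenotype is Phenotype.WHITE for a in panel)
        n_pig = len(panel) - n_white
        refined = refine_with_panel(survivors, panel, report.missing_panel_genotypes)
        report.add(
            f"panel_{i} ({n_white}w+{n_pig}p)", len(survivors), len(refined),
            tuple(sorted({c.gene.symbol for c in refined})),
        )
        survivors = refined

    report.final = survivors
    return report
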