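"""Synthetic datasets with the statistical structure the pipeline assumes.

The generator emulates the study design end to end at desk scale: a
biallelic causal SNV segregating at population frequency ``q`` under
Hardy-Weinberg proportions, a fully penetrant recessive affected
phenotype, a sequenced affected dam with her unaffected (obligate
carrier) calf produced by Mendelian transmission, background coding
SNVs and indels scattered through synthetic candidate-gene models, and
staged validation panels. Every generator is deterministic given
``(seed, config)``; independent numbered substreams keep the components
reproducible regardless of call order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .annotate import annotate, complement, genomic_position
from .io import VcfRecord
from .models import (
    AnimalRecord,
    EffectClass,
    GeneModel,
    Genotype,
    GenotypeCall,
    Origin,
    Phenotype,
    Variant,
    VariantKey,
)

logger = logging.getLogger(__name__)

_STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
)

#: Panel staging mirroring the study design: one additional white and
#: brown animal, then three of each, then the whole genotyped cohort.
DEFAULT_STAGES: tuple = ((1, 1), (3, 3), "all")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the synthetic generator.

    ``n_animals`` is the genotyped cohort size (the sequenced dam and
    calf are cohort members). ``q`` is the causal (white) allele
    frequency; the default 0.27 is the allele-frequency estimate from
    the published cohort counts ((2*22 + 11)/204). ``penetrance`` is the
    probability a homozygous-alt animal expresses the affected
    phenotype (1 = full penetrance, the model the study reports);
    ``error_rate`` is a per-call genotyping error knob, off by default.
    """

    seed: int = 0
    n_animals: int = 102
    q: float = 0.27
    n_background: int = 500
    n_genes: int = 16
    gene_length_codons: int = 200
    indel_rate: float = 0.1
    qual_range: tuple[float, float] = (20.0, 100.0)
    penetrance: float = 1.0
    error_rate: float = 0.0
    cumulative_panels: bool = True
    min_whites: int = 4

    def __post_init__(self) -> None:
        if not 0 < self.q < 1:
            raise ValueError(f"q must be in (0, 1), got {self.q}")
        if self.min_whites < 1:
            raise ValueError("min_whites must be >= 1")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.gene_length_codons < 2:
            raise ValueError("gene_length_codons must be >= 2")
        if self.n_animals < 2:
            raise ValueError("n_animals must be >= 2 (dam and calf)")
        if not 0 <= self.indel_rate <= 1:
            raise ValueError("indel_rate must be in [0, 1]")
        if not 0 <= self.penetrance <= 1:
            raise ValueError("penetrance must be in [0, 1]")
        lo, hi = self.qual_range
        if lo < 0 or hi < lo:
            raise ValueError(f"bad qual_range {self.qual_range}")


@dataclass
class SimulatedTruth:
    """Ground truth of one simulated dataset."""

    dam_id: str
    calf_id: str
    causal_genotypes: dict[str, Genotype]
    phenotypes: dict[str, Phenotype]
    causal_key: VariantKey | None = None
    causal_gene: str | None = None
    dam_forced: bool = False
    gene_layout: dict[str, tuple[str, tuple[tuple[int, int], ...]]] = field(
        default_factory=dict
    )


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def simulate_gene_models(config: SimulationConfig) -> list[GeneModel]:
    """Synthetic single-transcript candidate-gene models.

    Genes alternate strand (+, -, +, ...), sit at non-overlapping loci
    spread over up to six chromosomes, open with ATG, close with a stop
    codon, and contain no internal stops. The CDS is split into one to
    three segments separated by intron-sized gaps.
    """
    rng = _rng(config, 1)
    models = []
    n_chroms = min(config.n_genes, 6)
    next_start = {str(c + 1): 100_000 for c in range(n_chroms)}
    for i in range(config.n_genes):
        chrom = str(i % n_chroms + 1)
        strand = "+" if i % 2 == 0 else "-"
        n_codons = config.gene_length_codons
        internal = rng.choice(len(_SENSE_CODONS), size=n_codons - 2)
        cds_seq = "ATG" + "".join(_SENSE_CODONS[k] for k in internal) + _STOPS[i % 3]
        length = len(cds_seq)
        n_segments = int(rng.integers(1, 4))
        cuts = sorted(rng.choice(np.arange(1, length), size=n_segments - 1, replace=False))
        bounds = [0, *cuts, length]
        seg_lengths = [bounds[j + 1] - bounds[j] for j in range(n_segments)]
        start = next_start[chrom]
        genomic_segments = []
        for seg_len in seg_lengths:
            genomic_segments.append((start, start + seg_len - 1))
            start += seg_len + int(rng.integers(50, 500))
        next_start[chrom] = start + 50_000
        # transcription order: descending genomic for minus-strand genes
        ordered = tuple(genomic_segments if strand == "+" else genomic_segments[::-1])
        models.append(
            GeneModel(
                symbol=f"GENE{i + 1:02d}",
                accession=f"SYN_{i + 1:06d}.1",
                chrom=chrom,
                strand=strand,
                cds_segments=ordered,
                cds_seq=cds_seq,
            )
        )
    return models


def _hw_genotype(rng: np.random.Generator, q: float) -> Genotype:
    u = rng.random()
    if u < (1 - q) ** 2:
        return Genotype.HOM_REF
    if u < (1 - q) ** 2 + 2 * q * (1 - q):
        return Genotype.HET
    return Genotype.HOM_ALT


def simulate_cohort(config: SimulationConfig) -> tuple[list[AnimalRecord], SimulatedTruth]:
    """Cohort of ``n_animals`` with causal genotypes and phenotypes.

    All animals but the calf draw their causal genotype from
    Hardy-Weinberg(q); phenotype is WHITE for homozygous-alt animals
    with probability ``penetrance`` and PIGMENTED otherwise. The dam is
    the first WHITE animal (forced homozygous-alt, with a logged note,
    if none arises); the calf receives one maternal allele drawn
    uniformly from the dam and a paternal alt allele with probability
    ``q``, constrained PIGMENTED — with a homozygous-alt dam that makes
    the calf an obligate heterozygote. Genotype calls at the causal site
    are attached later, once the causal variant key exists.
    """
    rng = _rng(config, 2)
    ids = [f"A{i + 1:04d}" for i in range(config.n_animals)]
    calf_id = ids[-1]
    genotypes: dict[str, Genotype] = {}
    phenotypes: dict[str, Phenotype] = {}
    # The real cohort was assembled phenotype-aware (every known affected
    # animal was collected), not as a random cross-section: emulate that
    # by redrawing until at least min_whites affected animals exist, so a
    # staged validation design can be staffed. Genotypes within a draw
    # remain plain Hardy-Weinberg.
    for attempt in range(1000):
        genotypes.clear()
        phenotypes.clear()
        for aid in ids[:-1]:
            gt = _hw_genotype(rng, config.q)
            genotypes[aid] = gt
            white = gt is Genotype.HOM_ALT and rng.random() < config.penetrance
            phenotypes[aid] = Phenotype.WHITE if white else Phenotype.PIGMENTED
        whites = [aid for aid in ids[:-1] if phenotypes[aid] is Phenotype.WHITE]
        if len(whites) >= config.min_whites:
            break
    dam_forced = False
    if whites:
        dam_id = whites[0]
    deficit = config.min_whites - len(whites)
    if deficit > 0:
        # allele too rare for the cohort size: force the deficit, dam first
        pigmented = [aid for aid in ids[:-1] if phenotypes[aid] is Phenotype.PIGMENTED]
        for aid in pigmented[:deficit]:
            genotypes[aid] = Genotype.HOM_ALT
            phenotypes[aid] = Phenotype.WHITE
        if not whites:
            dam_id = pigmented[0]
            dam_forced = True
        logger.info(
            "only %d white animals arose at q=%.3g; %d forced homozygous-alt",
            len(whites), config.q, deficit,
        )
    # Mendelian transmission: maternal allele uniform from the dam's two
    # (both alt), paternal alt with probability q, rejected until the
    # PIGMENTED constraint holds (i.e. until the paternal allele is ref).
    while True:
        paternal_alt = rng.random() < config.q
        if not paternal_alt:
            break
    genotypes[calf_id] = Genotype.HET
    phenotypes[calf_id] = Phenotype.PIGMENTED
    records = [
        AnimalRecord(
            animal_id=aid,
            location="SIM",
            origin=Origin.G,
            phenotype=phenotypes[aid],
        )
        for aid in ids
    ]
    truth = SimulatedTruth(
        dam_id=dam_id,
        calf_id=calf_id,
        causal_genotypes=genotypes,
        phenotypes=phenotypes,
        dam_forced=dam_forced,
    )
    return records, truth


def _trio_genotypes(rng: np.random.Generator, q: float) -> tuple[Genotype, Genotype]:
    """Dam genotype from HW(q); calf by Mendelian transmission with a
    paternal allele that is alt with probability q."""
    dam = _hw_genotype(rng, q)
    maternal_alt = {
        Genotype.HOM_REF: False,
        Genotype.HET: bool(rng.random() < 0.5),
        Genotype.HOM_ALT: True,
    }[dam]
    paternal_alt = bool(rng.random() < q)
    calf = Genotype(
        ("HOM_REF", "HET", "HOM_ALT")[int(maternal_alt) + int(paternal_alt)]
    )
    return dam, calf


def _genomic_alleles(model: GeneModel, cdna_pos: int, alt_nt: str) -> tuple[int, str, str]:
    """Genomic (plus-strand) position and alleles for a coding change."""
    pos = genomic_position(model, cdna_pos)
    ref_coding = model.cds_seq[cdna_pos - 1]
    if model.strand == "+":
        return pos, ref_coding, alt_nt
    return pos, complement(ref_coding), complement(alt_nt)


def _pick_causal_site(
    rng: np.random.Generator, model: GeneModel
) -> tuple[Variant, int]:
    """A CDS site whose substitution is missense (the implanted causal)."""
    n = model.cds_length
    for _ in range(1000):
        cdna_pos = int(rng.integers(4, n - 2))  # avoid start and stop codons
        ref_nt = model.cds_seq[cdna_pos - 1]
        alt_nt = str(rng.choice([b for b in "ACGT" if b != ref_nt]))
        pos, g_ref, g_alt = _genomic_alleles(model, cdna_pos, alt_nt)
        variant = Variant(model.chrom, pos, g_ref, g_alt, qual=80.0)
        effect = annotate(variant, model)
        if effect is not None and effect.effect_class is EffectClass.MISSENSE:
            return variant, cdna_pos
    raise RuntimeError(f"could not place a missense site in {model.symbol}")


def simulate_variant_calls(
    config: SimulationConfig,
    gene_models: list[GeneModel],
    truth: SimulatedTruth,
) -> tuple[list[str], list[VcfRecord]]:
    """Two-sample (dam, calf) variant calls: the implanted causal SNV
    plus ``n_background`` unlinked coding variants.

    The causal SNV lands at a missense-producing CDS position of the
    first gene model, dam homozygous-alt and calf heterozygous. Each
    background site draws trio genotypes independently (dam from
    Hardy-Weinberg(q), calf by Mendelian transmission), an
    ``indel_rate`` fraction are emitted as single-base insertions or
    deletions, and QUAL is uniform over ``qual_range``. Records are
    sorted by position; the truth object gains the causal key and the
    gene layout. Deterministic under the config seed.
    """
    rng = _rng(config, 3)
    causal_model = gene_models[0]
    causal_variant, _ = _pick_causal_site(rng, causal_model)
    truth.causal_key = causal_variant.key
    truth.causal_gene = causal_model.symbol
    truth.gene_layout = {
        m.symbol: (m.strand, m.cds_segments) for m in gene_models
    }

    dam, calf = truth.dam_id, truth.calf_id
    records: list[VcfRecord] = [
        (
            causal_variant,
            {
                dam: GenotypeCall.make(dam, causal_variant.key, Genotype.HOM_ALT),
                calf: GenotypeCall.make(calf, causal_variant.key, Genotype.HET),
            },
        )
    ]
    used_positions = {causal_variant.key[:2]}
    causal_chrom, causal_pos = causal_variant.chrom, causal_variant.pos

    def placeable(chrom: str, pos: int) -> bool:
        # keep the implanted causal clear of the indel-proximity QC
        # window (3 bp) so it cannot be removed by a background indel
        if (chrom, pos) in used_positions:
            return False
        return chrom != causal_chrom or abs(pos - causal_pos) > 3

    lo, hi = config.qual_range
    for _ in range(config.n_background):
        model = gene_models[int(rng.integers(len(gene_models)))]
        for _ in range(100):
            cdna_pos = int(rng.integers(1, model.cds_length + 1))
            pos = genomic_position(model, cdna_pos)
            if placeable(model.chrom, pos):
                break
        else:
            continue
        used_positions.add((model.chrom, pos))
        ref_base = (
            model.cds_seq[cdna_pos - 1]
            if model.strand == "+"
            else complement(model.cds_seq[cdna_pos - 1])
        )
        if rng.random() < config.indel_rate:
            extra = str(rng.choice(list("ACGT")))
            if rng.random() < 0.5:
                ref, alt = ref_base, ref_base + extra  # insertion
            else:
                ref, alt = ref_base + extra, ref_base  # deletion
        else:
            ref = ref_base
            alt = str(rng.choice([b for b in "ACGT" if b != ref_base]))
        qual = float(lo + (hi - lo) * rng.random())
        variant = Variant(model.chrom, pos, ref, alt, qual=qual)
        dam_gt, calf_gt = _trio_genotypes(rng, config.q)
        records.append(
            (
                variant,
                {
                    dam: GenotypeCall.make(dam, variant.key, dam_gt),
                    calf: GenotypeCall.make(calf, variant.key, calf_gt),
                },
            )
        )
    records.sort(key=lambda rec: (rec[0].chrom, rec[0].pos))
    return [dam, calf], records


def simulate_panels(
    config: SimulationConfig,
    truth: SimulatedTruth,
    stages: Sequence = DEFAULT_STAGES,
    candidate_keys: Sequence[VariantKey] = (),
    cohort: list[AnimalRecord] | None = None,
) -> list[list[AnimalRecord]]:
    """Staged validation panels genotyped at every candidate variant.

    Each stage is ``(n_white, n_pigmented)`` or the string ``"all"``
    (entire cohort). Panels are cumulative (nested) by default —
    matching a validation series that keeps earlier animals — or
    disjoint with ``cumulative_panels=False``. The sequenced dam and
    calf are ordered last within their phenotype groups so that early
    panels test *additional* animals. Genotypes: the causal site comes
    from truth; every other candidate site draws per-animal
    Hardy-Weinberg(q) genotypes once, so an animal's genotype is
    consistent across the panels it appears in. An ``error_rate`` > 0
    flips that fraction of calls to a random other genotype.
    """
    if truth.causal_key is None:
        raise ValueError("truth has no causal key; run simulate_variant_calls first")
    if cohort is None:
        cohort = [
            AnimalRecord(aid, "SIM", Origin.G, truth.phenotypes[aid])
            for aid in truth.phenotypes
        ]
    rng = _rng(config, 4)
    keys = [truth.causal_key] + [k for k in candidate_keys if k != truth.causal_key]

    genotype_matrix: dict[str, dict[VariantKey, Genotype]] = {}
    for animal in cohort:
        row: dict[VariantKey, Genotype] = {}
        for key in keys:
            if key == truth.causal_key:
                gt = truth.causal_genotypes[animal.animal_id]
            else:
                gt = _hw_genotype(rng, config.q)
            if config.error_rate > 0 and rng.random() < config.error_rate:
                gt = rng.choice([g for g in Genotype if g is not gt])
            row[key] = gt
        genotype_matrix[animal.animal_id] = row

    def genotyped(animal: AnimalRecord) -> AnimalRecord:
        return AnimalRecord(
            animal_id=animal.animal_id,
            location=animal.location,
            origin=animal.origin,
            phenotype=animal.phenotype,
            genotypes={
                key: GenotypeCall.make(animal.animal_id, key, gt)
                for key, gt in genotype_matrix[animal.animal_id].items()
            },
        )

    def ordered(phenotype: Phenotype) -> list[AnimalRecord]:
        group = [a for a in cohort if a.phenotype is phenotype]
        sequenced = {truth.dam_id, truth.calf_id}
        return [a for a in group if a.animal_id not in sequenced] + [
            a for a in group if a.animal_id in sequenced
        ]

    whites = ordered(Phenotype.WHITE)
    pigmented = ordered(Phenotype.PIGMENTED)
    panels: list[list[AnimalRecord]] = []
    w_used = p_used = 0
    for stage in stages:
        if stage == "all":
            panels.append([genotyped(a) for a in cohort])
            continue
        n_white, n_pig = stage
        if n_white > len(whites) or n_pig > len(pigmented):
            raise ValueError(
                f"stage {stage} requests more animals than available "
                f"({len(whites)} white, {len(pigmented)} pigmented)"
            )
        if config.cumulative_panels:
            chosen = whites[:n_white] + pigmented[:n_pig]
        else:
            if w_used + n_white > len(whites) or p_used + n_pig > len(pigmented):
                raise ValueError(f"disjoint stage {stage} exhausts the cohort")
            chosen = whites[w_used : w_used + n_white] + pigmented[p_used : p_used + n_pig]
            w_used += n_white
            p_used += n_pig
        panels.append([genotyped(a) for a in chosen])
    return panels


@dataclass
class SimulatedDataset:
    """Everything one simulated study produces, bundled."""

    config: SimulationConfig
    gene_models: list[GeneModel]
    gene_list: set[str]
    cohort: list[AnimalRecord]
    truth: SimulatedTruth
    samples: list[str]
    vcf_records: list[VcfRecord]
    panels: list[list[AnimalRecord]]


def simulate_dataset(
    config: SimulationConfig, stages: Sequence = DEFAULT_STAGES
) -> SimulatedDataset:
    """Generate a complete dataset: gene models, cohort, trio variant
    calls, and staged panels genotyped at every emitted variant."""
    gene_models = simulate_gene_models(config)
    cohort, truth = simulate_cohort(config)
    samples, vcf_records = simulate_variant_calls(config, gene_models, truth)
    panels = simulate_panels(
        config, truth, stages,
        candidate_keys=[v.key for v, _ in vcf_records],
        cohort=cohort,
    )
    return SimulatedDataset(
        config=config,
        gene_models=gene_models,
        gene_list={m.symbol for m in gene_models},
        cohort=cohort,
        truth=truth,
        samples=samples,
        vcf_records=vcf_records,
        panels=panels,
    )
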