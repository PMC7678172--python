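"""Domain types for the recessive candidate-variant pipeline.

The pipeline searches for a fully penetrant recessive coding variant
(the study system is white coat-colour dilution in fallow deer, mapped
against the bovine reference) starting from a two-sample VCF of an
affected dam and her unaffected calf, a candidate-gene list, and gene
models that place variants in coding space.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field


class VariantClass(enum.Enum):
    SNV = "SNV"
    INDEL = "INDEL"


class Genotype(enum.Enum):
    HOM_REF = "HOM_REF"
    HET = "HET"
    HOM_ALT = "HOM_ALT"


class Phenotype(enum.Enum):
    PIGMENTED = "PIGMENTED"
    WHITE = "WHITE"


class Origin(enum.Enum):
    """Sampling-site type: game park/farm (G) or hunting ground (H)."""

    G = "G"
    H = "H"


class EffectClass(enum.Enum):
    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    START_LOST = "start-lost"


#: Effect classes retained by the non-synonymous filter.
NONSYNONYMOUS = frozenset(
    {EffectClass.MISSENSE, EffectClass.NONSENSE, EffectClass.START_LOST}
)

VariantKey = tuple[str, int, str, str]

_NUCS = frozenset("ACGT")


@dataclass(frozen=True)
class Variant:
    """One biallelic call site.

    ``pos`` is the 1-based genomic coordinate on ``chrom`` (reference
    chromosome naming, e.g. ``"18"``); ``qual`` is the phred-scaled call
    quality. ``vclass`` is derived from allele lengths: a site is an SNV
    iff both alleles are single nucleotides.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float = 0.0

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        for allele in (self.ref, self.alt):
            if not set(allele) <= _NUCS:
                raise ValueError(f"non-ACGT allele {allele!r} at {self.chrom}:{self.pos}")
        if self.qual < 0 or math.isnan(self.qual):
            raise ValueError(f"qual must be a non-negative real, got {self.qual}")

    @property
    def vclass(self) -> VariantClass:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return VariantClass.SNV
        return VariantClass.INDEL

    @property
    def is_snv(self) -> bool:
        return self.vclass is VariantClass.SNV

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class GeneModel:
    """A single transcript model mapping genomic positions to CDS space.

    ``cds_segments`` are 1-based inclusive ``(start, end)`` genomic
    intervals listed in transcription order: ascending for ``+`` strand
    genes, descending for ``-`` strand genes (each segment still stored
    as ``start <= end``). ``cds_seq`` is the coding-strand sequence whose
    length equals the summed segment lengths and is divisible by 3.
    """

    symbol: str
    accession: str
    chrom: str
    strand: str
    cds_segments: tuple[tuple[int, int], ...]
    cds_seq: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        segs = tuple((int(a), int(b)) for a, b in self.cds_segments)
        object.__setattr__(self, "cds_segments", segs)
        object.__setattr__(self, "cds_seq", self.cds_seq.upper())
        if not segs:
            raise ValueError(f"{self.symbol}: no CDS segments")
        for start, end in segs:
            if start < 1 or end < start:
                raise ValueError(f"{self.symbol}: bad segment ({start}, {end})")
        spans = sorted(segs)
        for (_, e1), (s2, _) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.symbol}: overlapping CDS segments")
        total = sum(end - start + 1 for start, end in segs)
        if total != len(self.cds_seq):
            raise ValueError(
                f"{self.symbol}: segment span {total} != CDS length {len(self.cds_seq)}"
            )
        if len(self.cds_seq) % 3 != 0:
            raise ValueError(f"{self.symbol}: CDS length {len(self.cds_seq)} not divisible by 3")
        if not set(self.cds_seq) <= _NUCS:
            raise ValueError(f"{self.symbol}: non-ACGT base in CDS sequence")

    @property
    def cds_length(self) -> int:
        return len(self.cds_seq)

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and any(
            start <= pos <= end for start, end in self.cds_segments
        )


@dataclass(frozen=True)
class CodingEffect:
    """Coding-space consequence of an SNV under one gene model.

    ``codon_ref``/``codon_alt`` follow the capitalised-codon convention:
    the variant base uppercase, flanking codon bases lowercase (e.g.
    ``cTg/cCg`` for a middle-base change). ``ref_nt``/``alt_nt`` are the
    coding-strand alleles (complemented relative to the genomic alleles
    for minus-strand genes).
    """

    cdna_pos: int
    ref_nt: str
    alt_nt: str
    codon_index: int
    codon_offset: int
    codon_ref: str
    codon_alt: str
    aa_ref: str
    aa_alt: str
    effect_class: EffectClass

    def __post_init__(self) -> None:
        expect_index = -(-self.cdna_pos // 3)  # ceil
        expect_offset = (self.cdna_pos - 1) % 3 + 1
        if (self.codon_index, self.codon_offset) != (expect_index, expect_offset):
            raise ValueError(
                f"codon arithmetic inconsistent for c.{self.cdna_pos}: "
                f"({self.codon_index}, {self.codon_offset})"
            )
        for codon in (self.codon_ref, self.codon_alt):
            caps = [i for i, ch in enumerate(codon) if ch.isupper()]
            if len(codon) != 3 or caps != [self.codon_offset - 1]:
                raise ValueError(f"codon {codon!r} must capitalise base {self.codon_offset}")

    @property
    def hgvs_c(self) -> str:
        """Coding-DNA notation, e.g. ``c.143T>C``."""
        return f"c.{self.cdna_pos}{self.ref_nt}>{self.alt_nt}"

    @property
    def hgvs_p(self) -> str:
        """Protein notation, e.g. ``p.L48P``; ``p.L48=`` when synonymous."""
        if self.effect_class is EffectClass.SYNONYMOUS:
            return f"p.{self.aa_ref}{self.codon_index}="
        return f"p.{self.aa_ref}{self.codon_index}{self.aa_alt}"

    @property
    def codon_display(self) -> str:
        return f"{self.codon_ref}/{self.codon_alt}"


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's diploid genotype at one biallelic site.

    ``allele_string`` renders the genotype with allele letters
    (``TT``/``TC``/``CC`` for a T>C SNV); it must agree with ``gt``:
    HOM_REF is ref+ref, HET is ref+alt, HOM_ALT is alt+alt.
    """

    sample_id: str
    variant_key: VariantKey
    gt: Genotype
    allele_string: str

    def __post_init__(self) -> None:
        _, _, ref, alt = self.variant_key
        expected = {
            Genotype.HOM_REF: ref + ref,
            Genotype.HET: ref + alt,
            Genotype.HOM_ALT: alt + alt,
        }[self.gt]
        if self.allele_string != expected:
            raise ValueError(
                f"allele string {self.allele_string!r} inconsistent with "
                f"{self.gt.value} for ref={ref} alt={alt}"
            )

    @classmethod
    def make(cls, sample_id: str, variant_key: VariantKey, gt: Genotype) -> "GenotypeCall":
        _, _, ref, alt = variant_key
        alleles = {
            Genotype.HOM_REF: ref + ref,
            Genotype.HET: ref + alt,
            Genotype.HOM_ALT: alt + alt,
        }[gt]
        return cls(sample_id, variant_key, gt, alleles)


@dataclass
class AnimalRecord:
    """A genotyped cohort animal with its binary phenotype.

    Wildtype brown and dark pigmented coats both map to PIGMENTED; the
    affected class is WHITE. ``genotypes`` maps variant key to the
    animal's call there; a missing key (or ``None``) means not genotyped.
    """

    animal_id: str
    location: str
    origin: Origin
    phenotype: Phenotype
    genotypes: dict[VariantKey, GenotypeCall | None] = field(default_factory=dict)

    def genotype_at(self, key: VariantKey) -> Genotype | None:
        call = self.genotypes.get(key)
        return None if call is None else call.gt
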