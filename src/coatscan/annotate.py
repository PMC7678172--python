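"""Coding-effect annotation of SNVs against single-transcript gene models.

Given a gene model (CDS segments in transcription order plus the
coding-strand sequence), an SNV is mapped into CDS space, its codon
located by codon arithmetic, the genomic alleles complemented for
minus-strand genes, and the amino-acid consequence read off the standard
genetic code. Output follows the capitalised-codon convention: the
variant base uppercase within a lowercase codon (``cTg/cCg``), with
HGVS-style ``c.``/``p.`` rendering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .models import CodingEffect, EffectClass, GeneModel, Variant

# Standard genetic code, bases enumerated T, C, A, G in the conventional
# textbook order (first base slowest).
_BASES = "TCAG"
_AA_ORDER = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"

GENETIC_CODE: dict[str, str] = {
    a + b + c: _AA_ORDER[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a codon (case-insensitive), ``*`` = stop."""
    return GENETIC_CODE[codon.upper()]


class AnnotationError(ValueError):
    """Gene model and variant disagree (reference mismatch or
    inconsistent strand evidence)."""


def cds_position(model: GeneModel, chrom: str, pos: int) -> int | None:
    """Map a genomic position to its 1-based CDS coordinate, or ``None``.

    Bases are counted along ``cds_segments`` in transcription order; for
    minus-strand genes each segment is traversed from its genomic end
    toward its start (the reverse-complement reading direction).
    """
    if chrom != model.chrom:
        return None
    offset = 0
    for start, end in model.cds_segments:
        if start <= pos <= end:
            if model.strand == "+":
                return offset + (pos - start) + 1
            return offset + (end - pos) + 1
        offset += end - start + 1
    return None


def genomic_position(model: GeneModel, cdna_pos: int) -> int:
    """Inverse of :func:`cds_position`: genomic coordinate of a CDS base."""
    if not 1 <= cdna_pos <= model.cds_length:
        raise ValueError(f"c.{cdna_pos} outside CDS of length {model.cds_length}")
    remaining = cdna_pos - 1
    for start, end in model.cds_segments:
        seg_len = end - start + 1
        if remaining < seg_len:
            return start + remaining if model.strand == "+" else end - remaining
        remaining -= seg_len
    raise AssertionError("unreachable: cdna_pos within validated CDS length")


def codon_arithmetic(cdna_pos: int) -> tuple[int, int]:
    """Residue number and within-codon offset for a CDS coordinate.

    ``codon_index = ceil(cdna_pos / 3)`` (1-based residue);
    ``codon_offset = ((cdna_pos - 1) mod 3) + 1`` (1..3). E.g. c.143 sits
    at the middle base (offset 2) of residue 48.
    """
    if cdna_pos < 1:
        raise ValueError(f"cdna_pos must be >= 1, got {cdna_pos}")
    return math.ceil(cdna_pos / 3), (cdna_pos - 1) % 3 + 1


def infer_strand(
    genomic_ref: str,
    genomic_alt: str,
    codon_ref: str,
    codon_alt: str,
    codon_offset: int,
) -> str:
    """Deduce transcript strand from genomic alleles vs codon capitals.

    Returns ``"+"`` if the capitalised coding bases equal the genomic
    alleles, ``"-"`` if they equal their Watson-Crick complements.
    Neither orientation matching is an annotation inconsistency.
    """
    for codon in (codon_ref, codon_alt):
        caps = [i for i, ch in enumerate(codon) if ch.isupper()]
        if len(codon) != 3 or caps != [codon_offset - 1]:
            raise ValueError(
                f"codon {codon!r} must carry exactly one capital at offset {codon_offset}"
            )
    coding_ref = codon_ref[codon_offset - 1]
    coding_alt = codon_alt[codon_offset - 1]
    if (coding_ref, coding_alt) == (genomic_ref.upper(), genomic_alt.upper()):
        return "+"
    if (coding_ref, coding_alt) == (
        complement(genomic_ref.upper()),
        complement(genomic_alt.upper()),
    ):
        return "-"
    raise AnnotationError(
        f"codon capitals {coding_ref}>{coding_alt} match neither orientation of "
        f"genomic {genomic_ref}>{genomic_alt}"
    )


def _capitalise(codon: str, offset: int, base: str) -> str:
    chars = list(codon.lower())
    chars[offset - 1] = base.upper()
    return "".join(chars)


def annotate(variant: Variant, model: GeneModel) -> CodingEffect | None:
    """Full coding-effect annotation of an SNV, or ``None`` if non-coding.

    The genomic alleles are complemented for minus-strand models before
    codon lookup. A disagreement between the model's CDS sequence and the
    variant's reference allele raises :class:`AnnotationError`.
    """
    if not variant.is_snv:
        raise ValueError(f"annotate expects an SNV, got {variant.ref}>{variant.alt}")
    cdna_pos = cds_position(model, variant.chrom, variant.pos)
    if cdna_pos is None:
        return None
    if model.strand == "+":
        ref_nt, alt_nt = variant.ref, variant.alt
    else:
        ref_nt, alt_nt = complement(variant.ref), complement(variant.alt)
    if model.cds_seq[cdna_pos - 1] != ref_nt:
        raise AnnotationError(
            f"{model.symbol} c.{cdna_pos}: CDS has {model.cds_seq[cdna_pos - 1]}, "
            f"variant reference implies {ref_nt}"
        )
    codon_index, codon_offset = codon_arithmetic(cdna_pos)
    codon_start = 3 * (codon_index - 1)
    ref_codon = model.cds_seq[codon_start : codon_start + 3]
    alt_codon = ref_codon[: codon_offset - 1] + alt_nt + ref_codon[codon_offset:]
    aa_ref = GENETIC_CODE[ref_codon]
    aa_alt = GENETIC_CODE[alt_codon]
    if aa_ref == aa_alt:
        effect = EffectClass.SYNONYMOUS
    elif aa_alt == "*":
        effect = EffectClass.NONSENSE
    elif codon_index == 1 and aa_ref == "M":
        effect = EffectClass.START_LOST
    else:
        effect = EffectClass.MISSENSE
    return CodingEffect(
        cdna_pos=cdna_pos,
        ref_nt=ref_nt,
        alt_nt=alt_nt,
        codon_index=codon_index,
        codon_offset=codon_offset,
        codon_ref=_capitalise(ref_codon, codon_offset, ref_nt),
        codon_alt=_capitalise(alt_codon, codon_offset, alt_nt),
        aa_ref=aa_ref,
        aa_alt=aa_alt,
        effect_class=effect,
    )


@dataclass(frozen=True)
class CandidateCheck:
    """Outcome of re-deriving one printed candidate annotation."""

    gene: str
    cdna_pos: int
    expected: str
    recomputed: str
    strand: str
    matches: bool


def verify_candidates(rows) -> tuple[int, list[CandidateCheck]]:
    """Recompute each printed candidate annotation and count matches.

    For every row (see :class:`coatscan.io.CandidateRow`) the residue
    number and codon offset are re-derived from the c. position, the
    strand from the genomic alleles against the codon capitals, the
    amino-acid change by translating the printed codons — and the result
    is compared with the printed substitution (e.g. ``p.L48P``). Returns
    ``(n_matching, per-row checks)``; a deliberately corrupted row counts
    as a mismatch rather than an error.
    """
    checks: list[CandidateCheck] = []
    for row in rows:
        codon_index, codon_offset = codon_arithmetic(row.cdna_pos)
        strand = infer_strand(row.ref, row.alt, row.codon_ref, row.codon_alt, codon_offset)
        aa_ref = translate_codon(row.codon_ref)
        aa_alt = translate_codon(row.codon_alt)
        recomputed = (
            f"p.{aa_ref}{codon_index}=" if aa_ref == aa_alt
            else f"p.{aa_ref}{codon_index}{aa_alt}"
        )
        checks.append(
            CandidateCheck(
                gene=row.gene,
                cdna_pos=row.cdna_pos,
                expected=row.aa_sub,
                recomputed=recomputed,
                strand=strand,
                matches=recomputed == row.aa_sub,
            )
        )
    return sum(c.matches for c in checks), checks
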