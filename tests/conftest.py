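"""Shared fixtures: small synthetic gene models and the packaged cohort.

The MC1R-like model is synthetic: real coordinates for the causal site
(bovine chr18:14,705,518) but a generated CDS — only the codon under
test (CTG at residue 48) is pinned to the published annotation.
"""

from __future__ import annotations

import numpy as np
import pytest

from coatscan import (
    GeneModel,
    Genotype,
    GenotypeCall,
    Variant,
    load_candidate_table,
    load_cohort_panel,
)

_SENSE = [
    c for c in (a + b + d for a in "ACGT" for b in "ACGT" for d in "ACGT")
    if c not in ("TAA", "TAG", "TGA")
]


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    body = "".join(_SENSE[k] for k in rng.choice(len(_SENSE), size=n_codons - 2))
    return "ATG" + body + "TGA"


@pytest.fixture(scope="session")
def mc1r_model() -> GeneModel:
    """Plus-strand single-exon model placing c.143 at chr18:14,705,518
    inside a CTG (leucine) codon at residue 48, as published."""
    rng = np.random.default_rng(180143)
    seq = list(_random_cds(rng, 318))  # 954 bp, the MC1R CDS length
    seq[141:144] = "CTG"  # codon 48
    start = 14705518 - 142  # genomic position of c.1
    return GeneModel(
        symbol="MC1R",
        accession="SYNTHETIC_MC1R.1",
        chrom="18",
        strand="+",
        cds_segments=((start, start + 954 - 1),),
        cds_seq="".join(seq),
    )


@pytest.fixture(scope="session")
def atrn_model() -> GeneModel:
    """Minus-strand model with a GAT (aspartate) codon at residue 525,
    mirroring the published ATRN annotation (genomic C>T, coding G>A)."""
    rng = np.random.default_rng(131573)
    n_codons = 600
    seq = list(_random_cds(rng, n_codons))
    seq[1572:1575] = "GAT"  # codon 525 spans c.1573-1575
    length = 3 * n_codons
    start = 51_640_000
    return GeneModel(
        symbol="ATRN",
        accession="SYNTHETIC_ATRN.1",
        chrom="13",
        strand="-",
        cds_segments=((start, start + length - 1),),
        cds_seq="".join(seq),
    )


@pytest.fixture(scope="session")
def candidate_rows():
    return load_candidate_table()


@pytest.fixture(scope="session")
def cohort_panel():
    return load_cohort_panel()


def make_call(variant: Variant, sample: str, gt: Genotype) -> GenotypeCall:
    return GenotypeCall.make(sample, variant.key, gt)
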