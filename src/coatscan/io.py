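"""Readers and writers: minimal VCF dialect, gene-model TSV, gene lists,
phenotype/genotyping panels, and the packaged reference fixtures.

The VCF dialect is a deliberately small v4.2 subset: tab-separated,
biallelic records only, ``GT`` as the first FORMAT key, phased separators
normalised to unphased, ``./.`` parsed as missing. Round-tripping through
:func:`write_vcf` and :func:`read_vcf` is lossless for this dialect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .models import (
    AnimalRecord,
    Genotype,
    GenotypeCall,
    GeneModel,
    Origin,
    Phenotype,
    Variant,
    VariantKey,
)


class VcfParseError(ValueError):
    """Malformed VCF content; the message names the offending line."""


class UnsupportedRecordError(VcfParseError):
    """Record outside the supported dialect (e.g. multi-allelic)."""


class PanelValidationError(ValueError):
    """Panel TSV contains an unparseable row."""


#: One VCF body entry: the site plus each declared sample's call
#: (``None`` where the genotype is missing).
VcfRecord = tuple[Variant, dict[str, GenotypeCall | None]]

_VCF_HEADER_LINES = (
    "##fileformat=VCFv4.2",
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
)

_GT_CODES = {
    "0/0": Genotype.HOM_REF,
    "0/1": Genotype.HET,
    "1/0": Genotype.HET,
    "1/1": Genotype.HOM_ALT,
}

_GT_RENDER = {
    Genotype.HOM_REF: "0/0",
    Genotype.HET: "0/1",
    Genotype.HOM_ALT: "1/1",
}


def read_vcf(path: str | Path) -> tuple[list[str], list[VcfRecord]]:
    """Parse a minimal VCF into variants with per-sample genotype calls.

    Returns ``(sample_ids, records)`` with records in file order.
    Multi-allelic ALT fields raise :class:`UnsupportedRecordError`;
    any other malformed line raises :class:`VcfParseError` naming the
    line number.
    """
    path = Path(path)
    samples: list[str] | None = None
    records: list[VcfRecord] = []
    with path.open() as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                fields = line.split("\t")
                if len(fields) < 10 or fields[8] != "FORMAT":
                    raise VcfParseError(
                        f"line {lineno}: header must declare FORMAT and at least one sample"
                    )
                samples = fields[9:]
                continue
            if samples is None:
                raise VcfParseError(f"line {lineno}: record before #CHROM header")
            records.append(_parse_record(line, lineno, samples))
    if samples is None:
        raise VcfParseError(f"{path}: no #CHROM header line found")
    return samples, records


def _parse_record(line: str, lineno: int, samples: list[str]) -> VcfRecord:
    fields = line.split("\t")
    if len(fields) != 9 + len(samples):
        raise VcfParseError(
            f"line {lineno}: expected {9 + len(samples)} columns, got {len(fields)}"
        )
    chrom, pos_s, _id, ref, alt, qual_s, _filt, _info, fmt = fields[:9]
    if "," in alt:
        raise UnsupportedRecordError(f"line {lineno}: multi-allelic record (ALT={alt!r})")
    if fmt.split(":")[0] != "GT":
        raise VcfParseError(f"line {lineno}: FORMAT must lead with GT, got {fmt!r}")
    try:
        pos = int(pos_s)
        qual = 0.0 if qual_s == "." else float(qual_s)
        variant = Variant(chrom=chrom, pos=pos, ref=ref, alt=alt, qual=qual)
    except ValueError as exc:
        raise VcfParseError(f"line {lineno}: {exc}") from exc
    calls: dict[str, GenotypeCall | None] = {}
    for sample, cell in zip(samples, fields[9:]):
        gt_token = cell.split(":")[0].replace("|", "/")
        if gt_token in (".", "./."):
            calls[sample] = None
            continue
        gt = _GT_CODES.get(gt_token)
        if gt is None:
            raise VcfParseError(f"line {lineno}: unsupported GT {gt_token!r} for {sample}")
        calls[sample] = GenotypeCall.make(sample, variant.key, gt)
    return variant, calls


def write_vcf(
    records: Sequence[VcfRecord], path: str | Path, samples: Sequence[str] | None = None
) -> Path:
    """Serialise records to the minimal dialect; inverse of :func:`read_vcf`.

    ``samples`` fixes the column order; by default it is taken from the
    first record. Every record must carry exactly that sample set.
    """
    path = Path(path)
    if samples is None:
        if not records:
            raise ValueError("cannot infer sample columns from an empty record list")
        samples = list(records[0][1])
    samples = list(samples)
    lines = list(_VCF_HEADER_LINES)
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    for variant, calls in records:
        if set(calls) != set(samples):
            raise ValueError(
                f"inconsistent sample columns at {variant.chrom}:{variant.pos}: "
                f"{sorted(calls)} != {sorted(samples)}"
            )
        qual = variant.qual
        qual_s = f"{qual:g}"
        cells = []
        for sample in samples:
            call = calls[sample]
            cells.append("./." if call is None else _GT_RENDER[call.gt])
        lines.append(
            "\t".join(
                [variant.chrom, str(variant.pos), ".", variant.ref, variant.alt,
                 qual_s, ".", ".", "GT", *cells]
            )
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def read_gene_list(path: str | Path) -> set[str]:
    """Read a one-symbol-per-line gene list into an upper-cased set.

    ``#`` comments and blank lines are ignored. An empty result warns
    rather than erroring (an empty candidate list is legal but almost
    certainly an operator mistake).
    """
    symbols: set[str] = set()
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if line:
            symbols.add(line.upper())
    if not symbols:
        warnings.warn(f"gene list {path} is empty", stacklevel=2)
    return symbols


def write_gene_list(symbols: Iterable[str], path: str | Path) -> Path:
    path = Path(path)
    path.write_text("\n".join(sorted({s.upper() for s in symbols})) + "\n")
    return path


# ---------------------------------------------------------------------------
# Gene-model TSV: symbol, accession, chrom, strand, segments, cds_seq
# with segments rendered "start-end;start-end" in transcription order.

def read_gene_models(path: str | Path) -> list[GeneModel]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {"symbol", "accession", "chrom", "strand", "segments", "cds_seq"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"gene-model table missing columns: {sorted(missing)}")
    models = []
    for row in frame.itertuples(index=False):
        segments = tuple(
            (int(a), int(b))
            for a, b in (part.split("-") for part in row.segments.split(";"))
        )
        models.append(
            GeneModel(
                symbol=row.symbol,
                accession=row.accession,
                chrom=row.chrom,
                strand=row.strand,
                cds_segments=segments,
                cds_seq=row.cds_seq,
            )
        )
    return models


def write_gene_models(models: Sequence[GeneModel], path: str | Path) -> Path:
    rows = [
        {
            "symbol": m.symbol,
            "accession": m.accession,
            "chrom": m.chrom,
            "strand": m.strand,
            "segments": ";".join(f"{a}-{b}" for a, b in m.cds_segments),
            "cds_seq": m.cds_seq,
        }
        for m in models
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return Path(path)


# ---------------------------------------------------------------------------
# Phenotype/genotyping panel TSV

_PHENOTYPE_TOKENS = {
    "wt": Phenotype.PIGMENTED,
    "wildtype": Phenotype.PIGMENTED,
    "brown": Phenotype.PIGMENTED,
    "dark pigmented": Phenotype.PIGMENTED,
    "wt/dark pigmented": Phenotype.PIGMENTED,
    "pigmented": Phenotype.PIGMENTED,
    "white": Phenotype.WHITE,
}

_MISSING_GT = {"", ".", "./.", "na", "nan"}

_FIXED_PANEL_COLUMNS = ["animal_id", "location", "origin", "phenotype"]


def parse_variant_column(name: str) -> VariantKey:
    chrom, pos, ref, alt = name.split(":")
    return (chrom, int(pos), ref, alt)


def format_variant_column(key: VariantKey) -> str:
    chrom, pos, ref, alt = key
    return f"{chrom}:{pos}:{ref}:{alt}"


def _parse_allele_cell(cell: str, sample: str, key: VariantKey) -> GenotypeCall | None:
    token = cell.strip()
    if token.lower() in _MISSING_GT:
        return None
    _, _, ref, alt = key
    alleles = token.split("/") if "/" in token else [token[: len(ref)], token[len(ref):]]
    pair = sorted(alleles)
    if pair == sorted([ref, ref]):
        gt = Genotype.HOM_REF
    elif pair == sorted([ref, alt]):
        gt = Genotype.HET
    elif pair == sorted([alt, alt]):
        gt = Genotype.HOM_ALT
    else:
        raise PanelValidationError(
            f"genotype {token!r} for {sample} does not match alleles {ref}/{alt}"
        )
    return GenotypeCall.make(sample, key, gt)


def read_panel(path: str | Path) -> list[AnimalRecord]:
    """Read a genotyping panel TSV into :class:`AnimalRecord` rows.

    Fixed leading columns ``animal_id, location, origin, phenotype`` are
    followed by one column per variant key (``chrom:pos:ref:alt``) whose
    cells hold allele-letter genotypes (``TT``/``TC``/``CC`` style) or a
    missing marker. Unknown phenotype tokens raise
    :class:`PanelValidationError` naming the offending row.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = set(_FIXED_PANEL_COLUMNS) - set(frame.columns)
    if missing:
        raise PanelValidationError(f"panel missing columns: {sorted(missing)}")
    variant_keys = {
        col: parse_variant_column(col)
        for col in frame.columns
        if col not in _FIXED_PANEL_COLUMNS
    }
    records: list[AnimalRecord] = []
    for idx, row in enumerate(frame.to_dict("records"), start=2):
        token = str(row["phenotype"]).strip().lower()
        phenotype = _PHENOTYPE_TOKENS.get(token)
        if phenotype is None:
            raise PanelValidationError(
                f"row {idx} (animal {row['animal_id']!r}): unknown phenotype {row['phenotype']!r}"
            )
        genotypes: dict[VariantKey, GenotypeCall | None] = {}
        for col, key in variant_keys.items():
            genotypes[key] = _parse_allele_cell(str(row[col]), str(row["animal_id"]), key)
        records.append(
            AnimalRecord(
                animal_id=str(row["animal_id"]),
                location=str(row["location"]),
                origin=Origin(str(row["origin"]).strip().upper()),
                phenotype=phenotype,
                genotypes=genotypes,
            )
        )
    return records


def _render_allele_cell(call: GenotypeCall | None, key: VariantKey) -> str:
    """``TT``-style for single-base alleles; ``AT/A`` style for indels."""
    if call is None:
        return "./."
    _, _, ref, alt = key
    pair = {
        Genotype.HOM_REF: (ref, ref),
        Genotype.HET: (ref, alt),
        Genotype.HOM_ALT: (alt, alt),
    }[call.gt]
    if len(ref) == 1 and len(alt) == 1:
        return "".join(pair)
    return "/".join(pair)


def write_panel(
    records: Sequence[AnimalRecord], path: str | Path, variant_keys: Sequence[VariantKey]
) -> Path:
    rows = []
    for rec in records:
        row: dict[str, str] = {
            "animal_id": rec.animal_id,
            "location": rec.location,
            "origin": rec.origin.value,
            "phenotype": "white" if rec.phenotype is Phenotype.WHITE else "WT",
        }
        for key in variant_keys:
            call = rec.genotypes.get(key)
            row[format_variant_column(key)] = _render_allele_cell(call, key)
        rows.append(row)
    columns = _FIXED_PANEL_COLUMNS + [format_variant_column(k) for k in variant_keys]
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)
    return Path(path)


# ---------------------------------------------------------------------------
# Packaged fixtures: the 19 Sanger-confirmed candidate annotations, the
# 102-animal MC1R genotyping panel, and the per-location cohort table.

#: Variant key of the causal MC1R coat-colour SNV (bovine chr18 coords).
MC1R_KEY: VariantKey = ("18", 14705518, "T", "C")


@dataclass(frozen=True)
class CandidateRow:
    """One printed candidate annotation: genomic site, gene, and the
    published coding interpretation (c. position, capitalised codons,
    amino-acid substitution)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    accession: str
    cdna_pos: int
    codon_ref: str
    codon_alt: str
    aa_sub: str


def _data_path(name: str):
    return resources.files("coatscan.data").joinpath(name)


def load_candidate_table() -> list[CandidateRow]:
    """The packaged 19-row candidate-SNP annotation table."""
    with resources.as_file(_data_path("candidate_annotations.tsv")) as path:
        frame = pd.read_csv(path, sep="\t", dtype=str)
    return [
        CandidateRow(
            chrom=row.chrom,
            pos=int(row.pos),
            ref=row.ref,
            alt=row.alt,
            gene=row.gene,
            accession=row.accession,
            cdna_pos=int(row.cdna_pos),
            codon_ref=row.codon_ref,
            codon_alt=row.codon_alt,
            aa_sub=row.aa_sub,
        )
        for row in frame.itertuples(index=False)
    ]


def load_cohort_panel() -> list[AnimalRecord]:
    """The packaged 102-animal cohort genotyped at the MC1R SNV.

    Margins reproduce the published counts (69 TT + 11 TC pigmented,
    22 CC white); the assignment of carriers to sampling locations is
    synthetic — the published table reports genotype totals only.
    """
    with resources.as_file(_data_path("cohort_panel.tsv")) as path:
        return read_panel(path)


def load_location_summary() -> pd.DataFrame:
    """Per-location cohort composition (location, origin, counts)."""
    with resources.as_file(_data_path("cohort_locations.tsv")) as path:
        return pd.read_csv(path, sep="\t")
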