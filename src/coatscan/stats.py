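"""Exact genotype-phenotype association on the genotyped cohort.

The central statistic is Fisher's exact conditional test for an r x c
contingency table, computed by exhaustive enumeration of all tables
sharing the observed margins. Under the null, a table's probability is

    P(table) = (prod_i R_i! * prod_j C_j!) / (N! * prod_ij n_ij!)

and the two-sided p-value sums the probabilities of all
margin-compatible tables no more probable than the observed one
(probability-mass criterion, with a small relative tie tolerance).
Everything is computed in log space. At the scale this pipeline needs
(phenotype x genotype, 2 x 3) exhaustive enumeration is exact and
instantaneous; no network-algorithm optimisation is required.

Also here: carrier frequency among unaffected animals, recessive-model
concordance, and cohort accounting.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .models import AnimalRecord, Genotype, Phenotype, VariantKey

_TIE_RTOL = 1e-7


class UndefinedStatistic(ValueError):
    """The requested quantity has an empty denominator (e.g. carrier
    frequency with zero pigmented animals)."""


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (13.75 -> 13.8 at one decimal, 0.5 -> 1)."""
    factor = 10**ndigits
    scaled = x * factor
    rounded = math.floor(scaled + 0.5) if scaled >= 0 else math.ceil(scaled - 0.5)
    return rounded / factor


@dataclass
class ContingencyTable:
    """Phenotype (rows) x genotype (columns) integer counts.

    The canonical layout is rows (PIGMENTED, WHITE) by columns
    (HOM_REF, HET, HOM_ALT) with columns labelled by allele letters
    (``TT``/``TC``/``CC``). ``n_excluded`` counts animals without a
    genotype call at the tested site.
    """

    counts: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    n_excluded: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D array")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("labels do not match counts shape")

    @property
    def row_margins(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def collapse_recessive(self) -> "ContingencyTable":
        """2x2 collapse: homozygous-alt vs all other genotypes."""
        if self.counts.shape[1] < 2:
            raise ValueError("need at least two genotype columns to collapse")
        merged = np.column_stack(
            [self.counts[:, :-1].sum(axis=1), self.counts[:, -1]]
        )
        return ContingencyTable(
            merged,
            self.row_labels,
            (f"non-{self.col_labels[-1]}", self.col_labels[-1]),
            self.n_excluded,
        )


_GT_ORDER = (Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT)


def build_table(records: list[AnimalRecord], variant_key: VariantKey) -> ContingencyTable:
    """Tabulate phenotype x genotype at one site over the cohort.

    Rows are (PIGMENTED, WHITE); columns the three genotypes rendered
    with the site's allele letters. Animals without a call at the site
    are excluded from the counts and tallied in ``n_excluded``.
    """
    _, _, ref, alt = variant_key
    counts = np.zeros((2, 3), dtype=int)
    excluded = 0
    for animal in records:
        gt = animal.genotype_at(variant_key)
        if gt is None:
            excluded += 1
            continue
        row = 0 if animal.phenotype is Phenotype.PIGMENTED else 1
        counts[row, _GT_ORDER.index(gt)] += 1
    return ContingencyTable(
        counts,
        row_labels=("PIGMENTED", "WHITE"),
        col_labels=(ref + ref, ref + alt, alt + alt),
        n_excluded=excluded,
    )


def _enumerate_tables(row_margins, col_margins):
    """Yield every non-negative integer matrix with the given margins.

    Rows are filled one at a time; within a row all but the last cell
    range over their feasible values and the last is forced. The final
    row is forced entirely by the column remainders. Feasibility pruning
    keeps the walk tight; at phenotype-by-genotype scale the whole space
    is tiny.
    """
    r, c = len(row_margins), len(col_margins)

    def fill(row_idx, col_remaining):
        if row_idx == r - 1:
            if all(x >= 0 for x in col_remaining) and sum(col_remaining) == row_margins[-1]:
                yield (tuple(col_remaining),)
            return
        target = row_margins[row_idx]
        ranges = [range(min(target, col_remaining[j]) + 1) for j in range(c - 1)]
        for head in itertools.product(*ranges):
            last = target - sum(head)
            if last < 0 or last > col_remaining[c - 1]:
                continue
            row = head + (last,)
            rest = [col_remaining[j] - row[j] for j in range(c)]
            for tail in fill(row_idx + 1, rest):
                yield (row,) + tail

    yield from fill(0, list(col_margins))


def _log_table_prob(cells, log_const):
    return log_const - sum(math.lgamma(x + 1) for row in cells for x in row)


def fisher_exact_rxc(table: ContingencyTable | np.ndarray, collapse: bool = False) -> float:
    """Two-sided exact conditional p-value for an r x c table.

    Enumerates all tables with the observed margins and sums the
    probabilities of those whose hypergeometric probability does not
    exceed the observed table's (relative tie tolerance 1e-7). Zero rows
    and columns are collapsed out first; a table with at most one
    non-trivial row or column admits a single configuration, so p = 1.

    ``collapse=True`` first merges genotype columns into homozygous-alt
    vs the rest (2 x 2 recessive collapse).
    """
    if isinstance(table, ContingencyTable):
        if collapse:
            table = table.collapse_recessive()
        counts = table.counts
    else:
        counts = np.asarray(table, dtype=int)
        if collapse:
            counts = np.column_stack([counts[:, :-1].sum(axis=1), counts[:, -1]])
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    counts = counts[counts.sum(axis=1) > 0][:, counts.sum(axis=0) > 0]
    if counts.size == 0 or counts.shape[0] == 1 or counts.shape[1] == 1:
        return 1.0

    row_margins = tuple(int(x) for x in counts.sum(axis=1))
    col_margins = tuple(int(x) for x in counts.sum(axis=0))
    total = sum(row_margins)
    log_const = (
        sum(math.lgamma(m + 1) for m in row_margins)
        + sum(math.lgamma(m + 1) for m in col_margins)
        - math.lgamma(total + 1)
    )
    observed = tuple(tuple(int(x) for x in row) for row in counts)
    log_p_obs = _log_table_prob(observed, log_const)
    threshold = log_p_obs + math.log1p(_TIE_RTOL)
    p = 0.0
    for cells in _enumerate_tables(row_margins, col_margins):
        log_p = _log_table_prob(cells, log_const)
        if log_p <= threshold:
            p += math.exp(log_p)
    return min(p, 1.0)


def enumeration_total_probability(row_margins, col_margins) -> float:
    """Sum of hypergeometric probabilities over all margin-compatible
    tables — equals 1 up to floating error (normalisation diagnostic)."""
    row_margins = tuple(int(x) for x in row_margins)
    col_margins = tuple(int(x) for x in col_margins)
    log_const = (
        sum(math.lgamma(m + 1) for m in row_margins)
        + sum(math.lgamma(m + 1) for m in col_margins)
        - math.lgamma(sum(row_margins) + 1)
    )
    return sum(
        math.exp(_log_table_prob(cells, log_const))
        for cells in _enumerate_tables(row_margins, col_margins)
    )


@dataclass(frozen=True)
class CarrierFrequency:
    """Heterozygote share among unaffected animals: the exact percentage
    and its integer rendering (half away from zero)."""

    pct: float
    rendered: int
    n_carriers: int
    n_unaffected: int


def carrier_frequency(table: ContingencyTable) -> CarrierFrequency:
    """Percentage of PIGMENTED animals heterozygous at the tested site."""
    pig = table.counts[table.row_labels.index("PIGMENTED")]
    n_pig = int(pig.sum())
    if n_pig == 0:
        raise UndefinedStatistic("no pigmented animals: carrier frequency undefined")
    n_het = int(pig[1])
    pct = 100.0 * n_het / n_pig
    return CarrierFrequency(pct, int(round_half_away(pct)), n_het, n_pig)


def concordance(table: ContingencyTable) -> float:
    """Percent agreement with the recessive-model prediction.

    The model predicts WHITE iff homozygous-alt, so matches are
    pigmented HOM_REF + pigmented HET + white HOM_ALT.
    """
    if table.total == 0:
        raise UndefinedStatistic("empty table: concordance undefined")
    pig = table.row_labels.index("PIGMENTED")
    white = 1 - pig
    matching = int(table.counts[pig, 0] + table.counts[pig, 1] + table.counts[white, 2])
    return 100.0 * matching / table.total


@dataclass
class CohortSummary:
    n_total: int
    n_pigmented: int
    n_white: int
    white_pct: float | None
    per_location: dict[str, dict[str, int]] = field(default_factory=dict)


def cohort_summary(records: list[AnimalRecord]) -> CohortSummary:
    """Cohort accounting: totals, white fraction (one decimal, half away
    from zero), and per-location phenotype counts."""
    n_total = len(records)
    n_white = sum(a.phenotype is Phenotype.WHITE for a in records)
    n_pig = n_total - n_white
    per_location: dict[str, dict[str, int]] = {}
    for a in records:
        loc = per_location.setdefault(a.location, {"n": 0, "n_pigmented": 0, "n_white": 0})
        loc["n"] += 1
        loc["n_white" if a.phenotype is Phenotype.WHITE else "n_pigmented"] += 1
    white_pct = None if n_total == 0 else round_half_away(100.0 * n_white / n_total, 1)
    return CohortSummary(n_total, n_pig, n_white, white_pct, per_location)


@dataclass
class AssociationResult:
    """Association summary for one candidate site on one cohort."""

    variant: VariantKey
    table: ContingencyTable
    p_value: float
    concordance_pct: float
    carrier: CarrierFrequency


def associate(records: list[AnimalRecord], variant_key: VariantKey) -> AssociationResult:
    """Build the table and compute the exact test, concordance, and
    carrier frequency in one step."""
    table = build_table(records, variant_key)
    return AssociationResult(
        variant=variant_key,
        table=table,
        p_value=fisher_exact_rxc(table),
        concordance_pct=concordance(table),
        carrier=carrier_frequency(table),
    )
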