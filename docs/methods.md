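# Methods

## Model and assumptions

The pipeline assumes a single fully penetrant autosomal-recessive
biallelic causal variant: an animal is affected (white-diluted) iff it
is homozygous for the alternative allele, with no phenocopies. Under
this model a sequenced affected dam with an unaffected calf pins two
genotypes for free — the dam must be hom-alt and the calf, carrying
exactly one maternal allele, an obligate heterozygote. The recessive
trio filter implements exactly that conjunction; every other genotype
pair, and any missing genotype, removes a candidate.

Variants are interpreted against single-transcript gene models (one
model per gene; isoform ambiguity is out of scope). A gene model is the
ordered list of CDS segments in transcription order plus the
coding-strand sequence; minus-strand genes are handled by complementing
the genomic alleles before codon lookup, never by rewriting the model.
Effect classes are synonymous, missense, nonsense and start-lost;
start-lost and nonsense are retained by the non-synonymous filter but
given no special weight, since the discovery setting treats any
protein-changing variant as a candidate.

## Filtering cascade

Stage order is fixed: indel-proximity QC → candidate-gene subset →
coding annotation → non-synonymous restriction → recessive trio filter
→ panel refinement (one stage per panel, in the order given). The QC
rule removes an SNV iff an indel on the same chromosome lies within 3
bp of its POS *and* the SNV's QUAL is strictly below that indel's; the
comparison is pairwise against the nearby indel, not against a global
threshold, which is the closest literal reading of the source
procedure. Equal QUAL keeps the SNV. Indels are never removed by the
rule.

Panel refinement is exact concordance, not a statistical threshold: a
candidate survives a panel iff every affected animal is hom-alt and no
unaffected animal is. The formal test is reserved for the full cohort,
matching the original order of operations (small panels first, one
exact test at the end). Missing panel genotypes neither confirm nor
eliminate a candidate; they are logged in the cascade report.

## Exact association test

The phenotype × genotype table (2 rows × 3 genotype columns) is tested
with Fisher's exact conditional test generalised to r×c: all tables
with the observed margins are enumerated, each assigned its
multivariate hypergeometric probability computed in log space
(`lgamma`), and the two-sided p-value sums the probabilities of tables
whose probability does not exceed the observed one. Ties are admitted
with a relative tolerance of 1e-7. Zero rows/columns are collapsed out
first; a table with at most one non-trivial row or column admits a
single configuration, so p = 1. Exhaustive enumeration is exact and
costs microseconds at this table size (the 2×3 cohort table has 78
margin-compatible configurations); the network algorithms used for
large sparse tables are unnecessary here. A 2×2 recessive collapse
(hom-alt vs rest) is available as an option but the 2×3 table is the
default and is what the reported p-value comes from.

Percentages are rendered half-away-from-zero: carrier frequency to an
integer (11/80 = 13.75 → "14 %"), cohort white fraction to one decimal
(22/102 → "21.6 %"). The exact fractions are always carried alongside
the renderings.

## Fixture-derived reference values

Three small TSV fixtures ship with the package: the 19-row candidate
annotation table, a 102-animal genotyping panel, and a per-location
cohort composition table. The panel reproduces the published genotype
margins exactly (69 TT + 11 TC pigmented, 22 CC white); the assignment
of the 11 carriers to sampling locations is synthetic, since only
totals were published. The per-location table is a best-effort
reconstruction: two rows of the printed source are typographically
ambiguous, and the values chosen here are the unique reading under
which every row sums and the printed totals (102 animals, 80 pigmented,
22 white, eight game parks and four hunting grounds) all hold. Only the
totals should be treated as authoritative.

The annotation-verification routine re-derives, for each candidate row,
the residue number and codon offset from the c. coordinate, the
transcript strand from the genomic alleles against the codon capitals,
and the amino-acid substitution by translating the printed codons. Note
that the published c.N X>Y column carries the *genomic* (plus-strand)
alleles even for minus-strand genes; the package's own annotator emits
coding-strand alleles in `c.` notation, and the verifier compares
strand-consistency exactly as printed, so both conventions are honoured
where each applies.

## Synthetic-data generator

The generator emulates the study design, not the sequencing process:
no reads, no coverage model, no reference genome — pipeline input
starts at variant calls.

Defaults (chosen once, as study conditions):

| parameter | default | rationale |
|---|---|---|
| `n_animals` | 102 | the genotyped cohort size |
| `q` | 0.27 | cohort allele-frequency estimate, (2·22 + 11)/204 ≈ 0.2696 |
| `n_background` | 500 | enough unlinked coding variants that every cascade stage does real work at desk scale |
| `n_genes` | 16 | the candidate-gene count surviving the published cascade |
| `gene_length_codons` | 200 | a mid-sized protein; MC1R itself is 317 codons |
| `indel_rate` | 0.1 | a visible minority of background calls, exercising the QC stage |
| `qual_range` | (20, 100) | typical phred QUAL span for accepted calls |
| `penetrance` | 1.0 | no discordant animal was observed |
| `error_rate` | 0.0 | genotyping reported as perfect; knob exists for robustness tests |
| `min_whites` | 4 | see below |

Cohort genotypes are Hardy–Weinberg draws at frequency `q`; phenotype
is deterministic from genotype at full penetrance. The dam is the first
affected animal; the calf receives one maternal allele (necessarily
alt) and a paternal allele that is alt with probability `q`, rejected
until the unaffected constraint holds — sires are not modelled as
individuals. Background sites draw dam genotypes from Hardy–Weinberg
and calf genotypes by the same Mendelian transmission, independently
across sites (no linkage), so the expected fraction of background
variants passing the trio filter is q²(1−q), a property the tests check
against binomial sampling error.

Two deliberate departures from a plain random cross-section, both
emulating how the real cohort was assembled:

- the cohort is redrawn (deterministically, from the same seeded
  stream) until at least `min_whites` affected animals exist, because
  the original cohort was phenotype-aware sampling — every known white
  animal was collected — and the staged validation design (1 white +
  1 pigmented, then 3+3, then all) needs affected animals to staff it.
  If the allele is too rare for redrawing to succeed, the deficit is
  forced hom-alt with a logged note. Within a draw, genotypes remain
  plain Hardy–Weinberg.
- background variants are never placed within 3 bp of the implanted
  causal site, so the causal cannot be silently removed by the
  indel-proximity QC of its own background; the study's causal variant,
  by construction of having been found, survived QC.

Panels genotype every candidate site: the causal genotype comes from
the cohort truth; every other site draws per-animal Hardy–Weinberg
genotypes once, so an animal's genotype is consistent across the nested
panels. Panels are cumulative by default (earlier validation animals
are retested on later panels), with a disjoint mode available. The dam
and calf sort last within their phenotype groups so early panels test
additional animals, as the original validation did.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: linkage between background sites, population
structure across the 12 sampling locations, genotyping failure
patterns, reference-mapping artefacts from cross-species alignment, and
any variant class beyond SNVs and 1-bp indels. Genome-scale variant
counts (millions of SNPs) are deliberately out of reach; the cascade is
exercised at hundreds of sites, which preserves every decision point of
the procedure while keeping the full test suite under ten seconds.

## Numerical choices and degenerate inputs

- All randomness flows through numpy Generators seeded as
  `[seed, stream]`, one fixed stream per generator component, so
  results are bit-reproducible and independent of call order.
- Fisher tie tolerance 1e-7 (relative, in log space); enumeration
  normalisation is tested to 1e-9.
- Empty tables, single-row tables, zero margins: p = 1. Carrier
  frequency with no unaffected animals and concordance of an empty
  table raise a distinct `UndefinedStatistic` error rather than
  returning a sentinel.
- Empty VCF bodies, empty panels and empty gene lists are legal inputs
  that produce empty outputs (an empty gene list warns).
- VCF QUAL serialises via `%g`; the supported dialect is biallelic,
  GT-first, with phased separators normalised to `/` and `./.` as
  missing.

## Known limitations

- One transcript model per gene; no isoform resolution, no splice-site
  or regulatory annotation.
- Only SNVs are annotated for coding effect; indels are carried through
  QC and then dropped at annotation, mirroring a discovery procedure
  that could not have detected indel or structural causes.
- The trio filter assumes zero genotyping error in the sequenced pair;
  a single miscall at the causal site would eliminate it. The
  `error_rate` knob exists to study this on panels, not on the trio.
- The exact test enumerates margin-compatible tables; it is intended
  for small tables (few rows/columns, cohort-scale counts), not for
  large sparse contingency problems.
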