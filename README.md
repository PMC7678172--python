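# coatscan

Candidate-gene discovery of a fully penetrant recessive coding variant,
built around the search for the cause of white coat-colour dilution in
fallow deer (*Dama dama*). Affected animals are not albinos — the coat
is diluted to pale beige while eyes and claws stay pigmented — and the
trait segregates as an autosomal recessive. The package takes the
analysis from a two-sample VCF (an affected dam and her unaffected,
obligate-carrier calf, mapped against the bovine reference) through a
candidate-gene filtering cascade to an exact genotype–phenotype
association on a genotyped cohort. The terminal result it reproduces is
the MC1R missense change NM_174108.2:c.143T>C (p.L48P), in genotype
class CC in every white animal and absent in homozygous form from every
pigmented one.

It is aimed at researchers doing trio- or duo-based recessive variant
prioritisation in non-model species, where annotation must run against
a related reference genome and validation proceeds by staged genotyping
panels rather than large case–control cohorts.

## The method

1. **Variant QC** — SNVs within 3 bp of an indel whose QUAL exceeds
   theirs are removed.
2. **Candidate-gene subsetting** — variants are kept only inside CDS
   segments of genes on a colour-gene list.
3. **Coding-effect annotation** — each SNV is mapped to its CDS
   coordinate (strand-aware: genomic alleles are Watson–Crick
   complemented for minus-strand genes), placed in its codon
   (`codon_index = ceil(c/3)`, `codon_offset = ((c−1) mod 3)+1`), and
   translated; output uses the capitalised-codon convention (`cTg/cCg`)
   and HGVS-like `c.`/`p.` notation.
4. **Non-synonymous restriction** — synonymous changes are dropped.
5. **Recessive trio filter** — under full penetrance the affected dam
   must be homozygous for the alternative allele and the unaffected
   calf heterozygous; all other genotype pairs are filtered out.
6. **Panel refinement** — surviving candidates are screened against
   validation panels of increasing size; a candidate survives only if
   every affected animal is hom-alt and no unaffected animal is.
7. **Exact association** — the full cohort's phenotype × genotype table
   is tested with Fisher's exact conditional test for r×c tables,
   computed by exhaustive enumeration of all tables with the observed
   margins: P(table) = (∏ᵢRᵢ! ∏ⱼCⱼ!)/(N! ∏ᵢⱼnᵢⱼ!), two-sided p = Σ P
   over tables no more probable than the observed one. Carrier
   frequency (heterozygote share among unaffected animals) and
   recessive-model concordance come from the same table.

A synthetic-data generator (`coatscan.simulate`) emulates the study
design — Hardy–Weinberg genotypes at causal allele frequency *q*, full
penetrance, Mendelian dam→calf transmission, unlinked background coding
variants, staged panels — so the whole pipeline is testable without the
original sequencing reads.

## Worked example

```python
from coatscan import (MC1R_KEY, build_table, carrier_frequency,
                      cohort_summary, concordance, fisher_exact_rxc,
                      load_cohort_panel)

panel = load_cohort_panel()          # packaged 102-animal cohort
table = build_table(panel, MC1R_KEY)
print(table.counts.tolist(), table.col_labels)
print("p      =", fisher_exact_rxc(table))
print("carrier =", carrier_frequency(table))
print("match  =", concordance(table))
print("white% =", cohort_summary(panel).white_pct)
```

prints

```
[[69, 11, 0], [0, 0, 22]] ('TT', 'TC', 'CC')
p      = 8.366987394199945e-23
carrier = CarrierFrequency(pct=13.75, rendered=14, n_carriers=11, n_unaffected=80)
match  = 100.0
white% = 21.6
```

Reading: of 80 pigmented animals 69 are TT and 11 are TC (13.75 % ≈ 14 %
carriers); all 22 white animals are CC. The recessive prediction
(white ⇔ CC) matches all 102 animals, the exact test gives
p ≈ 8.4 × 10⁻²³, and whites are 21.6 % of the cohort.

A full synthetic study — simulate, filter through the staged design
(1+1, then 3+3, then the whole cohort), associate — runs as

```sh
coatscan run-all --seed 1 --demo --out-dir scratch/demo
```

and exits non-zero only if no candidate survives the cascade.

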