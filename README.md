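# cypstar

Star-allele calling and metaboliser-phenotype prediction for the
pharmacogenes **CYP2D6** and **CYP2C19**, with cohort population-genetics
summaries and a synthetic-cohort simulator for studying genotyping-platform
concordance.

## The problem

CYP2D6 and CYP2C19 metabolise a large share of commonly prescribed drugs.
An individual's metaboliser status — poor (PM), intermediate (IM),
extensive (EM) or ultra-rapid (UM) — can be predicted from the pair of
*star alleles* (named haplotypes) they carry at each gene.  Calling star
alleles correctly is hard: alleles are defined by key SNPs, whole-gene
deletions (CYP2D6\*5), duplications (xN), gene conversions (exon-9
CYP2D7 tracts, \*4N/\*36), and hybrid haplotypes (CYP2C19 \*2+\*27); and
fixed-content genotyping platforms that lack probes for
population-specific alleles silently default them to the nearest allele
they *can* see — e.g. reporting the normal-function \*45B as the
reduced-function \*41, or missing a heterozygous \*5 deletion and calling
the surviving haplotype homozygous.  These errors matter most in
genetically diverse African populations, where many such alleles are
common.

`cypstar` implements the full genotype-to-phenotype path:

- **allele catalog** (`cypstar.catalog`) — star-allele definitions in
  gene-local coordinates with activity classes and the fixed numeric
  activities (increased 2.0, normal 1.0, decreased 0.5, absent 0.0,
  unknown 1.0);
- **caller** (`cypstar.caller`) — partitions a sample's variant calls
  into two haplotypes, matches each against the catalog (largest
  key-variant set wins, so 2988G>A upgrades a \*2 core to \*41),
  integrates deletion/duplication/exon-9-conversion assay flags, flags
  novel alleles, and reports *all* diplotypes consistent with unphased
  data;
- **phenotype** (`cypstar.phenotype`) — the additive Activity Score
  `AS = v(allele1) + v(allele2)` binned as `0 → PM`, `0.5–1.0 → IM`,
  `1.5–2.0 → EM`, `>2.0 → UM`, alongside categorical microarray-style
  rules, with a disagreement matrix between the two schemes;
- **popgen** (`cypstar.popgen`) — stratified allele-frequency tables,
  integer-count reconstruction from printed percentage tables,
  functional-class breakdowns, exact biallelic Hardy-Weinberg tests
  (Monte-Carlo for multi-allelic), two-sided Fisher's exact 2×2 tests,
  platform-concordance reports with miscall matrices, and pairwise LD
  (D, D′, r²) with EM phase resolution;
- **simulate** (`cypstar.simulate`) — stratified Hardy-Weinberg cohort
  generation from published South African allele frequencies (default:
  70 Black African / 10 Caucasian / 10 Coloured / 10 Indian samples) and
  parametrised platform error models (miscall maps, deletion dropout,
  failure and no-call rates).

## Worked example

A CYP2C19 sample heterozygous for both the \*2 splice-defect SNP
(19154G>A) and the \*27 promoter SNP (-1401G>A) has two consistent
explanations, with different Activity Scores:

```python
from cypstar import builtin_catalog, activity_score, classify_as
from cypstar.caller import ObservedGenotype, VariantCall, call_sample
from cypstar.catalog import Gene, parse_variant_label as V

cat = builtin_catalog()
obs = ObservedGenotype("NA001", Gene.CYP2C19,
                       (VariantCall(V("19154G>A"), "het"),
                        VariantCall(V("-1401G>A"), "het")))
call = call_sample(obs, cat)
print("primary:", "/".join(call.primary))
for pair in [call.primary, *call.alternatives]:
    s = activity_score(pair, "CYP2C19", cat)
    print(f"  {'/'.join(pair):12s} AS={s:.1f} -> {classify_as(s)}")
```

prints

```
primary: *2/*27
  *2/*27       AS=0.5 -> IM
  *1/*2+*27    AS=1.0 -> IM
```

The two SNPs may sit on opposite haplotypes (\*2/\*27, one absent plus
one decreased allele, AS 0.5) or on the same haplotype (the hybrid
\*2+\*27 opposite a wild-type \*1, AS 1.0).  Unphased data cannot
distinguish them, so the caller reports both; the key-SNP reading is
primary and the hybrid reports at allele level as \*2, since the
19154G>A splice defect is the allele-defining variant.

## Command line

```sh
cypstar simulate --seed 3 --out sim/            # synthetic cohort + truth labels
cypstar call --variants sim/cyp2d6_variants.tsv \
             --sidecar sim/cyp2d6_cnv_sidecar.tsv --out calls/
cypstar phenotype --calls calls/calls.tsv --strata strata.tsv --out pheno/
cypstar popgen    --calls calls/calls.tsv --strata strata.tsv --out pg/
cypstar compare   --calls-a truth_calls.tsv --calls-b chip_calls.tsv --out cmp/
```

Variant input is a minimal VCF 4.2 subset or a native TSV; CNV and
exon-9-conversion assay results travel in a per-sample sidecar TSV.
Every output carries a provenance header and a JSON mirror.

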