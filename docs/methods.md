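# Methods

## Star-allele model

A star allele is modelled as a set of *key variants* (all must be present
on a haplotype for the allele to match) plus *backbone variants* (carried
but non-defining, e.g. the -1584C>G promoter SNP on \*2).  Variants live
in 1-based gene-local coordinates; negative positions are upstream of the
ATG and position 0 does not exist — this matches the numbering convention
of the CYP nomenclature reference frames for both genes.  Copy-number
alleles are special-cased: \*5 (whole-gene deletion) has no variants and
copy multiplier 0; duplication alleles (\*1xN, \*2xN, \*4xN) reference a
base allele with multiplier 2.

Haplotype matching selects, among alleles whose key set is contained in
the observed haplotype, the one with the largest key set.  This encodes
key-SNP precedence: a \*2 core plus 2988G>A is \*41, a \*4 core plus
4157T>G is \*4P.  Two distinct maximal matches of equal size are a
genuine ambiguity and raise an error at the haplotype level (the
diplotype enumerator simply skips such partitions).  Variants the winner
cannot explain produce a novel-allele candidate whose activity is 1.0
(functionally unconfirmed) unless the haplotype carries a null-defining
variant — a variant belonging to the key set of an absent-function allele
and to no functional allele, e.g. the 1846G>A splice defect — in which
case 0.0.

### Alleles with unpublished definitions

The catalog must contain every allele the activity table names, but many
of their defining SNPs are not characterised within this project.  Those
entries carry placeholder positions from the public nomenclature, are
marked `provenance="external-nomenclature"`, and nothing downstream
depends on the specific positions — tests exercise only alleles whose key
variants are study-confirmed.  The exon-9 gene-conversion alleles \*4N
and \*36 are not defined by a point variant at all; they carry a
representative conversion-tract marker solely to keep key sets distinct,
and are assigned by the conversion assay flag, never by matching.

The \*27 promoter SNP is stored as -1401G>A; a -1041G>A form also
circulates, and the discrepancy is recorded in the allele's annotations
rather than silently resolved.

## Diplotype enumeration

Homozygous calls contribute their variant to both haplotypes, heterozygous
calls to exactly one; calls sharing a phase set stay together.  All
2^(h-1) assignments of the h het groups are enumerated (the global swap is
symmetric), each side matched, and the consistent diplotypes collected.
Pairs without novel candidates are preferred; ties order by combined
allele ordinal (hybrids sum their parts, so \*2/\*27 precedes
(\*2+\*27)/\*1).  The first pair is the primary call and the rest are
retained as alternatives — the enumerate-and-report-alternatives contract
is this package's own; no population-frequency prior is used, because the
calling rules themselves (key-SNP precedence) are what resolve ambiguity
wherever it can be resolved.

CNV evidence is applied after enumeration.  One deleted copy forces the
remaining calls onto a single haplotype (apparent homozygotes are
hemizygotes) and pairs it with \*5; conflicting alleles at one position
are then an evidence inconsistency and the sample becomes a no-call with
a diagnostic note.  A duplication promotes the hinted allele to its xN
form; when the duplicated product could not be characterised (no hint, or
the hinted allele sits on both haplotypes) the possible upgrade
assignments are enumerated as alternatives.  A duplication contributes
exactly one extra gene dose — xN activity is twice the base activity,
never more — because the detection assay amplifies a duplication-specific
product without counting copies.

## Activity Score and phenotype

The Activity Score is plain additivity over the fixed per-allele values
(2.0 / 1.0 / 0.5 / 0.0, unknown → 1.0).  Only additivity is implemented;
it reproduces every worked score in scope.  Bins: 0 → PM, 0.5–1.0 → IM,
1.5–2.0 → EM, >2.0 → UM.  Since all activities are multiples of 0.5 there
is no score between 0 and 0.5; off-grid scores are a domain error.

The categorical (microarray-style) scheme counts allele copies: ≥3
functional copies → UM; two absent alleles → PM; reduced-function alleles
→ IM — except that a mixed functional/reduced pair overlaps the IM and EM
rows, and is resolved to EM when AS ≥ 1.5 (with Table-value activities a
normal+reduced pair is always exactly 1.5, so the IM branch of this
overlap is a documented safety net rather than a reachable case).  The
two schemes genuinely disagree — e.g. a normal allele paired with an
absent one is EM categorically but IM numerically — and
`scheme_disagreement_matrix` quantifies this rather than hiding it.
Unknown-activity alleles default to numeric 1.0 and the call is tagged
`contains-unknown`; cohort tables keep separate rows for unknown, no-call
and failure outcomes.

## Statistics

* **Fisher's exact 2×2** — two-sided by hypergeometric enumeration with
  fixed margins; the tail sums every table whose probability is ≤ the
  observed one, with a 1+1e-7 relative guard against floating-point ties.
* **Hardy-Weinberg** — biallelic: exact enumeration of heterozygote
  counts conditional on allele counts (Levene/Haldane distribution),
  probability-ordered two-sided sum.  Multi-allelic: seeded Monte-Carlo
  permutation of the allele vector (default 100,000 permutations),
  statistic = conditional probability of the genotype table,
  `p = (1 + #{T_sim ≤ T_obs}) / (1 + n_perm)`.  Full multi-allelic
  enumeration is infeasible beyond tiny counts, which is why the
  permutation route exists; the biallelic branch is always exact.
* **LD** — D = p_AB − p_A·p_B, D′ = D/D_max, r² = D²/(p_A p_a p_B p_b).
  Unphased input resolves double heterozygotes by EM over haplotype
  frequencies (tolerance 1e-8, ≤1000 iterations).  The EM estimate
  coincides with revealed-phase direct counts whenever the likelihood
  pins the double-het phase (e.g. no repulsion haplotypes in the data);
  with genuinely mixed phase it returns the MLE, which differs from the
  phased tally — that is a property of the estimator, not a defect.
  Monomorphic loci return a flagged, undefined result.
* **Count reconstruction** — printed percentage tables are converted to
  integers by round-half-up against the stated "alleles identified"
  denominators; stratum totals must land within ±3 of the denominator
  (rounding slack for one-decimal tables).  This rounding rule is what
  reproduces the published functional-class tallies exactly.  One known
  caveat: the published decreased-class total (63) is reconstructible
  only if one printed 0.5% entry is actually 5.0%; the discrepancy is
  left as-is rather than guessed away, and no check depends on it.
* Significance is α = 0.05 with no multiple-testing correction, matching
  the comparisons in scope; `significant` flags in concordance reports
  use that threshold.

Failed and no-call samples are excluded from frequency denominators and
tallied in their own rows, which is why "alleles identified" can be less
than twice the cohort size.

## Synthetic cohorts

The generator draws, within each stratum, two alleles per individual
i.i.d. from the stratum's frequency map — Hardy-Weinberg by construction
— and derives the full assay readout: variant calls from the allele's
key+backbone variants (hemizygotes read as homozygous), deletion copy
counts, duplication flags with the characterised base allele as hint, and
exon-9 conversion flags.  Defaults are the study conditions: strata of
70/10/10/10 samples and the comprehensive-platform frequency columns
(CYP2D6 sequencing, CYP2C19 PCR-RFLP).  Printed columns summing to 97.8%
and 95.5% are renormalised proportionally.  A small CYP2C19 \*2+\*27
hybrid frequency (2.1% Black African, 5.0% Indian) is carved out of the
printed \*2 frequency, sized from the four individuals observed
homozygous for the \*2 SNP while heterozygous for the \*27 SNP.

The default microarray error profile encodes the documented failure
modes: uncovered alleles miscalled deterministically
(\*45B/\*46 → \*41, \*56B → \*10, \*59 → \*2 or \*22 at 50/50,
\*33/\*43 → \*1, novel alleles → their visible backbone), plus estimated
rates for the -1584-based \*41 designation failing (\*2 → \*41 at 0.375,
\*1 → \*41 at 0.088, both derived from reported miscall tallies over
reconstructed exposure counts), heterozygous-\*5 dropout at 12/17, and
whole-sample failure/no-call at 0.224/0.04.  Every value is a config
knob; the derived ones are estimates, not measured parameters.  Strata
are sampled independently — no admixture model — and each run uses a
single seeded generator recorded in the output provenance.

### What the simulator does and does not show

Passing the round-trip and discrepancy checks shows that the calling
logic is internally consistent with the generative model and that the
documented error modes propagate to the documented cohort-level
signatures (inflated \*41, missed \*5).  It does not validate against
real chromatograms or array intensities, does not model linkage between
strata, sequencing error, or allele-frequency uncertainty, and cannot
reproduce cohort-specific p-values or per-ethnicity point estimates that
depend on the study's actual (undeposited) genotypes.

## Problem sizes and numerical choices

The default test suite uses the 100-sample study-scale cohort; round-trip
checks run 100 seeded replicates per gene, the discrepancy property 100
replicates, and the HWE calibration 200 replicates of a 5,000-sample
stratum — sizes chosen to make binomial bands tight while keeping the
suite quick.  Exhaustive oracle sweeps cover all 2×2 tables with total
≤ 30 and all biallelic HWE configurations with n ≤ 12, the ranges where
exact rational enumeration is cheap.  Ties in diplotype ranking break on
(fewest novel candidates, combined allele ordinal, name), making every
call deterministic; identical inputs always produce identical calls.

## Known limitations

- Alleles marked `external-nomenclature` carry placeholder variant
  definitions; calling real data against them would require filling in
  the authoritative nomenclature positions.
- The VCF subset writes no genome-anchored coordinates: positions are
  gene-local plus a fixed per-gene offset recorded in the header, and
  insertions/deletions use an `N` anchor because no reference sequence is
  bundled.
- Read-level variant calling, chromatogram processing and splice-site
  prediction are out of scope; the caller starts from variant calls and
  assay flags.
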