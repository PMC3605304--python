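"""Cohort statistics: allele frequencies, count reconstruction from printed
frequency tables, functional-class breakdowns, exact Hardy-Weinberg tests,
Fisher's exact platform comparisons and pairwise linkage disequilibrium.

The exact tests follow the conditional-enumeration conventions of the
classical population-genetics literature: the biallelic Hardy-Weinberg
test enumerates heterozygote counts conditional on the allele counts and
sums the probabilities of all configurations no more probable than the
observed one (two-sided, probability-ordered); the 2x2 Fisher test sums
hypergeometric probabilities of all tables with the observed margins and
probability <= the observed table's.  Multi-allelic Hardy-Weinberg uses a
seeded Monte-Carlo permutation of the allele vector, since full
enumeration is infeasible beyond tiny counts.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import hypergeom

from .caller import DiplotypeCall, NovelAlleleCandidate
from .catalog import ActivityClass, AlleleCatalog, Gene

__all__ = [
    "CohortTable",
    "FunctionalBreakdown",
    "LDResult",
    "allele_frequency_table",
    "reconstruct_counts",
    "functional_class_breakdown",
    "hwe_exact_test",
    "fisher_exact_2x2",
    "platform_concordance",
    "ld_pairwise",
    "ALPHA",
]

ALPHA = 0.05  # significance threshold; no multiple-testing correction by default

_REL_GUARD = 1 + 1e-7  # relative tolerance when comparing tail probabilities


@dataclass
class CohortTable:
    """Stratified allele-frequency table (percent) with denominators
    ("alleles identified" per stratum, i.e. 2 x successful samples)."""

    gene: Gene
    frequencies: pd.DataFrame          # alleles x strata, percent
    denominators: dict[str, int]
    phenotypes: pd.DataFrame | None = None

    def strata(self) -> list[str]:
        return list(self.frequencies.columns)


@dataclass
class FunctionalBreakdown:
    """Allele tally aggregated by activity class."""

    counts: dict[str, int]
    percents: dict[str, float]
    total: int
    unknown_pooled: int  # unknown-class alleles pooled into "normal"


@dataclass
class LDResult:
    D: float
    D_prime: float
    r2: float
    defined: bool = True
    note: str = ""


# --------------------------------------------------------------------------
# Frequencies and printed-table ingestion
# --------------------------------------------------------------------------

def _primary_names(call: DiplotypeCall) -> list[str]:
    return [h.name if isinstance(h, NovelAlleleCandidate) else h
            for h in call.primary]


def allele_frequency_table(calls, strata: dict[str, str],
                           gene: Gene | str | None = None) -> CohortTable:
    """Allele frequencies (%) per stratum from resolved diplotype calls.

    Samples with ``phenotype == "no_call"`` or an empty primary diplotype
    count as failures and are excluded from the denominators.
    """
    calls = list(calls)
    if gene is None:
        gene = calls[0].gene
    gene = Gene(gene)
    tallies: dict[str, Counter] = {}
    denoms: dict[str, int] = {}
    for call in calls:
        if call.gene is not gene:
            continue
        stratum = strata.get(call.sample_id, "all")
        tallies.setdefault(stratum, Counter())
        denoms.setdefault(stratum, 0)
        if not call.primary or call.phenotype == "no_call":
            continue
        tallies[stratum].update(_primary_names(call))
        denoms[stratum] += 2
    order = [s for s in dict.fromkeys(strata.values()) if s in tallies]
    order += [s for s in tallies if s not in order]
    alleles = sorted({a for t in tallies.values() for a in t},
                     key=lambda n: (len(n), n))
    freq = pd.DataFrame(
        {s: [100.0 * tallies[s][a] / denoms[s] if denoms[s] else 0.0
             for a in alleles] for s in order},
        index=alleles,
    )
    return CohortTable(gene=gene, frequencies=freq,
                       denominators={s: denoms[s] for s in order})


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def reconstruct_counts(table: CohortTable) -> pd.DataFrame:
    """Integer allele counts from a printed percent table.

    count = round-half-up(freq/100 x denominator); reconstructed stratum
    totals are checked to land within +/-3 of the denominator (rounding
    slack for tables printed to one decimal).
    """
    missing = [s for s in table.strata() if s not in table.denominators]
    if missing:
        raise ValueError(f"missing denominators for strata: {missing}")
    counts = pd.DataFrame(index=table.frequencies.index,
                          columns=table.strata(), dtype=int)
    for s in table.strata():
        n = table.denominators[s]
        counts[s] = [
            _round_half_up(f / 100.0 * n) for f in table.frequencies[s]
        ]
        total = int(counts[s].sum())
        if abs(total - n) > 3:
            raise ValueError(
                f"stratum {s}: reconstructed total {total} deviates from "
                f"denominator {n} by more than rounding slack"
            )
    return counts


_BREAKDOWN_CLASSES = ["absent", "decreased", "normal", "increased"]


def functional_class_breakdown(counts: pd.DataFrame,
                               catalog: AlleleCatalog,
                               gene: Gene | str,
                               denominator: int | None = None
                               ) -> FunctionalBreakdown:
    """Aggregate allele counts by activity class.

    Unknown-class alleles are pooled with "normal" (their default numeric
    activity is 1.0) and also reported separately via ``unknown_pooled``.
    ``denominator`` overrides the percentage base — useful when counts
    were reconstructed from a rounded printed table whose stated
    "alleles identified" total differs from the reconstructed sum.
    """
    gene = Gene(gene)
    tally = {c: 0 for c in _BREAKDOWN_CLASSES}
    unknown_pooled = 0
    for allele, row in counts.iterrows():
        n = int(row.sum())
        if n == 0:
            continue
        if (gene, allele) not in catalog:
            raise KeyError(f"allele {allele} absent from catalog "
                           f"for {gene.value}")
        cls = catalog.get(gene, allele).activity
        if cls is ActivityClass.UNKNOWN:
            tally["normal"] += n
            unknown_pooled += n
        else:
            key = {ActivityClass.ABSENT: "absent",
                   ActivityClass.DECREASED: "decreased",
                   ActivityClass.NORMAL: "normal",
                   ActivityClass.INCREASED: "increased"}[cls]
            tally[key] += n
    total = sum(tally.values())
    base = denominator if denominator else total
    percents = {c: (100.0 * tally[c] / base if base else 0.0)
                for c in _BREAKDOWN_CLASSES}
    return FunctionalBreakdown(tally, percents, total, unknown_pooled)


# --------------------------------------------------------------------------
# Exact tests
# --------------------------------------------------------------------------

def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 table [[a, b], [c, d]].

    Sums hypergeometric probabilities (margins fixed) of every table whose
    probability is <= the observed one, with a small relative tolerance
    guard against floating-point ties.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    n = a + b + c + d
    if n == 0:
        raise ValueError("all-zero table")
    r1, c1 = a + b, a + c
    support = np.arange(max(0, c1 - (n - r1)), min(r1, c1) + 1)
    probs = hypergeom.pmf(support, n, r1, c1)
    p_obs = hypergeom.pmf(a, n, r1, c1)
    return float(min(1.0, probs[probs <= p_obs * _REL_GUARD].sum()))


def _log_hwe_prob(n_het: int, n_a: int, n_total_alleles: int) -> float:
    """log P(het count | allele counts) for the biallelic conditional
    distribution (Levene/Haldane)."""
    n = n_total_alleles // 2
    n_aa = (n_a - n_het) // 2
    n_bb = (n_total_alleles - n_a - n_het) // 2
    return (gammaln(n + 1) - gammaln(n_aa + 1) - gammaln(n_het + 1)
            - gammaln(n_bb + 1) + n_het * math.log(2)
            + gammaln(n_a + 1) + gammaln(n_total_alleles - n_a + 1)
            - gammaln(n_total_alleles + 1))


def _genotype_log_prob(genotype_counts: dict, allele_counts: Counter) -> float:
    """log conditional probability of a multi-allelic genotype table given
    its allele counts (the statistic ordered in the permutation test)."""
    n = sum(genotype_counts.values())
    n_het = sum(c for g, c in genotype_counts.items() if g[0] != g[1])
    lp = gammaln(n + 1) + n_het * math.log(2)
    for c in genotype_counts.values():
        lp -= gammaln(c + 1)
    for c in allele_counts.values():
        lp += gammaln(c + 1)
    lp -= gammaln(2 * n + 1)
    return lp


def hwe_exact_test(genotype_counts: dict, seed: int = 0,
                   n_permutations: int = 100_000) -> float:
    """Exact test of Hardy-Weinberg proportions.

    ``genotype_counts`` maps unordered allele pairs to sample counts, e.g.
    ``{("A", "A"): 3, ("A", "a"): 4, ("a", "a"): 3}``.  With two alleles
    the p-value is computed by full enumeration of heterozygote counts
    conditional on the allele counts (probability-ordered two-sided sum).
    With more alleles a seeded Monte-Carlo permutation of the allele
    vector is used and ``p = (1 + #{T_sim <= T_obs}) / (1 + n_perm)``.
    A monomorphic sample gives p = 1.0.
    """
    genotype_counts = {tuple(sorted(g)): c for g, c in genotype_counts.items()
                       if c > 0}
    n = sum(genotype_counts.values())
    if n == 0:
        raise ValueError("no samples")
    allele_counts: Counter = Counter()
    for (a, b), c in genotype_counts.items():
        allele_counts[a] += c
        allele_counts[b] += c
    k = len(allele_counts)
    if k <= 1:
        return 1.0
    if k == 2:
        a1, a2 = sorted(allele_counts)
        n_a = allele_counts[a1]
        total = 2 * n
        obs_het = genotype_counts.get((a1, a2), 0)
        lo = n_a % 2
        hi = min(n_a, total - n_a)
        support = range(lo, hi + 1, 2)
        logps = {h: _log_hwe_prob(h, n_a, total) for h in support}
        p_obs = math.exp(logps[obs_het])
        p = sum(math.exp(lp) for lp in logps.values()
                if math.exp(lp) <= p_obs * _REL_GUARD)
        return float(min(1.0, p))
    # Multi-allelic: permutation of the flattened allele vector.
    rng = np.random.default_rng(seed)
    vector = np.array(
        [a for (x, y), c in genotype_counts.items() for a in (x, y) * c]
    )
    t_obs = _genotype_log_prob(genotype_counts, allele_counts)
    hits = 0
    for _ in range(n_permutations):
        rng.shuffle(vector)
        sim = Counter(tuple(sorted((vector[2 * i], vector[2 * i + 1])))
                      for i in range(n))
        if _genotype_log_prob(sim, allele_counts) <= t_obs + 1e-9:
            hits += 1
    return (1 + hits) / (1 + n_permutations)


# --------------------------------------------------------------------------
# Platform concordance
# --------------------------------------------------------------------------

@dataclass
class ConcordanceReport:
    agreement_rate: float
    n_compared: int
    n_excluded: int
    per_allele: pd.DataFrame       # counts on each platform + Fisher p
    miscall_matrix: dict           # (allele_a -> allele_b) -> count

    def miscall_frame(self) -> pd.DataFrame:
        rows = [{"from": a, "to": b, "count": c}
                for (a, b), c in sorted(self.miscall_matrix.items())]
        return pd.DataFrame(rows, columns=["from", "to", "count"])


def _diplotype_of(call) -> tuple | None:
    if isinstance(call, DiplotypeCall):
        if not call.primary or call.phenotype == "no_call":
            return None
        return tuple(_primary_names(call))
    return tuple(call) if call is not None else None


def platform_concordance(calls_a: dict, calls_b: dict,
                         catalog: AlleleCatalog | None = None,
                         bonferroni: bool = False) -> ConcordanceReport:
    """Compare two platforms' calls on the same samples.

    ``calls_a``/``calls_b`` map sample_id to a :class:`DiplotypeCall`, an
    allele-name pair, or ``None`` (failed sample).  Samples failed on
    either side are excluded and tallied.  Produces the per-sample
    agreement rate, a per-allele 2x2 Fisher comparison (allele count vs
    all other alleles, platform A vs B) and the miscall matrix
    (platform-A allele -> platform-B allele, from per-sample multiset
    differences).  Significance uses alpha = 0.05 uncorrected by default;
    ``bonferroni`` divides alpha by the number of alleles compared.
    """
    shared = set(calls_a) & set(calls_b)
    if not shared:
        raise ValueError("platforms share no samples")
    pairs = {}
    excluded = 0
    for sid in sorted(shared):
        da, db = _diplotype_of(calls_a[sid]), _diplotype_of(calls_b[sid])
        if da is None or db is None:
            excluded += 1
            continue
        pairs[sid] = (da, db)
    agree = sum(Counter(da) == Counter(db) for da, db in pairs.values())
    count_a: Counter = Counter()
    count_b: Counter = Counter()
    miscalls: Counter = Counter()
    for da, db in pairs.values():
        count_a.update(da)
        count_b.update(db)
        removed = list((Counter(da) - Counter(db)).elements())
        added = list((Counter(db) - Counter(da)).elements())
        for frm, to in itertools.zip_longest(sorted(removed), sorted(added),
                                             fillvalue="<none>"):
            miscalls[(frm, to)] += 1
    total_a, total_b = sum(count_a.values()), sum(count_b.values())
    alleles = sorted(set(count_a) | set(count_b), key=lambda n: (len(n), n))
    alpha = ALPHA / len(alleles) if bonferroni and alleles else ALPHA
    rows = []
    for allele in alleles:
        ca, cb = count_a[allele], count_b[allele]
        p = fisher_exact_2x2([[ca, total_a - ca], [cb, total_b - cb]])
        rows.append({"allele": allele, "count_a": ca, "count_b": cb,
                     "fisher_p": p, "significant": p < alpha})
    per_allele = pd.DataFrame(
        rows, columns=["allele", "count_a", "count_b", "fisher_p",
                       "significant"])
    n_compared = len(pairs)
    rate = agree / n_compared if n_compared else float("nan")
    return ConcordanceReport(rate, n_compared, excluded, per_allele,
                             dict(miscalls))


# --------------------------------------------------------------------------
# Linkage disequilibrium
# --------------------------------------------------------------------------

def _em_haplotype_freq(genotypes: np.ndarray, tol: float = 1e-8,
                       max_iter: int = 1000) -> np.ndarray:
    """EM estimate of two-locus haplotype frequencies from unphased
    biallelic genotypes (rows of 0/1/2 alt-allele dosages).

    Only double heterozygotes are phase-ambiguous; the EM splits them
    between the coupling (AB/ab) and repulsion (Ab/aB) resolutions in
    proportion to the current haplotype-frequency products.
    """
    n = len(genotypes)
    # Fixed haplotype contributions from unambiguous genotypes.
    base = np.zeros(4)  # order: AB, Ab, aB, ab  (A = alt at locus 1)
    n_dh = 0
    for g1, g2 in genotypes:
        if g1 == 1 and g2 == 1:
            n_dh += 1
            continue
        # At most one locus heterozygous -> phase is determined: pair the
        # alt alleles together (only one pairing is possible anyway).
        a1 = [1] * g1 + [0] * (2 - g1)
        a2 = [1] * g2 + [0] * (2 - g2)
        for x, y in zip(sorted(a1, reverse=True), sorted(a2, reverse=True)):
            idx = {(1, 1): 0, (1, 0): 1, (0, 1): 2, (0, 0): 3}[(x, y)]
            base[idx] += 1
    freq = np.full(4, 0.25)
    total = 2.0 * n
    for _ in range(max_iter):
        p_coupling = freq[0] * freq[3]
        p_repulsion = freq[1] * freq[2]
        denom = p_coupling + p_repulsion
        w = 0.5 if denom == 0 else p_coupling / denom
        new = base.copy()
        new[0] += n_dh * w
        new[3] += n_dh * w
        new[1] += n_dh * (1 - w)
        new[2] += n_dh * (1 - w)
        new /= total
        if np.max(np.abs(new - freq)) < tol:
            freq = new
            break
        freq = new
    return freq


def _ld_from_freq(freq: np.ndarray) -> LDResult:
    # freq order: AB, Ab, aB, ab with A/B the alt alleles.
    pA = freq[0] + freq[1]
    pB = freq[0] + freq[2]
    qa, qb = 1 - pA, 1 - pB
    if min(pA, qa, pB, qb) <= 0:
        return LDResult(0.0, float("nan"), float("nan"), defined=False,
                        note="monomorphic locus: LD undefined")
    D = freq[0] - pA * pB
    if D >= 0:
        d_max = min(pA * qb, qa * pB)
    else:
        d_max = min(pA * pB, qa * qb)
    d_prime = D / d_max if d_max > 0 else 0.0
    r2 = D * D / (pA * qa * pB * qb)
    return LDResult(float(D), float(d_prime), float(r2))


def ld_pairwise(haplotypes=None, genotypes=None, tol: float = 1e-8,
                max_iter: int = 1000) -> LDResult:
    """Pairwise LD (D, D', r^2) between two biallelic loci.

    ``haplotypes``: iterable of (allele1, allele2) with alleles coded 0/1
    — phased data, counted directly.  ``genotypes``: iterable of
    (dosage1, dosage2) with dosages 0/1/2 — unphased data, resolved by EM
    over haplotype frequencies.
    """
    if (haplotypes is None) == (genotypes is None):
        raise ValueError("provide exactly one of haplotypes or genotypes")
    if haplotypes is not None:
        counts = np.zeros(4)
        for x, y in haplotypes:
            counts[{(1, 1): 0, (1, 0): 1, (0, 1): 2, (0, 0): 3}[(x, y)]] += 1
        if counts.sum() == 0:
            raise ValueError("no haplotypes")
        freq = counts / counts.sum()
    else:
        geno = np.asarray(list(genotypes), dtype=int)
        if geno.size == 0:
            raise ValueError("no genotypes")
        freq = _em_haplotype_freq(geno, tol=tol, max_iter=max_iter)
    return _ld_from_freq(freq)
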