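"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written by a different route from the
implementation: exact rational arithmetic and naive enumeration instead
of log-gamma algebra and vectorised tails.
"""

from __future__ import annotations

from collections import Counter
from fractions import Fraction
from math import comb, factorial


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by direct hypergeometric enumeration with exact
    rationals: sum the probabilities of every table with the observed
    margins whose probability does not exceed the observed table's."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)

    def weight(k: int) -> Fraction:
        return Fraction(comb(r1, k) * comb(r2, c1 - k), denom)

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = weight(a)
    return float(sum(weight(k) for k in range(lo, hi + 1)
                     if weight(k) <= p_obs))


def hwe_biallelic_oracle(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact biallelic Hardy-Weinberg p by full enumeration of
    heterozygote counts conditional on the allele counts, with exact
    rationals (Levene/Haldane conditional distribution)."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n - n_a
    if n_a == 0 or n_b == 0:
        return 1.0

    def prob(h: int) -> Fraction:
        hom_a = (n_a - h) // 2
        hom_b = (n_b - h) // 2
        return Fraction(
            factorial(n) * 2**h * factorial(n_a) * factorial(n_b),
            factorial(hom_a) * factorial(h) * factorial(hom_b)
            * factorial(2 * n),
        )

    support = range(n_a % 2, min(n_a, n_b) + 1, 2)
    p_obs = prob(n_ab)
    return float(sum(prob(h) for h in support if prob(h) <= p_obs))


def pairing_distribution(allele_counts: dict) -> dict:
    """Exact distribution over genotype tables induced by randomly pairing
    the allele multiset into diploid genotypes.  Recursive enumeration
    with exact rationals; feasible only for tiny counts."""
    dist: Counter = Counter()

    def rec(counts: dict, table: dict, weight: Fraction) -> None:
        counts = {x: c for x, c in counts.items() if c > 0}
        if not counts:
            dist[tuple(sorted(table.items()))] += weight
            return
        first = sorted(counts)[0]
        rest = sum(counts.values()) - 1
        for partner in sorted(counts):
            available = counts[partner] - (1 if partner == first else 0)
            if available <= 0:
                continue
            nxt_counts = dict(counts)
            nxt_counts[first] -= 1
            nxt_counts[partner] -= 1
            key = tuple(sorted((first, partner)))
            nxt_table = dict(table)
            nxt_table[key] = nxt_table.get(key, 0) + 1
            rec(nxt_counts, nxt_table, weight * Fraction(available, rest))

    rec(dict(allele_counts), {}, Fraction(1))
    return dict(dist)


def phenotype_tally_oracle(calls, strata: dict, scheme: str) -> dict:
    """Per-stratum phenotype percentages by direct per-sample counting."""
    out: dict = {}
    for call in calls:
        stratum = strata.get(call.sample_id, "all")
        label = (call.phenotype if scheme == "activity_score"
                 else call.phenotype_amplichip)
        out.setdefault(stratum, Counter())[label] += 1
    return {
        s: {lab: 100.0 * c / sum(tally.values())
            for lab, c in tally.items()}
        for s, tally in out.items()
    }


def allele_tally_oracle(truth_pairs: dict, strata: dict) -> dict:
    """Per-stratum allele frequencies (%) by direct counting of diplotype
    pairs; denominators are 2 x samples."""
    tallies: dict = {}
    for sid, pair in truth_pairs.items():
        tallies.setdefault(strata.get(sid, "all"), Counter()).update(pair)
    return {
        s: {a: 100.0 * c / sum(t.values()) for a, c in t.items()}
        for s, t in tallies.items()
    }
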