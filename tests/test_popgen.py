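"""Population-genetics statistics against independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import fisher_exact as scipy_fisher

from cypstar.caller import DiplotypeCall
from cypstar.catalog import Gene
from cypstar.popgen import (CohortTable, allele_frequency_table,
                            fisher_exact_2x2, functional_class_breakdown,
                            hwe_exact_test, ld_pairwise,
                            platform_concordance, reconstruct_counts,
                            _genotype_log_prob)

from oracles import (allele_tally_oracle, fisher_oracle,
                     hwe_biallelic_oracle, pairing_distribution)


# -- Fisher's exact --------------------------------------------------------

@pytest.mark.parametrize("table,expected", [
    ([[1, 1], [1, 1]], 1.0),
    ([[5, 0], [0, 5]], 2 / 252),        # 2 / C(10,5)
    ([[2, 0], [0, 2]], 1 / 3),
])
def test_fisher_worked_examples(table, expected):
    assert fisher_exact_2x2(table) == pytest.approx(expected, abs=1e-12)


def test_fisher_matches_oracle_small_tables():
    for total in range(1, 17):
        for a in range(total + 1):
            for b in range(total - a + 1):
                for c in range(total - a - b + 1):
                    d = total - a - b - c
                    assert fisher_exact_2x2([[a, b], [c, d]]) == pytest.approx(
                        fisher_oracle(a, b, c, d), abs=1e-10)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(st.tuples(*(st.integers(0, 40),) * 4))
def test_fisher_matches_scipy(cells):
    a, b, c, d = cells
    if a + b + c + d == 0:
        return
    ours = fisher_exact_2x2([[a, b], [c, d]])
    ref = scipy_fisher([[a, b], [c, d]]).pvalue
    assert ours == pytest.approx(ref, abs=1e-9)


def test_fisher_rejects_all_zero():
    with pytest.raises(ValueError):
        fisher_exact_2x2([[0, 0], [0, 0]])


# -- Hardy-Weinberg --------------------------------------------------------

def test_hwe_monomorphic_is_one():
    assert hwe_exact_test({("A", "A"): 10}) == 1.0


def test_hwe_biallelic_worked_example():
    p = hwe_exact_test({("A", "A"): 3, ("A", "a"): 4, ("a", "a"): 3})
    assert p == pytest.approx(hwe_biallelic_oracle(3, 4, 3), abs=1e-10)


def test_hwe_biallelic_matches_oracle_all_small_n():
    for n in range(1, 13):
        for n_aa in range(n + 1):
            for n_ab in range(n - n_aa + 1):
                n_bb = n - n_aa - n_ab
                counts = {("A", "A"): n_aa, ("A", "a"): n_ab,
                          ("a", "a"): n_bb}
                assert hwe_exact_test(counts) == pytest.approx(
                    hwe_biallelic_oracle(n_aa, n_ab, n_bb), abs=1e-10)


def test_hwe_multiallelic_matches_exhaustive_pairing():
    """Monte-Carlo p within 0.02 of the exact pairing-distribution oracle
    on a 3-allele, 9-sample configuration with heterozygote excess."""
    geno = {("A", "B"): 3, ("B", "C"): 3, ("A", "C"): 3}
    allele_counts = {"A": 6, "B": 6, "C": 6}
    dist = pairing_distribution(allele_counts)
    t_obs = _genotype_log_prob(geno, allele_counts)
    p_exact = float(sum(
        w for table, w in dist.items()
        if _genotype_log_prob(dict(table), allele_counts) <= t_obs + 1e-9))
    p_mc = hwe_exact_test(geno, seed=1, n_permutations=20_000)
    assert p_mc == pytest.approx(p_exact, abs=0.02)


def test_hwe_formula_equals_pairing_oracle_per_table():
    """The conditional-probability statistic itself agrees with the exact
    random-pairing distribution on every reachable table."""
    allele_counts = {"A": 5, "B": 4, "C": 3}
    dist = pairing_distribution(allele_counts)
    for table, weight in dist.items():
        lp = _genotype_log_prob(dict(table), allele_counts)
        assert float(weight) == pytest.approx(np.exp(lp), rel=1e-9)


def test_hwe_rejects_empty():
    with pytest.raises(ValueError):
        hwe_exact_test({})


# -- Linkage disequilibrium ------------------------------------------------

def test_ld_perfect_coupling():
    result = ld_pairwise(haplotypes=[(1, 1)] * 6 + [(0, 0)] * 14)
    assert result.D_prime == pytest.approx(1.0)
    assert result.r2 == pytest.approx(1.0)


def test_ld_independent_equifrequent_loci():
    haps = [(1, 1), (1, 0), (0, 1), (0, 0)] * 10
    result = ld_pairwise(haplotypes=haps)
    assert result.D == pytest.approx(0.0, abs=1e-12)


def test_ld_monomorphic_flagged():
    result = ld_pairwise(haplotypes=[(1, 0), (1, 1)])
    assert not result.defined


def test_ld_em_matches_phased_counts_when_phase_pinned():
    """On data whose double heterozygotes all resolve one way (no
    repulsion haplotypes present), the EM estimate equals the revealed-
    phase direct counts to convergence tolerance."""
    rng = np.random.default_rng(7)
    pool = [(1, 1), (0, 0)]
    haps = [pool[rng.choice(2, p=[0.3, 0.7])] for _ in range(400)]
    genotypes = [(haps[2 * i][0] + haps[2 * i + 1][0],
                  haps[2 * i][1] + haps[2 * i + 1][1]) for i in range(200)]
    phased = ld_pairwise(haplotypes=haps)
    unphased = ld_pairwise(genotypes=genotypes)
    assert unphased.D == pytest.approx(phased.D, abs=1e-6)
    assert unphased.r2 == pytest.approx(phased.r2, abs=1e-6)


def test_ld_requires_exactly_one_input():
    with pytest.raises(ValueError):
        ld_pairwise()


# -- Frequency tables ------------------------------------------------------

def _call(sid, gene, pair):
    return DiplotypeCall(sid, gene, pair, activity_score=1.0,
                         phenotype="EM", phenotype_amplichip="EM")


def test_frequency_table_trivial():
    calls = [_call(f"s{i}", Gene.CYP2D6, ("*1", "*17")) for i in range(70)]
    strata = {f"s{i}": "A" for i in range(70)}
    table = allele_frequency_table(calls, strata)
    assert table.frequencies.loc["*1", "A"] == 50.0
    assert table.frequencies.loc["*17", "A"] == 50.0
    assert table.denominators["A"] == 140


def test_frequency_table_excludes_failures_from_denominator():
    calls = [_call("s0", Gene.CYP2D6, ("*5", "*5")),
             DiplotypeCall("s1", Gene.CYP2D6, (), phenotype="no_call")]
    table = allele_frequency_table(calls, {"s0": "A", "s1": "A"})
    assert table.frequencies.loc["*5", "A"] == 100.0
    assert table.denominators["A"] == 2


def test_frequency_table_matches_tally_oracle(catalog):
    from cypstar.simulate import default_cyp2d6_config, simulate_truth
    truth = simulate_truth(default_cyp2d6_config(5), catalog)
    calls = [_call(r.sample_id, Gene.CYP2D6, r.diplotype) for r in truth]
    strata = {r.sample_id: r.stratum for r in truth}
    table = allele_frequency_table(calls, strata)
    oracle = allele_tally_oracle({r.sample_id: r.diplotype for r in truth},
                                 strata)
    for stratum, expect in oracle.items():
        for allele, pct in expect.items():
            assert table.frequencies.loc[allele, stratum] == pytest.approx(pct)
    # round trip: reconstruction recovers the exact counts
    counts = reconstruct_counts(table)
    from collections import Counter
    for stratum in table.strata():
        direct = Counter(a for r in truth if r.stratum == stratum
                         for a in r.diplotype)
        for allele, n in direct.items():
            assert counts.loc[allele, stratum] == n


def test_reconstruct_counts_round_half_up():
    import pandas as pd
    freq = pd.DataFrame({"A": [10.7, 0.7, 88.6]}, index=["x", "y", "z"])
    table = CohortTable(Gene.CYP2D6, freq, {"A": 140})
    counts = reconstruct_counts(table)
    assert counts["A"].tolist() == [15, 1, 124]


def test_reconstruct_counts_requires_denominator():
    import pandas as pd
    freq = pd.DataFrame({"A": [100.0]}, index=["x"])
    with pytest.raises(ValueError, match="denominator"):
        reconstruct_counts(CohortTable(Gene.CYP2D6, freq, {}))


def test_functional_breakdown_all_wild_type(catalog):
    import pandas as pd
    counts = pd.DataFrame({"A": [20]}, index=["*1"])
    breakdown = functional_class_breakdown(counts, catalog, Gene.CYP2D6)
    assert breakdown.percents["normal"] == 100.0
    assert breakdown.counts["absent"] == 0


def test_functional_breakdown_unknown_allele_raises(catalog):
    import pandas as pd
    counts = pd.DataFrame({"A": [1]}, index=["*999"])
    with pytest.raises(KeyError, match=r"\*999"):
        functional_class_breakdown(counts, catalog, Gene.CYP2D6)


# -- Concordance -----------------------------------------------------------

def test_concordance_identity():
    calls = {f"s{i}": ("*1", "*2") for i in range(50)}
    report = platform_concordance(calls, dict(calls))
    assert report.agreement_rate == 1.0
    assert report.miscall_matrix == {}
    assert np.allclose(report.per_allele["fisher_p"], 1.0)


def test_concordance_one_sample_differs():
    calls_a = {f"s{i}": ("*1", "*1") for i in range(100)}
    calls_b = dict(calls_a)
    calls_b["s99"] = ("*1", "*41")
    report = platform_concordance(calls_a, calls_b)
    assert report.agreement_rate == pytest.approx(0.99)
    assert report.miscall_matrix == {("*1", "*41"): 1}


def test_concordance_excludes_failed_samples():
    calls_a = {"s0": ("*1", "*1"), "s1": None}
    calls_b = {"s0": ("*1", "*1"), "s1": ("*1", "*2")}
    report = platform_concordance(calls_a, calls_b)
    assert report.n_compared == 1
    assert report.n_excluded == 1


def test_concordance_disjoint_samples_raise():
    with pytest.raises(ValueError):
        platform_concordance({"a": ("*1", "*1")}, {"b": ("*1", "*1")})
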