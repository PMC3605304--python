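"""Star-allele caller: haplotype matching, diplotype enumeration, CNV and
exon-9 integration, novel-allele detection, per-sample orchestration."""

import pytest

from cypstar.caller import (AmbiguousMatchError, InconsistentEvidenceError,
                            NovelAlleleCandidate, ObservedGenotype,
                            VariantCall, allele_level_name,
                            apply_exon9_conversion, call_sample,
                            detect_novel, enumerate_diplotypes,
                            integrate_cnv, match_haplotype, normalise_pair)
from cypstar.catalog import Gene, parse_variant_label as V


def calls(*specs):
    """('2988G>A', 'het'[, phase_set]) tuples -> VariantCall tuple."""
    return tuple(VariantCall(V(s[0]), s[1], s[2] if len(s) > 2 else None)
                 for s in specs)


def hap(catalog, gene, name):
    """All variants carried by a named allele (key + backbone)."""
    return sorted(catalog.get(gene, name).all_variants)


# -- match_haplotype -------------------------------------------------------

@pytest.mark.parametrize("gene,name", [
    ("CYP2D6", "*2"), ("CYP2D6", "*4"), ("CYP2D6", "*10"),
    ("CYP2D6", "*17"), ("CYP2D6", "*29"), ("CYP2D6", "*41"),
    ("CYP2D6", "*45B"), ("CYP2D6", "*46"), ("CYP2D6", "*4P"),
    ("CYP2D6", "*84"), ("CYP2D6", "*85"), ("CYP2D6", "*86"),
    ("CYP2C19", "*2"), ("CYP2C19", "*27"), ("CYP2C19", "*2+*27"),
])
def test_match_full_haplotypes(catalog, gene, name):
    """Every concrete allele's own variant set matches back to its name."""
    assert match_haplotype(hap(catalog, gene, name), gene, catalog) == name


def test_match_empty_set_is_reference(catalog):
    assert match_haplotype([], "CYP2D6", catalog) == "*1"


def test_key_snp_separates_41_from_2(catalog):
    """2988G>A on the *2 core is *41; the *2 core with only the promoter
    SNP stays *2 (the defining-SNP precedence the microarray lacks)."""
    core = [V("2850C>T"), V("4180G>C")]
    assert match_haplotype(core + [V("2988G>A")], "CYP2D6", catalog) == "*41"
    assert match_haplotype(core + [V("-1584C>G")], "CYP2D6", catalog) == "*2"


def test_largest_key_set_wins(catalog):
    # *4 core (100C>T + 1846G>A) beats *10 (100C>T alone)
    assert match_haplotype([V("100C>T"), V("1846G>A")], "CYP2D6",
                           catalog) == "*4"
    # adding 4157T>G upgrades *4 to the novel null *4P
    assert match_haplotype([V("100C>T"), V("1846G>A"), V("4157T>G")],
                           "CYP2D6", catalog) == "*4P"


def test_equal_maximal_matches_raise(catalog):
    # a haplotype carrying both the *17 and *41 full key sets is ambiguous
    mixed = hap(catalog, "CYP2D6", "*17") + [V("2988G>A")]
    with pytest.raises(AmbiguousMatchError, match=r"\*17.*\*41|\*41.*\*17"):
        match_haplotype(mixed, "CYP2D6", catalog)


def test_unexplained_variants_yield_novel_candidate(catalog):
    result = match_haplotype(hap(catalog, "CYP2D6", "*2") + [V("3999A>T")],
                             "CYP2D6", catalog)
    assert isinstance(result, NovelAlleleCandidate)
    assert result.backbone == "*2"
    assert {v.label for v in result.extra_variants} == {"3999A>T"}
    assert result.assigned_activity == 1.0


# -- detect_novel ----------------------------------------------------------

def test_novel_activity_rule(catalog):
    """Novel haplotypes default to activity 1.0 unless they carry a
    null-defining variant (the *84 vs *4P situations)."""
    star2 = catalog.get(Gene.CYP2D6, "*2")
    benign = detect_novel(hap(catalog, "CYP2D6", "*2") + [V("2574C>A")],
                          "CYP2D6", catalog, backbone=star2)
    assert benign.assigned_activity == 1.0
    star4 = catalog.get(Gene.CYP2D6, "*4")
    null = detect_novel(hap(catalog, "CYP2D6", "*4") + [V("4157T>G")],
                        "CYP2D6", catalog, backbone=star4)
    assert null.assigned_activity == 0.0
    assert detect_novel(hap(catalog, "CYP2D6", "*41"), "CYP2D6",
                        catalog) is None


# -- enumerate_diplotypes --------------------------------------------------

def test_cyp2c19_double_het_ambiguity(catalog):
    """Het 19154G>A + het -1401G>A is *2/*27 or (*2+*27)/*1; both must be
    reported, key-SNP pair first."""
    obs = ObservedGenotype("s", Gene.CYP2C19,
                           calls(("19154G>A", "het"), ("-1401G>A", "het")))
    pairs = enumerate_diplotypes(obs, catalog)
    assert pairs[0] == ("*2", "*27")
    assert ("*1", "*2+*27") in pairs[1:]


def test_cyp2c19_hom_2_het_27_resolves_uniquely(catalog):
    obs = ObservedGenotype("s", Gene.CYP2C19,
                           calls(("19154G>A", "hom"), ("-1401G>A", "het")))
    pairs = enumerate_diplotypes(obs, catalog)
    assert pairs[0] == ("*2", "*2+*27")
    # allele-level reporting collapses the hybrid onto *2
    assert [allele_level_name(n) for n in pairs[0]] == ["*2", "*2"]


def test_no_variants_is_wild_type(catalog):
    obs = ObservedGenotype("s", Gene.CYP2D6)
    assert enumerate_diplotypes(obs, catalog) == [("*1", "*1")]


def test_enumeration_never_empty_and_revalidates(catalog):
    """Every returned clean pair re-matches from its own haplotypes."""
    obs = ObservedGenotype("s", Gene.CYP2D6, calls(
        ("-1584C>G", "het"), ("2850C>T", "hom"), ("4180G>C", "hom"),
        ("2988G>A", "het")))
    pairs = enumerate_diplotypes(obs, catalog)
    assert pairs and pairs[0] == ("*2", "*41")
    for pair in pairs:
        for name in pair:
            if isinstance(name, str) and name != "*1":
                assert match_haplotype(hap(catalog, "CYP2D6", name),
                                       "CYP2D6", catalog) == name


def test_phase_sets_restrict_partitions(catalog):
    """Calls sharing a phase set stay on one haplotype, collapsing the
    *2/*27-type ambiguity."""
    obs = ObservedGenotype("s", Gene.CYP2C19, calls(
        ("19154G>A", "het", "ps1"), ("-1401G>A", "het", "ps1")))
    pairs = enumerate_diplotypes(obs, catalog)
    assert pairs == [("*1", "*2+*27")]


def test_unmatchable_set_returns_novel_pair(catalog):
    obs = ObservedGenotype("s", Gene.CYP2D6, calls(("3999A>T", "het")))
    pairs = enumerate_diplotypes(obs, catalog)
    assert len(pairs) == 1
    assert any(isinstance(h, NovelAlleleCandidate) for h in pairs[0])


# -- integrate_cnv ---------------------------------------------------------

def test_het_deletion_rewrites_hom_to_hemizygote(catalog):
    """Apparent homozygous *17 with one deleted copy is *17/*5 — the
    pattern the deletion-blind platform reports as *17/*17."""
    obs = ObservedGenotype("s", Gene.CYP2D6, calls(
        ("1023C>T", "hom"), ("2850C>T", "hom"), ("4180G>C", "hom")),
        deletion_copies=1)
    pairs = integrate_cnv(enumerate_diplotypes(obs, catalog), obs, catalog)
    assert pairs == [("*5", "*17")]


def test_hom_deletion_forces_5_5(catalog):
    obs = ObservedGenotype("s", Gene.CYP2D6, deletion_copies=2)
    assert call_sample(obs, catalog).primary == ("*5", "*5")


def test_duplication_hint_attaches_xn(catalog):
    obs = ObservedGenotype("s", Gene.CYP2D6, calls(
        ("-1584C>G", "het"), ("2850C>T", "het"), ("4180G>C", "het")),
        duplication_present=True, duplicated_allele_hint="*2")
    pairs = integrate_cnv(enumerate_diplotypes(obs, catalog), obs, catalog)
    assert pairs[0] == ("*1", "*2xN")


def test_no_cnv_flags_is_identity(catalog):
    obs = ObservedGenotype("s", Gene.CYP2D6, calls(("100C>T", "het")))
    pairs = enumerate_diplotypes(obs, catalog)
    assert integrate_cnv(list(pairs), obs, catalog) == pairs


def test_conflicting_calls_with_single_copy_raise(catalog):
    obs = ObservedGenotype("s", Gene.CYP2D6, calls(
        ("1758G>A", "het"), ("1758G>T", "het")), deletion_copies=1)
    with pytest.raises(InconsistentEvidenceError):
        integrate_cnv([], obs, catalog)


# -- exon-9 conversion -----------------------------------------------------

@pytest.mark.parametrize("pair,expected", [
    (("*1", "*4"), ("*1", "*4N")),
    (("*2", "*10"), ("*2", "*36")),
    (("*1", "*1"), ("*1", "*1")),
])
def test_exon9_relabelling(catalog, pair, expected):
    obs = ObservedGenotype("s", Gene.CYP2D6, exon9_conversion=True)
    out, notes = apply_exon9_conversion([pair], obs)
    assert out == [normalise_pair(expected)]
    if pair == expected:
        assert notes  # flag without a *4/*10 haplotype leaves a note


# -- call_sample -----------------------------------------------------------

def test_empty_observation_calls_wild_type(catalog):
    call = call_sample(ObservedGenotype("s", Gene.CYP2D6), catalog)
    assert call.primary == ("*1", "*1")
    assert call.activity_score == 2.0
    assert call.phenotype == "EM"


def test_hom_deletion_is_pm(catalog):
    call = call_sample(ObservedGenotype("s", Gene.CYP2D6,
                                        deletion_copies=2), catalog)
    assert call.activity_score == 0.0
    assert call.phenotype == "PM"


def test_inconsistent_evidence_becomes_no_call(catalog):
    obs = ObservedGenotype("s", Gene.CYP2D6, calls(
        ("1758G>A", "het"), ("1758G>T", "het")), deletion_copies=1)
    call = call_sample(obs, catalog)
    assert call.phenotype == "no_call"
    assert any("inconsistent" in n for n in call.notes)


def test_determinism(catalog):
    obs = ObservedGenotype("s", Gene.CYP2C19,
                           calls(("19154G>A", "het"), ("-1401G>A", "het")))
    assert call_sample(obs, catalog) == call_sample(obs, catalog)


def test_normalise_pair_orders_by_allele_number():
    assert normalise_pair(("*17", "*2")) == ("*2", "*17")
    assert normalise_pair(("*45B", "*5")) == ("*5", "*45B")
    assert normalise_pair(("*2xN", "*2")) == ("*2", "*2xN")
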