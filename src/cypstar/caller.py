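"""Diplotype assignment from per-sample variant observations.

The caller works at the haplotype level: the observed variant multiset
(homozygous calls contribute to both haplotypes, heterozygous calls to
exactly one) is partitioned into two haplotype sets, each matched against
the allele catalog.  An allele matches a haplotype when all of its key
variants are present; among matching alleles the one with the largest key
set wins, so a haplotype carrying the *2 core plus the 2988G>A key SNP is
called *41, not *2.  Variants the winner's key and backbone sets cannot
explain mark the haplotype as a novel-allele candidate.

Copy-number evidence is layered on afterwards: a single-copy deletion
result replaces the second haplotype with *5 (homozygous-looking calls
then collapse to the one remaining copy — the hemizygote pattern), a
duplication result promotes the hinted allele to its xN form, and a
positive exon-9 gene-conversion assay relabels *4 -> *4N and *10 -> *36.

When the observation is unphased and several partitions are internally
consistent, every consistent diplotype is retained: the first (fewest
novel candidates, then lowest combined allele number) becomes the primary
call and the rest are reported as alternatives.  The canonical example is
a CYP2C19 sample heterozygous for both 19154G>A and -1401G>A, which is
*2/*27 or equally (*2+*27)/*1.
"""

from __future__ import annotations

from dataclasses import dataclass

from .catalog import (AlleleCatalog, ActivityClass, Gene, VariantDef,
                      allele_ordinal)

__all__ = [
    "VariantCall",
    "ObservedGenotype",
    "NovelAlleleCandidate",
    "DiplotypeCall",
    "AmbiguousMatchError",
    "InconsistentEvidenceError",
    "match_haplotype",
    "enumerate_diplotypes",
    "integrate_cnv",
    "apply_exon9_conversion",
    "detect_novel",
    "call_sample",
    "normalise_pair",
    "pair_name",
    "allele_level_name",
]


class AmbiguousMatchError(ValueError):
    """Two distinct maximal allele matches of equal key-set size."""


class InconsistentEvidenceError(ValueError):
    """CNV evidence contradicts the observed variant calls."""


@dataclass(frozen=True)
class VariantCall:
    """One variant observed in a sample; ``phase_set`` groups calls known
    to be co-linear (e.g. from a cloned and sequenced single molecule)."""

    variant: VariantDef
    zygosity: str  # "het" | "hom"
    phase_set: str | None = None

    def __post_init__(self) -> None:
        if self.zygosity not in ("het", "hom"):
            raise ValueError(f"zygosity must be het|hom, got {self.zygosity}")


@dataclass(frozen=True)
class ObservedGenotype:
    """A sample's per-gene evidence: sequence calls plus assay flags."""

    sample_id: str
    gene: Gene
    calls: tuple[VariantCall, ...] = ()
    deletion_copies: int = 0          # number of *5 alleles (duplex XL-PCR)
    duplication_present: bool = False
    duplicated_allele_hint: str | None = None
    exon9_conversion: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.deletion_copies <= 2:
            raise ValueError("deletion_copies must be 0..2")
        if self.deletion_copies == 2 and self.calls:
            raise ValueError(
                "homozygous deletion cannot co-occur with variant calls"
            )


@dataclass(frozen=True)
class NovelAlleleCandidate:
    """A haplotype the catalog cannot fully explain.

    Activity follows the novel-allele rule: 1.0 (functionally unconfirmed)
    unless the haplotype carries a known null-defining variant such as the
    1846G>A splice defect, in which case 0.0.
    """

    backbone: str
    extra_variants: frozenset[VariantDef]
    assigned_activity: float
    rationale: str

    @property
    def name(self) -> str:
        labels = "+".join(v.label for v in sorted(self.extra_variants))
        return f"{self.backbone}+[{labels}]"


AlleleLike = "str | NovelAlleleCandidate"


@dataclass(frozen=True)
class DiplotypeCall:
    sample_id: str
    gene: Gene
    primary: tuple
    alternatives: tuple = ()
    activity_score: float = float("nan")
    phenotype: str = "no_call"            # AS-scheme phenotype
    phenotype_amplichip: str = "no_call"  # categorical-rule phenotype
    novel_candidates: tuple = ()
    notes: tuple = ()


def _name_of(h) -> str:
    return h.name if isinstance(h, NovelAlleleCandidate) else h


def _ordinal(h) -> float:
    if isinstance(h, NovelAlleleCandidate):
        return allele_ordinal(h.backbone) + 1000.0
    return allele_ordinal(h)


def normalise_pair(pair) -> tuple:
    """Order a diplotype lower allele number first (lexicographic on
    ordinal then name, so the result is deterministic)."""
    return tuple(sorted(pair, key=lambda h: (_ordinal(h), _name_of(h))))


def pair_name(pair) -> str:
    return "/".join(_name_of(h) for h in pair)


def allele_level_name(name: str) -> str:
    """Allele-level reporting name: a hybrid reports as the allele that
    carries the defining (null) SNP, so *2+*27 reports as *2."""
    if "+" in name and not name.endswith("]"):
        return name.split("+")[0]
    return name


# --------------------------------------------------------------------------
# Haplotype matching
# --------------------------------------------------------------------------

def match_haplotype(variants, gene: Gene | str, catalog: AlleleCatalog):
    """Match a single-haplotype variant set to a star allele.

    Returns the allele name when the catalog fully explains the set, or a
    :class:`NovelAlleleCandidate` when unexplained variants remain.  The
    empty set is the reference allele *1.

    Raises :class:`AmbiguousMatchError` when two distinct alleles match
    maximally with equal key-set size.
    """
    gene = Gene(gene)
    sites = {v.site for v in variants}
    best: list = []
    best_size = -1
    for allele in catalog.alleles_of(gene):
        if allele.cnv_multiplier != 1:
            continue  # *5 and xN are assigned from assay flags, not matching
        key_sites = {v.site for v in allele.key_variants}
        if key_sites <= sites:
            size = len(key_sites)
            if size > best_size:
                best, best_size = [allele], size
            elif size == best_size:
                best.append(allele)
    if len(best) > 1:
        names = ", ".join(a.name for a in best)
        raise AmbiguousMatchError(
            f"{gene.value}: equally maximal matches: {names}"
        )
    winner = best[0]
    explained = {v.site for v in winner.all_variants}
    extras = frozenset(v for v in variants if v.site not in explained)
    if not extras:
        return winner.name
    return detect_novel(variants, gene, catalog, backbone=winner)


def detect_novel(variants, gene: Gene | str, catalog: AlleleCatalog,
                 backbone=None) -> NovelAlleleCandidate | None:
    """Build a novel-allele candidate for a partially matched haplotype.

    ``backbone`` is the best partial match (recomputed when omitted);
    returns ``None`` for a fully matched set.
    """
    gene = Gene(gene)
    if backbone is None:
        result = match_haplotype(variants, gene, catalog)
        if isinstance(result, NovelAlleleCandidate):
            return result
        return None
    explained = {v.site for v in backbone.all_variants}
    extras = frozenset(v for v in variants if v.site not in explained)
    if not extras:
        return None
    null_sites = catalog.null_key_sites(gene)
    carried = {v.site for v in variants}
    if carried & null_sites:
        activity = 0.0
        why = ("carries a null-defining variant; non-functional by linkage "
               "(the *4P situation)")
    else:
        activity = 1.0
        why = "activity unconfirmed; assigned 1.0 for comparability"
    labels = ", ".join(v.label for v in sorted(extras))
    return NovelAlleleCandidate(
        backbone=backbone.name,
        extra_variants=extras,
        assigned_activity=activity,
        rationale=f"unexplained on {backbone.name} backbone: {labels}; {why}",
    )


# --------------------------------------------------------------------------
# Diplotype enumeration
# --------------------------------------------------------------------------

def _phase_groups(calls) -> tuple[list[VariantDef], list[tuple[VariantDef, ...]]]:
    """Split calls into the shared (homozygous) set and het phase groups."""
    shared: list[VariantDef] = []
    groups: dict[str, list[VariantDef]] = {}
    singles: list[tuple[VariantDef, ...]] = []
    for call in calls:
        if call.zygosity == "hom":
            shared.append(call.variant)
        elif call.phase_set is not None:
            groups.setdefault(call.phase_set, []).append(call.variant)
        else:
            singles.append((call.variant,))
    return shared, [tuple(g) for g in groups.values()] + singles


def enumerate_diplotypes(obs: ObservedGenotype, catalog: AlleleCatalog) -> list:
    """All diplotypes consistent with the observed (possibly unphased)
    variant calls, sorted by (fewest novel candidates, lowest combined
    allele number).  Never empty: if no partition matches cleanly, the
    single best pair of novel candidates is returned.
    """
    shared, het_groups = _phase_groups(obs.calls)
    seen: set[frozenset] = set()
    clean: list[tuple] = []
    fallback: list[tuple] = []
    n = len(het_groups)
    for mask in range(1 << max(n - 1, 0)):  # first group fixed on side A
        side_a = list(shared)
        side_b = list(shared)
        for i, group in enumerate(het_groups):
            bit = 0 if i == 0 else (mask >> (i - 1)) & 1
            (side_a if bit == 0 else side_b).extend(group)
        key = frozenset([frozenset(v.site for v in side_a),
                         frozenset(v.site for v in side_b)])
        if key in seen:
            continue
        seen.add(key)
        try:
            ha = match_haplotype(side_a, obs.gene, catalog)
            hb = match_haplotype(side_b, obs.gene, catalog)
        except AmbiguousMatchError:
            continue
        pair = normalise_pair((ha, hb))
        novel = sum(isinstance(h, NovelAlleleCandidate) for h in pair)
        (clean if novel == 0 else fallback).append((novel, pair))

    def sort_key(item):
        novel, pair = item
        return (novel, sum(_ordinal(h) for h in pair),
                tuple(_name_of(h) for h in pair))

    if clean:
        uniq: dict[tuple, tuple] = {}
        for item in sorted(clean, key=sort_key):
            names = tuple(_name_of(h) for h in item[1])
            uniq.setdefault(names, item[1])
        return list(uniq.values())
    if fallback:
        return [min(fallback, key=sort_key)[1]]
    # Every partition was ambiguous; fall back to a bulk novel candidate.
    all_vars = list(shared) + [v for g in het_groups for v in g]
    ref = catalog.get(obs.gene, catalog.reference_allele)
    cand = detect_novel(all_vars, obs.gene, catalog, backbone=ref)
    return [normalise_pair((cand if cand else "*1", "*1"))]


# --------------------------------------------------------------------------
# CNV and gene-conversion integration
# --------------------------------------------------------------------------

def integrate_cnv(pairs: list, obs: ObservedGenotype,
                  catalog: AlleleCatalog) -> list:
    """Fold deletion/duplication assay results into enumerated diplotypes."""
    if obs.deletion_copies == 2:
        return [("*5", "*5")]
    if obs.deletion_copies == 1:
        # One gene copy only: all calls must sit on a single haplotype
        # (homozygous-looking calls are hemizygous).  Conflicting alleles
        # at one position cannot be one haplotype.
        by_pos: dict[int, set] = {}
        for call in obs.calls:
            by_pos.setdefault(call.variant.position, set()).add(
                call.variant.site)
        for pos, sites in by_pos.items():
            if len(sites) > 1:
                raise InconsistentEvidenceError(
                    f"single-copy deletion but conflicting alleles at "
                    f"position {pos} require two non-deleted haplotypes"
                )
        haplotype = [call.variant for call in obs.calls]
        partner = match_haplotype(haplotype, obs.gene, catalog)
        pairs = [normalise_pair((partner, "*5"))]
    if obs.duplication_present:
        hint = obs.duplicated_allele_hint
        out = []
        for pair in pairs:
            if hint is None:
                # Duplication detected but the duplicated allele was not
                # characterised: any non-empty subset of the haplotypes may
                # carry it.  Enumerate, fewest extra copies first.
                seen: list[tuple] = []
                for mask in (0b01, 0b10, 0b11):
                    upgraded = [
                        (_name_of(h) + "xN" if mask >> i & 1
                         and not isinstance(h, NovelAlleleCandidate)
                         and _name_of(h) != "*5" else h)
                        for i, h in enumerate(pair)
                    ]
                    cand = normalise_pair(upgraded)
                    if cand not in seen and cand != tuple(pair):
                        seen.append(cand)
                out.extend(seen)
                continue
            upgraded = list(pair)
            matches = [i for i, h in enumerate(upgraded)
                       if _name_of(h) == hint]
            if matches:
                upgraded[matches[0]] = hint + "xN"
            out.append(normalise_pair(upgraded))
            if len(matches) == 2:
                # The duplication assay detects presence, not copy count:
                # with the hinted allele on both haplotypes, either or both
                # may carry the duplication.
                both = list(pair)
                both[matches[0]] = both[matches[1]] = hint + "xN"
                out.append(normalise_pair(both))
        pairs = out
    return pairs


def apply_exon9_conversion(pairs: list, obs: ObservedGenotype) -> tuple[list, list]:
    """Relabel *4 -> *4N and *10 -> *36 when the exon-9 gene-conversion
    assay is positive.  Returns (pairs, notes)."""
    if obs.gene is not Gene.CYP2D6 or not obs.exon9_conversion:
        return pairs, []
    relabel = {"*4": "*4N", "*10": "*36"}
    out, hit = [], False
    for pair in pairs:
        new = []
        for h in pair:
            name = _name_of(h)
            if name in relabel:
                new.append(relabel[name])
                hit = True
            else:
                new.append(h)
        out.append(normalise_pair(new))
    notes = [] if hit else [
        "exon-9 conversion assay positive but no *4/*10 haplotype to relabel"
    ]
    return out, notes


# --------------------------------------------------------------------------
# Orchestration
# --------------------------------------------------------------------------

def call_sample(obs: ObservedGenotype, catalog: AlleleCatalog) -> DiplotypeCall:
    """Full per-sample pipeline: enumerate -> CNV -> exon-9 -> score.

    Deterministic for fixed input.  Evidence inconsistencies surface as
    ``phenotype="no_call"`` with a diagnostic note rather than raising.
    """
    from . import phenotype as ph  # deferred: phenotype imports catalog only

    notes: list[str] = []
    try:
        if obs.deletion_copies == 2:
            pairs = [("*5", "*5")]
        else:
            pairs = enumerate_diplotypes(obs, catalog)
            pairs = integrate_cnv(pairs, obs, catalog)
        pairs, conv_notes = apply_exon9_conversion(pairs, obs)
        notes.extend(conv_notes)
    except (InconsistentEvidenceError, AmbiguousMatchError) as exc:
        return DiplotypeCall(
            sample_id=obs.sample_id, gene=obs.gene, primary=(),
            phenotype="no_call", phenotype_amplichip="no_call",
            notes=(f"inconsistent evidence: {exc}",),
        )
    # Deduplicate post-relabelling while preserving order.
    uniq: dict[tuple, tuple] = {}
    for pair in pairs:
        uniq.setdefault(tuple(_name_of(h) for h in pair), pair)
    pairs = list(uniq.values())
    primary, alternatives = pairs[0], tuple(pairs[1:])
    novel = tuple(h for h in primary if isinstance(h, NovelAlleleCandidate))
    score = ph.activity_score(primary, obs.gene, catalog)
    label = ph.classify_as(score)
    chip_label, _rule = ph.classify_amplichip_rules(primary, obs.gene, catalog)
    if any(_has_unknown_class(h, obs.gene, catalog) for h in primary):
        notes.append("contains-unknown")
    return DiplotypeCall(
        sample_id=obs.sample_id, gene=obs.gene,
        primary=primary, alternatives=alternatives,
        activity_score=score, phenotype=label,
        phenotype_amplichip=chip_label,
        novel_candidates=novel, notes=tuple(notes),
    )


def _has_unknown_class(h, gene: Gene, catalog: AlleleCatalog) -> bool:
    if isinstance(h, NovelAlleleCandidate):
        return True
    name = h[:-2] if h.endswith("xN") and (gene, h) not in catalog else h
    if (gene, name) in catalog:
        return catalog.get(gene, name).activity is ActivityClass.UNKNOWN
    return False
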