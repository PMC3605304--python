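"""Star-allele definitions and activity assignments for CYP2D6 and CYP2C19.

A *star allele* is a named haplotype of a pharmacogene, defined by one or
more key sequence variants in gene-local coordinates (1-based within the
gene reference frame; negative positions lie upstream of the ATG, position
0 does not exist).  Each allele carries an activity class — increased,
normal, decreased, absent or unknown — with a fixed numeric value used by
the Activity Score model:

    increased -> 2.0      normal -> 1.0      decreased -> 0.5
    absent    -> 0.0      unknown -> 1.0 (default, unconfirmed activity)

The built-in catalog covers the alleles relevant to South African cohort
screening of CYP2D6 and CYP2C19, including the CYP2D6 whole-gene deletion
(*5), gene duplications (xN), the exon-9 gene-conversion variants (*4N,
*36), four novel CYP2D6 alleles (*4P, *84, *85, *86) and the hybrid
CYP2C19 *2+*27 haplotype.  Alleles whose defining variants are not
confirmed within this project carry placeholder positions from the public
CYP nomenclature and are marked ``provenance="external-nomenclature"`` in
their annotations; downstream logic must not rely on those positions.
"""

from __future__ import annotations

import enum
import json
import re
from dataclasses import dataclass, field

__all__ = [
    "Gene",
    "VariantKind",
    "VariantDef",
    "ActivityClass",
    "StarAllele",
    "AlleleCatalog",
    "CatalogError",
    "builtin_catalog",
    "load_catalog",
    "save_catalog",
    "activity_of",
    "allele_ordinal",
    "parse_variant_label",
    "EXON9_MARKER",
]


class CatalogError(ValueError):
    """Malformed catalog content (parse failure or invariant violation)."""


class Gene(str, enum.Enum):
    CYP2D6 = "CYP2D6"
    CYP2C19 = "CYP2C19"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class VariantKind(str, enum.Enum):
    SNV = "SNV"
    INSERTION = "insertion"
    DELETION = "deletion"


_SNV_RE = re.compile(r"^(-?\d+)([ACGT])>([ACGT])$")
_INS_RE = re.compile(r"^(-?\d+)ins([ACGT]+)$")
_DEL_RE = re.compile(r"^(-?\d+)del([ACGT]+)$")


@dataclass(frozen=True, order=True)
class VariantDef:
    """A sequence variant in gene-local coordinates.

    ``label`` is the display form used throughout ("2988G>A", "-1584C>G",
    "1863insTTTGGGGCGAAA") and round-trips through
    :func:`parse_variant_label`.
    """

    position: int
    ref_allele: str
    alt_allele: str
    kind: VariantKind = VariantKind.SNV
    consequence: str | None = None

    def __post_init__(self) -> None:
        if self.position == 0:
            raise CatalogError("gene-local position 0 does not exist")
        if self.ref_allele == self.alt_allele:
            raise CatalogError(
                f"ref and alt identical at position {self.position}"
            )

    @property
    def label(self) -> str:
        if self.kind is VariantKind.SNV:
            return f"{self.position}{self.ref_allele}>{self.alt_allele}"
        if self.kind is VariantKind.INSERTION:
            return f"{self.position}ins{self.alt_allele}"
        return f"{self.position}del{self.ref_allele}"

    @property
    def site(self) -> tuple[int, str, str]:
        """Hashable identity used for haplotype matching."""
        return (self.position, self.ref_allele, self.alt_allele)

    def __str__(self) -> str:
        return self.label


def parse_variant_label(label: str, consequence: str | None = None) -> VariantDef:
    """Parse a display label like ``"2988G>A"`` back into a :class:`VariantDef`."""
    m = _SNV_RE.match(label)
    if m:
        return VariantDef(int(m.group(1)), m.group(2), m.group(3),
                          VariantKind.SNV, consequence)
    m = _INS_RE.match(label)
    if m:
        return VariantDef(int(m.group(1)), "-", m.group(2),
                          VariantKind.INSERTION, consequence)
    m = _DEL_RE.match(label)
    if m:
        return VariantDef(int(m.group(1)), m.group(2), "-",
                          VariantKind.DELETION, consequence)
    raise CatalogError(f"unparseable variant label: {label!r}")


class ActivityClass(str, enum.Enum):
    """Qualitative enzyme-activity class with its fixed numeric value."""

    INCREASED = "increased"
    NORMAL = "normal"
    DECREASED = "decreased"
    ABSENT = "absent"
    UNKNOWN = "unknown"

    @property
    def numeric(self) -> float:
        return _CLASS_VALUES[self]


_CLASS_VALUES = {
    ActivityClass.INCREASED: 2.0,
    ActivityClass.NORMAL: 1.0,
    ActivityClass.DECREASED: 0.5,
    ActivityClass.ABSENT: 0.0,
    ActivityClass.UNKNOWN: 1.0,  # default pending functional confirmation
}


@dataclass(frozen=True)
class StarAllele:
    """A named pharmacogene haplotype.

    ``key_variants`` define the allele (all must be present on a haplotype
    for it to match); ``backbone_variants`` are carried but non-defining,
    so their presence on a matched haplotype is explained without flagging
    novelty.  ``cnv_multiplier`` is the gene copy count contributed by the
    allele: 1 for ordinary alleles, 0 for the *5 whole-gene deletion, 2
    for duplication (xN) alleles, which reference their base allele via
    ``base_allele``.
    """

    gene: Gene
    name: str
    activity: ActivityClass
    key_variants: frozenset[VariantDef] = frozenset()
    backbone_variants: frozenset[VariantDef] = frozenset()
    cnv_multiplier: int = 1
    base_allele: str | None = None
    annotations: tuple[tuple[str, str], ...] = ()

    @property
    def numeric_activity(self) -> float:
        return self.activity.numeric

    @property
    def all_variants(self) -> frozenset[VariantDef]:
        return self.key_variants | self.backbone_variants

    def annotation_dict(self) -> dict[str, str]:
        return dict(self.annotations)


@dataclass
class AlleleCatalog:
    """Ordered star-allele definitions per gene, with *1 as reference."""

    alleles: dict[Gene, dict[str, StarAllele]] = field(default_factory=dict)
    reference_allele: str = "*1"

    def add(self, allele: StarAllele) -> None:
        per_gene = self.alleles.setdefault(allele.gene, {})
        if allele.name in per_gene:
            raise CatalogError(
                f"duplicate allele {allele.name} for {allele.gene.value}"
            )
        if allele.cnv_multiplier == 1:
            for other in per_gene.values():
                if (other.cnv_multiplier == 1
                        and other.key_variants == allele.key_variants):
                    raise CatalogError(
                        f"{allele.gene.value} {allele.name} and {other.name} "
                        "share identical key-variant sets"
                    )
        per_gene[allele.name] = allele

    def get(self, gene: Gene | str, name: str) -> StarAllele:
        gene = Gene(gene)
        try:
            return self.alleles[gene][name]
        except KeyError:
            raise KeyError(f"unknown allele {name} for {gene.value}") from None

    def __contains__(self, item: tuple[Gene | str, str]) -> bool:
        gene, name = item
        return name in self.alleles.get(Gene(gene), {})

    def genes(self) -> list[Gene]:
        return list(self.alleles)

    def alleles_of(self, gene: Gene | str) -> list[StarAllele]:
        return list(self.alleles.get(Gene(gene), {}).values())

    def null_key_sites(self, gene: Gene | str) -> frozenset[tuple[int, str, str]]:
        """Variant sites that mark loss of function for *gene*.

        A site qualifies when it belongs to the key set of an
        absent-function allele and to no functional allele's variants —
        the 1846G>A splice defect qualifies, the *2-core backbone SNPs
        carried by some null alleles do not.  Used when scoring novel
        haplotypes: a candidate carrying such a variant is assigned
        activity 0.0.
        """
        null_sites: set[tuple[int, str, str]] = set()
        functional_sites: set[tuple[int, str, str]] = set()
        for allele in self.alleles_of(gene):
            if allele.activity is ActivityClass.ABSENT:
                if allele.cnv_multiplier == 1:
                    null_sites.update(v.site for v in allele.key_variants)
            else:
                functional_sites.update(v.site for v in allele.all_variants)
        return frozenset(null_sites - functional_sites)

    def validate(self) -> None:
        for gene, per_gene in self.alleles.items():
            if self.reference_allele not in per_gene:
                raise CatalogError(f"{gene.value}: missing reference allele")
            ref = per_gene[self.reference_allele]
            if ref.key_variants:
                raise CatalogError(
                    f"{gene.value}: reference allele must have no key variants"
                )


def allele_ordinal(name: str) -> float:
    """Numeric ordering index of an allele name.

    ``*2`` -> 2, ``*45B`` -> 45, ``*2xN`` -> 2.5 (sorts after its base),
    hybrid ``*2+*27`` -> 29 (sum of parts).  Used for deterministic
    normalisation of diplotype pairs and ranking of alternatives.
    """
    if "+" in name:
        return sum(allele_ordinal(p if p.startswith("*") else "*" + p)
                   for p in name.split("+"))
    body = name.lstrip("*")
    extra = 0.0
    if body.endswith("xN"):
        body = body[:-2]
        extra = 0.5
    m = re.match(r"(\d+)", body)
    if not m:
        return float("inf")
    val = float(m.group(1)) + extra
    # letter suffixes (e.g. *45B, *4P, *4N) order after the bare number
    if re.search(r"\d+[A-Z]", body):
        val += 0.1
    return val


def activity_of(catalog: AlleleCatalog, gene: Gene | str, name: str) -> float:
    """Numeric activity of *name*, honouring the xN doubling rule.

    Duplication alleles contribute twice their base activity (one extra
    functional dose), so ``*1xN``/``*2xN`` give 2.0 and ``*4xN`` stays
    0.0.  A dynamic ``xN`` name absent from the catalog falls back to
    2 x the base allele's activity.
    """
    gene = Gene(gene)
    if (gene, name) in catalog:
        allele = catalog.get(gene, name)
        if allele.cnv_multiplier >= 2 and allele.base_allele:
            base = catalog.get(gene, allele.base_allele)
            return base.numeric_activity * allele.cnv_multiplier
        return allele.numeric_activity
    if name.endswith("xN"):
        base_name = name[:-2]
        if (gene, base_name) in catalog:
            return catalog.get(gene, base_name).numeric_activity * 2
    raise KeyError(f"unknown allele {name} for {gene.value}")


# --------------------------------------------------------------------------
# Built-in catalog
# --------------------------------------------------------------------------

def _v(label: str, consequence: str | None = None) -> VariantDef:
    return parse_variant_label(label, consequence)


# CYP2D6 gene-local variants (AY545216/M33388 numbering frame).
_M1584 = _v("-1584C>G")                 # promoter; *2 backbone
_V31 = _v("31G>A", "V11M")              # *35
_V77 = _v("77G>A", "R26H")              # *43
_V100 = _v("100C>T", "P34S")            # *10 / *4
_V1023 = _v("1023C>T", "T107I")         # *17
_V1659 = _v("1659G>A", "V136I")         # *29
_V1716 = _v("1716G>A")                  # *45/*46 group
_V1758A = _v("1758G>A")                 # *14
_V1846 = _v("1846G>A")                  # *4 splice defect (null)
_INS1863 = _v("1863insTTTGGGGCGAAA")    # *40
_V2291 = _v("2291G>A")                  # *59
_V2483 = _v("2483G>T", "A237S")         # *33
_V2574 = _v("2574C>A", "P267H")         # *84 defining
_V2606 = _v("2606G>A", "E278K")         # *86
_V2610 = _v("2610T>A", "M279K")         # *86 defining
_V2850 = _v("2850C>T", "R296C")         # *2 core
_V2988 = _v("2988G>A")                  # *41 key SNP
_V3183 = _v("3183G>A", "V338M")         # *29
_V3198 = _v("3198C>G", "R343G")         # *25
_V3201 = _v("3201C>T", "R344X")         # *56B (null)
_V3854 = _v("3854G>A")                  # *46
_V4157 = _v("4157T>G", "H478Q")         # *85 defining; also on *4P
_V4180 = _v("4180G>C", "S486T")         # *2 core
# Representative marker for the CYP2D7 exon-9 gene-conversion tract; kept so
# that *4N/*36 key sets stay distinct from *4/*10.  Assignment of these
# alleles is driven by the conversion assay flag, never by matching on it.
_EXON9 = _v("4133A>G")
EXON9_MARKER = _EXON9

# Placeholder defining variants for unknown-function alleles the activity
# table names but whose haplotypes this project never resolves.
_V1246 = _v("1246G>A")                  # *64 placeholder
_V2576 = _v("2576G>A")                  # *65 placeholder
_V3819 = _v("3819A>G")                  # *73 placeholder
_V3877 = _v("3877G>C")                  # *74 placeholder
_V1613 = _v("1613G>A")                  # *30 placeholder
_V822 = _v("822C>T")                    # *22 placeholder
_V213 = _v("213A>G")                    # *16 placeholder (structural hybrid)

# CYP2C19 gene-local variants.
_C19154 = _v("19154G>A")                # *2 splice defect (null)
_C17948 = _v("17948G>A", "W212X")       # *3 (null)
_C12784 = _v("12784G>A", "R144H")       # *9
_C55 = _v("55A>C", "I19L")              # *15
_CM806 = _v("-806C>T")                  # *17 promoter
# The *27 promoter SNP: reported as -1401 G>A in the primary results; a
# -1041 G>A form also circulates in the literature.  -1401 is used here.
_CM1401 = _v("-1401G>A")
_C12460 = _v("12460G>C")                # *28 placeholder

_EXT = (("provenance", "external-nomenclature"),)


def _allele(gene: Gene, name: str, activity: ActivityClass,
            key: set[VariantDef] | frozenset[VariantDef] = frozenset(),
            backbone: set[VariantDef] | frozenset[VariantDef] = frozenset(),
            cnv: int = 1, base: str | None = None,
            annotations: tuple[tuple[str, str], ...] = ()) -> StarAllele:
    return StarAllele(gene, name, activity, frozenset(key), frozenset(backbone),
                      cnv, base, tuple(sorted(annotations)))


def builtin_catalog() -> AlleleCatalog:
    """The study catalog: every allele of the CYP2D6/CYP2C19 activity table
    plus the four novel CYP2D6 alleles and the hybrid CYP2C19 *2+*27."""
    A = ActivityClass
    D6, C19 = Gene.CYP2D6, Gene.CYP2C19
    cat = AlleleCatalog()
    d6 = [
        _allele(D6, "*1", A.NORMAL),
        _allele(D6, "*2", A.NORMAL, {_V2850, _V4180}, {_M1584},
                annotations=_EXT),
        _allele(D6, "*4", A.ABSENT, {_V100, _V1846}),
        _allele(D6, "*5", A.ABSENT, cnv=0,
                annotations=(("note", "whole-gene deletion"),)),
        _allele(D6, "*10", A.DECREASED, {_V100}),
        _allele(D6, "*14", A.ABSENT, {_V1758A}),
        _allele(D6, "*16", A.ABSENT, {_V213}, annotations=_EXT),
        _allele(D6, "*17", A.DECREASED, {_V1023, _V2850, _V4180},
                annotations=_EXT),
        _allele(D6, "*22", A.NORMAL, {_V822}, annotations=_EXT),
        _allele(D6, "*25", A.UNKNOWN, {_V3198}, annotations=_EXT),
        _allele(D6, "*29", A.DECREASED, {_V1659, _V2850, _V3183, _V4180},
                annotations=_EXT),
        _allele(D6, "*30", A.UNKNOWN, {_V1613}, annotations=_EXT),
        _allele(D6, "*33", A.NORMAL, {_V2483}, annotations=_EXT),
        _allele(D6, "*35", A.NORMAL, {_V31, _V2850, _V4180}, {_M1584},
                annotations=_EXT),
        _allele(D6, "*36", A.DECREASED, {_V100, _EXON9},
                annotations=(("note", "exon 9 CYP2D7 conversion on *10"),)),
        _allele(D6, "*40", A.ABSENT, {_V1023, _INS1863, _V2850, _V4180},
                annotations=_EXT),
        _allele(D6, "*41", A.DECREASED, {_V2850, _V4180, _V2988},
                annotations=(("note", "key SNP 2988G>A"),)),
        _allele(D6, "*43", A.NORMAL, {_V77}, annotations=_EXT),
        _allele(D6, "*45B", A.NORMAL, {_V1716, _V2850, _V4180},
                annotations=_EXT),
        _allele(D6, "*46", A.NORMAL, {_V1716, _V3854, _V2850, _V4180},
                annotations=_EXT),
        _allele(D6, "*56B", A.ABSENT, {_V3201, _V2850, _V4180},
                annotations=_EXT),
        _allele(D6, "*59", A.DECREASED, {_V2291, _V2850, _V4180},
                annotations=_EXT),
        _allele(D6, "*64", A.UNKNOWN, {_V1246}, annotations=_EXT),
        _allele(D6, "*65", A.UNKNOWN, {_V2576}, annotations=_EXT),
        _allele(D6, "*73", A.UNKNOWN, {_V3819}, annotations=_EXT),
        _allele(D6, "*74", A.UNKNOWN, {_V3877}, annotations=_EXT),
        # Exon-9 gene-conversion form of *4.
        _allele(D6, "*4N", A.ABSENT, {_V100, _V1846, _EXON9}),
        # Novel alleles characterised in this cohort.
        _allele(D6, "*4P", A.ABSENT, {_V100, _V1846, _V4157},
                annotations=(("note", "novel; 4157T>G on *4 core; null via "
                                      "linked 1846G>A splice defect"),)),
        _allele(D6, "*84", A.UNKNOWN, {_V2850, _V4180, _V2574}, {_M1584},
                annotations=(("note", "novel; 2574C>A (P267H) on *2 backbone"),
                             ("SIFT", "0.03"), ("PolyPhen_PSIC", "0.871"))),
        _allele(D6, "*85", A.UNKNOWN, {_V2850, _V4180, _V4157}, {_M1584},
                annotations=(("note", "novel; 4157T>G (H478Q) on *2 backbone"),
                             ("SIFT", "0.58"), ("PolyPhen_PSIC", "0.419"))),
        _allele(D6, "*86", A.UNKNOWN, {_V2606, _V2610},
                annotations=(("note", "novel; 2606G>A (E278K) + 2610T>A "
                                      "(M279K)"),
                             ("SIFT_2610", "0.01"),
                             ("PolyPhen_PSIC_2610", "1.905"))),
        # Duplication alleles: one extra functional dose of the base allele.
        _allele(D6, "*1xN", A.INCREASED, cnv=2, base="*1"),
        _allele(D6, "*2xN", A.INCREASED, {_V2850, _V4180}, {_M1584},
                cnv=2, base="*2"),
        _allele(D6, "*4xN", A.ABSENT, {_V100, _V1846}, cnv=2, base="*4"),
    ]
    c19 = [
        _allele(C19, "*1", A.NORMAL),
        _allele(C19, "*2", A.ABSENT, {_C19154},
                annotations=(("note", "19154G>A splicing defect"),)),
        _allele(C19, "*3", A.ABSENT, {_C17948}, annotations=_EXT),
        _allele(C19, "*9", A.DECREASED, {_C12784}, annotations=_EXT),
        _allele(C19, "*15", A.UNKNOWN, {_C55}, annotations=_EXT),
        _allele(C19, "*17", A.INCREASED, {_CM806}, annotations=_EXT),
        _allele(C19, "*27", A.DECREASED, {_CM1401},
                annotations=(("note", "promoter SNP -1401G>A; a -1041G>A "
                                      "form is also reported"),)),
        _allele(C19, "*28", A.NORMAL, {_C12460}, annotations=_EXT),
        # Hybrid haplotype carrying both the *2 splice defect and the *27
        # promoter SNP; activity equals *2 (the splice defect dominates).
        _allele(C19, "*2+*27", A.ABSENT, {_C19154, _CM1401},
                annotations=(("note", "hybrid; listed at allele level as *2 "
                                      "since 19154G>A is allele-defining"),)),
    ]
    for allele in d6 + c19:
        cat.add(allele)
    cat.validate()
    return cat


# --------------------------------------------------------------------------
# Catalog file I/O (tab-separated, one allele per row)
# --------------------------------------------------------------------------

_HEADER = ["gene", "name", "key_variants", "backbone_variants",
           "activity_class", "cnv_multiplier", "base_allele", "annotations"]


def _format_variants(variants: frozenset[VariantDef]) -> str:
    parts = []
    for v in sorted(variants):
        parts.append(f"{v.label}|{v.consequence}" if v.consequence else v.label)
    return ",".join(parts) or "-"


def _parse_variants(cell: str, lineno: int) -> frozenset[VariantDef]:
    if cell in ("-", ""):
        return frozenset()
    out = []
    for part in cell.split(","):
        label, _, cons = part.partition("|")
        try:
            out.append(parse_variant_label(label, cons or None))
        except CatalogError as exc:
            raise CatalogError(f"line {lineno}: {exc}") from None
    return frozenset(out)


def save_catalog(catalog: AlleleCatalog, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_HEADER) + "\n")
        for gene in catalog.genes():
            for a in catalog.alleles_of(gene):
                fh.write("\t".join([
                    a.gene.value,
                    a.name,
                    _format_variants(a.key_variants),
                    _format_variants(a.backbone_variants),
                    a.activity.value,
                    str(a.cnv_multiplier),
                    a.base_allele or "-",
                    json.dumps(dict(a.annotations)) if a.annotations else "-",
                ]) + "\n")


def load_catalog(path) -> AlleleCatalog:
    cat = AlleleCatalog()
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise CatalogError(f"{path}: no alleles (empty file)")
    if lines[0].split("\t") != _HEADER:
        raise CatalogError(f"{path}: line 1: bad or missing header")
    if len(lines) == 1:
        raise CatalogError(f"{path}: no alleles")
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != len(_HEADER):
            raise CatalogError(
                f"{path}: line {lineno}: expected {len(_HEADER)} columns, "
                f"got {len(cells)}"
            )
        gene_s, name, key_s, back_s, class_s, cnv_s, base_s, ann_s = cells
        try:
            gene = Gene(gene_s)
            activity = ActivityClass(class_s)
            cnv = int(cnv_s)
        except ValueError as exc:
            raise CatalogError(f"{path}: line {lineno}: {exc}") from None
        annotations: tuple[tuple[str, str], ...] = ()
        if ann_s not in ("-", ""):
            try:
                annotations = tuple(sorted(json.loads(ann_s).items()))
            except json.JSONDecodeError as exc:
                raise CatalogError(
                    f"{path}: line {lineno}: bad annotations JSON: {exc}"
                ) from None
        allele = StarAllele(
            gene, name, activity,
            _parse_variants(key_s, lineno),
            _parse_variants(back_s, lineno),
            cnv, None if base_s in ("-", "") else base_s,
            annotations,
        )
        try:
            cat.add(allele)
        except CatalogError as exc:
            raise CatalogError(f"{path}: line {lineno}: {exc}") from None
    cat.validate()
    return cat
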