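"""Ground-truth cohort simulation and platform error models.

The generator emulates the study conditions: a stratified cohort (70
Black African, 10 Caucasian, 10 Coloured and 10 Indian individuals by
default) whose two alleles per gene are drawn i.i.d. within each stratum
— Hardy-Weinberg sampling — from the stratum's allele-frequency map.
The default maps are the comprehensive-platform frequency columns of the
study (XL-PCR+Sequencing for CYP2D6, PCR-RFLP for CYP2C19); printed
columns that do not sum to exactly 100% are renormalised proportionally.
The CYP2C19 maps carve a small *2+*27 hybrid-haplotype frequency out of
the printed *2 frequency (the hybrid was observed in three Black African
and one Indian individual and listed under *2).

Truth records carry the variant calls, deletion/duplication flags and
exon-9 conversion flags the wet-lab assays would report, so the caller
can be exercised end to end.  A :class:`PlatformProfile` then corrupts
truth into an "observed" call set: per-haplotype miscalls (e.g. the
microarray reporting *45B/*46 as *41 because it lacks their key SNPs),
heterozygous-deletion dropout (a *X/*5 sample reported as homozygous
*X/*X), and whole-sample failures and no-calls.  The error-free profile
is the identity.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import yaml

from .caller import ObservedGenotype, VariantCall, normalise_pair
from .catalog import AlleleCatalog, Gene, VariantDef

__all__ = [
    "SimulationConfig",
    "PlatformProfile",
    "TruthRecord",
    "PlatformCall",
    "DEFAULT_STRATA",
    "CYP2D6_SEQUENCING_FREQ",
    "CYP2C19_RFLP_FREQ",
    "ALLELES_IDENTIFIED",
    "default_cyp2d6_config",
    "default_cyp2c19_config",
    "amplichip_cyp2d6_profile",
    "amplichip_cyp2c19_profile",
    "error_free_profile",
    "simulate_truth",
    "apply_platform_model",
    "observed_genotype_for",
    "write_cohort",
    "read_cohort",
]

# Default stratum sample sizes (the healthy-volunteer cohort, n=100).
DEFAULT_STRATA = {"Black African": 70, "Caucasian": 10, "Coloured": 10,
                  "Indian": 10}

# CYP2D6 allele frequencies (%) per stratum, XL-PCR+Sequencing columns.
# Stored as printed; zero-frequency alleles omitted.
CYP2D6_SEQUENCING_FREQ: dict[str, dict[str, float]] = {
    "Black African": {"*1": 25.7, "*2": 8.6, "*5": 10.7, "*10": 5.7,
                      "*17": 25.7, "*29": 4.3, "*40": 3.6, "*41": 0.7,
                      "*43": 0.7, "*45B": 5.7, "*46": 0.7, "*56B": 0.7,
                      "*84": 0.7, "*85": 0.7, "*2xN": 0.7, "*4xN": 2.9},
    "Caucasian": {"*1": 30.0, "*2": 15.0, "*4": 20.0, "*5": 5.0, "*10": 5.0,
                  "*33": 5.0, "*35": 5.0, "*41": 15.0},
    "Coloured": {"*1": 30.0, "*2": 15.0, "*4": 15.0, "*5": 5.0, "*10": 5.0,
                 "*17": 10.0, "*29": 5.0, "*41": 5.0, "*43": 5.0,
                 "*59": 0.5},
    "Indian": {"*1": 45.0, "*2": 30.0, "*22": 5.0, "*41": 10.0, "*43": 5.0,
               "*86": 5.0},
}

# CYP2C19 allele frequencies (%) per stratum, PCR-RFLP columns.
CYP2C19_RFLP_FREQ: dict[str, dict[str, float]] = {
    "Black African": {"*1": 32.1, "*2": 17.9, "*9": 3.6, "*15": 5.7,
                      "*17": 16.4, "*27": 24.3},
    "Caucasian": {"*1": 70.0, "*2": 5.0, "*17": 25.0},
    "Coloured": {"*1": 40.0, "*2": 35.0, "*15": 10.0, "*27": 15.0},
    "Indian": {"*1": 40.0, "*2": 35.0, "*17": 5.0, "*27": 20.0},
}

# Alleles identified (n) per stratum on the comprehensive platforms.
ALLELES_IDENTIFIED = {"Black African": 140, "Caucasian": 20, "Coloured": 20,
                      "Indian": 20}

# Hybrid *2+*27 haplotype frequency (%), carved out of the printed *2
# frequency.  Estimated from the four individuals observed homozygous for
# the *2 key SNP while heterozygous for the *27 promoter SNP (3 Black
# African of 140 alleles, 1 Indian of 20).
CYP2C19_HYBRID_FREQ = {"Black African": 2.1, "Indian": 5.0}


@dataclass
class SimulationConfig:
    """Stratified HWE sampling configuration for one gene.

    ``frequencies`` are fractions summing to 1 +/- 1e-9 per stratum.
    """

    gene: Gene
    strata: dict[str, int]
    frequencies: dict[str, dict[str, float]]
    seed: int = 0

    def validate(self, catalog: AlleleCatalog | None = None) -> None:
        for stratum, n in self.strata.items():
            if n <= 0:
                raise ValueError(f"stratum {stratum}: sample size must be > 0")
            freqs = self.frequencies.get(stratum)
            if freqs is None:
                raise ValueError(f"stratum {stratum}: no frequency map")
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"stratum {stratum}: frequencies sum to {total!r}, not 1")
            if catalog is not None:
                for name in freqs:
                    if (self.gene, name) not in catalog:
                        raise ValueError(
                            f"stratum {stratum}: allele {name} missing from "
                            f"catalog for {self.gene.value}")

    def to_dict(self) -> dict:
        return {"gene": self.gene.value, "strata": dict(self.strata),
                "frequencies": {s: dict(f)
                                for s, f in self.frequencies.items()},
                "seed": self.seed}

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(gene=Gene(d["gene"]), strata=dict(d["strata"]),
                   frequencies={s: dict(f)
                                for s, f in d["frequencies"].items()},
                   seed=int(d.get("seed", 0)))

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def _normalise(percent_map: dict[str, float]) -> dict[str, float]:
    total = sum(percent_map.values())
    return {name: value / total for name, value in percent_map.items()}


def default_cyp2d6_config(seed: int = 0,
                          strata: dict[str, int] | None = None
                          ) -> SimulationConfig:
    return SimulationConfig(
        gene=Gene.CYP2D6,
        strata=dict(strata or DEFAULT_STRATA),
        frequencies={s: _normalise(f)
                     for s, f in CYP2D6_SEQUENCING_FREQ.items()},
        seed=seed,
    )


def default_cyp2c19_config(seed: int = 0,
                           strata: dict[str, int] | None = None
                           ) -> SimulationConfig:
    freqs = {}
    for stratum, table in CYP2C19_RFLP_FREQ.items():
        table = dict(table)
        hybrid = CYP2C19_HYBRID_FREQ.get(stratum, 0.0)
        if hybrid:
            table["*2"] = table["*2"] - hybrid
            table["*2+*27"] = hybrid
        freqs[stratum] = _normalise(table)
    return SimulationConfig(
        gene=Gene.CYP2C19,
        strata=dict(strata or DEFAULT_STRATA),
        frequencies=freqs,
        seed=seed,
    )


# --------------------------------------------------------------------------
# Platform error profiles
# --------------------------------------------------------------------------

@dataclass
class PlatformProfile:
    """Parametrised genotyping-platform error model.

    ``miscall_map`` maps a truth allele to [(called allele, probability),
    ...]; residual probability keeps the truth name.  Alleles the
    platform cannot represent at all are listed in ``uncovered_alleles``
    (informational) and fire their miscall with probability 1.0.
    """

    name: str
    miscall_map: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    deletion_dropout_prob: float = 0.0
    failure_prob: float = 0.0
    no_call_prob: float = 0.0
    uncovered_alleles: frozenset[str] = frozenset()

    def validate(self, catalog: AlleleCatalog, gene: Gene) -> None:
        probs = [self.deletion_dropout_prob, self.failure_prob,
                 self.no_call_prob]
        for source, options in self.miscall_map.items():
            total = sum(p for _, p in options)
            probs.extend(p for _, p in options)
            if total > 1 + 1e-9:
                raise ValueError(f"miscall probabilities for {source} "
                                 f"exceed 1")
            for target, _ in options:
                if (gene, target) not in catalog:
                    raise ValueError(f"miscall target {target} missing from "
                                     f"catalog for {gene.value}")
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")

    @property
    def is_identity(self) -> bool:
        return (not self.miscall_map and self.deletion_dropout_prob == 0
                and self.failure_prob == 0 and self.no_call_prob == 0)


def error_free_profile() -> PlatformProfile:
    return PlatformProfile(name="error-free")


def amplichip_cyp2d6_profile() -> PlatformProfile:
    """Default microarray error model for CYP2D6.

    Uncovered-allele miscalls fire with probability 1.0 (the array has no
    probes for those key SNPs and defaults them to the backbone allele it
    can see).  The *2->*41 and *1->*41 rates and the heterozygous-*5
    dropout rate are estimates derived from the reported miscall tallies
    over reconstructed exposure counts, not measured parameters; all are
    configurable.
    """
    return PlatformProfile(
        name="amplichip-cyp2d6",
        miscall_map={
            # alleles with no array coverage: deterministic defaults
            "*45B": [("*41", 1.0)],
            "*46": [("*41", 1.0)],
            "*56B": [("*10", 1.0)],
            "*59": [("*2", 0.5), ("*22", 0.5)],
            "*33": [("*1", 1.0)],
            "*43": [("*1", 1.0)],
            "*84": [("*2", 1.0)],   # novel; array sees only the *2 backbone
            "*85": [("*2", 1.0)],
            "*86": [("*1", 1.0)],
            "*4P": [("*4", 1.0)],   # novel; array sees only the *4 core
            # -1584C>G-based *41 designation failing outside Caucasians:
            # estimated 9 of ~24 *2 alleles and 5 of ~57 *1 alleles
            "*2": [("*41", 0.375)],
            "*1": [("*41", 0.088)],
        },
        deletion_dropout_prob=12 / 17,  # estimate: 17 true *5, 5 confirmed
        failure_prob=0.224,
        no_call_prob=0.04,
        uncovered_alleles=frozenset(
            {"*45B", "*46", "*56B", "*59", "*33", "*43", "*84", "*85",
             "*86", "*4P"}),
    )


def amplichip_cyp2c19_profile() -> PlatformProfile:
    """Microarray error model for CYP2C19: only *1/*2/*3 are on the array,
    so every other allele defaults to *1 and the hybrid to *2; the
    CYP2C19 reaction had no failures."""
    return PlatformProfile(
        name="amplichip-cyp2c19",
        miscall_map={
            "*9": [("*1", 1.0)],
            "*15": [("*1", 1.0)],
            "*17": [("*1", 1.0)],
            "*27": [("*1", 1.0)],
            "*28": [("*1", 1.0)],
            "*2+*27": [("*2", 1.0)],
        },
        uncovered_alleles=frozenset({"*9", "*15", "*17", "*27", "*28"}),
    )


# --------------------------------------------------------------------------
# Truth simulation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TruthRecord:
    sample_id: str
    stratum: str
    gene: Gene
    diplotype: tuple[str, str]
    observed: ObservedGenotype  # error-free assay readout of the truth


@dataclass(frozen=True)
class PlatformCall:
    sample_id: str
    stratum: str
    gene: Gene
    status: str                      # "ok" | "failure" | "no_call"
    called: tuple[str, str] | None   # None unless status == "ok"


def _strip(variant: VariantDef) -> VariantDef:
    # consequence annotations are catalog metadata, not assay output
    return VariantDef(variant.position, variant.ref_allele,
                      variant.alt_allele, variant.kind)


def observed_genotype_for(sample_id: str, gene: Gene,
                          diplotype: tuple[str, str],
                          catalog: AlleleCatalog) -> ObservedGenotype:
    """The error-free assay readout of a true diplotype: variant calls
    (hemizygotes read as homozygous), deletion copy count, duplication
    flag + hint, and the exon-9 conversion flag."""
    from .catalog import EXON9_MARKER
    deletion_copies = 0
    duplication = False
    duplicated_bases: list[str] = []
    exon9 = False
    haplotypes: list[frozenset[VariantDef]] = []
    for name in diplotype:
        if name == "*5":
            deletion_copies += 1
            continue
        allele = catalog.get(gene, name)
        variants = allele.all_variants
        if allele.cnv_multiplier >= 2:
            duplication = True
            duplicated_bases.append(allele.base_allele or name[:-2])
        if any(v.site == EXON9_MARKER.site for v in variants):
            exon9 = True
            variants = frozenset(v for v in variants
                                 if v.site != EXON9_MARKER.site)
        haplotypes.append(frozenset(_strip(v) for v in variants))
    calls = []
    all_variants = set().union(*haplotypes) if haplotypes else set()
    for variant in sorted(all_variants):
        copies = sum(variant in h for h in haplotypes)
        if deletion_copies == 1:
            zygosity = "hom"  # hemizygous reads as homozygous
        else:
            zygosity = "hom" if copies == 2 else "het"
        calls.append(VariantCall(variant, zygosity))
    # The duplication-specific product identifies the duplicated allele only
    # when a single distinct allele is duplicated; two different duplicated
    # alleles sequence as a mixture and yield no usable hint.
    hint = (duplicated_bases[0]
            if len(set(duplicated_bases)) == 1 and duplicated_bases else None)
    return ObservedGenotype(
        sample_id=sample_id, gene=gene, calls=tuple(calls),
        deletion_copies=deletion_copies, duplication_present=duplication,
        duplicated_allele_hint=hint, exon9_conversion=exon9,
    )


def simulate_truth(config: SimulationConfig,
                   catalog: AlleleCatalog) -> list[TruthRecord]:
    """Draw a stratified cohort under Hardy-Weinberg equilibrium.

    Within each stratum the two alleles of every individual are i.i.d.
    draws from the stratum frequency map.  Reproducible for a fixed
    config seed.
    """
    config.validate(catalog)
    rng = np.random.default_rng(config.seed)
    records = []
    counter = 0
    for stratum, n in config.strata.items():
        names = sorted(config.frequencies[stratum])
        probs = np.array([config.frequencies[stratum][a] for a in names])
        probs = probs / probs.sum()
        draws = rng.choice(len(names), size=(n, 2), p=probs)
        for i in range(n):
            counter += 1
            sid = f"S{counter:04d}"
            pair = normalise_pair((names[draws[i, 0]], names[draws[i, 1]]))
            records.append(TruthRecord(
                sample_id=sid, stratum=stratum, gene=config.gene,
                diplotype=pair,
                observed=observed_genotype_for(sid, config.gene, pair,
                                               catalog),
            ))
    return records


def apply_platform_model(truth: list[TruthRecord], profile: PlatformProfile,
                         seed: int,
                         catalog: AlleleCatalog | None = None
                         ) -> list[PlatformCall]:
    """Corrupt a truth cohort with a platform error model.

    Per sample: whole-run failure, then no-call, then per-haplotype
    miscalls, then heterozygous-*5 dropout (the surviving haplotype is
    reported homozygous).  The error-free profile is the identity.
    """
    if catalog is not None and truth:
        profile.validate(catalog, truth[0].gene)
    rng = np.random.default_rng(seed)
    out = []
    for rec in truth:
        if profile.failure_prob and rng.random() < profile.failure_prob:
            out.append(PlatformCall(rec.sample_id, rec.stratum, rec.gene,
                                    "failure", None))
            continue
        if profile.no_call_prob and rng.random() < profile.no_call_prob:
            out.append(PlatformCall(rec.sample_id, rec.stratum, rec.gene,
                                    "no_call", None))
            continue
        called = []
        for name in rec.diplotype:
            options = profile.miscall_map.get(name)
            if options:
                u = rng.random()
                cum = 0.0
                for target, p in options:
                    cum += p
                    if u < cum:
                        name = target
                        break
            called.append(name)
        if called.count("*5") == 1 and profile.deletion_dropout_prob:
            if rng.random() < profile.deletion_dropout_prob:
                partner = next(a for a in called if a != "*5")
                called = [partner, partner]
        out.append(PlatformCall(rec.sample_id, rec.stratum, rec.gene, "ok",
                                tuple(normalise_pair(called))))
    return out


# --------------------------------------------------------------------------
# Cohort files
# --------------------------------------------------------------------------

def write_cohort(truth: list[TruthRecord], observed: list[PlatformCall],
                 out_dir, config: SimulationConfig) -> dict[str, str]:
    """Write a simulated cohort: VCF + variant TSV + CNV sidecar + truth
    labels + observed platform calls + the config used (provenance)."""
    import csv
    from pathlib import Path

    from . import io as cio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tag = config.gene.value.lower()
    paths = {
        "vcf": out_dir / f"{tag}_variants.vcf",
        "variants": out_dir / f"{tag}_variants.tsv",
        "sidecar": out_dir / f"{tag}_cnv_sidecar.tsv",
        "truth": out_dir / f"{tag}_truth.tsv",
        "observed": out_dir / f"{tag}_observed.tsv",
        "config": out_dir / f"{tag}_config.yaml",
    }
    observations = [rec.observed for rec in truth]
    cio.write_vcf(observations, paths["vcf"])
    cio.write_variant_tsv(observations, paths["variants"], seed=config.seed)
    cio.write_cnv_sidecar(observations, paths["sidecar"], seed=config.seed)
    with open(paths["truth"], "w", newline="") as fh:
        cio.write_provenance_header(fh, seed=config.seed,
                                    extra={"config_hash": config.digest()})
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample", "stratum", "gene", "allele1", "allele2"])
        for rec in truth:
            writer.writerow([rec.sample_id, rec.stratum, rec.gene.value,
                             *rec.diplotype])
    with open(paths["observed"], "w", newline="") as fh:
        cio.write_provenance_header(fh, seed=config.seed,
                                    extra={"config_hash": config.digest()})
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample", "stratum", "gene", "status", "allele1",
                         "allele2"])
        for rec in observed:
            a, b = rec.called if rec.called else ("-", "-")
            writer.writerow([rec.sample_id, rec.stratum, rec.gene.value,
                             rec.status, a, b])
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}


def read_cohort(out_dir, gene: Gene) -> dict:
    """Re-load a written cohort; inverse of :func:`write_cohort`."""
    import csv
    from pathlib import Path

    from . import io as cio

    out_dir = Path(out_dir)
    tag = gene.value.lower()
    calls = cio.read_variant_tsv(out_dir / f"{tag}_variants.tsv")
    flags = cio.read_cnv_sidecar(out_dir / f"{tag}_cnv_sidecar.tsv")
    observations = cio.assemble_observations(calls, flags)

    def read_rows(path):
        with open(path) as fh:
            rows = [ln for ln in fh if not ln.startswith("#")]
        return list(csv.DictReader(rows, delimiter="\t"))

    truth = {r["sample"]: r for r in read_rows(out_dir / f"{tag}_truth.tsv")}
    observed = [
        PlatformCall(r["sample"], r["stratum"], Gene(r["gene"]), r["status"],
                     None if r["allele1"] == "-"
                     else (r["allele1"], r["allele2"]))
        for r in read_rows(out_dir / f"{tag}_observed.tsv")
    ]
    with open(out_dir / f"{tag}_config.yaml") as fh:
        config = SimulationConfig.from_dict(yaml.safe_load(fh))
    return {"observations": observations, "truth": truth,
            "observed": observed, "config": config}
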