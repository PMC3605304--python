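"""File formats: minimal VCF v4.2 subset, native variant TSV, CNV sidecar,
truth labels, diplotype-call tables.

Variant positions are stored internally in the gene-local frame (negative
for promoter variants).  VCF cannot carry negative positions, so each
gene's coordinates are shifted by a fixed positive offset recorded in the
VCF header (``##cypstar_offset=GENE:OFFSET``); readers shift back.  No
genome reference is attached: SNV REF/ALT are the gene-local ref and alt
bases, insertions/deletions use an ``N`` anchor base.
"""

from __future__ import annotations

import csv
from collections import defaultdict

import pysam
from cyvcf2 import VCF

from .caller import DiplotypeCall, ObservedGenotype, VariantCall
from .catalog import Gene, VariantDef, VariantKind

__all__ = [
    "GENE_OFFSETS",
    "write_vcf",
    "read_vcf",
    "write_variant_tsv",
    "read_variant_tsv",
    "write_cnv_sidecar",
    "read_cnv_sidecar",
    "assemble_observations",
    "write_calls_tsv",
    "read_calls_tsv",
    "write_provenance_header",
]

GENE_OFFSETS = {Gene.CYP2D6: 2000, Gene.CYP2C19: 2000}
_CONTIG_LENGTHS = {Gene.CYP2D6: 12000, Gene.CYP2C19: 30000}


def write_provenance_header(fh, seed=None, extra=None) -> None:
    from . import __version__
    fh.write(f"# cypstar {__version__}\n")
    if seed is not None:
        fh.write(f"# seed={seed}\n")
    for key, value in (extra or {}).items():
        fh.write(f"# {key}={value}\n")


# --------------------------------------------------------------------------
# VCF subset
# --------------------------------------------------------------------------

def _vcf_alleles(variant: VariantDef) -> tuple[str, str]:
    if variant.kind is VariantKind.SNV:
        return variant.ref_allele, variant.alt_allele
    if variant.kind is VariantKind.INSERTION:
        return "N", "N" + variant.alt_allele
    return "N" + variant.ref_allele, "N"


def _variant_from_vcf(pos: int, ref: str, alt: str) -> VariantDef:
    if len(ref) == 1 and len(alt) == 1:
        return VariantDef(pos, ref, alt, VariantKind.SNV)
    if len(alt) > len(ref):
        return VariantDef(pos, "-", alt[len(ref):], VariantKind.INSERTION)
    return VariantDef(pos, ref[len(alt):], "-", VariantKind.DELETION)


def write_vcf(observations: list[ObservedGenotype], path) -> None:
    """Write a multi-sample VCF 4.2 for one or more genes.

    One record per (gene, position, ref, alt); unphased diploid GT.
    Samples without a call at a site are 0/0 — the variant table is
    assumed complete over the genotyped region.
    """
    samples = list(dict.fromkeys(o.sample_id for o in observations))
    header = pysam.VariantHeader()
    header.add_line("##source=cypstar")
    for gene, offset in GENE_OFFSETS.items():
        header.contigs.add(gene.value, length=_CONTIG_LENGTHS[gene])
        header.add_line(f"##cypstar_offset={gene.value}:{offset}")
    header.formats.add("GT", 1, "String", "Genotype")
    for sid in samples:
        header.add_sample(sid)

    # site -> {sample: zygosity}
    sites: dict[tuple, dict[str, str]] = defaultdict(dict)
    for obs in observations:
        for call in obs.calls:
            key = (obs.gene, call.variant.position,
                   *_vcf_alleles(call.variant))
            sites[key][obs.sample_id] = call.zygosity

    with pysam.VariantFile(str(path), "w", header=header) as out:
        for (gene, pos, ref, alt) in sorted(
                sites, key=lambda k: (k[0].value, k[1], k[3])):
            rec = out.new_record(
                contig=gene.value, start=pos + GENE_OFFSETS[gene] - 1,
                alleles=(ref, alt), filter="PASS")
            per_sample = sites[(gene, pos, ref, alt)]
            for sid in samples:
                zyg = per_sample.get(sid)
                if zyg == "hom":
                    rec.samples[sid]["GT"] = (1, 1)
                elif zyg == "het":
                    rec.samples[sid]["GT"] = (0, 1)
                else:
                    rec.samples[sid]["GT"] = (0, 0)
                rec.samples[sid].phased = False
            out.write(rec)


def read_vcf(path) -> dict[tuple[str, Gene], list[VariantCall]]:
    """Read a cypstar VCF back into per-(sample, gene) variant calls."""
    vcf = VCF(str(path), gts012=True)
    offsets: dict[str, int] = {}
    for line in vcf.raw_header.splitlines():
        if line.startswith("##cypstar_offset="):
            gene_s, _, off = line.split("=", 1)[1].partition(":")
            offsets[gene_s] = int(off)
    samples = vcf.samples
    calls: dict[tuple[str, Gene], list[VariantCall]] = defaultdict(list)
    for rec in vcf:
        gene = Gene(rec.CHROM)
        pos = rec.POS - offsets.get(rec.CHROM, 0)
        variant = _variant_from_vcf(pos, rec.REF, rec.ALT[0])
        for sid, gt in zip(samples, rec.gt_types):
            if gt == 1:
                calls[(sid, gene)].append(VariantCall(variant, "het"))
            elif gt == 2:
                calls[(sid, gene)].append(VariantCall(variant, "hom"))
    vcf.close()
    return {k: sorted(v, key=lambda c: c.variant) for k, v in calls.items()}


# --------------------------------------------------------------------------
# Native TSVs
# --------------------------------------------------------------------------

_VARIANT_COLS = ["sample", "gene", "position", "ref", "alt", "kind",
                 "zygosity", "phase_set"]


def write_variant_tsv(observations: list[ObservedGenotype], path,
                      seed=None) -> None:
    with open(path, "w", newline="") as fh:
        write_provenance_header(fh, seed=seed)
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_VARIANT_COLS)
        for obs in observations:
            for call in sorted(obs.calls, key=lambda c: c.variant):
                v = call.variant
                writer.writerow([obs.sample_id, obs.gene.value, v.position,
                                 v.ref_allele, v.alt_allele, v.kind.value,
                                 call.zygosity, call.phase_set or "-"])


def read_variant_tsv(path) -> dict[tuple[str, Gene], list[VariantCall]]:
    calls: dict[tuple[str, Gene], list[VariantCall]] = defaultdict(list)
    with open(path) as fh:
        rows = [ln for ln in fh if not ln.startswith("#")]
    reader = csv.reader(rows, delimiter="\t")
    header = next(reader)
    if header != _VARIANT_COLS:
        raise ValueError(f"{path}: unexpected variant-table header")
    for row in reader:
        sid, gene_s, pos, ref, alt, kind, zyg, phase = row
        variant = VariantDef(int(pos), ref, alt, VariantKind(kind))
        calls[(sid, Gene(gene_s))].append(
            VariantCall(variant, zyg, None if phase == "-" else phase))
    return {k: sorted(v, key=lambda c: c.variant) for k, v in calls.items()}


_SIDECAR_COLS = ["sample", "gene", "deletion_copies", "duplication_present",
                 "duplicated_allele_hint", "exon9_conversion"]


def write_cnv_sidecar(observations: list[ObservedGenotype], path,
                      seed=None) -> None:
    with open(path, "w", newline="") as fh:
        write_provenance_header(fh, seed=seed)
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_SIDECAR_COLS)
        for obs in observations:
            writer.writerow([
                obs.sample_id, obs.gene.value, obs.deletion_copies,
                int(obs.duplication_present),
                obs.duplicated_allele_hint or "-",
                int(obs.exon9_conversion),
            ])


def read_cnv_sidecar(path) -> dict[tuple[str, Gene], dict]:
    flags: dict[tuple[str, Gene], dict] = {}
    with open(path) as fh:
        rows = [ln for ln in fh if not ln.startswith("#")]
    reader = csv.reader(rows, delimiter="\t")
    header = next(reader)
    if header != _SIDECAR_COLS:
        raise ValueError(f"{path}: unexpected sidecar header")
    for sid, gene_s, dels, dup, hint, conv in reader:
        flags[(sid, Gene(gene_s))] = {
            "deletion_copies": int(dels),
            "duplication_present": bool(int(dup)),
            "duplicated_allele_hint": None if hint == "-" else hint,
            "exon9_conversion": bool(int(conv)),
        }
    return flags


def assemble_observations(calls: dict[tuple[str, Gene], list[VariantCall]],
                          flags: dict[tuple[str, Gene], dict]
                          ) -> list[ObservedGenotype]:
    """Join a variant table with its CNV sidecar into observations.

    The sidecar drives the sample universe (a sample can have CNV flags
    and no variant calls); variant-only samples get default flags.
    """
    keys = list(dict.fromkeys(list(flags) + list(calls)))
    out = []
    for sid, gene in keys:
        kw = flags.get((sid, gene), {})
        out.append(ObservedGenotype(
            sample_id=sid, gene=gene,
            calls=tuple(calls.get((sid, gene), [])), **kw))
    return out


# --------------------------------------------------------------------------
# Diplotype-call tables
# --------------------------------------------------------------------------

_CALL_COLS = ["sample", "gene", "diplotype", "alternatives", "activity_score",
              "phenotype", "phenotype_amplichip", "novel_candidates", "notes"]


def write_calls_tsv(calls: list[DiplotypeCall], path, seed=None,
                    extra=None) -> None:
    from .caller import pair_name
    with open(path, "w", newline="") as fh:
        write_provenance_header(fh, seed=seed, extra=extra)
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_CALL_COLS)
        for c in calls:
            writer.writerow([
                c.sample_id, c.gene.value,
                pair_name(c.primary) if c.primary else "-",
                ";".join(pair_name(p) for p in c.alternatives) or "-",
                "" if c.activity_score != c.activity_score
                else f"{c.activity_score:g}",
                c.phenotype, c.phenotype_amplichip,
                ";".join(n.name for n in c.novel_candidates) or "-",
                ";".join(c.notes) or "-",
            ])


def read_calls_tsv(path) -> list[dict]:
    """Read a calls table back as row dicts (allele names only; novel
    candidates appear by display name)."""
    with open(path) as fh:
        rows = [ln for ln in fh if not ln.startswith("#")]
    reader = csv.DictReader(rows, delimiter="\t")
    out = []
    for rec in reader:
        diplotype = (tuple(rec["diplotype"].split("/"))
                     if rec["diplotype"] != "-" else None)
        out.append({
            "sample": rec["sample"],
            "gene": Gene(rec["gene"]),
            "diplotype": diplotype,
            "alternatives": [tuple(p.split("/"))
                             for p in rec["alternatives"].split(";")
                             if p and p != "-"],
            "activity_score": (float(rec["activity_score"])
                               if rec["activity_score"] else None),
            "phenotype": rec["phenotype"],
            "phenotype_amplichip": rec["phenotype_amplichip"],
            "notes": [] if rec["notes"] == "-" else rec["notes"].split(";"),
        })
    return out
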