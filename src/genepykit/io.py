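"""Readers and writers for the cohort's standard-format inputs.

Dialects: VCF v4.x (FORMAT GT/DP/GQ) via pysam; BED3+name with half-open
0-based intervals; 6-column PED; tab-separated annotation and participant
metadata tables.  VCF positions are 1-based and BED intervals 0-based
half-open; the conversion happens exactly once, at read time.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

from .model import (
    AnnotatedVariant,
    ClinvarClass,
    Individual,
    ParticipantMeta,
    Pedigree,
    SolvedStatus,
    VariantCohort,
    Zygosity,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CohortIOError",
    "ConfigurationError",
    "read_bed",
    "read_cohort_vcf",
    "write_cohort_vcf",
    "read_pedigree",
    "read_annotations",
    "read_metadata",
    "read_solved_genes",
]

ANNOTATION_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "cadd_phred",
    "gnomad_af",
    "coding_any_pm8",
    "coding_mane",
    "clinvar_class",
]


class CohortIOError(ValueError):
    """Malformed input file."""


class ConfigurationError(ValueError):
    """Input lacks a field the downstream filters require."""


def read_bed(bed_path: str | Path) -> dict[str, IntervalTree]:
    """Read BED3+name gene intervals into per-contig interval trees.

    Intervals are half-open 0-based ``[start, end)`` as BED defines them.
    """
    trees: dict[str, IntervalTree] = {}
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise CohortIOError(
                    f"{bed_path}:{lineno}: BED3+name requires 4 columns, got {len(fields)}"
                )
            chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            if end <= start:
                raise CohortIOError(f"{bed_path}:{lineno}: empty/inverted interval")
            trees.setdefault(chrom, IntervalTree()).addi(start, end, name)
    return trees


def _genes_at(trees: dict[str, IntervalTree] | None, chrom: str, pos: int) -> frozenset:
    """Genes overlapping a 1-based VCF position under half-open BED semantics."""
    if trees is None:
        return frozenset()
    tree = trees.get(chrom)
    if tree is None:
        return frozenset()
    return frozenset(iv.data for iv in tree.at(pos - 1))


def read_cohort_vcf(
    vcf_path: str | Path,
    bed_path: str | Path | None = None,
) -> VariantCohort:
    """Read a multi-sample VCF into a :class:`VariantCohort`.

    Multi-allelic records are decomposed into one biallelic record per
    alternate allele; the per-genotype DP/GQ of the original call is kept on
    every decomposed allele.  When ``bed_path`` is given, records overlapping
    no interval are dropped and ``gene_ids`` is populated from the overlap; a
    variant lying on an interval's half-open end coordinate is excluded.
    """
    trees = read_bed(bed_path) if bed_path is not None else None
    try:
        vf = pysam.VariantFile(str(vcf_path))
    except (ValueError, OSError) as exc:
        raise CohortIOError(f"malformed VCF {vcf_path}: {exc}") from exc
    with vf:
        for fmt in ("GT", "DP", "GQ"):
            if fmt not in vf.header.formats:
                raise ConfigurationError(
                    f"{vcf_path}: FORMAT field {fmt} missing from header; "
                    "genotype filters cannot be applied"
                )
        samples = list(vf.header.samples)
        n = len(samples)
        variants: list[AnnotatedVariant] = []
        try:
            records = list(vf)
        except (ValueError, OSError) as exc:
            raise CohortIOError(f"malformed VCF {vcf_path}: {exc}") from exc
        for rec in records:
            alts = rec.alts or ()
            genes = _genes_at(trees, rec.chrom, rec.pos)
            if trees is not None and not genes:
                continue
            # Pull per-sample fields once; decomposition reuses them per allele.
            gts = [rec.samples[s].get("GT") for s in samples]
            dps = np.array(
                [rec.samples[s].get("DP") or 0 for s in samples], dtype=np.int32
            )
            gqs = np.array(
                [rec.samples[s].get("GQ") or 0 for s in samples], dtype=np.int32
            )
            for ai, alt in enumerate(alts, start=1):
                zyg = np.empty(n, dtype=np.int8)
                for si, gt in enumerate(gts):
                    if gt is None or any(a is None for a in gt):
                        zyg[si] = Zygosity.MISSING
                    else:
                        zyg[si] = sum(1 for a in gt if a == ai)
                variants.append(
                    AnnotatedVariant(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=str(alt),
                        zygosity=zyg,
                        depth=dps.copy(),
                        gq=gqs.copy(),
                        gene_ids=genes,
                    )
                )
    return VariantCohort(samples=samples, variants=variants)


_GT_STRING = {Zygosity.MISSING: "./.", Zygosity.HOM_REF: "0/0", Zygosity.HET: "0/1", Zygosity.HOM_ALT: "1/1"}


def write_cohort_vcf(cohort: VariantCohort, path: str | Path) -> None:
    """Write the cohort back out as an uncompressed VCF v4.2 text file."""
    contigs: dict[str, int] = {}
    for v in cohort.variants:
        contigs[v.chrom] = max(contigs.get(v.chrom, 0), v.pos + len(v.ref) + 1000)
    with open(path, "w") as out:
        out.write("##fileformat=VCFv4.2\n")
        for chrom, length in contigs.items():
            out.write(f"##contig=<ID={chrom},length={length}>\n")
        out.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        out.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        out.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        out.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(cohort.samples)
            + "\n"
        )
        for v in sorted(cohort.variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
            cells = [
                f"{_GT_STRING[Zygosity(int(z))]}:{d}:{q}"
                for z, d, q in zip(v.zygosity, v.depth, v.gq)
            ]
            out.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t.\tGT:DP:GQ\t"
                + "\t".join(cells)
                + "\n"
            )


def read_pedigree(ped_path: str | Path) -> Pedigree:
    """Read a standard 6-column PED file.

    Column 6 codes the phenotype: 2 = affected, 1 = unaffected; anything else
    is unknown and maps to unaffected with a warning.  A parent id that never
    appears as an individual is set to null with a warning.
    """
    rows: list[tuple[str, ...]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise CohortIOError(f"{ped_path}:{lineno}: PED requires 6 columns")
            rows.append(tuple(fields[:6]))
    if not rows:
        logger.warning("%s: empty pedigree file", ped_path)
        return Pedigree()
    known = {r[1] for r in rows}
    individuals: dict[str, Individual] = {}
    for fam, sid, father, mother, sex, pheno in rows:
        father_id = father if father not in ("0", "", ".") else None
        mother_id = mother if mother not in ("0", "", ".") else None
        for pid, role in ((father_id, "father"), (mother_id, "mother")):
            if pid is not None and pid not in known:
                logger.warning(
                    "%s: %s %r of %r not in pedigree; setting to null", ped_path, role, pid, sid
                )
        if father_id not in known:
            father_id = None
        if mother_id not in known:
            mother_id = None
        if pheno not in ("1", "2"):
            logger.warning(
                "%s: unknown phenotype code %r for %r; treating as unaffected",
                ped_path,
                pheno,
                sid,
            )
        try:
            sex_code = int(sex)
        except ValueError:
            sex_code = 0
        individuals[sid] = Individual(
            sample_id=sid,
            family_id=fam,
            father_id=father_id,
            mother_id=mother_id,
            sex=sex_code if sex_code in (1, 2) else 0,
            affected=(pheno == "2"),
        )
    return Pedigree(individuals=individuals)


def _parse_bool(value) -> bool | None:
    if pd.isna(value):
        return None
    s = str(value).strip().lower()
    if s in ("1", "true", "t", "yes"):
        return True
    if s in ("0", "false", "f", "no"):
        return False
    raise CohortIOError(f"cannot parse boolean annotation value {value!r}")


def read_annotations(tsv_path: str | Path, cohort: VariantCohort) -> VariantCohort:
    """Join the annotation table onto the cohort's variants in place.

    The table is keyed by (chrom, pos, ref, alt); duplicate keys are an
    error (ambiguous annotation).  Variants absent from the table keep
    absent deleteriousness and allele frequency; the match rate is logged.
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    missing_cols = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing_cols:
        raise CohortIOError(f"{tsv_path}: missing annotation columns {missing_cols}")
    keys = list(zip(df["chrom"], df["pos"].astype(int), df["ref"], df["alt"]))
    if len(set(keys)) != len(keys):
        dupes = pd.Series(keys).value_counts()
        dupes = dupes[dupes > 1].index.tolist()[:5]
        raise CohortIOError(f"{tsv_path}: duplicate annotation keys, e.g. {dupes}")
    table = {k: row for k, (_, row) in zip(keys, df.iterrows())}
    matched = 0
    for v in cohort.variants:
        row = table.get(v.key)
        if row is None:
            v.deleteriousness_raw = None
            v.ref_pop_af = None
            continue
        matched += 1
        cadd = row["cadd_phred"]
        af = row["gnomad_af"]
        v.deleteriousness_raw = None if pd.isna(cadd) else float(cadd)
        v.ref_pop_af = None if pd.isna(af) else float(af)
        if v.ref_pop_af is not None and not (0.0 <= v.ref_pop_af <= 1.0):
            raise CohortIOError(f"{tsv_path}: allele frequency out of [0,1] for {v.key}")
        v.is_coding_any_transcript = _parse_bool(row["coding_any_pm8"])
        v.is_coding_mane = _parse_bool(row["coding_mane"])
        cls = row["clinvar_class"]
        v.clinvar_class = (
            ClinvarClass.NONE if pd.isna(cls) else ClinvarClass(str(cls).strip().upper())
        )
    if cohort.variants:
        logger.info(
            "annotation match rate: %d/%d (%.1f%%)",
            matched,
            len(cohort.variants),
            100.0 * matched / len(cohort.variants),
        )
    return cohort


def read_metadata(tsv_path: str | Path) -> dict[str, ParticipantMeta]:
    """Read the participant metadata table keyed by sample id."""
    df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    required = ["sample_id", "affected", "solved", "withdrawn", "hpo_terms"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortIOError(f"{tsv_path}: missing metadata columns {missing}")
    out: dict[str, ParticipantMeta] = {}
    for _, row in df.iterrows():
        sid = row["sample_id"]
        if sid in out:
            raise CohortIOError(f"{tsv_path}: duplicate sample_id {sid!r}")
        terms_raw = row["hpo_terms"]
        terms = (
            frozenset()
            if pd.isna(terms_raw) or not str(terms_raw).strip()
            else frozenset(t.strip() for t in str(terms_raw).split(";") if t.strip())
        )
        out[sid] = ParticipantMeta(
            sample_id=sid,
            affected=bool(_parse_bool(row["affected"])),
            solved=SolvedStatus(str(row["solved"]).strip().upper()),
            hpo_terms=terms,
            withdrawn=bool(_parse_bool(row["withdrawn"])),
        )
    return out


def read_solved_genes(tsv_path: str | Path) -> dict[str, set[str]]:
    """Map solved participants to their established diagnostic gene(s)."""
    df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    for col in ("sample_id", "gene_id"):
        if col not in df.columns:
            raise CohortIOError(f"{tsv_path}: missing column {col}")
    out: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        out.setdefault(row["sample_id"], set()).add(row["gene_id"])
    return out
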