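"""Self-contained synthetic rare-disease cohorts with planted diagnoses.

The simulator emulates the statistical structure the burden method assumes:
a polymorphic background of sites with reference allele frequencies spanning
rare to common, genotypes drawn under Hardy-Weinberg equilibrium, a
deleteriousness distribution with a heavy upper tail, Mendelian-consistent
parent-child trios, and planted rare, damaging, biallelic genotypes
(homozygous or compound heterozygous, in trans or in cis) in designated
affected, undiagnosed individuals.  It emits exactly the dialects the IO
layer consumes (VCF, annotation TSV, PED, metadata TSV) plus a truth table,
and is byte-reproducible from its seed.

It deliberately omits linkage disequilibrium, sequencing-error models and
population stratification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as cohort_io
from .model import (
    AnnotatedVariant,
    ClinvarClass,
    Individual,
    ParticipantMeta,
    Pedigree,
    SolvedStatus,
    VariantCohort,
)

__all__ = ["SimConfig", "PlantRecord", "SimulatedCohort", "simulate_cohort", "mendelian_trio_genotypes", "write_bundle"]

GENE_SPAN = 100_000  # bp reserved per gene on the synthetic contig
GENE_WIDTH = 90_000  # bp of actual gene interval


@dataclass(frozen=True)
class SimConfig:
    """Synthetic cohort parameters.

    Defaults describe the standard study conditions used throughout the test
    suite: a 1000-sample cohort over 50 genes, ~30% of samples in trios, and
    five planted biallelic genotypes at allele frequency 1e-5 with raw
    deleteriousness 40 (well above the CADD-15 analysis floor).  Background
    deleteriousness is a bulk-plus-tail mixture putting 10% of sites above
    20, so the coding/CADD filters do non-trivial work.
    """

    n_samples: int = 1000
    n_genes: int = 50
    sites_per_gene_range: tuple[int, int] = (5, 50)  # log-uniform
    af_range: tuple[float, float] = (1e-5, 0.5)  # log-uniform
    d_bulk_range: tuple[float, float] = (0.0, 20.0)
    d_tail_range: tuple[float, float] = (20.0, 45.0)
    d_tail_weight: float = 0.1
    p_coding_any: float = 0.7
    p_mane_given_coding: float = 0.9
    fraction_trios: float = 0.3
    n_planted: int = 5
    planted_kinds: tuple[str, ...] = ("hom", "compound-het-trans")
    planted_af: float = 1e-5
    planted_d: float = 40.0
    planted_clinvar: str = "P"
    n_withdrawn_plants: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for frac in (self.d_tail_weight, self.fraction_trios, self.p_coding_any, self.p_mane_given_coding):
            if not (0.0 <= frac <= 1.0):
                raise ValueError("fractions must lie in [0,1]")
        if self.planted_af > 1e-4:
            raise ValueError("planted allele frequency must be <= 1e-4 (rare by design)")
        if self.planted_d < 25.0:
            raise ValueError("planted deleteriousness must be >= 25")
        if self.n_planted > self.n_samples:
            raise ValueError("cannot plant more diagnoses than samples")
        if self.n_planted > self.n_genes:
            raise ValueError("one planted gene per plant: n_planted must be <= n_genes")


@dataclass(frozen=True)
class PlantRecord:
    sample_id: str
    gene_id: str
    variant_keys: tuple[tuple[str, int, str, str], ...]
    zygosity_kind: str  # hom | compound-het-trans | compound-het-cis
    expected_phase: str
    expected_tier: str


@dataclass
class SimulatedCohort:
    cohort: VariantCohort  # annotations already populated
    pedigree: Pedigree
    metadata: dict[str, ParticipantMeta]
    truth: list[PlantRecord]
    bed_intervals: list[tuple[str, int, int, str]]
    config: SimConfig


def mendelian_trio_genotypes(
    rng: np.random.Generator, af: float, n_trios: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(father, mother, child) alt-allele dosages at one biallelic site.

    Parents are drawn under Hardy-Weinberg at ``af``; the child receives one
    allele from each parent, transmitted with probability dosage/2.
    """
    father = rng.binomial(2, af, size=n_trios)
    mother = rng.binomial(2, af, size=n_trios)
    child = rng.binomial(1, father / 2.0) + rng.binomial(1, mother / 2.0)
    return father, mother, child


def _draw_site_genotypes(
    rng: np.random.Generator, af: float, n_trios: int, n_singletons: int
) -> np.ndarray:
    """Cohort dosages: trio blocks (child, father, mother) then singletons."""
    father, mother, child = mendelian_trio_genotypes(rng, af, n_trios)
    singles = rng.binomial(2, af, size=n_singletons)
    trio_block = np.empty(3 * n_trios, dtype=np.int8)
    trio_block[0::3] = child
    trio_block[1::3] = father
    trio_block[2::3] = mother
    return np.concatenate([trio_block, singles.astype(np.int8)])


def _expected_tier(kind: str, clinvar: str) -> str:
    if kind == "compound-het-cis":
        return "EXCLUDE"
    return "TOP" if clinvar in ("P", "LP") else "MIDDLE"


def simulate_cohort(config: SimConfig | None = None, seed: int | None = None) -> SimulatedCohort:
    """Generate a fully annotated in-memory cohort with planted diagnoses.

    Planted compound heterozygotes (and, for pedigree realism, homozygotes)
    are placed in trio children so phase is recoverable from parental
    genotypes.  Planted individuals are flagged affected + unsolved with
    three HPO terms; everyone else is unaffected.
    """
    config = config or SimConfig()
    if seed is not None:
        config = SimConfig(**{**vars(config), "seed": seed})
    rng = np.random.default_rng(config.seed)

    n_trios = int(config.fraction_trios * config.n_samples // 3)
    if config.n_planted > max(n_trios, 0):
        raise ValueError(
            f"{config.n_planted} plants need trio children but only {n_trios} trios; "
            "raise fraction_trios or n_samples"
        )
    n_singletons = config.n_samples - 3 * n_trios

    samples = [f"S{i:05d}" for i in range(config.n_samples)]
    individuals: dict[str, Individual] = {}
    for t in range(n_trios):
        child, father, mother = samples[3 * t], samples[3 * t + 1], samples[3 * t + 2]
        fam = f"F{t:04d}"
        individuals[father] = Individual(father, fam, None, None, sex=1)
        individuals[mother] = Individual(mother, fam, None, None, sex=2)
        individuals[child] = Individual(child, fam, father_id=father, mother_id=mother, sex=1)
    for s in samples[3 * n_trios:]:
        individuals[s] = Individual(s, family_id=s)

    genes = [f"GENE{g:04d}" for g in range(config.n_genes)]
    bed = [("chr1", g * GENE_SPAN, g * GENE_SPAN + GENE_WIDTH, genes[g]) for g in range(config.n_genes)]

    lo, hi = config.sites_per_gene_range
    plant_clinvar = ClinvarClass(config.planted_clinvar)
    variants: list[AnnotatedVariant] = []
    truth: list[PlantRecord] = []

    for g, gene in enumerate(genes):
        n_bg = int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
        plant_here = g < config.n_planted
        kind = config.planted_kinds[g % len(config.planted_kinds)] if plant_here else None
        n_plant_sites = 0 if not plant_here else (1 if kind == "hom" else 2)
        offsets = rng.choice(GENE_WIDTH, size=n_bg + n_plant_sites, replace=False)
        bg_pos = np.sort(offsets[:n_bg]) + g * GENE_SPAN + 1
        plant_pos = np.sort(offsets[n_bg:]) + g * GENE_SPAN + 1

        for pos in bg_pos:
            af = float(np.exp(rng.uniform(np.log(config.af_range[0]), np.log(config.af_range[1]))))
            if rng.random() < config.d_tail_weight:
                d_raw = float(rng.uniform(*config.d_tail_range))
            else:
                d_raw = float(rng.uniform(*config.d_bulk_range))
            coding_any = bool(rng.random() < config.p_coding_any)
            coding_mane = coding_any and bool(rng.random() < config.p_mane_given_coding)
            u = rng.random()
            clinvar = ClinvarClass.VUS if u < 0.05 else (ClinvarClass.B if u < 0.07 else ClinvarClass.NONE)
            dosage = _draw_site_genotypes(rng, af, n_trios, n_singletons)
            depth = rng.poisson(35, size=config.n_samples).astype(np.int32)
            gq = rng.integers(60, 100, size=config.n_samples).astype(np.int32)
            low_gq = rng.random(config.n_samples) < 0.05
            gq[low_gq] = rng.integers(0, 20, size=int(low_gq.sum()))
            site_mode = rng.random()
            if site_mode < 0.02:  # site-wide poor genotype quality
                gq = rng.integers(10, 31, size=config.n_samples).astype(np.int32)
            elif site_mode < 0.04:  # site-wide dropout: fails the call-rate filter
                drop = rng.random(config.n_samples) < 0.4
                depth[drop] = rng.integers(0, 10, size=int(drop.sum()))
            variants.append(
                AnnotatedVariant(
                    chrom="chr1",
                    pos=int(pos),
                    ref="A",
                    alt="T",
                    zygosity=dosage,
                    depth=depth,
                    gq=gq,
                    gene_ids=frozenset({gene}),
                    deleteriousness_raw=d_raw,
                    ref_pop_af=af,
                    is_coding_any_transcript=coding_any,
                    is_coding_mane=coding_mane,
                    clinvar_class=clinvar,
                )
            )

        if not plant_here:
            continue
        child_i, father_i, mother_i = 3 * g, 3 * g + 1, 3 * g + 2
        plant_variants: list[AnnotatedVariant] = []
        for k, pos in enumerate(plant_pos):
            dosage = _draw_site_genotypes(rng, config.planted_af, n_trios, n_singletons)
            depth = rng.poisson(35, size=config.n_samples).astype(np.int32)
            gq = rng.integers(60, 100, size=config.n_samples).astype(np.int32)
            if kind == "hom":
                dosage[child_i], dosage[father_i], dosage[mother_i] = 2, 1, 1
            elif kind == "compound-het-trans":
                if k == 0:
                    dosage[child_i], dosage[father_i], dosage[mother_i] = 1, 1, 0
                else:
                    dosage[child_i], dosage[father_i], dosage[mother_i] = 1, 0, 1
            elif kind == "compound-het-cis":
                dosage[child_i], dosage[father_i], dosage[mother_i] = 1, 0, 1
            else:
                raise ValueError(f"unknown planted zygosity kind {kind!r}")
            for i in (child_i, father_i, mother_i):
                depth[i], gq[i] = 50, 99
            plant_variants.append(
                AnnotatedVariant(
                    chrom="chr1",
                    pos=int(pos),
                    ref="G",
                    alt="C",
                    zygosity=dosage,
                    depth=depth,
                    gq=gq,
                    gene_ids=frozenset({gene}),
                    deleteriousness_raw=config.planted_d,
                    ref_pop_af=config.planted_af,
                    is_coding_any_transcript=True,
                    is_coding_mane=True,
                    clinvar_class=plant_clinvar,
                )
            )
        variants.extend(plant_variants)
        truth.append(
            PlantRecord(
                sample_id=samples[child_i],
                gene_id=gene,
                variant_keys=tuple(v.key for v in plant_variants),
                zygosity_kind=kind,
                expected_phase={
                    "hom": "NA_HOMOZYGOUS",
                    "compound-het-trans": "TRANS",
                    "compound-het-cis": "CIS",
                }[kind],
                expected_tier=_expected_tier(kind, config.planted_clinvar),
            )
        )

    planted_samples = {rec.sample_id: i for i, rec in enumerate(truth)}
    metadata: dict[str, ParticipantMeta] = {}
    for s in samples:
        if s in planted_samples:
            pi = planted_samples[s]
            metadata[s] = ParticipantMeta(
                sample_id=s,
                affected=True,
                solved=SolvedStatus.UNSOLVED,
                hpo_terms=frozenset({"HP:0000118", "HP:0001250", "HP:0012759"}),
                withdrawn=pi < config.n_withdrawn_plants,
            )
        else:
            metadata[s] = ParticipantMeta(sample_id=s, affected=False, solved=SolvedStatus.UNKNOWN)
    individuals = {
        s: Individual(
            ind.sample_id, ind.family_id, ind.father_id, ind.mother_id, ind.sex,
            affected=metadata[s].affected,
        )
        for s, ind in individuals.items()
    }

    return SimulatedCohort(
        cohort=VariantCohort(samples=samples, variants=variants),
        pedigree=Pedigree(individuals=individuals),
        metadata=metadata,
        truth=truth,
        bed_intervals=bed,
        config=config,
    )


def write_bundle(sim: SimulatedCohort, outdir: str | Path) -> dict[str, Path]:
    """Write the simulated cohort as the file bundle the pipeline consumes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "cohort.vcf",
        "bed": outdir / "genes.bed",
        "annotations": outdir / "annotations.tsv",
        "ped": outdir / "cohort.ped",
        "metadata": outdir / "metadata.tsv",
        "truth": outdir / "truth.tsv",
    }
    cohort_io.write_cohort_vcf(sim.cohort, paths["vcf"])
    with open(paths["bed"], "w") as out:
        for chrom, start, end, name in sim.bed_intervals:
            out.write(f"{chrom}\t{start}\t{end}\t{name}\n")
    with open(paths["annotations"], "w") as out:
        out.write("\t".join(cohort_io.ANNOTATION_COLUMNS) + "\n")
        for v in sorted(sim.cohort.variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
            out.write(
                f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{v.deleteriousness_raw:.6g}\t"
                f"{v.ref_pop_af:.6g}\t{int(v.is_coding_any_transcript)}\t"
                f"{int(v.is_coding_mane)}\t{v.clinvar_class.value}\n"
            )
    with open(paths["ped"], "w") as out:
        for s in sim.cohort.samples:
            ind = sim.pedigree.individuals[s]
            out.write(
                f"{ind.family_id}\t{ind.sample_id}\t{ind.father_id or 0}\t"
                f"{ind.mother_id or 0}\t{ind.sex}\t{2 if ind.affected else 1}\n"
            )
    with open(paths["metadata"], "w") as out:
        out.write("sample_id\taffected\tsolved\twithdrawn\thpo_terms\n")
        for s in sim.cohort.samples:
            m = sim.metadata[s]
            out.write(
                f"{s}\t{int(m.affected)}\t{m.solved.value}\t{int(m.withdrawn)}\t"
                f"{';'.join(sorted(m.hpo_terms))}\n"
            )
    with open(paths["truth"], "w") as out:
        out.write("sample_id\tgene\tvariant_keys\tzygosity\tphase\texpected_tier\n")
        for rec in sim.truth:
            keys = ",".join("{}:{}:{}:{}".format(*k) for k in rec.variant_keys)
            out.write(
                f"{rec.sample_id}\t{rec.gene_id}\t{keys}\t{rec.zygosity_kind}\t"
                f"{rec.expected_phase}\t{rec.expected_tier}\n"
            )
    return paths
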