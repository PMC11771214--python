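"""End-to-end orchestration: score a cohort, then rank, triage, prioritize.

Two stages rather than one monolith, so a scored matrix can serve as a
reference dataset: ``run_rank_prioritize`` accepts an external reference
matrix and ranks the new cohort's samples within the pooled cohort, provided
both matrices carry the same config fingerprint.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import io as cohort_io
from .model import ParticipantMeta, Pedigree, VariantCohort
from .prioritize import CasePrioritizer, PrioritizedCase, Tier, TierRules
from .qc import FilterConfig
from .rank import CohortRanker, RankEntry, TriageCategory, triage
from .score import GenePyMatrix, GenePyScorer, ScoreConfig

logger = logging.getLogger(__name__)

__all__ = ["PipelineError", "load_cohort", "run_score", "run_rank_prioritize"]


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage that raised it."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


def _stage(stage: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc


def load_cohort(vcf: str | Path, bed: str | Path, annotations: str | Path) -> VariantCohort:
    cohort = _stage("read_vcf", cohort_io.read_cohort_vcf, vcf, bed)
    _stage("read_annotations", cohort_io.read_annotations, annotations, cohort)
    return cohort


def run_score(
    vcf: str | Path,
    bed: str | Path,
    annotations: str | Path,
    outdir: str | Path,
    filter_config: FilterConfig | None = None,
    score_config: ScoreConfig | None = None,
    genes: list[str] | None = None,
) -> GenePyMatrix:
    """Score a cohort and write the matrix plus the filter report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = load_cohort(vcf, bed, annotations)
    fcfg = filter_config or FilterConfig()
    scfg = score_config or ScoreConfig()
    if genes is None:
        genes = [iv.data for tree in cohort_io.read_bed(bed).values() for iv in sorted(tree)]
    scorer = GenePyScorer(
        **vars(fcfg), **vars(scfg), genes=genes
    )
    matrix = _stage("score", scorer.score_matrix, cohort)
    matrix.to_tsv(outdir / "matrix.tsv")
    report = pd.DataFrame(
        [
            {
                "variant": "{}:{}:{}:{}".format(*r.key),
                "status": r.status,
                "reason": r.reason,
                "mean_gq": r.mean_gq,
                "call_rate": r.call_rate,
            }
            for r in scorer.site_report_
        ]
    )
    report.to_csv(outdir / "filter_report.tsv", sep="\t", index=False)
    n_sites = len(scorer.site_report_)
    n_pass = sum(1 for r in scorer.site_report_ if r.status == "pass")
    logger.info(
        "score: %d variants read, %d passed site filters, %d selected for scoring "
        "(%s), %d genes x %d samples",
        n_sites,
        n_pass,
        scorer.selection_counts_["selected"],
        scorer.selection_counts_,
        len(matrix.genes),
        len(matrix.samples),
    )
    return matrix


@dataclass
class RankPrioritizeResult:
    top_table: pd.DataFrame
    triage_table: pd.DataFrame
    cases: list[PrioritizedCase]
    tier_summary: pd.DataFrame


def _tier_summary(cases: list[PrioritizedCase]) -> pd.DataFrame:
    """Tier x deprioritization-flag tabulation of the prioritized cases."""
    rows = []
    for tier in Tier:
        sub = [c for c in cases if c.tier == tier]
        rows.append(
            {
                "tier": tier.value,
                "n_cases": len(sub),
                "noncoding_mane": sum(c.flags.noncoding_mane for c in sub),
                "common_in_callset": sum(c.flags.common_in_callset for c in sub),
                "non_segregating": sum(c.flags.non_segregating for c in sub),
                "in_cis": sum(c.flags.in_cis for c in sub),
                "no_second_hit": sum(c.flags.no_second_hit for c in sub),
            }
        )
    return pd.DataFrame(rows)


def run_rank_prioritize(
    matrix: GenePyMatrix | str | Path,
    vcf: str | Path,
    bed: str | Path,
    annotations: str | Path,
    ped: str | Path,
    metadata: str | Path,
    outdir: str | Path,
    solved_genes: str | Path | None = None,
    reference_matrix: GenePyMatrix | str | Path | None = None,
    top_n: int = 5,
    min_hpo_terms: int = 2,
    min_deleteriousness: float = 15.0,
    rules: TierRules | None = None,
) -> RankPrioritizeResult:
    """Rank per gene, select and triage top scorers, prioritize candidates."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not isinstance(matrix, GenePyMatrix):
        matrix = _stage("read_matrix", GenePyMatrix.from_tsv, matrix)
    cohort = load_cohort(vcf, bed, annotations)
    pedigree = _stage("read_pedigree", cohort_io.read_pedigree, ped)
    meta = _stage("read_metadata", cohort_io.read_metadata, metadata)
    missing = [s for s in matrix.samples if s not in meta]
    if missing:
        raise PipelineError("rank", f"matrix samples missing from metadata: {missing[:5]}")
    solved = (
        _stage("read_solved_genes", cohort_io.read_solved_genes, solved_genes)
        if solved_genes is not None
        else {}
    )
    rules = rules or TierRules()

    if reference_matrix is not None:
        if not isinstance(reference_matrix, GenePyMatrix):
            reference_matrix = _stage("read_matrix", GenePyMatrix.from_tsv, reference_matrix)
        ranker = CohortRanker(top_n=top_n, min_hpo_terms=min_hpo_terms).fit(reference_matrix)
        ranks = _stage("rank", ranker.transform, matrix)
        rows = [
            {
                "gene": gene,
                "sample_id": s,
                "score": float(matrix.data.at[gene, s]),
                "rank": int(ranks.at[gene, s]),
            }
            for gene in matrix.genes
            for s in matrix.samples
            if ranks.at[gene, s] <= top_n and matrix.data.at[gene, s] > 0
        ]
        top = pd.DataFrame(rows, columns=["gene", "sample_id", "score", "rank"])
    else:
        ranker = CohortRanker(top_n=top_n, min_hpo_terms=min_hpo_terms).fit(matrix)
        top = _stage("rank", ranker.top_table)

    triage_rows = []
    assessable: list[tuple[str, str, int, float]] = []
    for gene, sub in top.groupby("gene", sort=False):
        entries = [
            RankEntry(sample_id=r.sample_id, score=r.score, rank=r.rank)
            for r in sub.itertuples()
        ]
        for t in _stage("triage", triage, entries, gene, meta, solved, min_hpo_terms):
            triage_rows.append(
                {
                    "gene": t.gene_id,
                    "sample_id": t.sample_id,
                    "score": t.score,
                    "rank": t.rank,
                    "category": t.category.value,
                }
            )
            if t.category == TriageCategory.AFFECTED_UNSOLVED_ASSESSABLE:
                assessable.append((t.sample_id, t.gene_id, t.rank, t.score))
    triage_table = pd.DataFrame(
        triage_rows, columns=["gene", "sample_id", "score", "rank", "category"]
    )

    prioritizer = CasePrioritizer(
        min_deleteriousness=min_deleteriousness,
        common_af_threshold=rules.common_af_threshold,
        pathogenic_classes=rules.pathogenic_classes,
    ).fit()
    cases = []
    for sample_id, gene_id, rank, score in assessable:
        case = _stage(
            "prioritize",
            prioritizer.prioritize_case,
            cohort,
            sample_id,
            gene_id,
            pedigree=pedigree,
            metadata=meta,
            rank=rank,
            score=score,
        )
        if case is not None:
            cases.append(case)

    top.to_csv(outdir / "top_ranked.tsv", sep="\t", index=False)
    triage_table.to_csv(outdir / "triage.tsv", sep="\t", index=False)
    with open(outdir / "cases.json", "w") as out:
        json.dump([c.to_dict() for c in cases], out, indent=2)
    summary = _tier_summary(cases)
    summary.to_csv(outdir / "tier_summary.tsv", sep="\t", index=False)
    logger.info(
        "rank: %d top-ranked entries, %d assessable, %d cases (%s)",
        len(top),
        len(assessable),
        len(cases),
        {t.value: int((summary.set_index('tier').at[t.value, 'n_cases'])) for t in Tier},
    )
    return RankPrioritizeResult(
        top_table=top, triage_table=triage_table, cases=cases, tier_summary=summary
    )
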