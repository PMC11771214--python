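"""Per-gene cohort ranking, top-N selection with tie retention, and triage.

Ranks are competition ("min") ranks: the highest score is rank 1, tied
scores share the minimal rank, and the next distinct score's rank is the
number of strictly higher-scoring individuals plus one.  Top-N selection
keeps every individual whose rank is at most N, so a tie straddling the
cutoff keeps all its members; individuals with score exactly 0 are never
selected — a zero score means no qualifying variant, which cannot be a
missed biallelic diagnosis.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator

from .model import ParticipantMeta
from .score import GenePyMatrix

__all__ = [
    "RankEntry",
    "RankedGene",
    "TriageCategory",
    "TriagedParticipant",
    "CohortRanker",
    "rank_gene",
    "select_top",
    "triage",
]


@dataclass(frozen=True)
class RankEntry:
    sample_id: str
    score: float
    rank: int


@dataclass
class RankedGene:
    """Per-gene ordering of individuals, highest score first.

    Ties share a competition rank; within a tie the listing order is by
    sample id, for reproducible output only.
    """

    gene_id: str
    entries: list[RankEntry]


class TriageCategory(str, Enum):
    UNAFFECTED = "UNAFFECTED"
    AFFECTED_SOLVED_SAME_GENE = "AFFECTED_SOLVED_SAME_GENE"
    AFFECTED_SOLVED_OTHER_GENE = "AFFECTED_SOLVED_OTHER_GENE"
    AFFECTED_UNSOLVED_NO_HPO = "AFFECTED_UNSOLVED_NO_HPO"
    AFFECTED_UNSOLVED_INSUFFICIENT_HPO = "AFFECTED_UNSOLVED_INSUFFICIENT_HPO"
    AFFECTED_UNSOLVED_ASSESSABLE = "AFFECTED_UNSOLVED_ASSESSABLE"


@dataclass(frozen=True)
class TriagedParticipant:
    sample_id: str
    gene_id: str
    rank: int
    score: float
    category: TriageCategory


def competition_ranks(scores: np.ndarray) -> np.ndarray:
    """Rank 1 = highest score; ties share the minimal rank."""
    return rankdata(-np.asarray(scores, dtype=float), method="min").astype(int)


def rank_gene(matrix: GenePyMatrix | pd.DataFrame, gene: str) -> RankedGene:
    """Competition-rank every individual's score for one gene."""
    df = matrix.data if isinstance(matrix, GenePyMatrix) else matrix
    if gene not in df.index:
        raise KeyError(f"gene {gene!r} not in matrix")
    scores = df.loc[gene]
    ranks = competition_ranks(scores.to_numpy())
    entries = [
        RankEntry(sample_id=s, score=float(v), rank=int(r))
        for s, v, r in zip(scores.index, scores.to_numpy(), ranks)
    ]
    entries.sort(key=lambda e: (-e.score, e.sample_id))
    return RankedGene(gene_id=gene, entries=entries)


def select_top(ranked: RankedGene, n: int = 5) -> list[RankEntry]:
    """All entries with competition rank <= n and a nonzero score."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return [e for e in ranked.entries if e.rank <= n and e.score > 0.0]


def triage(
    selected: list[RankEntry],
    gene_id: str,
    metadata: dict[str, ParticipantMeta],
    solved_genes: dict[str, set[str]] | None = None,
    min_hpo_terms: int = 2,
) -> list[TriagedParticipant]:
    """Assign each top-ranked participant to exactly one triage category.

    Unaffected individuals are set aside; affected, solved individuals are
    split by whether their established diagnostic gene is this gene; affected
    unsolved individuals need at least ``min_hpo_terms`` recorded HPO terms
    to be assessable.
    """
    solved_genes = solved_genes or {}
    missing = [e.sample_id for e in selected if e.sample_id not in metadata]
    if missing:
        raise KeyError(f"samples missing from metadata: {missing}")
    out: list[TriagedParticipant] = []
    for e in selected:
        meta = metadata[e.sample_id]
        if not meta.affected:
            cat = TriageCategory.UNAFFECTED
        elif meta.solved == meta.solved.SOLVED:
            diagnostic = solved_genes.get(e.sample_id, set())
            cat = (
                TriageCategory.AFFECTED_SOLVED_SAME_GENE
                if gene_id in diagnostic
                else TriageCategory.AFFECTED_SOLVED_OTHER_GENE
            )
        elif len(meta.hpo_terms) == 0:
            cat = TriageCategory.AFFECTED_UNSOLVED_NO_HPO
        elif len(meta.hpo_terms) < min_hpo_terms:
            cat = TriageCategory.AFFECTED_UNSOLVED_INSUFFICIENT_HPO
        else:
            cat = TriageCategory.AFFECTED_UNSOLVED_ASSESSABLE
        out.append(
            TriagedParticipant(
                sample_id=e.sample_id,
                gene_id=gene_id,
                rank=e.rank,
                score=e.score,
                category=cat,
            )
        )
    return out


class CohortRanker(BaseEstimator):
    """Rank individuals per gene, optionally against a reference matrix.

    ``fit`` stores a reference score matrix.  ``transform`` ranks the samples
    of a new matrix within the pooled reference + new cohort, so a stored
    matrix can serve as a reference dataset for later cohorts scored with
    identical configs: ranks returned for a new sample equal the ranks it
    would receive inside a merged cohort.
    """

    def __init__(self, top_n: int = 5, min_hpo_terms: int = 2):
        self.top_n = top_n
        self.min_hpo_terms = min_hpo_terms

    def fit(self, X: GenePyMatrix | pd.DataFrame, y=None) -> "CohortRanker":
        df = X.data if isinstance(X, GenePyMatrix) else X
        self.reference_ = df
        self.fingerprint_ = X.config_fingerprint if isinstance(X, GenePyMatrix) else ""
        return self

    def transform(self, X: GenePyMatrix | pd.DataFrame) -> pd.DataFrame:
        """Ranks (genes x new samples) of new samples within the pooled cohort."""
        new = X.data if isinstance(X, GenePyMatrix) else X
        if isinstance(X, GenePyMatrix) and self.fingerprint_ and X.config_fingerprint:
            if X.config_fingerprint != self.fingerprint_:
                raise ValueError(
                    "config fingerprint mismatch: new matrix was not built with "
                    "the reference matrix's configs"
                )
        if list(new.index) != list(self.reference_.index):
            raise ValueError("gene sets of reference and new matrix differ")
        overlap = set(new.columns) & set(self.reference_.columns)
        if overlap:
            raise ValueError(f"samples present in both reference and new matrix: {sorted(overlap)[:5]}")
        merged = pd.concat([self.reference_, new], axis=1)
        ranks = np.vstack([competition_ranks(row) for row in merged.to_numpy()])
        return pd.DataFrame(ranks, index=merged.index, columns=merged.columns)[new.columns]

    def rank_gene(self, gene: str) -> RankedGene:
        return rank_gene(self.reference_, gene)

    def top_table(
        self,
        metadata: dict[str, ParticipantMeta] | None = None,
        solved_genes: dict[str, set[str]] | None = None,
    ) -> pd.DataFrame:
        """Top-N report over all genes of the fitted matrix, one row per
        retained (gene, sample); triage category included when metadata given."""
        rows = []
        for gene in self.reference_.index:
            selected = select_top(self.rank_gene(gene), self.top_n)
            if metadata is not None:
                triaged = triage(selected, gene, metadata, solved_genes, self.min_hpo_terms)
                for t in triaged:
                    rows.append(
                        {
                            "gene": gene,
                            "sample_id": t.sample_id,
                            "score": t.score,
                            "rank": t.rank,
                            "category": t.category.value,
                        }
                    )
            else:
                for e in selected:
                    rows.append(
                        {"gene": gene, "sample_id": e.sample_id, "score": e.score, "rank": e.rank}
                    )
        cols = ["gene", "sample_id", "score", "rank"] + (
            ["category"] if metadata is not None else []
        )
        return pd.DataFrame(rows, columns=cols)
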