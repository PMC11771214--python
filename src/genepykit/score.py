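"""The GenePy gene-pathogenicity statistic.

Each variant carried by an individual contributes

    s = -D * log10(f1 * f2)

where ``D`` is a unit-interval deleteriousness weight derived from a raw
in-silico score (CADD-phred here) and ``(f1, f2)`` are the reference-population
frequencies of the individual's two alleles at the site: a heterozygote
carries (fa, 1 - fa), a homozygote (fa, fa), with ``fa`` the alternate-allele
frequency floored at ``af_floor``.  For a rare allele a homozygote therefore
scores twice a heterozygote.  Per gene and per individual these contributions
are summed (or, in ``max_variant_mode``, the largest single contribution is
taken), giving a genes x individuals score matrix.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin

from .model import AnnotatedVariant, VariantCohort, Zygosity
from .qc import FilterConfig, SiteFilterRecord, filter_genotypes, filter_sites, select_scoring_variants

__all__ = [
    "ScoreConfig",
    "VariantScore",
    "GenePyMatrix",
    "GenePyScorer",
    "transform_deleteriousness",
    "allele_frequencies",
    "score_variant",
    "score_gene",
    "build_matrix",
]

D_TRANSFORMS = ("clip_scale", "raw", "rank_unit")


@dataclass(frozen=True)
class ScoreConfig:
    """Scoring knobs.

    d_transform
        How the raw deleteriousness score maps to the unit-interval weight D:
        ``clip_scale`` (default) clips at ``d_cap`` and divides by it;
        ``raw`` uses the raw score unchanged; ``rank_unit`` uses the
        empirical rank of the score among the cohort's scored variants,
        mapped to (0, 1].
    d_cap
        Clip point for ``clip_scale``, in CADD-phred units.
    af_floor
        Lower bound on allele frequency; prevents unbounded scores for
        alleles unobserved in the reference population (~ a singleton in a
        50k-genome reference).
    max_variant_mode
        Score each gene by its highest-scoring single variant instead of the
        sum — a dominant-disease mode that stops long genes accruing score
        from many modest variants.
    """

    d_transform: str = "clip_scale"
    d_cap: float = 40.0
    af_floor: float = 1e-5
    max_variant_mode: bool = False

    def __post_init__(self) -> None:
        if self.d_transform not in D_TRANSFORMS:
            raise ValueError(f"d_transform must be one of {D_TRANSFORMS}")
        if not (0.0 < self.af_floor < 0.5):
            raise ValueError("af_floor must lie in (0, 0.5)")
        if self.d_cap <= 0:
            raise ValueError("d_cap must be positive")


@dataclass(frozen=True)
class VariantScore:
    """A single individual x variant score contribution."""

    sample_id: str
    key: tuple[str, int, str, str]
    d: float
    f1: float
    f2: float
    score: float


def transform_deleteriousness(
    raw: float,
    config: ScoreConfig | None = None,
    rank_map: dict[float, float] | None = None,
) -> float:
    """Map a raw deleteriousness score to the weight D."""
    config = config or ScoreConfig()
    if raw < 0:
        raise ValueError(f"raw deleteriousness must be non-negative; got {raw}")
    if config.d_transform == "clip_scale":
        return min(raw, config.d_cap) / config.d_cap
    if config.d_transform == "raw":
        return float(raw)
    if rank_map is None:
        raise ValueError("rank_unit transform requires a fitted rank map")
    return rank_map[raw]


def build_rank_map(raw_values: list[float]) -> dict[float, float]:
    """Empirical-rank map onto (0, 1] for the rank_unit transform."""
    arr = np.asarray(raw_values, dtype=float)
    ranks = rankdata(arr, method="average") / len(arr)
    return {float(v): float(r) for v, r in zip(arr, ranks)}


def allele_frequencies(
    ref_pop_af: float | None, zygosity: Zygosity, config: ScoreConfig | None = None
) -> tuple[float, float]:
    """Allele-frequency pair (f1, f2) for a carried genotype.

    The alternate frequency is floored at ``af_floor`` (and symmetrically
    capped at ``1 - af_floor`` so the heterozygote's reference-allele term
    stays positive).  HET -> (fa, 1 - fa); HOM_ALT -> (fa, fa).
    """
    config = config or ScoreConfig()
    if zygosity not in (Zygosity.HET, Zygosity.HOM_ALT):
        raise ValueError(f"no allele-frequency pair for zygosity {zygosity!r}")
    fa = config.af_floor if ref_pop_af is None else max(ref_pop_af, config.af_floor)
    fa = min(fa, 1.0 - config.af_floor)
    if zygosity == Zygosity.HET:
        return (fa, 1.0 - fa)
    return (fa, fa)


def score_variant(d: float, f1: float, f2: float) -> float:
    """One summand of the statistic: ``-d * log10(f1 * f2)``."""
    if f1 * f2 <= 0.0:
        raise ValueError("allele frequencies must be positive (apply the floor first)")
    return -d * np.log10(f1 * f2)


def score_gene(variant_scores: list[VariantScore], config: ScoreConfig | None = None) -> float:
    """Aggregate one individual's variant scores within one gene."""
    config = config or ScoreConfig()
    if not variant_scores:
        return 0.0
    values = [vs.score for vs in variant_scores]
    return max(values) if config.max_variant_mode else float(sum(values))


def config_fingerprint(filter_config: FilterConfig, score_config: ScoreConfig) -> str:
    payload = json.dumps(
        {"filter": vars(filter_config), "score": vars(score_config)}, sort_keys=True
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class GenePyMatrix:
    """Genes x individuals score matrix with config provenance."""

    data: pd.DataFrame  # index: gene ids, columns: sample ids
    config_fingerprint: str = ""

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate gene ids in matrix")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate sample ids in matrix")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    def to_tsv(self, path) -> None:
        with open(path, "w") as out:
            out.write(f"#config_fingerprint={self.config_fingerprint}\n")
            self.data.to_csv(out, sep="\t", index_label="gene", float_format="%.17g")

    @classmethod
    def from_tsv(cls, path) -> "GenePyMatrix":
        fingerprint = ""
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#config_fingerprint="):
                fingerprint = first.strip().split("=", 1)[1]
            else:
                fh.seek(0)
            # round_trip parser: "%.17g" cells must reparse to the same double
            df = pd.read_csv(fh, sep="\t", index_col="gene", float_precision="round_trip")
        df.index.name = None
        return cls(data=df, config_fingerprint=fingerprint)


class GenePyScorer(BaseEstimator, TransformerMixin):
    """Transform a variant cohort into a GenePy genes x samples matrix.

    The estimator bundles the QC thresholds and scoring knobs as flat sklearn
    parameters.  ``fit`` validates the cohort and, for the ``rank_unit``
    deleteriousness transform, learns the empirical rank map over the
    cohort's scoring-eligible variants; ``transform`` runs genotype masking,
    site filtering, variant selection and scoring, returning the matrix as a
    :class:`pandas.DataFrame`.  One sample's scores never depend on other
    samples' genotypes except through the shared site filters.

    Parameters mirror :class:`~genepykit.qc.FilterConfig` and
    :class:`ScoreConfig`; ``genes`` optionally fixes the gene set (and row
    order) of the output matrix.
    """

    def __init__(
        self,
        min_depth: int = 10,
        min_gq: int = 20,
        min_mean_gq: float = 35.0,
        min_call_rate: float = 0.70,
        min_deleteriousness: float = 15.0,
        require_coding_any: bool = True,
        mean_gq_post_mask: bool = True,
        d_transform: str = "clip_scale",
        d_cap: float = 40.0,
        af_floor: float = 1e-5,
        max_variant_mode: bool = False,
        genes: list[str] | None = None,
    ):
        self.min_depth = min_depth
        self.min_gq = min_gq
        self.min_mean_gq = min_mean_gq
        self.min_call_rate = min_call_rate
        self.min_deleteriousness = min_deleteriousness
        self.require_coding_any = require_coding_any
        self.mean_gq_post_mask = mean_gq_post_mask
        self.d_transform = d_transform
        self.d_cap = d_cap
        self.af_floor = af_floor
        self.max_variant_mode = max_variant_mode
        self.genes = genes

    # -- config plumbing ---------------------------------------------------
    def filter_config(self) -> FilterConfig:
        return FilterConfig(
            min_depth=self.min_depth,
            min_gq=self.min_gq,
            min_mean_gq=self.min_mean_gq,
            min_call_rate=self.min_call_rate,
            min_deleteriousness=self.min_deleteriousness,
            require_coding_any=self.require_coding_any,
            mean_gq_post_mask=self.mean_gq_post_mask,
        )

    def score_config(self) -> ScoreConfig:
        return ScoreConfig(
            d_transform=self.d_transform,
            d_cap=self.d_cap,
            af_floor=self.af_floor,
            max_variant_mode=self.max_variant_mode,
        )

    # -- pipeline stages ---------------------------------------------------
    def _qc(self, cohort: VariantCohort) -> tuple[list[AnnotatedVariant], list[SiteFilterRecord], dict[str, int]]:
        fcfg = self.filter_config()
        masked = [filter_genotypes(v, fcfg) for v in cohort.variants]
        survivors, site_report = filter_sites(masked, fcfg, pre_mask_variants=cohort.variants)
        selected, selection_counts = select_scoring_variants(survivors, fcfg)
        return selected, site_report, selection_counts

    def fit(self, X: VariantCohort, y=None) -> "GenePyScorer":
        self.filter_config()  # validates thresholds
        self.score_config()
        selected, site_report, selection_counts = self._qc(X)
        self.samples_ = list(X.samples)
        self.site_report_ = site_report
        self.selection_counts_ = selection_counts
        self.rank_map_ = (
            build_rank_map([v.deleteriousness_raw for v in selected])
            if self.d_transform == "rank_unit" and selected
            else None
        )
        self.fingerprint_ = config_fingerprint(self.filter_config(), self.score_config())
        return self

    def _weight(self, raw: float) -> float:
        return transform_deleteriousness(raw, self.score_config(), self.rank_map_)

    def variant_contributions(self, variant: AnnotatedVariant) -> np.ndarray:
        """Per-sample score contributions of one scoring-eligible variant."""
        scfg = self.score_config()
        d = self._weight(variant.deleteriousness_raw)
        n = variant.n_samples
        contrib = np.zeros(n)
        het = variant.zygosity == Zygosity.HET
        hom = variant.zygosity == Zygosity.HOM_ALT
        if het.any():
            f1, f2 = allele_frequencies(variant.ref_pop_af, Zygosity.HET, scfg)
            contrib[het] = score_variant(d, f1, f2)
        if hom.any():
            f1, f2 = allele_frequencies(variant.ref_pop_af, Zygosity.HOM_ALT, scfg)
            contrib[hom] = score_variant(d, f1, f2)
        return contrib

    def transform(self, X: VariantCohort) -> pd.DataFrame:
        if not hasattr(self, "samples_"):
            raise RuntimeError("GenePyScorer must be fitted before transform")
        selected, _, _ = self._qc(X)
        gene_order = list(self.genes) if self.genes is not None else None
        if gene_order is None:
            seen: dict[str, None] = {}
            for v in selected:
                for g in sorted(v.gene_ids):
                    seen.setdefault(g, None)
            gene_order = list(seen)
        if len(set(gene_order)) != len(gene_order):
            raise ValueError("duplicate gene ids")
        gene_idx = {g: i for i, g in enumerate(gene_order)}
        mat = np.zeros((len(gene_order), X.n_samples))
        for v in selected:
            contrib = self.variant_contributions(v)
            for g in v.gene_ids:
                gi = gene_idx.get(g)
                if gi is None:
                    continue
                if self.max_variant_mode:
                    np.maximum(mat[gi], contrib, out=mat[gi])
                else:
                    mat[gi] += contrib
        return pd.DataFrame(mat, index=gene_order, columns=list(X.samples))

    def score_matrix(self, X: VariantCohort) -> GenePyMatrix:
        """Fit-and-transform convenience returning the provenance-stamped matrix."""
        df = self.fit(X).transform(X)
        return GenePyMatrix(data=df, config_fingerprint=self.fingerprint_)


def build_matrix(
    cohort: VariantCohort,
    genes: list[str] | None = None,
    filter_config: FilterConfig | None = None,
    score_config: ScoreConfig | None = None,
) -> GenePyMatrix:
    """Build the GenePy matrix from a cohort with dataclass configs."""
    fcfg = filter_config or FilterConfig()
    scfg = score_config or ScoreConfig()
    scorer = GenePyScorer(
        min_depth=fcfg.min_depth,
        min_gq=fcfg.min_gq,
        min_mean_gq=fcfg.min_mean_gq,
        min_call_rate=fcfg.min_call_rate,
        min_deleteriousness=fcfg.min_deleteriousness,
        require_coding_any=fcfg.require_coding_any,
        mean_gq_post_mask=fcfg.mean_gq_post_mask,
        d_transform=scfg.d_transform,
        d_cap=scfg.d_cap,
        af_floor=scfg.af_floor,
        max_variant_mode=scfg.max_variant_mode,
        genes=genes,
    )
    return scorer.score_matrix(cohort)
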