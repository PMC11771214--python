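"""Genotype- and site-level quality filters and scoring-variant selection.

Filtering proceeds in three stages, mirroring standard cohort practice:

1. genotype masking — calls below the depth or GQ minimum become missing;
2. site filters — a variant survives only if its mean GQ over non-missing
   calls exceeds the threshold (strictly) and its call rate meets the
   cohort-wide minimum (inclusively);
3. scoring selection — only coding (±8 bp, any transcript) variants with a
   deleteriousness score at or above the floor are modelled.

Depth and GQ minima are inclusive (``>=``); the mean-GQ threshold is a
strict ``>``; the call-rate threshold is inclusive (``>=``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import AnnotatedVariant, Zygosity

__all__ = [
    "FilterConfig",
    "SiteFilterRecord",
    "filter_genotypes",
    "filter_sites",
    "select_scoring_variants",
]


@dataclass(frozen=True)
class FilterConfig:
    """Quality and variant-selection thresholds.

    Parameters
    ----------
    min_depth, min_gq
        Per-genotype minima (inclusive); failing calls are masked to missing.
    min_mean_gq
        Site-level mean GQ over non-missing calls; strict inequality.
    min_call_rate
        Minimum fraction of cohort samples with a non-missing call after
        genotype masking (inclusive). The denominator is every sample in the
        VCF, including those whose calls the depth/GQ mask removed.
    min_deleteriousness
        Floor on the raw deleteriousness score (CADD-phred scale, inclusive).
    require_coding_any
        Restrict scoring to variants coding ±8 bp on any transcript.
    mean_gq_post_mask
        Compute mean GQ after genotype masking (default) or before.
    """

    min_depth: int = 10
    min_gq: int = 20
    min_mean_gq: float = 35.0
    min_call_rate: float = 0.70
    min_deleteriousness: float = 15.0
    require_coding_any: bool = True
    mean_gq_post_mask: bool = True

    def __post_init__(self) -> None:
        if min(self.min_depth, self.min_gq, self.min_mean_gq, self.min_deleteriousness) < 0:
            raise ValueError("filter thresholds must be non-negative")
        if not (0.0 <= self.min_call_rate <= 1.0):
            raise ValueError("min_call_rate must lie in [0,1]")


@dataclass(frozen=True)
class SiteFilterRecord:
    """One row of the site-filter report."""

    key: tuple[str, int, str, str]
    status: str  # "pass" or "fail"
    reason: str  # "", "mean_gq", "call_rate", "mean_gq,call_rate", "no_calls"
    mean_gq: float
    call_rate: float


def filter_genotypes(variant: AnnotatedVariant, config: FilterConfig) -> AnnotatedVariant:
    """Mask calls below the depth/GQ minima to missing on a copy.

    Idempotent: already-missing calls stay missing and are not re-counted.
    """
    out = variant.copy()
    called = out.zygosity != Zygosity.MISSING
    fail = called & ((out.depth < config.min_depth) | (out.gq < config.min_gq))
    out.zygosity[fail] = Zygosity.MISSING
    out.n_masked_calls = variant.n_masked_calls + int(fail.sum())
    return out


def _site_stats(
    variant: AnnotatedVariant, pre_mask: AnnotatedVariant | None, config: FilterConfig
) -> tuple[float, float]:
    source = variant if config.mean_gq_post_mask or pre_mask is None else pre_mask
    ok = source.nonmissing_mask()
    mean_gq = float(source.gq[ok].mean()) if ok.any() else float("nan")
    call_rate = float(variant.nonmissing_mask().sum()) / variant.n_samples
    return mean_gq, call_rate


def filter_sites(
    variants: list[AnnotatedVariant],
    config: FilterConfig,
    pre_mask_variants: list[AnnotatedVariant] | None = None,
) -> tuple[list[AnnotatedVariant], list[SiteFilterRecord]]:
    """Apply the mean-GQ and call-rate site filters.

    Expects genotype masking to have been applied already.  Returns the
    surviving variants plus a per-site report recording each removal reason.
    """
    if variants and variants[0].n_samples == 0:
        raise ValueError("cohort has zero samples; site filters undefined")
    survivors: list[AnnotatedVariant] = []
    report: list[SiteFilterRecord] = []
    for i, v in enumerate(variants):
        pre = pre_mask_variants[i] if pre_mask_variants is not None else None
        mean_gq, call_rate = _site_stats(v, pre, config)
        reasons = []
        if np.isnan(mean_gq):
            reasons.append("no_calls")
        elif not (mean_gq > config.min_mean_gq):
            reasons.append("mean_gq")
        if call_rate < config.min_call_rate:
            reasons.append("call_rate")
        if reasons:
            report.append(SiteFilterRecord(v.key, "fail", ",".join(reasons), mean_gq, call_rate))
        else:
            survivors.append(v)
            report.append(SiteFilterRecord(v.key, "pass", "", mean_gq, call_rate))
    return survivors, report


def select_scoring_variants(
    variants: list[AnnotatedVariant], config: FilterConfig
) -> tuple[list[AnnotatedVariant], dict[str, int]]:
    """Retain variants eligible for burden scoring.

    A variant qualifies when it is coding ±8 bp on any transcript (if
    required) and its raw deleteriousness is at or above the floor; variants
    with absent deleteriousness are excluded and counted separately.
    """
    selected: list[AnnotatedVariant] = []
    counts = {"selected": 0, "noncoding": 0, "low_deleteriousness": 0, "absent_deleteriousness": 0}
    for v in variants:
        if config.require_coding_any and not v.is_coding_any_transcript:
            counts["noncoding"] += 1
        elif v.deleteriousness_raw is None:
            counts["absent_deleteriousness"] += 1
        elif v.deleteriousness_raw < config.min_deleteriousness:
            counts["low_deleteriousness"] += 1
        else:
            selected.append(v)
            counts["selected"] += 1
    return selected, counts
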