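"""Shared fixtures: hand-constructed variants and a labelled QC cohort."""

from __future__ import annotations

import numpy as np
import pytest

from genepykit.model import AnnotatedVariant, ClinvarClass, VariantCohort


def make_variant(
    zygosity,
    depth=30,
    gq=80,
    chrom="chr1",
    pos=100,
    ref="A",
    alt="T",
    gene="GENE1",
    af=1e-4,
    cadd=20.0,
    coding_any=True,
    coding_mane=True,
    clinvar=ClinvarClass.NONE,
) -> AnnotatedVariant:
    """Build a variant from per-sample zygosity codes; scalars broadcast."""
    zyg = np.asarray(zygosity, dtype=np.int8)
    n = len(zyg)
    return AnnotatedVariant(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        zygosity=zyg,
        depth=np.broadcast_to(np.asarray(depth, dtype=np.int32), (n,)).copy(),
        gq=np.broadcast_to(np.asarray(gq, dtype=np.int32), (n,)).copy(),
        gene_ids=frozenset({gene}) if isinstance(gene, str) else frozenset(gene),
        deleteriousness_raw=cadd,
        ref_pop_af=af,
        is_coding_any_transcript=coding_any,
        is_coding_mane=coding_mane,
        clinvar_class=clinvar,
    )


# Hand-labelled QC cohort: 10 samples, 50 sites cycling through 10 designed
# categories; truth (pass/fail + reason) is fixed by construction, never by
# running the filters.
QC_N_SAMPLES = 10
QC_CATEGORIES = [
    # (label, expected_pass, builder kwargs)
    ("clean_pass", True, {}),
    ("fail_mean_gq", False, {"gq": 30}),
    ("fail_call_rate_depth", False, {"depth": [5] * 7 + [30] * 3}),
    ("fail_low_cadd", False, {"cadd": 14.99}),
    ("fail_noncoding", False, {"cadd": 30.0, "coding_any": False, "coding_mane": False}),
    # All calls sit exactly on the DP/GQ minima; inclusive thresholds keep
    # them (mean GQ 43.7, call rate 1.0) while exclusive ones would mask 7/10
    # calls and fail the site on call rate.
    ("pass_boundary_dp_gq", True, {"depth": [10] * 10, "gq": [20] * 7 + [99] * 3}),
    ("fail_mean_gq_exact_35", False, {"gq": 35}),
    ("fail_call_rate_boundary", False, {"depth": [5] * 4 + [30] * 6}),  # 6/10 = 0.6
    ("pass_call_rate_boundary", True, {"depth": [5] * 3 + [30] * 7}),  # 7/10 = 0.7
    ("fail_absent_cadd", False, {"cadd": None}),
]


def qc_labelled_cohort() -> tuple[VariantCohort, set, dict]:
    """(cohort, truth survivor keys, key -> category label)."""
    samples = [f"Q{i}" for i in range(QC_N_SAMPLES)]
    variants, truth, labels = [], set(), {}
    pos = 0
    for cycle in range(5):
        for label, expected_pass, kwargs in QC_CATEGORIES:
            pos += 10
            v = make_variant(
                zygosity=[1] + [0] * (QC_N_SAMPLES - 1),  # one het carrier
                pos=pos,
                gene="QCGENE",
                **kwargs,
            )
            variants.append(v)
            labels[v.key] = label
            if expected_pass:
                truth.add(v.key)
    return VariantCohort(samples=samples, variants=variants), truth, labels


@pytest.fixture(scope="session")
def qc_cohort():
    return qc_labelled_cohort()
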