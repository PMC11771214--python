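"""The burden statistic: D transform, frequency pairs, per-variant and
per-gene scores, and the matrix builder."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genepykit.model import VariantCohort, Zygosity
from genepykit.score import (
    GenePyMatrix,
    GenePyScorer,
    ScoreConfig,
    VariantScore,
    allele_frequencies,
    build_matrix,
    score_gene,
    score_variant,
    transform_deleteriousness,
)

from conftest import make_variant


def vs(score):
    return VariantScore("s", ("chr1", 1, "A", "T"), 1.0, 0.1, 0.1, score)


class TestDeleteriousnessTransform:
    @pytest.mark.parametrize("raw,expected", [(40.0, 1.0), (20.0, 0.5), (55.0, 1.0), (0.0, 0.0)])
    def test_clip_scale(self, raw, expected):
        assert transform_deleteriousness(raw, ScoreConfig()) == pytest.approx(expected)

    def test_raw_mode_passthrough(self):
        assert transform_deleteriousness(23.5, ScoreConfig(d_transform="raw")) == 23.5

    def test_negative_raw_rejected(self):
        with pytest.raises(ValueError):
            transform_deleteriousness(-1.0, ScoreConfig())

    def test_rank_unit_maps_onto_unit_interval(self):
        from genepykit.score import build_rank_map

        rank_map = build_rank_map([15.0, 20.0, 30.0, 40.0])
        cfg = ScoreConfig(d_transform="rank_unit")
        vals = [transform_deleteriousness(r, cfg, rank_map) for r in (15.0, 20.0, 30.0, 40.0)]
        assert vals == [0.25, 0.5, 0.75, 1.0]


class TestAlleleFrequencies:
    def test_hom_pair_and_score(self):
        f1, f2 = allele_frequencies(0.01, Zygosity.HOM_ALT)
        assert (f1, f2) == (0.01, 0.01)
        assert score_variant(0.5, f1, f2) == pytest.approx(2.0)

    def test_het_pair_and_score(self):
        f1, f2 = allele_frequencies(0.01, Zygosity.HET)
        assert (f1, f2) == (0.01, 0.99)
        assert score_variant(0.5, f1, f2) == pytest.approx(-0.5 * math.log10(0.0099))
        assert score_variant(0.5, f1, f2) == pytest.approx(1.0022, abs=1e-4)

    def test_absent_frequency_uses_floor(self):
        assert allele_frequencies(None, Zygosity.HOM_ALT) == (1e-5, 1e-5)

    @pytest.mark.parametrize("zyg", [Zygosity.HOM_REF, Zygosity.MISSING])
    def test_uncarried_genotypes_rejected(self, zyg):
        with pytest.raises(ValueError):
            allele_frequencies(0.1, zyg)


class TestScoreVariant:
    def test_zero_deleteriousness_scores_zero(self):
        assert score_variant(0.0, 0.3, 0.7) == 0.0

    def test_fixed_common_allele_scores_zero(self):
        assert score_variant(1.0, 1.0, 1.0) == 0.0

    def test_hand_computed_value(self):
        assert score_variant(1.0, 0.1, 0.9) == pytest.approx(-math.log10(0.09))

    def test_nonpositive_frequency_rejected(self):
        with pytest.raises(ValueError):
            score_variant(1.0, 0.0, 0.5)


class TestScoreGene:
    def test_sum_mode(self):
        assert score_gene([vs(2.0), vs(1.0)]) == 3.0

    def test_max_mode(self):
        assert score_gene([vs(2.0), vs(1.0)], ScoreConfig(max_variant_mode=True)) == 2.0

    def test_empty_set_scores_zero(self):
        assert score_gene([]) == 0.0


class TestMatrix:
    def test_single_hom_cell_closed_form(self):
        # d = 1 (raw 40 / cap 40), hom at fa = 1e-4: -log10(1e-8) = 8
        cohort = VariantCohort(samples=["A"], variants=[make_variant([2], af=1e-4, cadd=40.0)])
        m = build_matrix(cohort)
        assert m.data.at["GENE1", "A"] == pytest.approx(8.0)

    def test_no_variants_gives_all_zero_matrix(self):
        cohort = VariantCohort(samples=["A", "B"], variants=[])
        m = build_matrix(cohort, genes=["G1", "G2"])
        assert (m.data.to_numpy() == 0).all()
        assert m.data.shape == (2, 2)

    def test_hom_ref_and_missing_contribute_nothing(self):
        cohort = VariantCohort(
            samples=["A", "B", "C", "D", "E"], variants=[make_variant([0, -1, 1, 0, 0])]
        )
        m = build_matrix(cohort)
        assert m.data.at["GENE1", "A"] == 0.0
        assert m.data.at["GENE1", "B"] == 0.0
        assert m.data.at["GENE1", "C"] > 0.0

    def test_variant_in_two_genes_scores_both(self):
        v = make_variant([1], gene={"G1", "G2"})
        m = build_matrix(VariantCohort(samples=["A"], variants=[v]))
        assert m.data.at["G1", "A"] == m.data.at["G2", "A"] > 0

    def test_permuting_sample_order_permutes_columns_only(self):
        v1 = make_variant([1, 2, 0], pos=10)
        v2 = make_variant([0, 1, 1], pos=20, cadd=25.0, af=1e-3)
        m1 = build_matrix(VariantCohort(samples=["A", "B", "C"], variants=[v1, v2]))
        v1p = make_variant([0, 2, 1], pos=10)
        v2p = make_variant([1, 1, 0], pos=20, cadd=25.0, af=1e-3)
        m2 = build_matrix(VariantCohort(samples=["C", "B", "A"], variants=[v1p, v2p]))
        pd.testing.assert_frame_equal(m1.data, m2.data[["A", "B", "C"]])

    def test_duplicate_gene_ids_rejected(self):
        cohort = VariantCohort(samples=["A"], variants=[make_variant([1])])
        with pytest.raises(ValueError, match="duplicate"):
            build_matrix(cohort, genes=["G", "G"])

    def test_tsv_round_trip_lossless(self, tmp_path):
        cohort = VariantCohort(
            samples=["A", "B"], variants=[make_variant([1, 2], af=3.7e-4, cadd=23.456)]
        )
        m = build_matrix(cohort)
        path = tmp_path / "m.tsv"
        m.to_tsv(path)
        back = GenePyMatrix.from_tsv(path)
        assert back.config_fingerprint == m.config_fingerprint
        pd.testing.assert_frame_equal(back.data, m.data)

    def test_fingerprint_tracks_config(self):
        cohort = VariantCohort(samples=["A"], variants=[make_variant([1])])
        m1 = build_matrix(cohort)
        m2 = build_matrix(cohort, score_config=ScoreConfig(af_floor=1e-4))
        assert m1.config_fingerprint != m2.config_fingerprint


class TestScoreProperties:
    @given(
        af=st.floats(2.5e-5, 0.4),  # halving stays above the frequency floor
        d_raw=st.floats(15.0, 45.0),
        zyg=st.sampled_from([Zygosity.HET, Zygosity.HOM_ALT]),
    )
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_monotonicity_in_frequency_and_deleteriousness(self, af, d_raw, zyg):
        cfg = ScoreConfig()
        d = transform_deleteriousness(d_raw, cfg)
        s = score_variant(d, *allele_frequencies(af, zyg, cfg))
        rarer = score_variant(d, *allele_frequencies(af / 2, zyg, cfg))
        assert rarer > s
        if d_raw < cfg.d_cap:  # above the cap D saturates
            d_up = transform_deleteriousness(min(d_raw * 1.5, cfg.d_cap), cfg)
            assert score_variant(d_up, *allele_frequencies(af, zyg, cfg)) > s

    def test_hom_het_ratio_approaches_two_for_rare_alleles(self):
        cfg = ScoreConfig()
        d = 0.8
        hom = score_variant(d, *allele_frequencies(1e-5, Zygosity.HOM_ALT, cfg))
        het = score_variant(d, *allele_frequencies(1e-5, Zygosity.HET, cfg))
        assert 1.9 <= hom / het <= 2.0

    def test_sample_scores_independent_of_other_samples_genotypes(self):
        base = VariantCohort(samples=["A", "B"], variants=[make_variant([1, 0])])
        changed = VariantCohort(samples=["A", "B"], variants=[make_variant([1, 2])])
        mA1 = build_matrix(base).data["A"]
        mA2 = build_matrix(changed).data["A"]
        pd.testing.assert_series_equal(mA1, mA2)


class TestScorerEstimator:
    def test_sklearn_param_round_trip(self):
        scorer = GenePyScorer(af_floor=1e-4, max_variant_mode=True)
        params = scorer.get_params()
        clone = GenePyScorer(**params)
        assert clone.get_params() == params

    def test_transform_before_fit_raises(self):
        with pytest.raises(RuntimeError):
            GenePyScorer().transform(VariantCohort(samples=["A"], variants=[]))

    def test_max_variant_mode_takes_single_best(self):
        v1 = make_variant([1], pos=10, af=1e-4, cadd=40.0)  # het: -log10(1e-4 * 0.9999)
        v2 = make_variant([2], pos=20, af=1e-2, cadd=40.0)  # hom: -log10(1e-4) = 4
        cohort = VariantCohort(samples=["A"], variants=[v1, v2])
        msum = build_matrix(cohort).data.at["GENE1", "A"]
        mmax = build_matrix(cohort, score_config=ScoreConfig(max_variant_mode=True)).data.at[
            "GENE1", "A"
        ]
        best = -math.log10(1e-4 * (1 - 1e-4))
        assert mmax == pytest.approx(best)
        assert msum == pytest.approx(best + 4.0)
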