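"""Candidate extraction, trio phasing, deprioritization flags and tiers."""

import itertools

import pytest

from genepykit.model import ClinvarClass, Individual, Pedigree, VariantCohort, Zygosity
from genepykit.prioritize import (
    CandidateVariantPair,
    CasePrioritizer,
    FlagSet,
    Phase,
    Tier,
    TierRules,
    assign_flags,
    assign_tier,
    extract_candidates,
    infer_phase,
)

from conftest import make_variant

SAMPLES = ["CHILD", "DAD", "MUM", "SIB", "X1", "X2", "X3", "X4", "X5", "X6"]


def trio_pedigree(sib_affected=False) -> Pedigree:
    inds = {
        "CHILD": Individual("CHILD", "F1", father_id="DAD", mother_id="MUM", affected=True),
        "DAD": Individual("DAD", "F1", sex=1),
        "MUM": Individual("MUM", "F1", sex=2),
        "SIB": Individual(
            "SIB", "F1", father_id="DAD", mother_id="MUM", affected=sib_affected
        ),
    }
    for s in SAMPLES[4:]:
        inds[s] = Individual(s, family_id=s)
    return Pedigree(individuals=inds)


def cohort_with(*variants) -> VariantCohort:
    return VariantCohort(samples=list(SAMPLES), variants=list(variants))


def zyg(child, dad=0, mum=0, sib=0, rest=0):
    return [child, dad, mum, sib] + [rest] * 6


class TestExtractCandidates:
    def test_single_hom_variant_is_complete_genotype(self):
        v = make_variant(zyg(2), pos=10)
        pair = extract_candidates(cohort_with(v), "CHILD", "GENE1")
        assert pair.phase == Phase.NA_HOMOZYGOUS
        assert [z for _, z in pair.variants] == [Zygosity.HOM_ALT]

    def test_three_hets_pairs_top_two_by_score_with_context(self):
        v1 = make_variant(zyg(1), pos=10, af=1e-5, cadd=40.0)  # score 10ish, top
        v2 = make_variant(zyg(1), pos=20, af=1e-3, cadd=30.0)  # second
        v3 = make_variant(zyg(1), pos=30, af=1e-2, cadd=16.0)  # context
        pair = extract_candidates(cohort_with(v3, v1, v2), "CHILD", "GENE1")
        assert [v.pos for v, _ in pair.variants] == [10, 20]
        assert [v.pos for v in pair.context_variants] == [30]
        assert pair.phase == Phase.UNKNOWN  # not yet phased

    def test_single_het_is_na_single(self):
        pair = extract_candidates(cohort_with(make_variant(zyg(1))), "CHILD", "GENE1")
        assert pair.phase == Phase.NA_SINGLE

    def test_low_deleteriousness_variants_do_not_qualify(self):
        v = make_variant(zyg(1), cadd=14.0)
        assert extract_candidates(cohort_with(v), "CHILD", "GENE1") is None

    def test_no_nonref_genotype_returns_none(self):
        v = make_variant(zyg(0, rest=1))
        assert extract_candidates(cohort_with(v), "CHILD", "GENE1") is None


def phased_pair(dad1, mum1, dad2, mum2, pedigree=None):
    v1 = make_variant(zyg(1, dad=dad1, mum=mum1), pos=10)
    v2 = make_variant(zyg(1, dad=dad2, mum=mum2), pos=20)
    cohort = cohort_with(v1, v2)
    pair = extract_candidates(cohort, "CHILD", "GENE1")
    return infer_phase(pair, pedigree or trio_pedigree(), cohort), cohort


class TestInferPhase:
    def test_one_variant_per_parent_is_trans(self):
        pair, _ = phased_pair(dad1=1, mum1=0, dad2=0, mum2=1)
        assert pair.phase == Phase.TRANS

    def test_both_variants_single_parent_is_cis(self):
        pair, _ = phased_pair(dad1=0, mum1=1, dad2=0, mum2=1)
        assert pair.phase == Phase.CIS

    def test_singleton_without_parents_is_unknown(self):
        v1 = make_variant(zyg(0, rest=1), pos=10)
        v2 = make_variant(zyg(0, rest=1), pos=20)
        cohort = cohort_with(v1, v2)
        pair = extract_candidates(cohort, "X1", "GENE1")
        assert infer_phase(pair, trio_pedigree(), cohort).phase == Phase.UNKNOWN

    def test_variant_absent_from_both_parents_notes_de_novo(self):
        pair, _ = phased_pair(dad1=0, mum1=0, dad2=0, mum2=1)
        assert pair.phase == Phase.UNKNOWN
        assert pair.de_novo_note and pair.mendelian_inconsistent

    def test_both_variants_in_both_parents_uninformative(self):
        pair, _ = phased_pair(dad1=1, mum1=1, dad2=1, mum2=1)
        assert pair.phase == Phase.UNKNOWN
        assert not pair.de_novo_note

    def test_missing_parent_genotype_uninformative(self):
        pair, _ = phased_pair(dad1=-1, mum1=1, dad2=0, mum2=1)
        assert pair.phase == Phase.UNKNOWN

    def test_homozygous_candidate_needs_no_phase(self):
        v = make_variant(zyg(2, dad=1, mum=1))
        cohort = cohort_with(v)
        pair = extract_candidates(cohort, "CHILD", "GENE1")
        assert infer_phase(pair, trio_pedigree(), cohort).phase == Phase.NA_HOMOZYGOUS


class TestAssignFlags:
    def test_mane_noncoding_variant_flagged(self):
        v1 = make_variant(zyg(1), pos=10, coding_mane=False)
        v2 = make_variant(zyg(1), pos=20)
        cohort = cohort_with(v1, v2)
        pair = extract_candidates(cohort, "CHILD", "GENE1")
        assert assign_flags(pair, cohort).noncoding_mane

    def test_common_in_callset_uses_cohort_genotypes(self):
        # 8% alt alleles in the call-set despite a rare reference-population AF
        v1 = make_variant(zyg(1, rest=0), pos=10)
        v2 = make_variant([1, 0, 0, 1] + [1, 1, 1, 1, 0, 0], pos=20, af=1e-4)
        assert v2.cohort_alt_af() == pytest.approx(0.30)
        cohort = cohort_with(v1, v2)
        pair = extract_candidates(cohort, "CHILD", "GENE1")
        flags = assign_flags(pair, cohort)
        assert flags.common_in_callset

    def test_solitary_het_flags_no_second_hit(self):
        cohort = cohort_with(make_variant(zyg(1)))
        pair = extract_candidates(cohort, "CHILD", "GENE1")
        flags = assign_flags(pair, cohort)
        assert flags.no_second_hit and flags.hard_exclude

    def test_cis_pair_flagged(self):
        pair, cohort = phased_pair(dad1=0, mum1=1, dad2=0, mum2=1)
        assert assign_flags(pair, cohort, trio_pedigree()).in_cis

    def test_affected_sib_without_genotype_fails_segregation(self):
        v = make_variant(zyg(2, dad=1, mum=1, sib=1))  # sib affected but only het
        cohort = cohort_with(v)
        pair = extract_candidates(cohort, "CHILD", "GENE1")
        flags = assign_flags(pair, cohort, trio_pedigree(sib_affected=True))
        assert flags.non_segregating

    def test_affected_sib_sharing_genotype_segregates(self):
        v = make_variant(zyg(2, dad=1, mum=1, sib=2))
        cohort = cohort_with(v)
        pair = extract_candidates(cohort, "CHILD", "GENE1")
        assert not assign_flags(pair, cohort, trio_pedigree(sib_affected=True)).non_segregating

    def test_unaffected_relatives_place_no_constraint(self):
        v = make_variant(zyg(2, dad=1, mum=1, sib=0))
        cohort = cohort_with(v)
        pair = extract_candidates(cohort, "CHILD", "GENE1")
        assert not assign_flags(pair, cohort, trio_pedigree(sib_affected=False)).non_segregating


P, LP, VUS = ClinvarClass.P, ClinvarClass.LP, ClinvarClass.VUS
NOFLAGS = FlagSet()


class TestAssignTier:
    def test_hom_lp_no_flags_is_top(self):
        assert assign_tier(NOFLAGS, Phase.NA_HOMOZYGOUS, [LP]) == Tier.TOP

    def test_trans_p_lp_pair_is_top(self):
        assert assign_tier(NOFLAGS, Phase.TRANS, [P, LP]) == Tier.TOP

    def test_two_lp_unknown_phase_is_middle(self):
        assert assign_tier(NOFLAGS, Phase.UNKNOWN, [LP, LP]) == Tier.MIDDLE

    def test_vus_pair_in_trans_is_middle(self):
        assert assign_tier(NOFLAGS, Phase.TRANS, [VUS, LP]) == Tier.MIDDLE

    def test_noncoding_mane_demotes_to_low_even_when_pathogenic(self):
        flags = FlagSet(noncoding_mane=True)
        assert assign_tier(flags, Phase.TRANS, [P, P]) == Tier.LOW

    @pytest.mark.parametrize(
        "flags",
        [
            FlagSet(common_in_callset=True),
            FlagSet(non_segregating=True),
            FlagSet(in_cis=True),
            FlagSet(no_second_hit=True),
        ],
    )
    def test_hard_flags_force_exclude(self, flags):
        assert assign_tier(flags, Phase.NA_HOMOZYGOUS, [P]) == Tier.EXCLUDE

    def test_withdrawn_is_closed_regardless(self):
        assert assign_tier(FlagSet(in_cis=True), Phase.CIS, [P, P], withdrawn=True) == Tier.CLOSED

    def test_tier_function_total_and_deterministic(self):
        """Every (flags x phase x class pair) combination maps to exactly one
        tier, and no TOP case carries a hard-exclude flag."""
        classes = list(ClinvarClass)
        bools = (False, True)
        for nc, cm, ns, ic, nsh, phase, c1, c2, wd in itertools.product(
            bools, bools, bools, bools, bools, Phase, classes, classes, bools
        ):
            flags = FlagSet(nc, cm, ns, ic, nsh)
            tier = assign_tier(flags, phase, [c1, c2], withdrawn=wd)
            assert tier in Tier
            if tier == Tier.TOP:
                assert not flags.hard_exclude and not wd

    def test_configurable_pathogenic_classes(self):
        rules = TierRules(pathogenic_classes=("P",))
        assert assign_tier(NOFLAGS, Phase.NA_HOMOZYGOUS, [LP], rules=rules) == Tier.MIDDLE


class TestTierRules:
    def test_yaml_round_trip(self, tmp_path):
        rules = TierRules(common_af_threshold=0.01, pathogenic_classes=("P",))
        path = tmp_path / "rules.yaml"
        rules.to_yaml(path)
        assert TierRules.from_yaml(path) == rules


def wide_cohort(*variants) -> VariantCohort:
    """Pad with reference-genotype samples so a single planted family's
    alleles stay below the 5% call-set frequency threshold."""
    padded = []
    extra = [f"P{i}" for i in range(90)]
    for v in variants:
        w = make_variant(
            list(v.zygosity) + [0] * 90,
            pos=v.pos,
            clinvar=v.clinvar_class,
            coding_mane=v.is_coding_mane,
        )
        padded.append(w)
    return VariantCohort(samples=list(SAMPLES) + extra, variants=padded)


class TestCasePrioritizer:
    def test_end_to_end_hom_pathogenic_top(self):
        v = make_variant(zyg(2, dad=1, mum=1), clinvar=P)
        cohort = wide_cohort(v)
        case = CasePrioritizer().fit().prioritize_case(
            cohort, "CHILD", "GENE1", pedigree=trio_pedigree(), rank=1, score=10.0
        )
        assert case.tier == Tier.TOP
        assert case.pair.phase == Phase.NA_HOMOZYGOUS
        assert case.to_dict()["tier"] == "TOP"

    def test_acmg_class_upgrades_conflicting_clinvar(self):
        v = make_variant(zyg(2, dad=1, mum=1), clinvar=VUS)
        cohort = wide_cohort(v)
        case = CasePrioritizer().fit().prioritize_case(
            cohort,
            "CHILD",
            "GENE1",
            pedigree=trio_pedigree(),
            acmg={v.key: ClinvarClass.LP},
        )
        assert case.tier == Tier.TOP  # more pathogenic of (VUS, LP) wins
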