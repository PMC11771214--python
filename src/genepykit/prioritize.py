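"""Biallelic candidate extraction, trio phasing, deprioritization and tiering.

For each assessable participant in an implicated gene, the candidate is the
participant's qualifying genotype: a homozygous damaging variant, or the two
highest-scoring heterozygous damaging variants (a putative compound
heterozygote).  Trio genotypes phase heterozygous pairs where possible: two
variants traced to different parents are in trans (biallelic), to the same
single parent in cis (monoallelic, not diagnostic for recessive disease).

Deprioritization flags follow the field's review practice: a variant
non-coding on the MANE transcript, a variant common (>5%) in the call-set
itself, failure to segregate among affected relatives, variants in cis, or a
solitary heterozygous variant.  The hard flags (common, non-segregating,
cis, single het) force EXCLUDE; a MANE-noncoding variant demotes to LOW.
TOP — a putative missed diagnosis — requires a homozygous
pathogenic/likely-pathogenic variant or a phased-in-trans P/LP pair;
everything else (VUS pairs, unknown phase) is MIDDLE.  Withdrawn
participants are CLOSED.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import yaml
from sklearn.base import BaseEstimator

from .model import (
    AnnotatedVariant,
    ClinvarClass,
    ParticipantMeta,
    Pedigree,
    VariantCohort,
    Zygosity,
)
from .score import GenePyScorer, ScoreConfig

__all__ = [
    "Phase",
    "Tier",
    "TierRules",
    "CandidateVariantPair",
    "FlagSet",
    "PrioritizedCase",
    "CasePrioritizer",
    "extract_candidates",
    "infer_phase",
    "assign_flags",
    "assign_tier",
]


class Phase(str, Enum):
    TRANS = "TRANS"
    CIS = "CIS"
    UNKNOWN = "UNKNOWN"
    NA_HOMOZYGOUS = "NA_HOMOZYGOUS"
    NA_SINGLE = "NA_SINGLE"


class Tier(str, Enum):
    TOP = "TOP"
    MIDDLE = "MIDDLE"
    LOW = "LOW"
    EXCLUDE = "EXCLUDE"
    CLOSED = "CLOSED"


@dataclass(frozen=True)
class TierRules:
    """Configurable tier policy (laboratories may adjust and reload)."""

    common_af_threshold: float = 0.05
    pathogenic_classes: tuple[str, ...] = ("P", "LP")

    def is_pathogenic(self, cls: ClinvarClass) -> bool:
        return cls.value in self.pathogenic_classes

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as out:
            yaml.safe_dump(
                {
                    "common_af_threshold": self.common_af_threshold,
                    "pathogenic_classes": list(self.pathogenic_classes),
                },
                out,
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TierRules":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(
            common_af_threshold=float(raw.get("common_af_threshold", 0.05)),
            pathogenic_classes=tuple(raw.get("pathogenic_classes", ("P", "LP"))),
        )


@dataclass
class CandidateVariantPair:
    """One participant's candidate biallelic genotype in one gene."""

    sample_id: str
    gene_id: str
    variants: list[tuple[AnnotatedVariant, Zygosity]]  # 1 or 2 entries
    phase: Phase
    context_variants: list[AnnotatedVariant] = field(default_factory=list)
    de_novo_note: bool = False
    mendelian_inconsistent: bool = False

    def __post_init__(self) -> None:
        if not 1 <= len(self.variants) <= 2:
            raise ValueError("candidate must hold 1 or 2 variants")
        if self.phase == Phase.NA_HOMOZYGOUS and not (
            len(self.variants) == 1 and self.variants[0][1] == Zygosity.HOM_ALT
        ):
            raise ValueError("NA_HOMOZYGOUS requires exactly one homozygous variant")
        if self.phase == Phase.NA_SINGLE and not (
            len(self.variants) == 1 and self.variants[0][1] == Zygosity.HET
        ):
            raise ValueError("NA_SINGLE requires exactly one heterozygous variant")


@dataclass(frozen=True)
class FlagSet:
    noncoding_mane: bool = False
    common_in_callset: bool = False
    non_segregating: bool = False
    in_cis: bool = False
    no_second_hit: bool = False

    @property
    def hard_exclude(self) -> bool:
        return self.common_in_callset or self.non_segregating or self.in_cis or self.no_second_hit

    def any(self) -> bool:
        return self.hard_exclude or self.noncoding_mane


@dataclass
class PrioritizedCase:
    pair: CandidateVariantPair
    flags: FlagSet
    clinvar_classes: list[ClinvarClass]
    acmg_classes: list[ClinvarClass]
    tier: Tier
    rank: int | None = None
    score: float | None = None

    def to_dict(self) -> dict:
        return {
            "sample_id": self.pair.sample_id,
            "gene": self.pair.gene_id,
            "variants": [
                {"key": "{}:{}:{}:{}".format(*v.key), "zygosity": Zygosity(int(z)).name}
                for v, z in self.pair.variants
            ],
            "context_variants": ["{}:{}:{}:{}".format(*v.key) for v in self.pair.context_variants],
            "phase": self.pair.phase.value,
            "de_novo_note": self.pair.de_novo_note,
            "flags": vars(self.flags),
            "clinvar_classes": [c.value for c in self.clinvar_classes],
            "acmg_classes": [c.value for c in self.acmg_classes],
            "tier": self.tier.value,
            "rank": self.rank,
            "score": self.score,
        }


def extract_candidates(
    cohort: VariantCohort,
    sample_id: str,
    gene_id: str,
    min_deleteriousness: float = 15.0,
    score_config: ScoreConfig | None = None,
) -> CandidateVariantPair | None:
    """Extract the participant's qualifying variants in the gene.

    Qualifying = non-reference genotype and deleteriousness at or above the
    floor.  A homozygous qualifying variant is a complete biallelic genotype
    and becomes the candidate on its own; otherwise the two highest-scoring
    heterozygous variants form the pair (extras kept as context).  Returns
    None when nothing qualifies.
    """
    scorer = GenePyScorer(**(vars(score_config) if score_config else {}))
    scorer.rank_map_ = None
    si = cohort.sample_index(sample_id)
    qualifying: list[tuple[float, AnnotatedVariant, Zygosity]] = []
    for v in cohort.variants:
        if gene_id not in v.gene_ids:
            continue
        z = Zygosity(int(v.zygosity[si]))
        if z not in (Zygosity.HET, Zygosity.HOM_ALT):
            continue
        if v.deleteriousness_raw is None or v.deleteriousness_raw < min_deleteriousness:
            continue
        contrib = float(scorer.variant_contributions(v)[si])
        qualifying.append((contrib, v, z))
    if not qualifying:
        return None
    qualifying.sort(key=lambda t: (-t[0], t[1].key))
    # A homozygous variant is a complete biallelic genotype, but it only
    # becomes the candidate when the score ordering puts it in the top two —
    # a weak common homozygote must not displace a rare damaging het pair.
    top_homs = [q for q in qualifying[:2] if q[2] == Zygosity.HOM_ALT]
    if top_homs:
        top = top_homs[0]
        rest = [v for _, v, _ in qualifying if v is not top[1]]
        return CandidateVariantPair(
            sample_id=sample_id,
            gene_id=gene_id,
            variants=[(top[1], top[2])],
            phase=Phase.NA_HOMOZYGOUS,
            context_variants=rest,
        )
    if len(qualifying) == 1:
        _, v, z = qualifying[0]
        return CandidateVariantPair(
            sample_id=sample_id,
            gene_id=gene_id,
            variants=[(v, z)],
            phase=Phase.NA_SINGLE,
        )
    pair = qualifying[:2]
    rest = [v for _, v, _ in qualifying[2:]]
    return CandidateVariantPair(
        sample_id=sample_id,
        gene_id=gene_id,
        variants=[(v, z) for _, v, z in pair],
        phase=Phase.UNKNOWN,
        context_variants=rest,
    )


def _parent_carries(variant: AnnotatedVariant, cohort: VariantCohort, parent_id: str | None) -> bool | None:
    """Whether the parent carries the alternate allele; None when unknowable."""
    if parent_id is None:
        return None
    try:
        pi = cohort.sample_index(parent_id)
    except KeyError:
        return None
    z = Zygosity(int(variant.zygosity[pi]))
    if z == Zygosity.MISSING:
        return None
    return z in (Zygosity.HET, Zygosity.HOM_ALT)


def infer_phase(
    pair: CandidateVariantPair, pedigree: Pedigree, cohort: VariantCohort
) -> CandidateVariantPair:
    """Phase a heterozygous pair from parental genotypes, in place.

    Both variants carried by one parent and absent from the other -> CIS;
    each traced to a different parent -> TRANS; uninformative configurations
    (missing parents or genotypes, both variants in both parents) -> UNKNOWN.
    A variant absent from both parents is a possible de novo event (or a
    genotyping inconsistency) and leaves the phase UNKNOWN with a note.
    """
    if pair.phase in (Phase.NA_HOMOZYGOUS, Phase.NA_SINGLE):
        return pair
    father, mother = pedigree.parents_of(pair.sample_id)
    carriage = []
    for v, _ in pair.variants:
        in_father = _parent_carries(v, cohort, father)
        in_mother = _parent_carries(v, cohort, mother)
        carriage.append((in_father, in_mother))
    if any(c == (None, None) for c in carriage) or father is None or mother is None:
        pair.phase = Phase.UNKNOWN
        return pair
    (f1, m1), (f2, m2) = carriage
    if (f1 is False and m1 is False) or (f2 is False and m2 is False):
        # Child allele absent from both parents at a Mendelian-consistent site.
        pair.phase = Phase.UNKNOWN
        pair.de_novo_note = True
        pair.mendelian_inconsistent = True
        return pair
    if None in (f1, m1, f2, m2):
        pair.phase = Phase.UNKNOWN
        return pair
    v1_only_father = f1 and not m1
    v1_only_mother = m1 and not f1
    v2_only_father = f2 and not m2
    v2_only_mother = m2 and not f2
    if (v1_only_father and v2_only_mother) or (v1_only_mother and v2_only_father):
        pair.phase = Phase.TRANS
    elif (v1_only_father and v2_only_father) or (v1_only_mother and v2_only_mother):
        pair.phase = Phase.CIS
    else:
        pair.phase = Phase.UNKNOWN
    return pair


def _segregates(
    pair: CandidateVariantPair, cohort: VariantCohort, pedigree: Pedigree
) -> bool | None:
    """Do affected relatives in the family share the candidate genotype?

    Returns None when there are no informative affected relatives.
    """
    relatives = [
        ind
        for ind in pedigree.family_members(pair.sample_id)
        if ind.affected and ind.sample_id != pair.sample_id
    ]
    informative = False
    for rel in relatives:
        try:
            ri = cohort.sample_index(rel.sample_id)
        except KeyError:
            continue
        states = [Zygosity(int(v.zygosity[ri])) for v, _ in pair.variants]
        if any(z == Zygosity.MISSING for z in states):
            continue
        informative = True
        if pair.phase == Phase.NA_HOMOZYGOUS:
            if states[0] != Zygosity.HOM_ALT:
                return False
        else:
            if any(z == Zygosity.HOM_REF for z in states):
                return False
    return True if informative else None


def assign_flags(
    pair: CandidateVariantPair,
    cohort: VariantCohort,
    pedigree: Pedigree | None = None,
    rules: TierRules | None = None,
) -> FlagSet:
    """Table-style deprioritization flags for one candidate."""
    rules = rules or TierRules()
    noncoding = any(v.is_coding_mane is False for v, _ in pair.variants)
    common = any(v.cohort_alt_af() > rules.common_af_threshold for v, _ in pair.variants)
    non_seg = False
    if pedigree is not None:
        seg = _segregates(pair, cohort, pedigree)
        non_seg = seg is False
    return FlagSet(
        noncoding_mane=noncoding,
        common_in_callset=common,
        non_segregating=non_seg,
        in_cis=pair.phase == Phase.CIS,
        no_second_hit=pair.phase == Phase.NA_SINGLE,
    )


def effective_classes(
    pair: CandidateVariantPair, acmg: dict[tuple, ClinvarClass] | None = None
) -> tuple[list[ClinvarClass], list[ClinvarClass], list[ClinvarClass]]:
    """(clinvar, acmg, per-variant effective class = more pathogenic of the two)."""
    clinvar = [v.clinvar_class for v, _ in pair.variants]
    acmg = acmg or {}
    acmg_classes = [acmg.get(v.key, ClinvarClass.NONE) for v, _ in pair.variants]
    eff = [ClinvarClass.most_pathogenic(c, a) for c, a in zip(clinvar, acmg_classes)]
    return clinvar, acmg_classes, eff


def assign_tier(
    flags: FlagSet,
    phase: Phase,
    variant_classes: list[ClinvarClass],
    withdrawn: bool = False,
    rules: TierRules | None = None,
) -> Tier:
    """Total, deterministic tier assignment.

    Order of precedence: CLOSED (withdrawn) > EXCLUDE (any hard flag) >
    LOW (MANE-noncoding variant) > TOP (homozygous P/LP, or P/LP pair in
    trans) > MIDDLE (everything else: VUS pairs, unknown phase, ...).
    """
    rules = rules or TierRules()
    if withdrawn:
        return Tier.CLOSED
    if flags.hard_exclude:
        return Tier.EXCLUDE
    if flags.noncoding_mane:
        return Tier.LOW
    all_pathogenic = len(variant_classes) > 0 and all(rules.is_pathogenic(c) for c in variant_classes)
    if phase == Phase.NA_HOMOZYGOUS and all_pathogenic:
        return Tier.TOP
    if phase == Phase.TRANS and len(variant_classes) == 2 and all_pathogenic:
        return Tier.TOP
    return Tier.MIDDLE


class CasePrioritizer(BaseEstimator):
    """End-to-end prioritization of assessable participants.

    Stateless beyond its parameters; ``fit`` validates them.  The main entry
    point :meth:`prioritize_case` runs extraction, phasing, flagging and
    tiering for one (participant, gene) and returns a
    :class:`PrioritizedCase` (or None when no variant qualifies, which can
    happen when a high score came from a now-excluded variant class).
    """

    def __init__(
        self,
        min_deleteriousness: float = 15.0,
        common_af_threshold: float = 0.05,
        pathogenic_classes: tuple[str, ...] = ("P", "LP"),
    ):
        self.min_deleteriousness = min_deleteriousness
        self.common_af_threshold = common_af_threshold
        self.pathogenic_classes = pathogenic_classes

    def rules(self) -> TierRules:
        return TierRules(
            common_af_threshold=self.common_af_threshold,
            pathogenic_classes=tuple(self.pathogenic_classes),
        )

    def fit(self, X=None, y=None) -> "CasePrioritizer":
        if self.min_deleteriousness < 0 or not (0 < self.common_af_threshold < 1):
            raise ValueError("invalid prioritizer parameters")
        return self

    def prioritize_case(
        self,
        cohort: VariantCohort,
        sample_id: str,
        gene_id: str,
        pedigree: Pedigree | None = None,
        metadata: dict[str, ParticipantMeta] | None = None,
        acmg: dict[tuple, ClinvarClass] | None = None,
        rank: int | None = None,
        score: float | None = None,
    ) -> PrioritizedCase | None:
        withdrawn = bool(metadata and sample_id in metadata and metadata[sample_id].withdrawn)
        pair = extract_candidates(
            cohort, sample_id, gene_id, min_deleteriousness=self.min_deleteriousness
        )
        if pair is None:
            return None
        if pedigree is not None:
            infer_phase(pair, pedigree, cohort)
        flags = assign_flags(pair, cohort, pedigree, self.rules())
        clinvar, acmg_classes, eff = effective_classes(pair, acmg)
        tier = assign_tier(flags, pair.phase, eff, withdrawn=withdrawn, rules=self.rules())
        return PrioritizedCase(
            pair=pair,
            flags=flags,
            clinvar_classes=clinvar,
            acmg_classes=acmg_classes,
            tier=tier,
            rank=rank,
            score=score,
        )
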