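"""Core data model for cohort variant burden analysis.

Genotype calls are stored column-wise: each :class:`AnnotatedVariant` carries
numpy arrays of zygosity, read depth and genotype quality aligned to the
cohort sample order held by :class:`VariantCohort`.  This keeps whole-cohort
operations (genotype masking, site filters, scoring) vectorised over samples
while :meth:`AnnotatedVariant.call` still exposes the single-call view.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum, IntEnum

import numpy as np

__all__ = [
    "Zygosity",
    "ClinvarClass",
    "SolvedStatus",
    "GenotypeCall",
    "AnnotatedVariant",
    "VariantCohort",
    "Individual",
    "Pedigree",
    "ParticipantMeta",
    "PedigreeError",
]


class Zygosity(IntEnum):
    """Diploid genotype state with respect to a single alternate allele.

    Integer values equal the alternate-allele dosage for called genotypes,
    so ``max(z, 0)`` is the allele count contributed to a cohort frequency.
    """

    MISSING = -1
    HOM_REF = 0
    HET = 1
    HOM_ALT = 2


class ClinvarClass(str, Enum):
    """ClinVar-style clinical significance, consumed as an input annotation."""

    P = "P"
    LP = "LP"
    VUS = "VUS"
    LB = "LB"
    B = "B"
    NONE = "NONE"

    @property
    def severity(self) -> int:
        return _CLASS_SEVERITY[self]

    @classmethod
    def most_pathogenic(cls, *classes: "ClinvarClass") -> "ClinvarClass":
        return max(classes, key=lambda c: c.severity)


_CLASS_SEVERITY = {
    ClinvarClass.P: 5,
    ClinvarClass.LP: 4,
    ClinvarClass.VUS: 3,
    ClinvarClass.LB: 2,
    ClinvarClass.B: 1,
    ClinvarClass.NONE: 0,
}


class SolvedStatus(str, Enum):
    SOLVED = "SOLVED"
    UNSOLVED = "UNSOLVED"
    UNKNOWN = "UNKNOWN"


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's call at one site."""

    sample_id: str
    zygosity: Zygosity
    depth: int = 0
    gq: int = 0

    def __post_init__(self) -> None:
        if self.depth < 0 or self.gq < 0:
            raise ValueError("depth and GQ must be non-negative")


@dataclass
class AnnotatedVariant:
    """A biallelic site (post multi-allelic decomposition) with annotations.

    ``zygosity``, ``depth`` and ``gq`` are per-sample arrays in the cohort's
    sample order.  Annotation fields default to absent (``None``) until
    populated from the annotation table; ``gene_ids`` is determined solely by
    BED interval overlap.
    """

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    zygosity: np.ndarray
    depth: np.ndarray
    gq: np.ndarray
    gene_ids: frozenset = frozenset()
    deleteriousness_raw: float | None = None
    ref_pop_af: float | None = None
    is_coding_any_transcript: bool | None = None
    is_coding_mane: bool | None = None
    clinvar_class: ClinvarClass = ClinvarClass.NONE
    n_masked_calls: int = 0

    def __post_init__(self) -> None:
        self.zygosity = np.asarray(self.zygosity, dtype=np.int8)
        self.depth = np.asarray(self.depth, dtype=np.int32)
        self.gq = np.asarray(self.gq, dtype=np.int32)
        if not (len(self.zygosity) == len(self.depth) == len(self.gq)):
            raise ValueError("zygosity/depth/gq arrays must have equal length")
        if self.pos < 1:
            raise ValueError(f"VCF positions are 1-based; got {self.pos}")
        if self.ref_pop_af is not None and not (0.0 <= self.ref_pop_af <= 1.0):
            raise ValueError(f"ref_pop_af must lie in [0,1]; got {self.ref_pop_af}")
        self.gene_ids = frozenset(self.gene_ids)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def n_samples(self) -> int:
        return len(self.zygosity)

    def call(self, idx: int, samples: list[str]) -> GenotypeCall:
        return GenotypeCall(
            sample_id=samples[idx],
            zygosity=Zygosity(int(self.zygosity[idx])),
            depth=int(self.depth[idx]),
            gq=int(self.gq[idx]),
        )

    def copy(self) -> "AnnotatedVariant":
        return dataclasses.replace(
            self,
            zygosity=self.zygosity.copy(),
            depth=self.depth.copy(),
            gq=self.gq.copy(),
        )

    def nonmissing_mask(self) -> np.ndarray:
        return self.zygosity != Zygosity.MISSING

    def cohort_alt_af(self) -> float:
        """Alternate-allele frequency computed from the cohort's own calls."""
        ok = self.nonmissing_mask()
        n = int(ok.sum())
        if n == 0:
            return 0.0
        return float(self.zygosity[ok].sum()) / (2.0 * n)


@dataclass
class VariantCohort:
    """A multi-sample variant collection with a fixed sample order."""

    samples: list[str]
    variants: list[AnnotatedVariant] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids in cohort")
        self._sample_index = {s: i for i, s in enumerate(self.samples)}

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, sample_id: str) -> int:
        return self._sample_index[sample_id]

    def gene_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for v in self.variants:
            for g in sorted(v.gene_ids):
                seen.setdefault(g, None)
        return list(seen)

    def copy(self) -> "VariantCohort":
        return VariantCohort(list(self.samples), [v.copy() for v in self.variants])


class PedigreeError(ValueError):
    pass


@dataclass(frozen=True)
class Individual:
    sample_id: str
    family_id: str = "0"
    father_id: str | None = None
    mother_id: str | None = None
    sex: int = 0  # PED convention: 1 male, 2 female, 0 unknown
    affected: bool = False


@dataclass
class Pedigree:
    individuals: dict[str, Individual] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        # Iterative DFS over parent links; any back-edge is a parentage cycle.
        WHITE, GREY, BLACK = 0, 1, 2
        state = {sid: WHITE for sid in self.individuals}
        for root in self.individuals:
            if state[root] != WHITE:
                continue
            stack: list[tuple[str, int]] = [(root, 0)]
            while stack:
                sid, pi = stack[-1]
                if pi == 0:
                    state[sid] = GREY
                parents = [
                    p
                    for p in (self.individuals[sid].father_id, self.individuals[sid].mother_id)
                    if p is not None and p in self.individuals
                ]
                if pi < len(parents):
                    stack[-1] = (sid, pi + 1)
                    p = parents[pi]
                    if state[p] == GREY:
                        raise PedigreeError(f"cyclic parentage involving {p!r}")
                    if state[p] == WHITE:
                        stack.append((p, 0))
                else:
                    state[sid] = BLACK
                    stack.pop()

    def __len__(self) -> int:
        return len(self.individuals)

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self.individuals

    def parents_of(self, sample_id: str) -> tuple[str | None, str | None]:
        """(father_id, mother_id), each None when absent or unresolvable."""
        ind = self.individuals.get(sample_id)
        if ind is None:
            return (None, None)
        f = ind.father_id if ind.father_id in self.individuals else None
        m = ind.mother_id if ind.mother_id in self.individuals else None
        return (f, m)

    def family_members(self, sample_id: str) -> list[Individual]:
        ind = self.individuals.get(sample_id)
        if ind is None:
            return []
        return [i for i in self.individuals.values() if i.family_id == ind.family_id]


@dataclass(frozen=True)
class ParticipantMeta:
    sample_id: str
    affected: bool
    solved: SolvedStatus = SolvedStatus.UNKNOWN
    hpo_terms: frozenset = frozenset()
    withdrawn: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "hpo_terms", frozenset(self.hpo_terms))
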