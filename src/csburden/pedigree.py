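"""Autosomal-dominant cosegregation filtering on pedigrees.

A candidate variant cosegregates with a dominant, fully penetrant
trait when every genotyped affected family member carries it
(heterozygously) and every genotyped unaffected member does not.
Missing genotypes are non-informative — they neither support nor
violate — and a family with fewer than two informative members cannot
support cosegregation at all.

Phenocopies are out of model: an affected non-carrier is a hard
violation.  A configurable number of unaffected carriers may be
tolerated for reduced-penetrance screens (default zero).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import InputFormatError
from .variants import AnnotatedVariant, Classification, MutationClass, classify

#: Carrier-state vocabulary for pedigree genotypes.
CARRIER_STATES = ("het", "ref", "missing")


@dataclass(frozen=True)
class PedigreeMember:
    member_id: str
    father_id: str | None
    mother_id: str | None
    sex: str  # "1"/"2"/"0" per PED convention, or "M"/"F"/"U"
    affected: bool


@dataclass
class Pedigree:
    """Family members plus per-member carrier states per variant.

    ``genotypes`` maps member id -> variant id -> one of ``"het"``,
    ``"ref"``, ``"missing"``.  A member absent from ``genotypes`` (or a
    variant absent from their map) is treated as missing.
    """

    family_id: str
    members: list[PedigreeMember]
    genotypes: dict[str, dict[str, str]] = field(default_factory=dict)
    proband_id: str | None = None

    def __post_init__(self) -> None:
        ids = {m.member_id for m in self.members}
        for m in self.members:
            for parent in (m.father_id, m.mother_id):
                if parent is not None and parent not in ids:
                    raise InputFormatError(
                        f"{self.family_id}: member {m.member_id} references "
                        f"unknown parent {parent}"
                    )
        if not any(m.affected for m in self.members):
            raise InputFormatError(f"{self.family_id}: no affected member")
        for member, gmap in self.genotypes.items():
            for vid, state in gmap.items():
                if state not in CARRIER_STATES:
                    raise InputFormatError(
                        f"{self.family_id}/{member}: bad carrier state {state!r} "
                        f"for {vid}"
                    )
        if self.proband_id is None:
            # default proband: first affected member in file order
            self.proband_id = next(m.member_id for m in self.members if m.affected)
        elif self.proband_id not in ids:
            raise InputFormatError(
                f"{self.family_id}: proband {self.proband_id} not in pedigree"
            )

    def state(self, member_id: str, variant_id: str) -> str:
        return self.genotypes.get(member_id, {}).get(variant_id, "missing")


@dataclass(frozen=True)
class SegregationVerdict:
    variant_id: str
    cosegregates: bool
    informative_members: int
    violations: tuple[str, ...]


def dominant_candidates(
    ped: Pedigree,
    variants: Sequence[AnnotatedVariant],
    tolerated_unaffected_carriers: int = 0,
) -> list[SegregationVerdict]:
    """Test each variant for dominant cosegregation in one family.

    A variant cosegregates iff there are no violations and at least two
    informative (genotyped) members.  Violations are affected members
    without the variant and unaffected carriers beyond the tolerated
    count.

    Raises
    ------
    InputFormatError
        If the proband has no genotype for any tested variant.
    """
    proband_states = [ped.state(ped.proband_id, v.variant_id) for v in variants]
    if variants and all(s == "missing" for s in proband_states):
        raise InputFormatError(
            f"{ped.family_id}: proband {ped.proband_id} is ungenotyped"
        )
    verdicts = []
    for v in variants:
        informative = 0
        affected_noncarriers: list[str] = []
        unaffected_carriers: list[str] = []
        for m in ped.members:
            state = ped.state(m.member_id, v.variant_id)
            if state == "missing":
                continue
            informative += 1
            if m.affected and state == "ref":
                affected_noncarriers.append(m.member_id)
            elif not m.affected and state == "het":
                unaffected_carriers.append(m.member_id)
        excess_unaffected = unaffected_carriers[tolerated_unaffected_carriers:]
        violations = affected_noncarriers + excess_unaffected
        coseg = not violations and informative >= 2
        verdicts.append(
            SegregationVerdict(v.variant_id, coseg, informative, tuple(violations))
        )
    return verdicts


_CLASS_RANK = {
    MutationClass.LGD: 0,
    MutationClass.MISSENSE_DMIS: 1,
    MutationClass.MISSENSE_NON_DMIS: 2,
    MutationClass.OTHER: 3,
}


def rank_candidates(
    verdicts: Sequence[SegregationVerdict],
    variants: Sequence[AnnotatedVariant],
    cadd_threshold: float = 20.0,
) -> list[SegregationVerdict]:
    """Order verdicts for review: cosegregating first, then by severity.

    Within each cosegregation group, loss-of-function (LGD) candidates
    precede damaging missense, which precede everything else; ties
    break by descending CADD, then stably by input order.
    """
    by_id = {v.variant_id: v for v in variants}

    def key(item: tuple[int, SegregationVerdict]):
        idx, verdict = item
        v = by_id.get(verdict.variant_id)
        if v is None:
            return (not verdict.cosegregates, 4, 0.0, idx)
        cl = classify(v, cadd_threshold)
        cadd = v.cadd if v.cadd is not None else float("-inf")
        return (not verdict.cosegregates, _CLASS_RANK[cl.mclass], -cadd, idx)

    return [v for _, v in sorted(enumerate(verdicts), key=lambda it: key(it))]


# ---------------------------------------------------------------------------
# PED format IO (6-column pre-genotype standard)


def read_ped(path: str | Path) -> list[Pedigree]:
    """Read standard 6-column PED: fam, id, father, mother, sex, phenotype.

    Phenotype coding: 2 = affected, 1 = unaffected, 0/-9 = unknown
    (treated as unaffected for the dominant filter, i.e. informative
    only through genotype absence).  Parent id 0 means founder.
    """
    families: dict[str, list[PedigreeMember]] = {}
    order: list[str] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise InputFormatError(f"{path}:{line_no}: expected 6 PED columns")
            fam, mid, father, mother, sex, pheno = parts[:6]
            member = PedigreeMember(
                member_id=mid,
                father_id=None if father == "0" else father,
                mother_id=None if mother == "0" else mother,
                sex=sex,
                affected=pheno == "2",
            )
            if fam not in families:
                families[fam] = []
                order.append(fam)
            families[fam].append(member)
    return [Pedigree(fam, families[fam]) for fam in order]


def write_ped(pedigrees: Iterable[Pedigree], path) -> None:
    """Write 6-column PED to a path or an open text handle."""
    fh = path if hasattr(path, "write") else open(path, "w")
    try:
        for ped in pedigrees:
            for m in ped.members:
                fh.write(
                    "\t".join(
                        [
                            ped.family_id,
                            m.member_id,
                            m.father_id or "0",
                            m.mother_id or "0",
                            m.sex,
                            "2" if m.affected else "1",
                        ]
                    )
                    + "\n"
                )
    finally:
        if fh is not path:
            fh.close()


def attach_genotypes(
    ped: Pedigree, genotypes: Mapping[str, Iterable[str]], variant_ids: Iterable[str]
) -> None:
    """Join VCF-derived carrier sets onto a pedigree by member id.

    Members present in ``genotypes`` get an explicit het/ref state for
    every variant in ``variant_ids``; absent members stay missing.
    """
    vids = list(variant_ids)
    for m in ped.members:
        if m.member_id in genotypes:
            carried = set(genotypes[m.member_id])
            ped.genotypes[m.member_id] = {
                vid: ("het" if vid in carried else "ref") for vid in vids
            }
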