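"""Two-stage carrier logic under an assumed dominant, fully penetrant model.

Stage one removes, globally, every variant carried by any genotyped,
non-exempt unaffected individual in any family. Stage two calls, per
family, the variants carried by all genotyped affected members and by no
genotyped non-exempt unaffected member. "Carried" means at least one alt
allele — heterozygous and homozygous both count. Individuals with the
intermediate (suggestive) phenotype are ignored in both directions, as
are unknown phenotypes and ungenotyped members.

Penetrance-exempt individuals are unaffected members excluded from the
"absent in unaffected" constraint at both stages, modelling reduced
penetrance in their family.

Missing genotypes are treated conservatively: in an affected member a
missing call fails the "present in all affected" requirement; in an
unaffected member it never counts as carriage. Both policies are
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .types import (
    AnnotatedVariant,
    Pedigree,
    VariantKey,
    VariantRecord,
)


class NotEvaluableError(ValueError):
    """The segregation rule is undefined for this family (no genotyped
    affected member)."""


@dataclass(frozen=True)
class SegregationCall:
    """Per-(family, variant) segregation status.

    ``segregates``  all genotyped affected carry, no genotyped non-exempt
    unaffected carries; ``incomplete``  all affected carry but at least one
    unaffected carries; ``fails``  some affected member does not carry.
    """

    family_id: str
    key: VariantKey
    status: str  # "segregates" | "incomplete" | "fails"


@dataclass
class SegregationResult:
    """Variants passing the segregation rule in one family, with that
    family's genotyped phenotype tallies."""

    family_id: str
    variants: list[VariantKey]
    n_affected: int
    n_suggestive: int
    n_unaffected: int

    @property
    def n_segregating(self) -> int:
        return len(self.variants)


@dataclass(frozen=True)
class MissingGenotypePolicy:
    """How missing calls enter the carrier logic. Defaults are the
    conservative reading: missing never proves carriage, and an affected
    member with a missing call blocks the family's segregation call."""

    affected_missing_fails: bool = True
    unaffected_missing_carries: bool = False


def _carries(count: Optional[int]) -> Optional[bool]:
    return None if count is None else count >= 1


def remove_global_unaffected_carriers(
    dataset: Sequence[AnnotatedVariant],
    pedigrees: Sequence[Pedigree],
    policy: MissingGenotypePolicy = MissingGenotypePolicy(),
) -> list[AnnotatedVariant]:
    """Drop every variant with an alt allele in any genotyped, non-exempt
    unaffected individual across all families (complete-penetrance
    assumption). Suggestive and unknown phenotypes never trigger removal."""
    blockers = [
        m.individual_id
        for ped in pedigrees
        for m in ped.genotyped_members("unaffected")
        if not m.penetrance_exempt
    ]
    out = []
    for rec, ann in dataset:
        removed = False
        for sample in blockers:
            carries = _carries(rec.sample_alt_counts.get(sample))
            if carries is None:
                carries = policy.unaffected_missing_carries
            if carries:
                removed = True
                break
        if not removed:
            out.append((rec, ann))
    return out


def classify_segregation(
    family: Pedigree,
    variant: VariantRecord,
    policy: MissingGenotypePolicy = MissingGenotypePolicy(),
) -> SegregationCall:
    """Call one variant against one family's genotyped members."""
    affected = family.genotyped_members("affected")
    if not affected:
        raise NotEvaluableError(
            f"family {family.family_id} has no genotyped affected member"
        )
    all_affected_carry = True
    for m in affected:
        carries = _carries(variant.sample_alt_counts.get(m.individual_id))
        if carries is None:
            carries = not policy.affected_missing_fails
        if not carries:
            all_affected_carry = False
            break
    if not all_affected_carry:
        return SegregationCall(family.family_id, variant.key, "fails")
    unaffected_carrier = False
    for m in family.genotyped_members("unaffected"):
        if m.penetrance_exempt:
            continue
        carries = _carries(variant.sample_alt_counts.get(m.individual_id))
        if carries is None:
            carries = policy.unaffected_missing_carries
        if carries:
            unaffected_carrier = True
            break
    status = "incomplete" if unaffected_carrier else "segregates"
    return SegregationCall(family.family_id, variant.key, status)


def segregating_variants(
    pedigrees: Sequence[Pedigree],
    dataset: Sequence[AnnotatedVariant],
    policy: MissingGenotypePolicy = MissingGenotypePolicy(),
) -> list[SegregationResult]:
    """Per-family segregating variant lists, ordered by (chrom, pos, alt).

    Families with no genotyped affected member yield an empty result
    rather than an error, so a whole-cohort sweep never aborts on an
    uninformative family.
    """
    results = []
    for ped in pedigrees:
        counts = ped.phenotype_counts()
        keys: list[VariantKey] = []
        if counts["affected"] > 0:
            for rec, _ in dataset:
                call = classify_segregation(ped, rec, policy)
                if call.status == "segregates":
                    keys.append(rec.key)
        keys = sorted(set(keys), key=lambda k: (k[0], k[1], k[3]))
        results.append(
            SegregationResult(
                family_id=ped.family_id,
                variants=keys,
                n_affected=counts["affected"],
                n_suggestive=counts["suggestive"],
                n_unaffected=counts["unaffected"],
            )
        )
    return results
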