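"""Core domain types shared across the pipeline.

A variant is identified throughout by its key ``(chrom, pos, ref, alt)``
with a 1-based position; the string form ``"chrom:pos:ref:alt"`` is used
in reports and truth tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from graphlib import CycleError, TopologicalSorter
from typing import Iterator, Mapping, Optional, Sequence

VariantKey = tuple[str, int, str, str]

SEXES = ("male", "female", "unknown")
PHENOTYPES = ("affected", "suggestive", "unaffected", "unknown")

EFFECT_CLASSES = (
    "frameshift_indel",
    "nonframeshift_indel",
    "nonsynonymous",
    "stopgain",
    "stoploss",
    "unknown_effect",
    "splicing",
    "synonymous",
    "other",
)

#: Effect classes retained by the default protein-altering filter.
DEFAULT_RETAINED_EFFECTS = frozenset(
    {
        "frameshift_indel",
        "nonframeshift_indel",
        "nonsynonymous",
        "stopgain",
        "stoploss",
        "unknown_effect",
    }
)

#: Population frequency sources consulted by the rarity filter, in the
#: order they appear in annotation tables.
DEFAULT_AF_SOURCES = (
    "1000g_all",
    "1000g_eur",
    "exac_all",
    "exac_nfe",
    "exac_fin",
    "esp6500_all",
)

#: Adult-onset actionable genes removed to avoid incidental findings.
ACMG_SECONDARY_GENES = frozenset(
    {"BRCA1", "BRCA2", "MLH1", "MSH2", "MSH6", "PMS2", "MUTYH"}
)


class FormatError(ValueError):
    """Malformed input file content."""


class ConsistencyError(ValueError):
    """Structurally valid input that violates a cross-record invariant."""


class ConfigurationError(ValueError):
    """Invalid or infeasible run configuration."""


def variant_key_str(key: VariantKey) -> str:
    chrom, pos, ref, alt = key
    return f"{chrom}:{pos}:{ref}:{alt}"


def parse_variant_key(text: str) -> VariantKey:
    chrom, pos, ref, alt = text.split(":")
    return (chrom, int(pos), ref, alt)


@dataclass
class PedigreeIndividual:
    """One family member; ``genotyped=False`` members (e.g. individuals who
    declined sequencing) are legal and ignored by genotype-dependent rules.

    ``penetrance_exempt`` marks an unaffected individual excluded from the
    "absent in unaffected" constraints, modelling reduced penetrance.
    """

    family_id: str
    individual_id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    sex: str = "unknown"
    phenotype: str = "unknown"
    penetrance_exempt: bool = False
    genotyped: bool = True

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"invalid sex {self.sex!r}")
        if self.phenotype not in PHENOTYPES:
            raise ValueError(f"invalid phenotype {self.phenotype!r}")
        if (self.father_id is None) != (self.mother_id is None):
            raise ConsistencyError(
                f"{self.individual_id}: father and mother must both be set or both null"
            )
        if self.penetrance_exempt and self.phenotype != "unaffected":
            raise ConsistencyError(
                f"{self.individual_id}: penetrance exemption requires an unaffected phenotype"
            )

    @property
    def is_founder(self) -> bool:
        return self.father_id is None


@dataclass
class Pedigree:
    """A single family as a parent-linked acyclic graph of individuals."""

    family_id: str
    members: list[PedigreeIndividual] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[str] = set()
        for m in self.members:
            if m.family_id != self.family_id:
                raise ConsistencyError(
                    f"member {m.individual_id} belongs to family {m.family_id}, "
                    f"not {self.family_id}"
                )
            if m.individual_id in seen:
                raise ConsistencyError(
                    f"duplicate individual {m.individual_id!r} in family {self.family_id}"
                )
            seen.add(m.individual_id)
        for m in self.members:
            for pid in (m.father_id, m.mother_id):
                if pid is not None and pid not in seen:
                    raise ConsistencyError(
                        f"family {self.family_id}: parent {pid!r} of "
                        f"{m.individual_id!r} is never defined"
                    )
        # raises CycleError if someone is their own ancestor
        try:
            list(self._toposorter().static_order())
        except CycleError as exc:
            raise ConsistencyError(
                f"family {self.family_id}: pedigree contains a cycle"
            ) from exc

    def _toposorter(self) -> TopologicalSorter:
        ts: TopologicalSorter = TopologicalSorter()
        for m in self.members:
            parents = [p for p in (m.father_id, m.mother_id) if p is not None]
            ts.add(m.individual_id, *parents)
        return ts

    def topological_order(self) -> list[PedigreeIndividual]:
        """Members ordered so every parent precedes its children."""
        by_id = self.by_id
        return [by_id[i] for i in self._toposorter().static_order()]

    @property
    def by_id(self) -> dict[str, PedigreeIndividual]:
        return {m.individual_id: m for m in self.members}

    @property
    def founders(self) -> list[PedigreeIndividual]:
        return [m for m in self.members if m.is_founder]

    def genotyped_members(self, phenotype: Optional[str] = None) -> list[PedigreeIndividual]:
        out = [m for m in self.members if m.genotyped]
        if phenotype is not None:
            out = [m for m in out if m.phenotype == phenotype]
        return out

    def phenotype_counts(self) -> dict[str, int]:
        """Genotyped-member tallies per phenotype state."""
        counts = {p: 0 for p in PHENOTYPES}
        for m in self.genotyped_members():
            counts[m.phenotype] += 1
        return counts


@dataclass
class RawSite:
    """A called site before multiallelic decomposition.

    ``genotypes`` maps each sample to a pair of allele indices into
    ``[ref] + alts`` (diploid GT), with ``None`` for a missing allele.
    """

    chrom: str
    pos: int
    ref: str
    alts: list[str]
    rsid: Optional[str] = None
    genotypes: dict[str, tuple[Optional[int], Optional[int]]] = field(default_factory=dict)


@dataclass
class VariantRecord:
    """One normalised biallelic site with per-sample alt-allele counts.

    ``sample_alt_counts`` values are 0, 1, 2, or ``None`` for a missing
    genotype (including half-missing diploid calls).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    rsid: Optional[str] = None
    sample_alt_counts: dict[str, Optional[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ConsistencyError(f"{self.chrom}:{self.pos}: ref equals alt ({self.ref!r})")
        if self.pos < 1:
            raise ConsistencyError(f"{self.chrom}:{self.pos}: positions are 1-based")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def key_str(self) -> str:
        return variant_key_str(self.key)

    def carriers(self, sample_ids: Optional[Sequence[str]] = None) -> list[str]:
        """Samples with at least one alt allele (het and hom both count)."""
        ids = self.sample_alt_counts.keys() if sample_ids is None else sample_ids
        return [
            s
            for s in ids
            if (self.sample_alt_counts.get(s) or 0) >= 1
        ]


MISSING = None


@dataclass
class VariantAnnotation:
    """External annotation for one biallelic variant.

    ``population_afs`` maps a frequency source to an allele fraction in
    [0, 1]; absent sources mean the variant was not seen in that panel.
    ``control_maf`` is the in-cohort control minor allele frequency,
    already folded to the minor allele.
    """

    gene: Optional[str] = None
    effect: str = "other"
    population_afs: dict[str, float] = field(default_factory=dict)
    control_maf: Optional[float] = None
    cadd_phred: Optional[float] = None
    is_indel: bool = False

    def __post_init__(self) -> None:
        if self.effect not in EFFECT_CLASSES:
            raise ValueError(f"invalid effect class {self.effect!r}")
        for source, af in self.population_afs.items():
            if af is not None and not (0.0 <= af <= 1.0):
                raise ValueError(f"{source}: allele frequency {af} outside [0, 1]")
        if self.control_maf is not None and not (0.0 <= self.control_maf <= 1.0):
            raise ValueError(f"control MAF {self.control_maf} outside [0, 1]")
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise ValueError(f"negative CADD score {self.cadd_phred}")

    @classmethod
    def all_missing(cls) -> "VariantAnnotation":
        return cls(gene=None, effect="other")


AnnotatedVariant = tuple[VariantRecord, VariantAnnotation]


def iter_all_samples(pedigrees: Sequence[Pedigree]) -> Iterator[PedigreeIndividual]:
    for ped in pedigrees:
        yield from ped.members


def genotyped_sample_ids(pedigrees: Sequence[Pedigree]) -> set[str]:
    return {m.individual_id for ped in pedigrees for m in ped.members if m.genotyped}
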