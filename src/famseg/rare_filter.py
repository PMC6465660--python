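"""Variant-level rarity and deleteriousness cascade.

Rules, in cascade order (each variant is tagged with the first rule it
fails):

``population_rarity``
    every configured reference-panel frequency is missing, <= 1%, or
    >= 99% (reference-flipped sites), and the in-cohort control MAF is
    missing or < 1%. A variant absent from every panel counts as rare.
``effect_cadd``
    the effect class is protein-altering (frameshift / nonframeshift
    indel, nonsynonymous, stop gain/loss, unknown effect) and the CADD
    phred score is >= 20, or missing for an indel.
``acmg_gene``
    the variant does not fall in an adult-onset actionable gene
    (BRCA1, BRCA2, MLH1, MSH2, MSH6, PMS2, MUTYH by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .types import (
    ACMG_SECONDARY_GENES,
    DEFAULT_AF_SOURCES,
    DEFAULT_RETAINED_EFFECTS,
    AnnotatedVariant,
    Pedigree,
    VariantAnnotation,
    VariantKey,
)


@dataclass
class FilterConfig:
    """Thresholds for the variant-level cascade; defaults follow the
    familial exome workflow this package implements."""

    maf_threshold: float = 0.01
    flipped_threshold: float = 0.99
    control_maf_threshold: float = 0.01
    cadd_threshold: float = 20.0
    retained_effects: frozenset[str] = DEFAULT_RETAINED_EFFECTS
    excluded_genes: frozenset[str] = ACMG_SECONDARY_GENES
    af_sources: tuple[str, ...] = DEFAULT_AF_SOURCES
    hwe_threshold: float = 1e-8

    def __post_init__(self) -> None:
        if not (0.0 < self.maf_threshold < self.flipped_threshold < 1.0):
            raise ValueError("need 0 < maf_threshold < flipped_threshold < 1")
        if not (0.0 < self.control_maf_threshold <= 1.0):
            raise ValueError("control_maf_threshold must be in (0, 1]")
        self.retained_effects = frozenset(self.retained_effects)
        self.excluded_genes = frozenset(self.excluded_genes)


@dataclass(frozen=True)
class FilterDecision:
    """Per-variant audit record: the verdict and the first failed rule."""

    key: VariantKey
    verdict: str  # "retained" | "removed"
    failed_rule: Optional[str] = None

    def __post_init__(self) -> None:
        if (self.verdict == "removed") != (self.failed_rule is not None):
            raise ValueError("failed_rule must be set iff verdict is 'removed'")


def is_population_rare(ann: VariantAnnotation, cfg: FilterConfig) -> bool:
    """True if rare (or reference-flipped) in every configured panel and
    below the control-cohort MAF cutoff.

    The >= 99% branch applies only to reference-panel frequencies; the
    control MAF is already folded to the minor allele, so only the strict
    ``< control_maf_threshold`` test applies there.
    """
    for source in cfg.af_sources:
        af = ann.population_afs.get(source)
        if af is None:
            continue
        if not (0.0 <= af <= 1.0):
            raise ValueError(f"{source}: allele frequency {af} outside [0, 1]")
        if not (af <= cfg.maf_threshold or af >= cfg.flipped_threshold):
            return False
    if ann.control_maf is not None:
        if not (0.0 <= ann.control_maf <= 1.0):
            raise ValueError(f"control MAF {ann.control_maf} outside [0, 1]")
        if ann.control_maf >= cfg.control_maf_threshold:
            return False
    return True


def passes_effect_and_cadd(ann: VariantAnnotation, cfg: FilterConfig) -> bool:
    """Protein-altering effect class and CADD >= threshold (a missing
    CADD score is accepted for indels only)."""
    if ann.effect not in cfg.retained_effects:
        return False
    if ann.cadd_phred is None:
        return ann.is_indel
    return ann.cadd_phred >= cfg.cadd_threshold


def apply_rare_filters(
    dataset: Sequence[AnnotatedVariant],
    pedigrees: Sequence[Pedigree],
    cfg: Optional[FilterConfig] = None,
) -> tuple[list[AnnotatedVariant], list[FilterDecision]]:
    """Run the cascade over a QC-passed dataset.

    Every input variant receives exactly one :class:`FilterDecision`; the
    retained dataset preserves input order. *pedigrees* is accepted for
    interface symmetry with the segregation stage (none of these rules
    are genotype-dependent).
    """
    cfg = cfg or FilterConfig()
    retained: list[AnnotatedVariant] = []
    decisions: list[FilterDecision] = []
    for rec, ann in dataset:
        if not is_population_rare(ann, cfg):
            decisions.append(FilterDecision(rec.key, "removed", "population_rarity"))
        elif not passes_effect_and_cadd(ann, cfg):
            decisions.append(FilterDecision(rec.key, "removed", "effect_cadd"))
        elif ann.gene is not None and ann.gene in cfg.excluded_genes:
            decisions.append(FilterDecision(rec.key, "removed", "acmg_gene"))
        else:
            decisions.append(FilterDecision(rec.key, "retained"))
            retained.append((rec, ann))
    return retained, decisions


def decision_tally(decisions: Sequence[FilterDecision]) -> dict[str, int]:
    tally: dict[str, int] = {"retained": 0}
    for d in decisions:
        rule = d.failed_rule or "retained"
        tally[rule] = tally.get(rule, 0) + 1
    return tally
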