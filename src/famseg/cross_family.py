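"""Cross-family evidence aggregation.

After per-family segregation calls, evidence is pooled across families:
variants segregating in two or more families; genes with two or more
distinct segregating variants whose contributing families span two or
more families; genes hit twice within a single family; cohort summary
statistics; and a 2x2 allelic odds-ratio helper for looking a shared
variant up in an external case-control cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import math

import pandas as pd
from scipy import stats

from .types import AnnotatedVariant, VariantKey, variant_key_str
from .segregation import SegregationResult


@dataclass(frozen=True)
class SharedVariantReport:
    """One variant segregating in two or more families."""

    key: VariantKey
    families: frozenset[str]
    gene: Optional[str] = None
    any_homozygous_carrier: bool = False

    def __post_init__(self) -> None:
        if len(self.families) < 2:
            raise ValueError("shared variant requires >= 2 families")


@dataclass(frozen=True)
class MultiVariantGeneReport:
    """A gene with >= 2 distinct segregating variants whose contributing
    families span >= 2 families."""

    gene: str
    variants: tuple[VariantKey, ...]
    families: frozenset[str]

    def __post_init__(self) -> None:
        if len(set(self.variants)) < 2 or len(self.families) < 2:
            raise ValueError("need >= 2 distinct variants over >= 2 families")


@dataclass
class CohortSummary:
    per_family: pd.DataFrame  # family_id, n_affected, n_suggestive, n_unaffected, n_segregating
    mean_segregating: float
    mean_segregating_rounded: int
    min_segregating: int
    max_segregating: int
    total_affected: int
    total_suggestive: int
    total_unaffected: int

    @property
    def total_individuals(self) -> int:
        return self.total_affected + self.total_suggestive + self.total_unaffected


@dataclass(frozen=True)
class FamilyCounts:
    """Bare per-family tallies, for summaries built from published counts
    rather than from variant lists."""

    family_id: str
    n_affected: int
    n_suggestive: int
    n_unaffected: int
    n_segregating: int


@dataclass(frozen=True)
class AssocResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    counts: tuple[tuple[int, int], tuple[int, int]]
    continuity_corrected: bool = False


# ---------------------------------------------------------------------------


def gene_map_from_dataset(dataset: Sequence[AnnotatedVariant]) -> dict[VariantKey, str]:
    return {rec.key: ann.gene for rec, ann in dataset if ann.gene is not None}


def homozygous_keys_from_dataset(dataset: Sequence[AnnotatedVariant]) -> set[VariantKey]:
    return {
        rec.key
        for rec, _ in dataset
        if any(c == 2 for c in rec.sample_alt_counts.values())
    }


def variant_family_map(
    results: Sequence[SegregationResult],
) -> dict[VariantKey, frozenset[str]]:
    fam_of: dict[VariantKey, set[str]] = {}
    for res in results:
        for key in res.variants:
            fam_of.setdefault(key, set()).add(res.family_id)
    return {k: frozenset(v) for k, v in fam_of.items()}


def shared_variants(
    results: Sequence[SegregationResult],
    gene_of: Optional[Mapping[VariantKey, str]] = None,
    homozygous_keys: Optional[set[VariantKey]] = None,
) -> list[SharedVariantReport]:
    """Variants whose segregating-family set has size >= 2.

    *homozygous_keys* flags variants with at least one homozygous carrier
    anywhere in the cohort (reported, not acted on). Output is ordered by
    (chrom, pos, alt).
    """
    gene_of = gene_of or {}
    homozygous_keys = homozygous_keys or set()
    fam_of = variant_family_map(results)
    reports = [
        SharedVariantReport(
            key=key,
            families=families,
            gene=gene_of.get(key),
            any_homozygous_carrier=key in homozygous_keys,
        )
        for key, families in fam_of.items()
        if len(families) >= 2
    ]
    return sorted(reports, key=lambda r: (r.key[0], r.key[1], r.key[3]))


def multi_variant_genes(
    results: Sequence[SegregationResult],
    gene_of: Mapping[VariantKey, str],
    strict: bool = False,
) -> tuple[list[MultiVariantGeneReport], dict[str, list[str]]]:
    """Genes with multiple segregating variants across families, plus the
    per-family multi-hit list.

    A gene qualifies for the cross-family report when it has >= 2 distinct
    segregating variants and the union of their segregating families has
    size >= 2 (with ``strict=True``, every contributing variant must
    itself segregate in >= 2 families). Separately returns, per family,
    the genes with >= 2 segregating variants inside that one family.
    """
    fam_of = variant_family_map(results)
    by_gene: dict[str, dict[VariantKey, frozenset[str]]] = {}
    for key, families in fam_of.items():
        gene = gene_of.get(key)
        if gene is not None:
            by_gene.setdefault(gene, {})[key] = families
    reports = []
    for gene, variants in by_gene.items():
        eligible = (
            {k: f for k, f in variants.items() if len(f) >= 2} if strict else variants
        )
        union = frozenset().union(*eligible.values()) if eligible else frozenset()
        if len(eligible) >= 2 and len(union) >= 2:
            reports.append(
                MultiVariantGeneReport(
                    gene=gene,
                    variants=tuple(sorted(eligible, key=lambda k: (k[0], k[1], k[3]))),
                    families=union,
                )
            )
    reports.sort(key=lambda r: r.gene)

    within_family: dict[str, list[str]] = {}
    for res in results:
        gene_hits: dict[str, int] = {}
        for key in res.variants:
            gene = gene_of.get(key)
            if gene is not None:
                gene_hits[gene] = gene_hits.get(gene, 0) + 1
        multi = sorted(g for g, n in gene_hits.items() if n >= 2)
        if multi:
            within_family[res.family_id] = multi
    return reports, within_family


def cohort_summary(
    results: Sequence[SegregationResult | FamilyCounts],
) -> CohortSummary:
    """Per-family tallies with cohort-level mean / min / max segregating
    counts (mean reported exact and rounded) and phenotype totals."""
    if not results:
        raise ValueError("cohort summary requires at least one family")
    rows = [
        {
            "family_id": r.family_id,
            "n_affected": r.n_affected,
            "n_suggestive": r.n_suggestive,
            "n_unaffected": r.n_unaffected,
            "n_segregating": r.n_segregating,
        }
        for r in results
    ]
    df = pd.DataFrame(rows)
    mean = float(df["n_segregating"].mean())
    return CohortSummary(
        per_family=df,
        mean_segregating=mean,
        mean_segregating_rounded=int(round(mean)),
        min_segregating=int(df["n_segregating"].min()),
        max_segregating=int(df["n_segregating"].max()),
        total_affected=int(df["n_affected"].sum()),
        total_suggestive=int(df["n_suggestive"].sum()),
        total_unaffected=int(df["n_unaffected"].sum()),
    )


def allelic_odds_ratio(
    case_alt: int, case_ref: int, ctrl_alt: int, ctrl_ref: int
) -> AssocResult:
    """Allelic 2x2 association: cross-product odds ratio, 95% CI by the
    log-OR normal approximation, and a two-sided Fisher exact p-value.

    Any zero cell triggers the Haldane-Anscombe +0.5 correction for the
    OR and CI (flagged in the result); the Fisher p always uses the raw
    counts.
    """
    cells = (case_alt, case_ref, ctrl_alt, ctrl_ref)
    if any(c < 0 for c in cells):
        raise ValueError("counts must be non-negative")
    if case_alt + case_ref == 0 or ctrl_alt + ctrl_ref == 0:
        raise ValueError("both margins must be positive")
    corrected = any(c == 0 for c in cells)
    a, b, c, d = ((x + 0.5 for x in cells) if corrected else cells)
    odds_ratio = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.975)
    ci_low = math.exp(math.log(odds_ratio) - z * se)
    ci_high = math.exp(math.log(odds_ratio) + z * se)
    _, p = stats.fisher_exact(
        [[case_alt, case_ref], [ctrl_alt, ctrl_ref]], alternative="two-sided"
    )
    return AssocResult(
        odds_ratio=float(odds_ratio),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        p_value=float(p),
        counts=((case_alt, case_ref), (ctrl_alt, ctrl_ref)),
        continuity_corrected=corrected,
    )


# ---------------------------------------------------------------------------
# Report writers (tab-separated, mirroring the published table layouts)


def write_cohort_summary(summary: CohortSummary, dest) -> None:
    df = summary.per_family.rename(
        columns={
            "family_id": "Family",
            "n_affected": "No. of affected individuals",
            "n_suggestive": "No. of suggestive individuals",
            "n_unaffected": "No. of unaffected individuals",
            "n_segregating": "No. of segregating variants",
        }
    )
    df.to_csv(dest, sep="\t", index=False)


def write_shared_variant_report(reports: Sequence[SharedVariantReport], dest) -> None:
    rows = [
        {
            "Families": " + ".join(sorted(r.families)),
            "Chr": r.key[0],
            "Position": r.key[1],
            "Ref": r.key[2],
            "Alt": r.key[3],
            "Gene": r.gene or ".",
            "Homozygous carrier": "yes" if r.any_homozygous_carrier else "no",
        }
        for r in reports
    ]
    pd.DataFrame(
        rows,
        columns=["Families", "Chr", "Position", "Ref", "Alt", "Gene", "Homozygous carrier"],
    ).to_csv(dest, sep="\t", index=False)


def write_multigene_report(reports: Sequence[MultiVariantGeneReport], dest) -> None:
    rows = [
        {
            "Gene": r.gene,
            "Families": " + ".join(sorted(r.families)),
            "N variants": len(r.variants),
            "Variants": ";".join(variant_key_str(k) for k in r.variants),
        }
        for r in reports
    ]
    pd.DataFrame(
        rows, columns=["Gene", "Families", "N variants", "Variants"]
    ).to_csv(dest, sep="\t", index=False)
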