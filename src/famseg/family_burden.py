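"""Pedigree-aware gene-burden testing by gene-dropping permutation.

For a gene's qualifying rare variants, the observed statistic is

    S = sum over families [ (# genotyped affected carriers)
                            - (# genotyped non-exempt unaffected carriers) ]

where a carrier holds at least one alt allele of any qualifying variant.
The null distribution conditions on the observed founder genotypes —
appropriate for rare variants, where the variant's presence in a family
is a given — and re-transmits alleles through each pedigree under
Mendelian inheritance: every non-founder draws one allele uniformly from
each parent's two, independently across meioses and iterations. The
one-sided permutation p-value uses the add-one convention

    p = (1 + #{S_null >= S_obs}) / (n_iterations + 1)

so p is never 0 and never below 1/(n_iterations + 1).

Founders without an observed genotype are imputed hom-ref unless observed
carriage in the family's non-founders forces a carrier founder, in which
case one heterozygous founder is chosen uniformly per iteration among the
minimal explanations (unobserved founders ancestral to an observed
carrier). Suggestive individuals contribute to neither term of S.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .types import ConfigurationError, Pedigree, PedigreeIndividual, VariantRecord


@dataclass
class GeneDropConfig:
    n_iterations: int = 100_000
    seed: int = 0
    statistic: str = "affected_minus_unaffected_carriers"

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.statistic != "affected_minus_unaffected_carriers":
            raise ValueError(f"unknown statistic {self.statistic!r}")


@dataclass(frozen=True)
class BurdenResult:
    gene: str
    observed_statistic: int
    p_value: float
    n_iterations: int
    families_used: frozenset[str]
    skipped_families: frozenset[str] = frozenset()


def gene_rng(gene: str, seed: int) -> np.random.Generator:
    """Independent, order-invariant random stream for one gene."""
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(gene.encode())])
    )


# ---------------------------------------------------------------------------
# Gene dropping


def gene_drop(
    pedigree: Pedigree,
    founder_alt_counts: Mapping[str, int],
    rng: np.random.Generator,
) -> dict[str, int]:
    """One Mendelian drop of a single variant through a pedigree.

    Founders keep their assigned alt counts; each non-founder receives
    one allele drawn uniformly from each parent's two.
    """
    matrix = gene_drop_matrix(pedigree, founder_alt_counts, 1, rng)
    return {ind: int(counts[0]) for ind, counts in matrix.items()}


def gene_drop_matrix(
    pedigree: Pedigree,
    founder_alt_counts: Mapping[str, int | np.ndarray],
    n_iter: int,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Vectorised gene dropping: *n_iter* independent drops at once.

    Founder values may be scalars (held fixed across iterations) or
    per-iteration arrays of shape ``(n_iter,)``. A parent with alt count
    ``c`` transmits the alt allele with probability ``c/2`` at each
    meiosis, which is exact for unphased diploid counts.
    """
    counts: dict[str, np.ndarray] = {}
    for member in pedigree.topological_order():
        if member.is_founder:
            try:
                value = founder_alt_counts[member.individual_id]
            except KeyError:
                raise ConfigurationError(
                    f"founder {member.individual_id!r} has no assigned genotype"
                ) from None
            arr = np.asarray(value)
            counts[member.individual_id] = (
                np.full(n_iter, int(arr)) if arr.ndim == 0 else arr.astype(np.int64)
            )
        else:
            father = counts[member.father_id]
            mother = counts[member.mother_id]
            from_father = rng.random(n_iter) < father / 2.0
            from_mother = rng.random(n_iter) < mother / 2.0
            counts[member.individual_id] = (
                from_father.astype(np.int64) + from_mother.astype(np.int64)
            )
    return counts


# ---------------------------------------------------------------------------
# Burden test


def _founder_ancestors(pedigree: Pedigree) -> dict[str, set[str]]:
    anc: dict[str, set[str]] = {}
    for m in pedigree.topological_order():
        if m.is_founder:
            anc[m.individual_id] = {m.individual_id}
        else:
            anc[m.individual_id] = anc[m.father_id] | anc[m.mother_id]
    return anc


def _founder_counts_for_variant(
    pedigree: Pedigree,
    variant: VariantRecord,
    n_iter: int,
    rng: np.random.Generator,
) -> dict[str, int | np.ndarray]:
    """Observed founder genotypes, with unobserved founders imputed.

    Unobserved founders are hom-ref unless the variant is carried by an
    observed member with no observed carrier founder among its ancestors;
    then one unobserved founder ancestral to an observed carrier is set
    heterozygous, chosen uniformly per iteration.
    """
    observed: dict[str, int] = {}
    unobserved: list[str] = []
    for f in pedigree.founders:
        count = variant.sample_alt_counts.get(f.individual_id) if f.genotyped else None
        if count is None:
            unobserved.append(f.individual_id)
        else:
            observed[f.individual_id] = count
    counts: dict[str, int | np.ndarray] = dict(observed)
    for fid in unobserved:
        counts[fid] = 0
    if not unobserved:
        return counts
    any_founder_carrier = any(c >= 1 for c in observed.values())
    carriers = [
        m.individual_id
        for m in pedigree.members
        if not m.is_founder
        and m.genotyped
        and (variant.sample_alt_counts.get(m.individual_id) or 0) >= 1
    ]
    if any_founder_carrier or not carriers:
        return counts
    anc = _founder_ancestors(pedigree)
    carrier_ancestors = set().union(*(anc[c] for c in carriers))
    candidates = [fid for fid in unobserved if fid in carrier_ancestors]
    if not candidates:
        candidates = unobserved
    choice = rng.integers(len(candidates), size=n_iter)
    for i, fid in enumerate(candidates):
        arr = np.zeros(n_iter, dtype=np.int64)
        arr[choice == i] = 1
        counts[fid] = arr
    return counts


def _observed_statistic(
    pedigree: Pedigree, variants: Sequence[VariantRecord]
) -> int:
    s = 0
    for m in pedigree.genotyped_members():
        carrier = any(
            (v.sample_alt_counts.get(m.individual_id) or 0) >= 1 for v in variants
        )
        if not carrier:
            continue
        if m.phenotype == "affected":
            s += 1
        elif m.phenotype == "unaffected" and not m.penetrance_exempt:
            s -= 1
    return s


def _null_statistics(
    pedigree: Pedigree,
    variants: Sequence[VariantRecord],
    n_iter: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-iteration family contribution to S under re-dropped genotypes."""
    carrier = {
        m.individual_id: np.zeros(n_iter, dtype=bool)
        for m in pedigree.genotyped_members()
    }
    for variant in variants:
        founder_counts = _founder_counts_for_variant(pedigree, variant, n_iter, rng)
        dropped = gene_drop_matrix(pedigree, founder_counts, n_iter, rng)
        for ind in carrier:
            carrier[ind] |= dropped[ind] >= 1
    s = np.zeros(n_iter, dtype=np.int64)
    for m in pedigree.genotyped_members():
        if m.phenotype == "affected":
            s += carrier[m.individual_id]
        elif m.phenotype == "unaffected" and not m.penetrance_exempt:
            s -= carrier[m.individual_id]
    return s


def family_burden_test(
    gene: str,
    qualifying_variants: Sequence[VariantRecord],
    pedigrees: Sequence[Pedigree],
    cfg: Optional[GeneDropConfig] = None,
) -> BurdenResult:
    """Gene-dropping permutation burden test for one gene.

    *qualifying_variants* are the gene's rare variants surviving the
    variant-level cascade (before any segregation filtering); observed
    genotypes travel inside the records. Families with no genotyped
    member are skipped and reported in ``skipped_families``.
    """
    cfg = cfg or GeneDropConfig()
    rng = gene_rng(gene, cfg.seed)
    usable = [p for p in pedigrees if p.genotyped_members()]
    skipped = frozenset(p.family_id for p in pedigrees) - frozenset(
        p.family_id for p in usable
    )
    if not qualifying_variants or not usable:
        return BurdenResult(
            gene=gene,
            observed_statistic=0,
            p_value=1.0,
            n_iterations=cfg.n_iterations,
            families_used=frozenset(p.family_id for p in usable),
            skipped_families=skipped,
        )
    s_obs = sum(_observed_statistic(p, qualifying_variants) for p in usable)
    s_null = np.zeros(cfg.n_iterations, dtype=np.int64)
    for ped in usable:
        s_null += _null_statistics(ped, qualifying_variants, cfg.n_iterations, rng)
    n_ge = int(np.count_nonzero(s_null >= s_obs))
    p = (1 + n_ge) / (cfg.n_iterations + 1)
    return BurdenResult(
        gene=gene,
        observed_statistic=int(s_obs),
        p_value=float(p),
        n_iterations=cfg.n_iterations,
        families_used=frozenset(p.family_id for p in usable),
        skipped_families=skipped,
    )


def burden_scan(
    variants_by_gene: Mapping[str, Sequence[VariantRecord]],
    pedigrees: Sequence[Pedigree],
    cfg: Optional[GeneDropConfig] = None,
) -> list[BurdenResult]:
    """Run the burden test over many genes; per-gene random streams are
    derived from the master seed, so results do not depend on gene order."""
    cfg = cfg or GeneDropConfig()
    return [
        family_burden_test(gene, list(variants), pedigrees, cfg)
        for gene, variants in sorted(variants_by_gene.items())
    ]
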