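"""Dataset-level quality steps applied before rare-variant filtering.

Order of operations on a joint called dataset:

1. multiallelic sites are decomposed into biallelic records, with shared
   leading/trailing bases trimmed;
2. variants inside low-complexity regions (LCRs) are removed;
3. variants out of Hardy-Weinberg equilibrium (exact-test p below a
   threshold, default 1e-8, strict ``<``) are removed;
4. variants with minor allele count 0 among the family samples are removed.

The HWE test here is the conditional exact test: with allele counts fixed,
the p-value sums the probabilities of every heterozygote count whose
hypergeometric probability does not exceed that of the observed count.
It is computed over all genotyped samples of the joint input by default;
relatedness between family members biases it toward heterozygote excess,
which is why the threshold is extreme and the sample set configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy.special import gammaln

from .types import (
    AnnotatedVariant,
    ConfigurationError,
    ConsistencyError,
    RawSite,
    VariantRecord,
)
from . import io_formats


@dataclass(frozen=True)
class GenotypeCounts:
    """Diploid genotype counts at one biallelic site (missing excluded)."""

    n_hom_ref: int
    n_het: int
    n_hom_alt: int

    def __post_init__(self) -> None:
        if min(self.n_hom_ref, self.n_het, self.n_hom_alt) < 0:
            raise ValueError("genotype counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_hom_ref + self.n_het + self.n_hom_alt

    @classmethod
    def from_record(
        cls, record: VariantRecord, samples: Optional[Iterable[str]] = None
    ) -> "GenotypeCounts":
        ids = record.sample_alt_counts.keys() if samples is None else samples
        tally = [0, 0, 0]
        for s in ids:
            c = record.sample_alt_counts.get(s)
            if c is not None:
                tally[c] += 1
        return cls(*tally)


class RegionSet:
    """Genomic intervals (0-based half-open), sorted and merged per chromosome."""

    def __init__(self, intervals: Mapping[str, Sequence[tuple[int, int]]]):
        self._trees: dict[str, IntervalTree] = {}
        for chrom, ivs in intervals.items():
            tree = IntervalTree.from_tuples(ivs)
            tree.merge_overlaps(strict=False)
            self._trees[chrom] = tree

    @classmethod
    def from_bed(cls, bed_source) -> "RegionSet":
        return cls(io_formats.read_bed(bed_source))

    @property
    def intervals(self) -> dict[str, list[tuple[int, int]]]:
        return {
            chrom: sorted((iv.begin, iv.end) for iv in tree)
            for chrom, tree in self._trees.items()
        }

    def contains(self, chrom: str, pos: int) -> bool:
        """True if the 1-based position *pos* falls inside any interval."""
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlaps_point(pos - 1))

    def __len__(self) -> int:
        return sum(len(t) for t in self._trees.values())


# ---------------------------------------------------------------------------
# Multiallelic decomposition


def trim_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Trim shared leading then trailing bases, keeping at least one base
    of each allele; the position advances by the number of leading bases
    removed. (No reference-genome left-alignment is attempted.)"""
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    return pos, ref, alt


def decompose_multiallelic(raw_site: RawSite) -> list[VariantRecord]:
    """Split a multi-alt site into one biallelic record per alt allele.

    For record *k*, each sample's alt count is the number of allele-*k*
    copies in its original genotype; genotypes with any missing allele
    are recorded as missing. Alleles are prefix/suffix trimmed.
    """
    n_alleles = 1 + len(raw_site.alts)
    for sample, pair in raw_site.genotypes.items():
        for a in pair:
            if a is not None and not (0 <= a < n_alleles):
                raise ConsistencyError(
                    f"{raw_site.chrom}:{raw_site.pos} sample {sample}: "
                    f"allele index {a} out of range"
                )
    records = []
    for k, alt in enumerate(raw_site.alts, start=1):
        counts: dict[str, Optional[int]] = {}
        for sample, pair in raw_site.genotypes.items():
            if any(a is None for a in pair):
                counts[sample] = None
            else:
                counts[sample] = sum(1 for a in pair if a == k)
        pos, ref, alt_trimmed = trim_alleles(raw_site.pos, raw_site.ref, alt)
        records.append(
            VariantRecord(
                chrom=raw_site.chrom,
                pos=pos,
                ref=ref,
                alt=alt_trimmed,
                rsid=raw_site.rsid,
                sample_alt_counts=counts,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def hwe_exact_p(counts: GenotypeCounts) -> float:
    """Conditional exact Hardy-Weinberg test p-value.

    With the allele counts fixed, each possible heterozygote count ``h``
    (same parity as the minor allele count) has probability

        P(h) = 2^h * n! / (n_rr! h! n_cc!) * nA! * na! / (2n)!

    and the p-value is the total probability of all ``h`` whose P is at
    most that of the observed count. Monomorphic sites return 1.0.
    """
    n = counts.total
    if n == 0:
        raise ValueError("total genotype count must be positive")
    n_a = 2 * counts.n_hom_alt + counts.n_het  # alt allele copies
    n_r = 2 * counts.n_hom_ref + counts.n_het
    n_rare = min(n_a, n_r)
    if n_rare == 0:
        return 1.0
    n_common = 2 * n - n_rare  # canonical (rare, common) order keeps the
    hets = np.arange(n_rare % 2, n_rare + 1, 2)  # result exactly label-symmetric
    hom_rare = (n_rare - hets) // 2
    hom_common = (n_common - hets) // 2
    log_probs = (
        hets * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(hom_rare + 1)
        - gammaln(hets + 1)
        - gammaln(hom_common + 1)
        + gammaln(n_rare + 1)
        + gammaln(n_common + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(log_probs - log_probs.max())
    probs /= probs.sum()
    obs = probs[hets == counts.n_het][0]
    # tolerance absorbs float noise in the <= comparison of tied outcomes
    p = probs[probs <= obs * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


# ---------------------------------------------------------------------------
# QC prefilter


def qc_prefilter(
    dataset: Sequence[AnnotatedVariant],
    lcr: RegionSet,
    hwe_threshold: float,
    family_samples: Iterable[str],
    hwe_samples: Optional[Iterable[str]] = None,
) -> tuple[list[AnnotatedVariant], dict[str, int]]:
    """Apply LCR, HWE, and minor-allele-count rules to a decomposed dataset.

    *family_samples* defines the sample set for the MAC >= 1 restriction;
    *hwe_samples* (default: every sample present in each record) defines
    the genotype pool for the HWE test. Returns the retained dataset and
    a per-rule removal tally; each variant is tallied at most once, under
    the first rule it fails (order: lcr, hwe, mac).
    """
    family_samples = list(family_samples)
    if not family_samples:
        raise ConfigurationError("family_samples must be non-empty")
    hwe_sample_list = None if hwe_samples is None else list(hwe_samples)
    tally = {"lcr": 0, "hwe": 0, "mac": 0, "retained": 0}
    retained: list[AnnotatedVariant] = []
    for rec, ann in dataset:
        if lcr.contains(rec.chrom, rec.pos):
            tally["lcr"] += 1
            continue
        counts = GenotypeCounts.from_record(rec, hwe_sample_list)
        if counts.total > 0 and hwe_exact_p(counts) < hwe_threshold:
            tally["hwe"] += 1
            continue
        alt_copies = 0
        ref_copies = 0
        for s in family_samples:
            c = rec.sample_alt_counts.get(s)
            if c is not None:
                alt_copies += c
                ref_copies += 2 - c
        if min(alt_copies, ref_copies) < 1:
            tally["mac"] += 1
            continue
        tally["retained"] += 1
        retained.append((rec, ann))
    return retained, tally
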