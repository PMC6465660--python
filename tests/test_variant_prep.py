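from fractions import Fraction
from math import factorial

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from famseg.types import ConfigurationError, ConsistencyError, RawSite, VariantRecord
from famseg.variant_prep import (
    GenotypeCounts,
    RegionSet,
    decompose_multiallelic,
    hwe_exact_p,
    qc_prefilter,
    trim_alleles,
)


def hwe_enumeration_oracle(a: int, h: int, b: int) -> float:
    """Exact-rational enumeration over all heterozygote counts with the
    allele counts fixed; independent of the log-gamma implementation."""
    n = a + h + b
    n_alt, n_ref = 2 * b + h, 2 * a + h
    n_rare = min(n_alt, n_ref)
    if n_rare == 0:
        return 1.0
    weights = {}
    for k in range(n_rare % 2, n_rare + 1, 2):
        hom_r = (n_rare - k) // 2
        hom_c = n - hom_r - k
        weights[k] = (
            2**k * factorial(n) // (factorial(hom_r) * factorial(k) * factorial(hom_c))
        )
    total = sum(weights.values())
    w_obs = weights[h]
    return float(Fraction(sum(w for w in weights.values() if w <= w_obs), total))


class TestDecompose:
    def test_biallelic_identity(self):
        site = RawSite("1", 50, "A", ["T"], "rs9", {"s1": (0, 1), "s2": (1, 1)})
        (rec,) = decompose_multiallelic(site)
        assert (rec.chrom, rec.pos, rec.ref, rec.alt, rec.rsid) == ("1", 50, "A", "T", "rs9")
        assert rec.sample_alt_counts == {"s1": 1, "s2": 2}

    def test_mixed_genotype_split(self):
        # GT 1/2 at a triallelic site: one copy of each alt
        site = RawSite("2", 10, "A", ["C", "T"], None, {"s1": (1, 2), "s2": (0, 2)})
        rec_c, rec_t = decompose_multiallelic(site)
        assert rec_c.alt == "C" and rec_c.sample_alt_counts == {"s1": 1, "s2": 0}
        assert rec_t.alt == "T" and rec_t.sample_alt_counts == {"s1": 1, "s2": 1}

    def test_trimming_advances_position(self):
        site = RawSite("3", 100, "ACG", ["AG"], None, {"s1": (0, 1)})
        (rec,) = decompose_multiallelic(site)
        assert (rec.pos, rec.ref, rec.alt) == (101, "CG", "G")

    def test_half_missing_becomes_missing(self):
        site = RawSite("1", 5, "A", ["G"], None, {"s1": (0, None)})
        (rec,) = decompose_multiallelic(site)
        assert rec.sample_alt_counts["s1"] is None

    def test_out_of_range_allele_index(self):
        site = RawSite("1", 5, "A", ["G"], None, {"s1": (0, 3)})
        with pytest.raises(ConsistencyError):
            decompose_multiallelic(site)

    @given(
        n_alts=st.integers(1, 3),
        gts=st.lists(st.tuples(st.integers(0, 3), st.integers(0, 3)), min_size=1, max_size=8),
    )
    @settings(max_examples=200, deadline=None)
    def test_alt_copy_conservation(self, n_alts, gts):
        """Summed over emitted records, alt counts equal the original
        site's non-ref allele copies."""
        genotypes = {
            f"s{i}": (min(a, n_alts), min(b, n_alts)) for i, (a, b) in enumerate(gts)
        }
        site = RawSite("1", 100, "A", ["C", "G", "T"][:n_alts], None, genotypes)
        records = decompose_multiallelic(site)
        for sample, (a, b) in genotypes.items():
            original_nonref = sum(1 for x in (a, b) if x != 0)
            assert sum(r.sample_alt_counts[sample] for r in records) == original_nonref


def _independent_trim(pos, ref, alt):
    """Character-list reimplementation of prefix/suffix trimming."""
    r, a = list(ref), list(alt)
    while len(r) > 1 and len(a) > 1 and r[0] == a[0]:
        r.pop(0)
        a.pop(0)
        pos += 1
    while len(r) > 1 and len(a) > 1 and r[-1] == a[-1]:
        r.pop()
        a.pop()
    return pos, "".join(r), "".join(a)


@given(
    pos=st.integers(1, 1000),
    ref=st.text(alphabet="ACGT", min_size=1, max_size=6),
    alt=st.text(alphabet="ACGT", min_size=1, max_size=6),
)
@settings(max_examples=300, deadline=None)
def test_trim_matches_independent_routine(pos, ref, alt):
    if ref == alt:
        return
    assert trim_alleles(pos, ref, alt) == _independent_trim(pos, ref, alt)


class TestHweExact:
    def test_monomorphic_site_is_in_equilibrium(self):
        assert hwe_exact_p(GenotypeCounts(10, 0, 0)) == 1.0
        assert hwe_exact_p(GenotypeCounts(0, 0, 7)) == 1.0

    def test_extreme_heterozygote_excess(self):
        # frozen from the exact-rational enumeration oracle
        assert hwe_exact_p(GenotypeCounts(1, 98, 1)) == pytest.approx(
            4.023545294005432e-26, rel=1e-10
        )

    @given(a=st.integers(0, 40), h=st.integers(0, 40), b=st.integers(0, 40))
    @settings(max_examples=200, deadline=None)
    def test_allele_label_symmetry(self, a, h, b):
        if a + h + b == 0:
            return
        assert hwe_exact_p(GenotypeCounts(a, h, b)) == hwe_exact_p(GenotypeCounts(b, h, a))

    def test_matches_enumeration_small_sweep(self):
        """Exhaustive agreement with the enumeration oracle up to n=60
        (the full n<=200 sweep runs in the acceptance suite)."""
        for n in range(1, 61):
            for n_alt in range(0, n + 1):
                for h in range(n_alt % 2, n_alt + 1, 2):
                    b = (n_alt - h) // 2
                    a = n - b - h
                    assert hwe_exact_p(GenotypeCounts(a, h, b)) == pytest.approx(
                        hwe_enumeration_oracle(a, h, b), abs=1e-12
                    )

    def test_rejects_empty_and_negative(self):
        with pytest.raises(ValueError):
            hwe_exact_p(GenotypeCounts(0, 0, 0))
        with pytest.raises(ValueError):
            GenotypeCounts(-1, 2, 0)


def _rec(chrom, pos, counts):
    return VariantRecord(chrom=chrom, pos=pos, ref="A", alt="G", sample_alt_counts=counts)


class TestQcPrefilter:
    lcr = RegionSet({"1": [(1000, 2000)]})

    def test_lcr_containment(self):
        inside = _rec("1", 1001, {"s1": 1, "s2": 0})  # 1-based 1001 = 0-based 1000
        outside = _rec("1", 2001, {"s1": 1, "s2": 0})
        kept, tally = qc_prefilter(
            [(inside, None), (outside, None)], self.lcr, 1e-8, ["s1", "s2"]
        )
        assert [r.pos for r, _ in kept] == [2001]
        assert tally["lcr"] == 1

    def test_all_hom_ref_removed_as_mac(self):
        rec = _rec("2", 5, {"s1": 0, "s2": 0})
        kept, tally = qc_prefilter([(rec, None)], self.lcr, 1e-8, ["s1", "s2"])
        assert kept == [] and tally["mac"] == 1

    def test_hwe_threshold_is_strict(self):
        """A variant whose HWE p equals the threshold exactly is retained."""
        counts = {f"s{i}": 1 for i in range(30)}  # universal heterozygosity
        rec = _rec("2", 5, counts)
        p = hwe_exact_p(GenotypeCounts.from_record(rec))
        kept_eq, _ = qc_prefilter([(rec, None)], self.lcr, p, list(counts))
        assert len(kept_eq) == 1
        kept_above, tally = qc_prefilter([(rec, None)], self.lcr, p * (1 + 1e-9), list(counts))
        assert kept_above == [] and tally["hwe"] == 1

    def test_idempotent(self, study_cohort):
        lcr = RegionSet(study_cohort.lcr_intervals)
        dataset = study_cohort.dataset()
        once, tally1 = qc_prefilter(dataset, lcr, 1e-8, study_cohort.samples)
        twice, tally2 = qc_prefilter(once, lcr, 1e-8, study_cohort.samples)
        assert twice == once
        assert tally2["retained"] == tally1["retained"] == len(once)

    def test_empty_family_samples_is_error(self):
        with pytest.raises(ConfigurationError):
            qc_prefilter([], self.lcr, 1e-8, [])
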