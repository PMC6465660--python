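import itertools
import math

import numpy as np
import pytest

from famseg.family_burden import (
    GeneDropConfig,
    family_burden_test,
    gene_drop,
    gene_drop_matrix,
    gene_rng,
)
from famseg.types import ConfigurationError, Pedigree, PedigreeIndividual, VariantRecord


def nuclear_family(n_children, phenotypes=None, family_id="F1", genotyped_parents=True):
    phenotypes = phenotypes or ["affected"] * n_children
    members = [
        PedigreeIndividual(family_id, "p1", sex="male", phenotype="unknown",
                           genotyped=genotyped_parents),
        PedigreeIndividual(family_id, "p2", sex="female", phenotype="unknown",
                           genotyped=genotyped_parents),
    ]
    for i, pheno in enumerate(phenotypes):
        members.append(
            PedigreeIndividual(family_id, f"c{i}", father_id="p1", mother_id="p2",
                               phenotype=pheno)
        )
    return Pedigree(family_id=family_id, members=members)


class TestGeneDrop:
    def test_nothing_to_transmit(self, rng):
        ped = nuclear_family(3)
        dropped = gene_drop(ped, {"p1": 0, "p2": 0}, rng)
        assert all(v == 0 for v in dropped.values())

    def test_homozygous_founder_obligate_transmission(self, rng):
        ped = nuclear_family(4)
        for _ in range(50):
            dropped = gene_drop(ped, {"p1": 2, "p2": 0}, rng)
            assert all(dropped[f"c{i}"] >= 1 for i in range(4))

    def test_het_founder_transmits_to_half_of_meioses(self, rng):
        ped = nuclear_family(1)
        n = 10_000
        counts = gene_drop_matrix(ped, {"p1": 1, "p2": 0}, n, rng)
        frac = np.mean(counts["c0"] >= 1)
        se = math.sqrt(0.25 / n)
        assert abs(frac - 0.5) <= 3 * se

    def test_unassigned_founder_is_an_error(self, rng):
        with pytest.raises(ConfigurationError):
            gene_drop(nuclear_family(1), {"p1": 1}, rng)


def _variant(counts, pos=500):
    return VariantRecord(chrom="7", pos=pos, ref="C", alt="T", sample_alt_counts=counts)


def exact_tail_probability(pedigree, variant, s_obs):
    """Exact P(S_null >= s_obs) by enumeration over every transmission
    pattern (one bit per meiosis per parental allele)."""
    order = pedigree.topological_order()
    non_founders = [m for m in order if not m.is_founder]
    founder_counts = {
        f.individual_id: variant.sample_alt_counts.get(f.individual_id) or 0
        for f in pedigree.founders
    }
    total = 0.0
    n_meioses = 2 * len(non_founders)
    for bits in itertools.product([0, 1], repeat=n_meioses):
        counts = dict(founder_counts)
        for j, m in enumerate(non_founders):
            b_f, b_m = bits[2 * j], bits[2 * j + 1]
            # bit selects one of the parent's two alleles; with count c the
            # chosen allele is alt iff its index < c
            counts[m.individual_id] = int(b_f < counts[m.father_id]) + int(
                b_m < counts[m.mother_id]
            )
        s = 0
        for m in pedigree.genotyped_members():
            if counts[m.individual_id] >= 1:
                if m.phenotype == "affected":
                    s += 1
                elif m.phenotype == "unaffected" and not m.penetrance_exempt:
                    s -= 1
        if s >= s_obs:
            total += 1
    return total / 2**n_meioses


class TestBurdenTest:
    def test_no_carriers_gives_p_one(self):
        ped = nuclear_family(2)
        v = _variant({m.individual_id: 0 for m in ped.members})
        res = family_burden_test("G", [v], [ped], GeneDropConfig(1000, seed=3))
        assert res.observed_statistic == 0
        assert res.p_value == 1.0

    def test_empty_variant_set_is_defined(self):
        res = family_burden_test("G", [], [nuclear_family(2)], GeneDropConfig(100, 1))
        assert res.observed_statistic == 0 and res.p_value == 1.0

    def test_three_affected_carrier_children_matches_exact_eighth(self):
        """Het founder, three affected carrier children: the Monte-Carlo p
        agrees with the exact transmission probability (1/2)^3 within
        three Monte-Carlo standard errors at 1e5 iterations."""
        ped = nuclear_family(3)
        v = _variant({"p1": 1, "p2": 0, "c0": 1, "c1": 1, "c2": 1})
        n = 100_000
        res = family_burden_test("G", [v], [ped], GeneDropConfig(n, seed=9))
        assert res.observed_statistic == 3
        se = math.sqrt(0.125 * 0.875 / n)
        assert abs(res.p_value - 0.125) <= 3 * se

    def test_matches_exact_enumeration_on_small_pedigrees(self):
        """MC p converges to the enumeration oracle on pedigrees with
        few meioses (mixed phenotypes, 8 meioses)."""
        ped = nuclear_family(
            4, ["affected", "affected", "unaffected", "suggestive"]
        )
        v = _variant({"p1": 1, "p2": 0, "c0": 1, "c1": 1, "c2": 0, "c3": 1})
        s_obs = 2
        exact = exact_tail_probability(ped, v, s_obs)
        n = 100_000
        res = family_burden_test("G", [v], [ped], GeneDropConfig(n, seed=21))
        assert res.observed_statistic == s_obs
        se = math.sqrt(exact * (1 - exact) / n)
        assert abs(res.p_value - exact) <= 3 * se

    def test_determinism_and_gene_stream_independence(self):
        ped = nuclear_family(3)
        v = _variant({"p1": 1, "p2": 0, "c0": 1, "c1": 1, "c2": 1})
        cfg = GeneDropConfig(5000, seed=4)
        r1 = family_burden_test("G", [v], [ped], cfg)
        r2 = family_burden_test("G", [v], [ped], cfg)
        assert r1.p_value == r2.p_value
        r3 = family_burden_test("OTHER", [v], [ped], cfg)
        assert r3.p_value != r1.p_value or r3.gene != r1.gene

    def test_extra_affected_carrier_never_increases_p(self):
        """With founder genotypes (and hence the null) fixed, observing
        one more affected carrier child can only shrink the p-value."""
        phenos = ["affected"] * 4
        ped = nuclear_family(4, phenos)
        base_counts = {"p1": 1, "p2": 0, "c0": 1, "c1": 1, "c2": 0, "c3": 0}
        more_counts = dict(base_counts, c2=1)
        cfg = GeneDropConfig(20_000, seed=12)
        p_base = family_burden_test("G", [_variant(base_counts)], [ped], cfg).p_value
        p_more = family_burden_test("G", [_variant(more_counts)], [ped], cfg).p_value
        assert p_more <= p_base

    def test_ungenotyped_family_skipped(self):
        ped = nuclear_family(2)
        for m in ped.members:
            m.genotyped = False
        res = family_burden_test("G", [_variant({})], [ped], GeneDropConfig(100, 1))
        assert res.skipped_families == {"F1"}

    def test_forced_carrier_founder_imputation(self):
        """Carrier children with ungenotyped founders force one imputed
        heterozygous founder, so the null can reach the observed S."""
        ped = nuclear_family(3, genotyped_parents=False)
        v = _variant({"c0": 1, "c1": 1, "c2": 1})
        res = family_burden_test("G", [v], [ped], GeneDropConfig(10_000, seed=2))
        assert res.observed_statistic == 3
        # a single het founder transmits to all three children w.p. 1/8
        se = math.sqrt(0.125 * 0.875 / 10_000)
        assert abs(res.p_value - 0.125) <= 4 * se

    def test_p_floor_respected(self):
        ped = nuclear_family(3)
        v = _variant({"p1": 1, "p2": 0, "c0": 1, "c1": 1, "c2": 1})
        res = family_burden_test("G", [v], [ped], GeneDropConfig(50, seed=8))
        assert res.p_value >= 1 / 51


def test_gene_rng_is_order_invariant():
    a = gene_rng("ABC", 7).integers(0, 1000, 5)
    b = gene_rng("ABC", 7).integers(0, 1000, 5)
    c = gene_rng("XYZ", 7).integers(0, 1000, 5)
    assert np.array_equal(a, b)
    assert not np.array_equal(a, c)
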