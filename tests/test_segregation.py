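import pytest

from famseg.rare_filter import apply_rare_filters
from famseg.segregation import (
    MissingGenotypePolicy,
    NotEvaluableError,
    classify_segregation,
    remove_global_unaffected_carriers,
    segregating_variants,
)
from famseg.types import Pedigree, PedigreeIndividual, VariantAnnotation, VariantRecord
from famseg.variant_prep import RegionSet, qc_prefilter


def make_family(family_id, phenotypes, exempt=()):
    """A nuclear family: two founder parents plus one child per phenotype
    entry; children are named c0, c1, ... and all members genotyped."""
    members = [
        PedigreeIndividual(family_id, f"{family_id}_p1", sex="male", phenotype="unknown"),
        PedigreeIndividual(family_id, f"{family_id}_p2", sex="female", phenotype="unknown"),
    ]
    for i, pheno in enumerate(phenotypes):
        members.append(
            PedigreeIndividual(
                family_id,
                f"{family_id}_c{i}",
                father_id=f"{family_id}_p1",
                mother_id=f"{family_id}_p2",
                phenotype=pheno,
                penetrance_exempt=f"{family_id}_c{i}" in exempt,
            )
        )
    return Pedigree(family_id=family_id, members=members)


def variant(counts, pos=100):
    return VariantRecord(chrom="1", pos=pos, ref="A", alt="G", sample_alt_counts=counts)


class TestGlobalUnaffectedRemoval:
    fam = make_family("F1", ["affected", "unaffected", "suggestive"])

    def test_unaffected_carrier_triggers_removal(self):
        v = variant({"F1_c0": 1, "F1_c1": 1})
        assert remove_global_unaffected_carriers([(v, None)], [self.fam]) == []

    def test_exempt_unaffected_carrier_is_ignored(self):
        fam = make_family("F14", ["affected", "unaffected"], exempt=("F14_c1",))
        v = variant({"F14_c0": 1, "F14_c1": 1})
        assert len(remove_global_unaffected_carriers([(v, None)], [fam])) == 1

    def test_suggestive_carrier_never_triggers_removal(self):
        v = variant({"F1_c2": 1})
        assert len(remove_global_unaffected_carriers([(v, None)], [self.fam])) == 1

    def test_removal_spans_families(self):
        other = make_family("F2", ["unaffected"])
        v = variant({"F1_c0": 1, "F2_c0": 1})
        assert remove_global_unaffected_carriers([(v, None)], [self.fam, other]) == []


class TestClassify:
    def test_segregates(self):
        fam = make_family("F1", ["affected", "affected", "unaffected"])
        v = variant({"F1_c0": 1, "F1_c1": 1, "F1_c2": 0})
        assert classify_segregation(fam, v).status == "segregates"

    def test_affected_noncarrier_fails(self):
        fam = make_family("F1", ["affected", "affected"])
        v = variant({"F1_c0": 1, "F1_c1": 0})
        assert classify_segregation(fam, v).status == "fails"

    def test_homozygous_affected_with_het_unaffected_is_incomplete(self):
        fam = make_family("F1", ["affected", "unaffected", "unaffected"])
        v = variant({"F1_c0": 2, "F1_c1": 1, "F1_c2": 1})
        assert classify_segregation(fam, v).status == "incomplete"

    def test_no_genotyped_affected_is_not_evaluable(self):
        fam = make_family("F1", ["unaffected"])
        with pytest.raises(NotEvaluableError):
            classify_segregation(fam, variant({"F1_c0": 0}))

    def test_missing_genotype_in_affected_blocks_by_default(self):
        fam = make_family("F1", ["affected", "affected"])
        v = variant({"F1_c0": 1, "F1_c1": None})
        assert classify_segregation(fam, v).status == "fails"
        lenient = MissingGenotypePolicy(affected_missing_fails=False)
        assert classify_segregation(fam, v, lenient).status == "segregates"


class TestSegregatingVariants:
    def test_single_affected_no_unaffected_is_vacuously_segregating(self):
        fam = make_family("F1", ["affected"])
        results = segregating_variants([fam], [(variant({"F1_c0": 1}), None)])
        assert results[0].variants == [("1", 100, "A", "G")]

    def test_planted_variant_found_only_in_target_families(self, study_cohort):
        dataset = _pipeline_to_segregation(study_cohort)
        results = segregating_variants(study_cohort.pedigrees, dataset)
        by_family = {r.family_id: set(r.variants) for r in results}
        truth = study_cohort.truth
        planted = truth[(truth.kind == "planted") & (truth.expected_rule == "segregates")]
        from famseg.types import parse_variant_key

        for row in planted.itertuples(index=False):
            key = parse_variant_key(row.variant)
            targets = set(row.target_families.split(";"))
            for fam_id, seen in by_family.items():
                assert (key in seen) == (fam_id in targets)

    def test_counts_match_brute_force_recount(self, study_cohort):
        """Per-family segregating sets equal a direct nested-loop
        evaluation of the carrier rule."""
        dataset = _pipeline_to_segregation(study_cohort)
        results = segregating_variants(study_cohort.pedigrees, dataset)
        for ped, res in zip(study_cohort.pedigrees, results):
            affected = [m.individual_id for m in ped.genotyped_members("affected")]
            unaffected = [
                m.individual_id
                for m in ped.genotyped_members("unaffected")
                if not m.penetrance_exempt
            ]
            expected = set()
            if affected:
                for rec, _ in dataset:
                    carries = lambda s: (rec.sample_alt_counts.get(s) or 0) >= 1
                    if all(
                        rec.sample_alt_counts.get(s) is not None and carries(s)
                        for s in affected
                    ) and not any(carries(s) for s in unaffected):
                        expected.add(rec.key)
            assert set(res.variants) == expected

    def test_removing_unaffected_member_never_shrinks_result(self, study_cohort):
        dataset = _pipeline_to_segregation(study_cohort)
        for ped in study_cohort.pedigrees:
            unaffected = ped.genotyped_members("unaffected")
            leaves = [
                m for m in unaffected
                if not any(x.father_id == m.individual_id or x.mother_id == m.individual_id
                           for x in ped.members)
            ]
            if not leaves:
                continue
            drop = leaves[0].individual_id
            reduced = Pedigree(
                family_id=ped.family_id,
                members=[m for m in ped.members if m.individual_id != drop],
            )
            before = set(segregating_variants([ped], dataset)[0].variants)
            after = set(segregating_variants([reduced], dataset)[0].variants)
            assert before <= after

    def test_stage_order_is_immaterial(self, study_cohort):
        """Global unaffected-carrier removal before per-family calls and
        the merged single pass retain identical per-family sets."""
        cohort = study_cohort
        dataset = _cascade_output(cohort)
        two_stage = segregating_variants(
            cohort.pedigrees, remove_global_unaffected_carriers(dataset, cohort.pedigrees)
        )
        merged = segregating_variants(cohort.pedigrees, dataset)
        blockers = {
            m.individual_id
            for ped in cohort.pedigrees
            for m in ped.genotyped_members("unaffected")
            if not m.penetrance_exempt
        }
        for res_two, res_one in zip(two_stage, merged):
            filtered = {
                k for k in res_one.variants
                if not any(
                    (rec.sample_alt_counts.get(s) or 0) >= 1
                    for rec, _ in dataset
                    if rec.key == k
                    for s in blockers
                )
            }
            assert set(res_two.variants) == filtered


def _cascade_output(cohort):
    lcr = RegionSet(cohort.lcr_intervals)
    prepped, _ = qc_prefilter(cohort.dataset(), lcr, 1e-8, cohort.samples)
    retained, _ = apply_rare_filters(prepped, cohort.pedigrees)
    return retained


def _pipeline_to_segregation(cohort):
    return remove_global_unaffected_carriers(_cascade_output(cohort), cohort.pedigrees)
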