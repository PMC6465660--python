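"""Synthetic multi-family exome cohorts for end-to-end testing.

The generator emulates the shape of a familial exome study: a cohort of
families of 2-7 genotyped members spanning 2-4 generations, a three-state
affection status (affected / suggestive / unaffected), rare heterozygous
protein-altering variants planted so that they segregate with affection
status under configurable penetrance, and background variants dropped
through the pedigrees from founder genotypes sampled at each variant's
population frequency (so Hardy-Weinberg holds for founders in
expectation).

A set of deliberate filter violators — synonymous, common, low-CADD,
LCR-resident, Hardy-Weinberg-violating, actionable-gene, and
zero-minor-allele-count variants, each passing every other rule — makes
every removal tally nonzero, and a truth table records each planted or
violator variant's expected pipeline fate.

Genotypes are simulated directly at the called-VCF level; no sequence
reads, linkage disequilibrium, or realistic exome site density are
modelled.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io_formats
from .family_burden import gene_drop_matrix
from .types import (
    ConfigurationError,
    Pedigree,
    PedigreeIndividual,
    VariantAnnotation,
    VariantKey,
    VariantRecord,
    variant_key_str,
    DEFAULT_AF_SOURCES,
)

#: Reserved chromosome carrying the synthetic low-complexity region.
LCR_CHROM = "22"
LCR_INTERVALS = {LCR_CHROM: [(10_000_000, 10_100_000)]}

PLANT_MODES = ("fully_segregating", "incomplete", "null")


@dataclass(frozen=True)
class PlantSpec:
    """One variant planted with a phenotype-linked carrier pattern.

    ``fully_segregating`` satisfies the segregation rule in every target
    family; ``incomplete`` additionally places one unaffected carrier;
    ``null`` assigns carriers independently of phenotype cohort-wide.
    """

    target_families: tuple[str, ...]
    gene: str
    effect: str = "nonsynonymous"
    cadd: Optional[float] = 25.0
    population_af: float = 0.002
    mode: str = "fully_segregating"

    def __post_init__(self) -> None:
        if self.mode not in PLANT_MODES:
            raise ValueError(f"unknown plant mode {self.mode!r}")
        if self.population_af > 0.01:
            raise ValueError("planted variants must be rare (AF <= 0.01)")
        is_indel = "indel" in self.effect
        if self.cadd is None and not is_indel:
            raise ValueError("missing CADD is only allowed for indel effects")


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror an 18-family cohort of 72 genotyped individuals with
    a roughly 46/25/29 split of affected / suggestive / unaffected, the
    phenotype mix of the familial chorioretinopathy study design this
    package targets.
    """

    n_families: int = 18
    family_size_range: tuple[int, int] = (2, 7)
    generations_range: tuple[int, int] = (2, 4)
    affected_fraction_target: float = 0.46
    suggestive_fraction: float = 0.25
    n_background_variants: int = 300
    background_maf_range: tuple[float, float] = (1e-4, 0.2)
    planted_variants: tuple[PlantSpec, ...] = ()
    penetrance: float = 1.0
    missing_genotype_rate: float = 0.01
    n_violators_per_rule: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.family_size_range
        if not (1 <= lo <= hi):
            raise ConfigurationError("family_size_range must be ordered and positive")
        glo, ghi = self.generations_range
        if not (2 <= glo <= ghi <= 4):
            raise ConfigurationError("generations must lie in 2..4")
        for frac in (
            self.affected_fraction_target,
            self.suggestive_fraction,
            self.penetrance,
            self.missing_genotype_rate,
        ):
            if not (0.0 <= frac <= 1.0):
                raise ConfigurationError("fractions must lie in [0, 1]")
        if self.affected_fraction_target + self.suggestive_fraction > 1.0:
            raise ConfigurationError("phenotype fractions exceed 1")


def default_plants(n_families: int = 18) -> tuple[PlantSpec, ...]:
    """The standard planting layout: two variants shared by two families
    each, a two-variant gene split over two families, a single-family
    variant, an incompletely segregating variant, and a phenotype-
    independent null variant."""
    if n_families < 8:
        raise ConfigurationError("default plants need at least 8 families")
    return (
        PlantSpec(("F01", "F02"), gene="PLNT1"),
        PlantSpec(("F03", "F07"), gene="PLNT2"),
        PlantSpec(("F04",), gene="PLNT3"),
        PlantSpec(("F05",), gene="PLNT3"),
        PlantSpec(("F06",), gene="PLNT4"),
        PlantSpec(("F08",), gene="PLNT5", mode="incomplete"),
        PlantSpec((), gene="PLNT6", mode="null"),
    )


def study_cohort_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The default study-shaped cohort with the standard planting layout."""
    cfg = SimulationConfig(seed=seed, planted_variants=default_plants(), **overrides)
    return cfg


@dataclass
class SyntheticCohort:
    """In-memory result of one simulation, plus file writers."""

    config: SimulationConfig
    pedigrees: list[Pedigree]
    records: list[VariantRecord]
    annotations: dict[VariantKey, VariantAnnotation]
    lcr_intervals: dict[str, list[tuple[int, int]]]
    truth: pd.DataFrame
    exemption_candidates: list[str]

    @property
    def samples(self) -> list[str]:
        return [
            m.individual_id
            for ped in self.pedigrees
            for m in ped.members
            if m.genotyped
        ]

    def dataset(self) -> list[tuple[VariantRecord, VariantAnnotation]]:
        return [(rec, self.annotations[rec.key]) for rec in self.records]

    def write(self, outdir: str | os.PathLike) -> dict[str, str]:
        outdir = os.fspath(outdir)
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "vcf": os.path.join(outdir, "cohort.vcf"),
            "ped": os.path.join(outdir, "cohort.ped"),
            "annotation": os.path.join(outdir, "annotations.tsv"),
            "lcr": os.path.join(outdir, "lcr.bed"),
            "truth": os.path.join(outdir, "truth.tsv"),
            "exemptions": os.path.join(outdir, "exemptions.txt"),
        }
        io_formats.write_vcf(self.records, self.samples, paths["vcf"])
        io_formats.write_pedigree(self.pedigrees, paths["ped"])
        io_formats.write_annotation_table(self.annotations, paths["annotation"])
        io_formats.write_bed(self.lcr_intervals, paths["lcr"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        with open(paths["exemptions"], "wt") as fh:
            for ind in self.exemption_candidates:
                fh.write(ind + "\n")
        return paths


# ---------------------------------------------------------------------------
# Pedigree simulation


def _build_family(
    family_id: str,
    n_genotyped: int,
    generations: int,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> Pedigree:
    serial = [0]

    def new_id() -> str:
        serial[0] += 1
        return f"{family_id}_{serial[0]:02d}"

    members: list[PedigreeIndividual] = []

    def add(father=None, mother=None, sex=None) -> PedigreeIndividual:
        if sex is None:
            sex = "male" if rng.random() < 0.5 else "female"
        m = PedigreeIndividual(
            family_id=family_id,
            individual_id=new_id(),
            father_id=father,
            mother_id=mother,
            sex=sex,
            phenotype="unknown",
        )
        members.append(m)
        return m

    f1 = add(sex="male")
    f2 = add(sex="female")
    gen2 = [
        add(father=f1.individual_id, mother=f2.individual_id)
        for _ in range(int(rng.integers(2, 5)))
    ]
    last_gen = gen2
    for _ in range(generations - 2):
        parent = last_gen[int(rng.integers(len(last_gen)))]
        spouse = add(sex="female" if parent.sex == "male" else "male")
        father, mother = (
            (parent, spouse) if parent.sex == "male" else (spouse, parent)
        )
        last_gen = [
            add(father=father.individual_id, mother=mother.individual_id)
            for _ in range(int(rng.integers(1, 4)))
        ]
    while len(members) < n_genotyped:
        add(father=f1.individual_id, mother=f2.individual_id)
    genotyped_idx = rng.choice(len(members), size=n_genotyped, replace=False)
    genotyped = {members[i].individual_id for i in genotyped_idx}
    for m in members:
        m.genotyped = m.individual_id in genotyped
    # three-state phenotype draw for genotyped members, unknown otherwise
    p_aff = cfg.affected_fraction_target
    p_sug = cfg.suggestive_fraction
    for m in members:
        if not m.genotyped:
            continue
        u = rng.random()
        m.phenotype = (
            "affected" if u < p_aff else "suggestive" if u < p_aff + p_sug else "unaffected"
        )
    genotyped_members = [m for m in members if m.genotyped]
    if not any(m.phenotype == "affected" for m in genotyped_members):
        pick = genotyped_members[int(rng.integers(len(genotyped_members)))]
        pick.phenotype = "affected"
    return Pedigree(family_id=family_id, members=members)


def simulate_pedigrees(
    cfg: SimulationConfig, rng: np.random.Generator
) -> list[Pedigree]:
    """Simulate the cohort's pedigrees: acyclic, multi-generation, with
    at least one genotyped affected member per family."""
    lo, hi = cfg.family_size_range
    glo, ghi = cfg.generations_range
    pedigrees = []
    for i in range(cfg.n_families):
        n_genotyped = int(rng.integers(lo, hi + 1))
        generations = int(rng.integers(glo, ghi + 1))
        pedigrees.append(
            _build_family(f"F{i + 1:02d}", n_genotyped, generations, cfg, rng)
        )
    return pedigrees


# ---------------------------------------------------------------------------
# Variant simulation


class _SiteAllocator:
    """Unique (chrom, pos) allocation; chromosome 22 is reserved for the
    synthetic LCR so only deliberate LCR violators land there."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.used: set[tuple[str, int]] = set()

    def next_site(self, chrom: Optional[str] = None, pos_range=(100_000, 50_000_000)):
        while True:
            c = chrom or str(int(self.rng.integers(1, 22)))
            p = int(self.rng.integers(*pos_range))
            if (c, p) not in self.used:
                self.used.add((c, p))
                return c, p


def _annotation_for(
    gene: str,
    effect: str,
    cadd: Optional[float],
    af: float,
    rng: np.random.Generator,
    control_maf: Optional[float] = None,
) -> VariantAnnotation:
    # per-source jitter exercises the multi-source rarity rule with
    # discordant panels
    afs = {}
    for source in DEFAULT_AF_SOURCES:
        jitter = float(np.clip(af * (1 + 0.2 * rng.standard_normal()), 0.0, 1.0))
        afs[source] = jitter
    if control_maf is None:
        control_maf = float(np.clip(af * (1 + 0.2 * rng.standard_normal()), 0.0, 0.5))
    return VariantAnnotation(
        gene=gene,
        effect=effect,
        population_afs=afs,
        control_maf=control_maf,
        cadd_phred=cadd,
        is_indel="indel" in effect,
    )


def _hom_ref_counts(samples: Sequence[str]) -> dict[str, Optional[int]]:
    return {s: 0 for s in samples}


def _drop_background(
    pedigrees: Sequence[Pedigree],
    maf: float,
    rng: np.random.Generator,
) -> dict[str, Optional[int]]:
    counts: dict[str, Optional[int]] = {}
    for ped in pedigrees:
        founder_counts = {
            f.individual_id: int(rng.binomial(2, maf)) for f in ped.founders
        }
        dropped = gene_drop_matrix(ped, founder_counts, 1, rng)
        for m in ped.members:
            if m.genotyped:
                counts[m.individual_id] = int(dropped[m.individual_id][0])
    return counts


def _apply_missing(
    counts: dict[str, Optional[int]], rate: float, rng: np.random.Generator
) -> None:
    if rate <= 0:
        return
    for s in list(counts):
        if rng.random() < rate:
            counts[s] = None


def simulate_dataset(
    cfg: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> SyntheticCohort:
    """Generate the full cohort: pedigrees, genotypes, annotations, LCR
    intervals, and the truth table of expected pipeline fates."""
    rng = rng or np.random.default_rng(cfg.seed)
    pedigrees = simulate_pedigrees(cfg, rng)
    samples = [
        m.individual_id for ped in pedigrees for m in ped.members if m.genotyped
    ]
    by_family = {p.family_id: p for p in pedigrees}
    alloc = _SiteAllocator(rng)
    records: list[VariantRecord] = []
    annotations: dict[VariantKey, VariantAnnotation] = {}
    truth_rows: list[dict] = []
    exemption_candidates: list[str] = []

    def emit(rec, ann, kind, expected_stage, expected_rule, families=(), mode="",
             exempt=()):
        records.append(rec)
        annotations[rec.key] = ann
        truth_rows.append(
            {
                "variant": rec.key_str,
                "gene": ann.gene or ".",
                "kind": kind,
                "expected_stage": expected_stage,
                "expected_rule": expected_rule,
                "target_families": ";".join(families),
                "mode": mode,
                "exemption_candidates": ";".join(exempt),
            }
        )

    # --- planted variants -------------------------------------------------
    for spec in cfg.planted_variants:
        chrom, pos = alloc.next_site()
        counts = _hom_ref_counts(samples)
        exempt: list[str] = []
        if spec.mode == "null":
            for s in samples:
                if rng.random() < 0.05:
                    counts[s] = 1
            stage, rule = "none", ""
        else:
            for fam in spec.target_families:
                if fam not in by_family:
                    raise ConfigurationError(f"unknown target family {fam!r}")
                ped = by_family[fam]
                affected = ped.genotyped_members("affected")
                if not affected:
                    raise ConfigurationError(
                        f"cannot plant in family {fam}: no genotyped affected member"
                    )
                for m in affected:
                    counts[m.individual_id] = 1
                for m in ped.genotyped_members("suggestive"):
                    if rng.random() < 0.5:
                        counts[m.individual_id] = 1
            # reduced penetrance: carrier phenotypes may flip to unaffected;
            # such individuals are exemption candidates in the truth table
            if cfg.penetrance < 1.0:
                for fam in spec.target_families:
                    for m in by_family[fam].genotyped_members("affected"):
                        if counts[m.individual_id] and rng.random() > cfg.penetrance:
                            m.phenotype = "unaffected"
                            exempt.append(m.individual_id)
                            exemption_candidates.append(m.individual_id)
            if spec.mode == "incomplete":
                carrier = _pick_unaffected_carrier(
                    pedigrees, spec.target_families, exempt, rng
                )
                counts[carrier] = 1
                stage, rule = "segregation", "unaffected_carrier"
            else:
                stage, rule = "segregation", "segregates"
        rec = VariantRecord(
            chrom=chrom, pos=pos, ref="C", alt="T", sample_alt_counts=counts
        )
        ann = _annotation_for(spec.gene, spec.effect, spec.cadd, spec.population_af, rng)
        # planted variants are rare by contract: clamp jitter at the 1% line
        ann.population_afs = {k: min(v, 0.01) for k, v in ann.population_afs.items()}
        if ann.control_maf is not None:
            ann.control_maf = min(ann.control_maf, 0.009)
        emit(rec, ann, "planted", stage, rule, spec.target_families, spec.mode, exempt)

    # --- deliberate filter violators --------------------------------------
    violator_recipes = _violator_recipes()
    for name, (stage, rule, make) in violator_recipes.items():
        for j in range(cfg.n_violators_per_rule):
            rec, ann = make(pedigrees, samples, alloc, rng, j)
            emit(rec, ann, f"violator:{name}", stage, rule)

    # --- background variants ----------------------------------------------
    lo, hi = cfg.background_maf_range
    for i in range(cfg.n_background_variants):
        maf = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        chrom, pos = alloc.next_site()
        counts = _drop_background(pedigrees, maf, rng)
        _apply_missing(counts, cfg.missing_genotype_rate, rng)
        effect = str(
            rng.choice(
                ["nonsynonymous", "synonymous", "frameshift_indel", "splicing",
                 "unknown_effect", "other"],
                p=[0.45, 0.25, 0.05, 0.05, 0.1, 0.1],
            )
        )
        cadd = float(rng.uniform(0, 40))
        rec = VariantRecord(
            chrom=chrom, pos=pos, ref="G", alt="A", sample_alt_counts=counts
        )
        ann = _annotation_for(f"BG{i:04d}", effect, cadd, maf, rng)
        emit(rec, ann, "background", "unspecified", "")

    truth = pd.DataFrame(truth_rows)
    return SyntheticCohort(
        config=cfg,
        pedigrees=pedigrees,
        records=records,
        annotations=annotations,
        lcr_intervals={k: list(v) for k, v in LCR_INTERVALS.items()},
        truth=truth,
        exemption_candidates=exemption_candidates,
    )


def _pick_unaffected_carrier(pedigrees, target_families, exempt, rng) -> str:
    pools = [
        [m for m in ped.genotyped_members("unaffected")
         if not m.penetrance_exempt and m.individual_id not in exempt]
        for ped in pedigrees
        if ped.family_id in target_families
    ] + [
        [m for m in ped.genotyped_members("unaffected")
         if not m.penetrance_exempt and m.individual_id not in exempt]
        for ped in pedigrees
    ]
    for pool in pools:
        if pool:
            return pool[int(rng.integers(len(pool)))].individual_id
    raise ConfigurationError("no genotyped unaffected individual to carry the variant")


def _affected_carriers_one_family(pedigrees, counts, rng) -> None:
    ped = pedigrees[int(rng.integers(len(pedigrees)))]
    for m in ped.genotyped_members("affected"):
        counts[m.individual_id] = 1


def _violator_recipes():
    """Each recipe builds a variant failing exactly one rule."""

    def lcr(pedigrees, samples, alloc, rng, j):
        start, end = LCR_INTERVALS[LCR_CHROM][0]
        chrom, pos = alloc.next_site(chrom=LCR_CHROM, pos_range=(start + 1, end))
        counts = _hom_ref_counts(samples)
        _affected_carriers_one_family(pedigrees, counts, rng)
        return (
            VariantRecord(chrom=chrom, pos=pos, ref="A", alt="G", sample_alt_counts=counts),
            _annotation_for("VLCR", "nonsynonymous", 25.0, 0.001, rng),
        )

    def hwe(pedigrees, samples, alloc, rng, j):
        chrom, pos = alloc.next_site()
        counts = {s: 1 for s in samples}  # universal heterozygosity
        return (
            VariantRecord(chrom=chrom, pos=pos, ref="A", alt="G", sample_alt_counts=counts),
            _annotation_for("VHWE", "nonsynonymous", 25.0, 0.001, rng),
        )

    def mac(pedigrees, samples, alloc, rng, j):
        chrom, pos = alloc.next_site()
        return (
            VariantRecord(
                chrom=chrom, pos=pos, ref="A", alt="G",
                sample_alt_counts=_hom_ref_counts(samples),
            ),
            _annotation_for("VMAC", "nonsynonymous", 25.0, 0.001, rng),
        )

    def high_maf(pedigrees, samples, alloc, rng, j):
        chrom, pos = alloc.next_site()
        counts = _hom_ref_counts(samples)
        _affected_carriers_one_family(pedigrees, counts, rng)
        ann = _annotation_for("VMAF", "nonsynonymous", 25.0, 0.001, rng)
        ann.population_afs["exac_nfe"] = 0.05  # one discordant common panel
        return (
            VariantRecord(chrom=chrom, pos=pos, ref="A", alt="G", sample_alt_counts=counts),
            ann,
        )

    def high_control(pedigrees, samples, alloc, rng, j):
        chrom, pos = alloc.next_site()
        counts = _hom_ref_counts(samples)
        _affected_carriers_one_family(pedigrees, counts, rng)
        return (
            VariantRecord(chrom=chrom, pos=pos, ref="A", alt="G", sample_alt_counts=counts),
            _annotation_for("VCTL", "nonsynonymous", 25.0, 0.001, rng, control_maf=0.02),
        )

    def synonymous(pedigrees, samples, alloc, rng, j):
        chrom, pos = alloc.next_site()
        counts = _hom_ref_counts(samples)
        _affected_carriers_one_family(pedigrees, counts, rng)
        return (
            VariantRecord(chrom=chrom, pos=pos, ref="A", alt="G", sample_alt_counts=counts),
            _annotation_for("VSYN", "synonymous", 25.0, 0.001, rng),
        )

    def low_cadd(pedigrees, samples, alloc, rng, j):
        chrom, pos = alloc.next_site()
        counts = _hom_ref_counts(samples)
        _affected_carriers_one_family(pedigrees, counts, rng)
        return (
            VariantRecord(chrom=chrom, pos=pos, ref="A", alt="G", sample_alt_counts=counts),
            _annotation_for("VCAD", "nonsynonymous", 5.0, 0.001, rng),
        )

    def acmg(pedigrees, samples, alloc, rng, j):
        chrom, pos = alloc.next_site()
        counts = _hom_ref_counts(samples)
        _affected_carriers_one_family(pedigrees, counts, rng)
        return (
            VariantRecord(chrom=chrom, pos=pos, ref="A", alt="G", sample_alt_counts=counts),
            _annotation_for("BRCA2", "nonsynonymous", 25.0, 0.001, rng),
        )

    return {
        "lcr": ("prep", "lcr", lcr),
        "hwe": ("prep", "hwe", hwe),
        "mac": ("prep", "mac", mac),
        "high_maf": ("cascade", "population_rarity", high_maf),
        "high_control_maf": ("cascade", "population_rarity", high_control),
        "synonymous": ("cascade", "effect_cadd", synonymous),
        "low_cadd": ("cascade", "effect_cadd", low_cadd),
        "acmg_gene": ("cascade", "acmg_gene", acmg),
    }


# ---------------------------------------------------------------------------
# Null genes for burden-test calibration


def simulate_calibration_cohort(
    rng: np.random.Generator,
    n_families: int = 36,
    family_size_range: tuple[int, int] = (16, 20),
    cfg: Optional[SimulationConfig] = None,
) -> list[Pedigree]:
    """Pedigrees for type-I-error studies of the burden test.

    Every member is genotyped and phenotyped. Full founder observation
    makes the test's conditioning on founder genotypes exact (no
    imputation enters the null), and the large families give the integer
    statistic a fine-grained null support, so the permutation p-value's
    discreteness does not dominate its distribution.
    """
    cfg = cfg or SimulationConfig(
        n_families=n_families,
        family_size_range=family_size_range,
        generations_range=(3, 4),
    )
    pedigrees = simulate_pedigrees(cfg, rng)
    p_aff, p_sug = cfg.affected_fraction_target, cfg.suggestive_fraction
    for ped in pedigrees:
        for m in ped.members:
            m.genotyped = True
            if m.phenotype == "unknown":
                u = rng.random()
                m.phenotype = (
                    "affected" if u < p_aff
                    else "suggestive" if u < p_aff + p_sug
                    else "unaffected"
                )
    return pedigrees


def simulate_null_gene_records(
    pedigrees: Sequence[Pedigree],
    n_genes: int,
    rng: np.random.Generator,
    founder_allele_freq: float = 0.35,
    variants_per_gene: int = 1,
) -> dict[str, list[VariantRecord]]:
    """Genes whose genotypes are gene-dropped with no phenotype link.

    Founder genotypes are Hardy-Weinberg draws at *founder_allele_freq*
    (high enough that most families are informative) and descend by
    Mendelian transmission, independently of the fixed phenotypes —
    the type-I-error reference condition for the burden test.
    """
    out: dict[str, list[VariantRecord]] = {}
    for g in range(n_genes):
        variants = []
        for v in range(variants_per_gene):
            counts: dict[str, Optional[int]] = {}
            for ped in pedigrees:
                founder_counts = {
                    f.individual_id: int(rng.binomial(2, founder_allele_freq))
                    for f in ped.founders
                }
                dropped = gene_drop_matrix(ped, founder_counts, 1, rng)
                for m in ped.members:
                    if m.genotyped:
                        counts[m.individual_id] = int(dropped[m.individual_id][0])
            variants.append(
                VariantRecord(
                    chrom="1",
                    pos=1_000_000 + g * 10 + v,
                    ref="A",
                    alt="T",
                    sample_alt_counts=counts,
                )
            )
        out[f"NULL{g:05d}"] = variants
    return out
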