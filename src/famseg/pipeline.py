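"""Configuration-driven orchestration of the full analysis.

Stages, in order: sample-set validation, QC prefilter (LCR / HWE / MAC),
the variant-level rarity cascade, global unaffected-carrier removal,
per-family segregation, cross-family aggregation, and the gene-dropping
burden test over multi-variant genes. Two runs with identical
configuration and seed produce byte-identical report files (no
timestamps enter any output).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import yaml

from . import io_formats
from .cross_family import (
    cohort_summary,
    gene_map_from_dataset,
    homozygous_keys_from_dataset,
    multi_variant_genes,
    shared_variants,
    write_cohort_summary,
    write_multigene_report,
    write_shared_variant_report,
)
from .family_burden import BurdenResult, GeneDropConfig, burden_scan
from .rare_filter import FilterConfig, apply_rare_filters, decision_tally
from .segregation import remove_global_unaffected_carriers, segregating_variants
from .types import ConfigurationError, genotyped_sample_ids, variant_key_str
from .variant_prep import RegionSet, decompose_multiallelic, qc_prefilter

log = logging.getLogger("famseg")


@dataclass
class RunConfig:
    vcf: str
    ped: str
    annotation: str
    lcr_bed: Optional[str] = None
    outdir: str = "famseg_out"
    exemptions: tuple[str, ...] = ()
    filter: FilterConfig = field(default_factory=FilterConfig)
    burden: GeneDropConfig = field(default_factory=GeneDropConfig)
    run_burden: bool = True
    strict_multigene: bool = False

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        filter_cfg = FilterConfig(**{
            **raw.get("filter", {}),
            **(
                {"retained_effects": frozenset(raw["filter"]["retained_effects"])}
                if "retained_effects" in raw.get("filter", {})
                else {}
            ),
            **(
                {"excluded_genes": frozenset(raw["filter"]["excluded_genes"])}
                if "excluded_genes" in raw.get("filter", {})
                else {}
            ),
        })
        burden_cfg = GeneDropConfig(**raw.get("burden", {}))
        return cls(
            vcf=raw["vcf"],
            ped=raw["ped"],
            annotation=raw["annotation"],
            lcr_bed=raw.get("lcr_bed"),
            outdir=raw.get("outdir", "famseg_out"),
            exemptions=tuple(raw.get("exemptions", ())),
            filter=filter_cfg,
            burden=burden_cfg,
            run_burden=bool(raw.get("run_burden", True)),
            strict_multigene=bool(raw.get("strict_multigene", False)),
        )

    def config_hash(self) -> str:
        """Hash of the analysis parameters (thresholds, seed, exemptions,
        stage toggles) — deliberately excludes file paths so runs on the
        same inputs from different locations compare equal."""

        def default(o):
            if isinstance(o, frozenset):
                return sorted(o)
            raise TypeError(type(o))

        params = {
            "filter": asdict(self.filter),
            "burden": asdict(self.burden),
            "exemptions": sorted(self.exemptions),
            "run_burden": self.run_burden,
            "strict_multigene": self.strict_multigene,
        }
        blob = json.dumps(params, sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages, write report files to ``cfg.outdir``, and
    return the machine-readable run report."""
    for path in (cfg.vcf, cfg.ped, cfg.annotation, cfg.lcr_bed):
        if path is not None and not os.path.exists(path):
            raise ConfigurationError(f"input file not found: {path}")
    os.makedirs(cfg.outdir, exist_ok=True)

    pedigrees = io_formats.parse_pedigree(cfg.ped, cfg.exemptions)
    samples, sites = io_formats.read_vcf(cfg.vcf)
    if not sites:
        raise ConfigurationError("VCF contains no variant records")
    io_formats.mark_genotyped(pedigrees, samples)  # fatal before any filtering
    annotations = io_formats.read_annotation_table(cfg.annotation)

    dataset = []
    for site in sites:
        for rec in decompose_multiallelic(site):
            from .types import VariantAnnotation

            dataset.append(
                (rec, annotations.get(rec.key, VariantAnnotation.all_missing()))
            )
    n_input = len(dataset)

    lcr = RegionSet.from_bed(cfg.lcr_bed) if cfg.lcr_bed else RegionSet({})
    family_samples = sorted(genotyped_sample_ids(pedigrees))
    prepped, prep_tally = qc_prefilter(
        dataset, lcr, cfg.filter.hwe_threshold, family_samples
    )
    log.info("QC prefilter tally: %s", prep_tally)

    cascade_retained, decisions = apply_rare_filters(prepped, pedigrees, cfg.filter)
    cascade_tally = decision_tally(decisions)
    log.info("rarity cascade tally: %s", cascade_tally)
    _write_decisions(decisions, os.path.join(cfg.outdir, "filter_decisions.tsv"))

    post_global = remove_global_unaffected_carriers(cascade_retained, pedigrees)
    results = segregating_variants(pedigrees, post_global)

    gene_of = gene_map_from_dataset(post_global)
    hom_keys = homozygous_keys_from_dataset(post_global)
    shared = shared_variants(results, gene_of, hom_keys)
    multigene, within_family = multi_variant_genes(
        results, gene_of, strict=cfg.strict_multigene
    )
    summary = cohort_summary(results)

    write_cohort_summary(summary, os.path.join(cfg.outdir, "cohort_summary.tsv"))
    write_shared_variant_report(shared, os.path.join(cfg.outdir, "shared_variants.tsv"))
    write_multigene_report(multigene, os.path.join(cfg.outdir, "multi_variant_genes.tsv"))
    _write_segregating(results, gene_of, os.path.join(cfg.outdir, "segregating_variants.tsv"))

    burden_results: list[BurdenResult] = []
    if cfg.run_burden and multigene:
        variants_by_gene = {
            report.gene: [
                rec for rec, ann in cascade_retained if ann.gene == report.gene
            ]
            for report in multigene
        }
        burden_results = burden_scan(variants_by_gene, pedigrees, cfg.burden)
        _write_burden(burden_results, os.path.join(cfg.outdir, "burden_results.tsv"))

    report = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.burden.seed,
        "n_families": len(pedigrees),
        "n_samples": len(samples),
        "stage_counts": {
            "input": n_input,
            "qc_prefilter": prep_tally,
            "rarity_cascade": cascade_tally,
            "post_unaffected_carrier_removal": len(post_global),
            "n_shared_variants": len(shared),
            "n_multi_variant_genes": len(multigene),
            "n_within_family_multihit_families": len(within_family),
        },
        "cohort_summary": {
            "mean_segregating": summary.mean_segregating,
            "mean_segregating_rounded": summary.mean_segregating_rounded,
            "min_segregating": summary.min_segregating,
            "max_segregating": summary.max_segregating,
            "total_affected": summary.total_affected,
            "total_suggestive": summary.total_suggestive,
            "total_unaffected": summary.total_unaffected,
        },
        "burden": {
            r.gene: {"S": r.observed_statistic, "p": r.p_value}
            for r in burden_results
        },
    }
    with open(os.path.join(cfg.outdir, "run_report.json"), "wt") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def _write_decisions(decisions, dest: str) -> None:
    with open(dest, "wt") as fh:
        fh.write("variant\tverdict\tfailed_rule\n")
        for d in decisions:
            fh.write(
                f"{variant_key_str(d.key)}\t{d.verdict}\t{d.failed_rule or '.'}\n"
            )


def _write_segregating(results, gene_of, dest: str) -> None:
    with open(dest, "wt") as fh:
        fh.write("family\tchrom\tpos\tref\talt\tgene\n")
        for res in results:
            for key in res.variants:
                chrom, pos, ref, alt = key
                fh.write(
                    f"{res.family_id}\t{chrom}\t{pos}\t{ref}\t{alt}\t"
                    f"{gene_of.get(key, '.')}\n"
                )


def _write_burden(results: Sequence[BurdenResult], dest: str) -> None:
    with open(dest, "wt") as fh:
        fh.write("gene\tobserved_statistic\tp_value\tn_iterations\n")
        for r in sorted(results, key=lambda r: r.gene):
            fh.write(
                f"{r.gene}\t{r.observed_statistic}\t{r.p_value:.6g}\t{r.n_iterations}\n"
            )
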