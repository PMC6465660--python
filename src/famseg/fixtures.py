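"""Loaders for the transcribed published-cohort tables shipped with the
package (``famseg/data/``).

The tables summarise an 18-family chronic central serous
chorioretinopathy exome cohort: per-family phenotype tallies with
segregating-variant counts, the variants segregating in two families,
and the variants in genes hit across multiple families. The variant
tables carry no REF/ALT alleles, so loader-synthesised variant keys use
empty allele fields; positions make each key unique.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .cross_family import FamilyCounts
from .segregation import SegregationResult
from .types import VariantKey


def _read(name: str) -> pd.DataFrame:
    path = resources.files("famseg").joinpath("data", name)
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t", comment="#", na_values=["."])


def load_family_overview() -> list[FamilyCounts]:
    df = _read("family_overview.tsv")
    return [
        FamilyCounts(
            family_id=str(r.family),
            n_affected=int(r.n_affected),
            n_suggestive=int(r.n_suggestive),
            n_unaffected=int(r.n_unaffected),
            n_segregating=int(r.n_segregating),
        )
        for r in df.itertuples(index=False)
    ]


def _counts_by_family() -> dict[str, FamilyCounts]:
    return {fc.family_id: fc for fc in load_family_overview()}


def _results_from_rows(
    rows: list[tuple[str, VariantKey]]
) -> list[SegregationResult]:
    counts = _counts_by_family()
    per_family: dict[str, list[VariantKey]] = {}
    for family, key in rows:
        per_family.setdefault(family, []).append(key)
    results = []
    for family, keys in per_family.items():
        fc = counts[family]
        results.append(
            SegregationResult(
                family_id=family,
                variants=sorted(set(keys), key=lambda k: (k[0], k[1], k[3])),
                n_affected=fc.n_affected,
                n_suggestive=fc.n_suggestive,
                n_unaffected=fc.n_unaffected,
            )
        )
    return results


def load_shared_variant_fixture() -> dict:
    """The two-family shared-variant table, reshaped for
    :func:`famseg.cross_family.shared_variants`: per-family segregation
    results restricted to these variants, the variant-to-gene map, and
    the keys with a homozygous carrier."""
    df = _read("shared_variants.tsv")
    rows: list[tuple[str, VariantKey]] = []
    gene_of: dict[VariantKey, str] = {}
    homozygous: set[VariantKey] = set()
    for r in df.itertuples(index=False):
        key: VariantKey = (str(r.chrom), int(r.pos), "", "")
        gene_of[key] = str(r.gene)
        if str(r.any_homozygous) == "yes":
            homozygous.add(key)
        for family in str(r.families).split(";"):
            rows.append((family, key))
    return {
        "results": _results_from_rows(rows),
        "gene_of": gene_of,
        "homozygous_keys": homozygous,
    }


def load_multigene_fixture() -> dict:
    """The multi-family gene table, reshaped for
    :func:`famseg.cross_family.multi_variant_genes`."""
    df = _read("multigene_variants.tsv")
    rows: list[tuple[str, VariantKey]] = []
    gene_of: dict[VariantKey, str] = {}
    for r in df.itertuples(index=False):
        key: VariantKey = (str(r.chrom), int(r.pos), "", "")
        gene_of[key] = str(r.gene)
        rows.append((str(r.family), key))
    return {"results": _results_from_rows(rows), "gene_of": gene_of}
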