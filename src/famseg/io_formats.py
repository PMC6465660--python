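"""Readers and writers for every external format the pipeline touches.

Formats
-------
* **PED** — 6 whitespace-delimited columns ``family individual father mother
  sex phenotype``. The phenotype column uses a three-state dialect:
  ``1`` unaffected, ``2`` affected, ``3`` suggestive (an intermediate
  phenotype), ``0``/``-9`` unknown. ``0`` in a parent column means no
  recorded parent.
* **VCF v4.x** — read through :mod:`cyvcf2`; only ``GT`` is used.
  Coordinates are 1-based inclusive.
* **Annotation table** — tab-separated with a mandatory header, keyed by
  ``(chrom, pos, ref, alt)``; missing values written as ``.``.
* **BED3** — 0-based half-open intervals, converted at parse time.
"""

from __future__ import annotations

import io
import os
import tempfile
from typing import IO, Iterable, Mapping, Optional, Sequence, TextIO, Union

import pandas as pd
from cyvcf2 import VCF

from .types import (
    DEFAULT_AF_SOURCES,
    AnnotatedVariant,
    ConsistencyError,
    FormatError,
    Pedigree,
    PedigreeIndividual,
    RawSite,
    VariantAnnotation,
    VariantRecord,
)

PathOrStream = Union[str, os.PathLike, TextIO]

_PHENOTYPE_CODES = {"1": "unaffected", "2": "affected", "3": "suggestive",
                    "0": "unknown", "-9": "unknown"}
_PHENOTYPE_TO_CODE = {"unaffected": "1", "affected": "2", "suggestive": "3",
                      "unknown": "0"}
_SEX_CODES = {"1": "male", "2": "female", "0": "unknown"}
_SEX_TO_CODE = {"male": "1", "female": "2", "unknown": "0"}

ANNOTATION_COLUMNS = (
    ("chrom", "pos", "ref", "alt", "gene", "effect")
    + tuple(f"af_{s}" for s in DEFAULT_AF_SOURCES)
    + ("control_maf", "cadd_phred", "is_indel")
)


def _open_text(source: PathOrStream) -> tuple[TextIO, bool]:
    if hasattr(source, "read"):
        return source, False  # caller-owned stream
    return open(os.fspath(source), "rt"), True


# ---------------------------------------------------------------------------
# PED


def parse_pedigree(
    ped_source: PathOrStream,
    exemption_list: Sequence[str] = (),
) -> list[Pedigree]:
    """Parse a 6-column PED file into one :class:`Pedigree` per family.

    Individuals named in *exemption_list* get ``penetrance_exempt=True``
    (they must be unaffected). All individuals start as ``genotyped=True``;
    call :func:`mark_genotyped` with the VCF sample list to reconcile.
    """
    stream, owned = _open_text(ped_source)
    exemptions = set(exemption_list)
    members_by_family: dict[str, list[PedigreeIndividual]] = {}
    seen_keys: set[tuple[str, str]] = set()
    try:
        for lineno, line in enumerate(stream, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 6:
                raise FormatError(f"PED line {lineno}: expected 6 columns, got {len(fields)}")
            fam, ind, father, mother, sex_code, pheno_code = fields
            if pheno_code not in _PHENOTYPE_CODES:
                raise FormatError(f"PED line {lineno}: unknown phenotype code {pheno_code!r}")
            if sex_code not in _SEX_CODES:
                raise FormatError(f"PED line {lineno}: unknown sex code {sex_code!r}")
            if (fam, ind) in seen_keys:
                raise ConsistencyError(
                    f"PED line {lineno}: duplicate individual {ind!r} in family {fam!r}"
                )
            seen_keys.add((fam, ind))
            members_by_family.setdefault(fam, []).append(
                PedigreeIndividual(
                    family_id=fam,
                    individual_id=ind,
                    father_id=None if father == "0" else father,
                    mother_id=None if mother == "0" else mother,
                    sex=_SEX_CODES[sex_code],
                    phenotype=_PHENOTYPE_CODES[pheno_code],
                    penetrance_exempt=ind in exemptions
                    and _PHENOTYPE_CODES[pheno_code] == "unaffected",
                )
            )
    finally:
        if owned:
            stream.close()
    # exemptions naming a non-unaffected individual are a configuration error
    for fam, members in members_by_family.items():
        for m in members:
            if m.individual_id in exemptions and m.phenotype != "unaffected":
                raise ConsistencyError(
                    f"exempted individual {m.individual_id!r} is not unaffected"
                )
    return [Pedigree(family_id=fam, members=members)
            for fam, members in members_by_family.items()]


def write_pedigree(pedigrees: Sequence[Pedigree], dest: PathOrStream) -> None:
    stream, owned = (dest, False) if hasattr(dest, "write") else (open(os.fspath(dest), "wt"), True)
    try:
        for ped in pedigrees:
            for m in ped.members:
                stream.write(
                    "\t".join(
                        [
                            ped.family_id,
                            m.individual_id,
                            m.father_id or "0",
                            m.mother_id or "0",
                            _SEX_TO_CODE[m.sex],
                            _PHENOTYPE_TO_CODE[m.phenotype],
                        ]
                    )
                    + "\n"
                )
    finally:
        if owned:
            stream.close()


def mark_genotyped(pedigrees: Sequence[Pedigree], vcf_samples: Iterable[str]) -> None:
    """Set ``genotyped`` on every pedigree member from the VCF sample list.

    Raises :class:`ConsistencyError` if a VCF sample matches no pedigree
    member, or matches more than one. Enforced before any filtering.
    """
    samples = list(vcf_samples)
    sample_set = set(samples)
    if len(sample_set) != len(samples):
        raise ConsistencyError("duplicate sample ids in VCF header")
    owners: dict[str, int] = {s: 0 for s in sample_set}
    for ped in pedigrees:
        for m in ped.members:
            if m.individual_id in owners:
                owners[m.individual_id] += 1
            m.genotyped = m.individual_id in sample_set
    unmatched = sorted(s for s, n in owners.items() if n == 0)
    if unmatched:
        raise ConsistencyError(f"VCF samples absent from pedigrees: {unmatched}")
    multi = sorted(s for s, n in owners.items() if n > 1)
    if multi:
        raise ConsistencyError(f"VCF samples matching multiple pedigree members: {multi}")


# ---------------------------------------------------------------------------
# VCF


def _materialise_vcf(source: PathOrStream) -> tuple[str, Optional[str]]:
    """cyvcf2 needs a path; spool stream input to a temporary file."""
    if hasattr(source, "read"):
        tmp = tempfile.NamedTemporaryFile(
            "wt", suffix=".vcf", delete=False, encoding="utf-8"
        )
        with tmp:
            tmp.write(source.read())
        return tmp.name, tmp.name
    return os.fspath(source), None


def read_vcf(vcf_source: PathOrStream) -> tuple[list[str], list[RawSite]]:
    """Read a VCF into raw (possibly multiallelic) sites.

    Returns the header sample list and one :class:`RawSite` per record,
    with diploid allele-index pairs per sample (``None`` = missing allele).
    """
    path, tmp = _materialise_vcf(vcf_source)
    try:
        try:
            vcf = VCF(path)
        except Exception as exc:  # htslib raises bare OSError on bad input
            raise FormatError(f"cannot read VCF: {exc}") from exc
        samples = list(vcf.samples)
        sites: list[RawSite] = []
        for v in vcf:
            genotypes: dict[str, tuple[Optional[int], Optional[int]]] = {}
            for i, sample in enumerate(samples):
                gt = v.genotypes[i]
                alleles = gt[:-1]  # trailing element is the phased flag
                if len(alleles) == 1:
                    alleles = [alleles[0], alleles[0]]
                if len(alleles) != 2:
                    raise FormatError(
                        f"{v.CHROM}:{v.POS} sample {sample}: non-diploid GT"
                    )
                pair = tuple(None if a < 0 else int(a) for a in alleles)
                n_alleles = 1 + len(v.ALT)
                for a in pair:
                    if a is not None and a >= n_alleles:
                        raise ConsistencyError(
                            f"{v.CHROM}:{v.POS} sample {sample}: allele index {a} "
                            f"out of range for {n_alleles} alleles"
                        )
                genotypes[sample] = pair  # type: ignore[assignment]
            sites.append(
                RawSite(
                    chrom=v.CHROM,
                    pos=v.POS,
                    ref=v.REF,
                    alts=list(v.ALT),
                    rsid=v.ID,
                    genotypes=genotypes,
                )
            )
        return samples, sites
    finally:
        if tmp is not None:
            os.unlink(tmp)


_VCF_HEADER = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_vcf(
    records: Sequence[VariantRecord],
    samples: Sequence[str],
    dest: PathOrStream,
) -> None:
    """Write biallelic records as a minimal GT-only VCF v4.2 body."""
    stream, owned = (dest, False) if hasattr(dest, "write") else (open(os.fspath(dest), "wt"), True)
    gt_of = {0: "0/0", 1: "0/1", 2: "1/1", None: "./."}
    try:
        stream.write(_VCF_HEADER)
        for chrom in sorted({r.chrom for r in records}, key=_chrom_sort_key):
            stream.write(f"##contig=<ID={chrom}>\n")
        stream.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(samples) + "\n")
        for rec in sorted(records, key=lambda r: (_chrom_sort_key(r.chrom), r.pos, r.alt)):
            gts = "\t".join(gt_of[rec.sample_alt_counts.get(s)] for s in samples)
            stream.write(
                f"{rec.chrom}\t{rec.pos}\t{rec.rsid or '.'}\t{rec.ref}\t{rec.alt}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )
    finally:
        if owned:
            stream.close()


def _chrom_sort_key(chrom: str) -> tuple[int, str]:
    c = chrom.removeprefix("chr")
    return (int(c), "") if c.isdigit() else (10**6, c)


# ---------------------------------------------------------------------------
# Annotation table


def _nan_to_none(value) -> Optional[float]:
    return None if pd.isna(value) else float(value)


def read_annotation_table(
    annotation_source: PathOrStream,
) -> dict[tuple[str, int, str, str], VariantAnnotation]:
    """Read the per-variant annotation table keyed by (chrom, pos, ref, alt)."""
    df = pd.read_csv(
        annotation_source, sep="\t", comment="#", na_values=["."], dtype={"chrom": str}
    )
    missing_cols = {"chrom", "pos", "ref", "alt"} - set(df.columns)
    if missing_cols:
        raise FormatError(f"annotation table lacks key columns: {sorted(missing_cols)}")
    table: dict[tuple[str, int, str, str], VariantAnnotation] = {}
    af_cols = [c for c in df.columns if c.startswith("af_")]
    for row in df.itertuples(index=False):
        key = (str(row.chrom), int(row.pos), str(row.ref), str(row.alt))
        if key in table:
            raise ConsistencyError(f"duplicate annotation key {key}")
        population_afs = {}
        for col in af_cols:
            af = _nan_to_none(getattr(row, col))
            if af is not None:
                population_afs[col[3:]] = af
        gene = getattr(row, "gene", None)
        table[key] = VariantAnnotation(
            gene=None if pd.isna(gene) else str(gene),
            effect=str(getattr(row, "effect", "other")),
            population_afs=population_afs,
            control_maf=_nan_to_none(getattr(row, "control_maf", float("nan"))),
            cadd_phred=_nan_to_none(getattr(row, "cadd_phred", float("nan"))),
            is_indel=bool(getattr(row, "is_indel", False)),
        )
    return table


def write_annotation_table(
    annotations: Mapping[tuple[str, int, str, str], VariantAnnotation],
    dest: PathOrStream,
) -> None:
    rows = []
    for key in sorted(annotations, key=lambda k: (_chrom_sort_key(k[0]), k[1], k[3])):
        ann = annotations[key]
        row: dict[str, object] = dict(zip(("chrom", "pos", "ref", "alt"), key))
        row["gene"] = ann.gene if ann.gene is not None else "."
        row["effect"] = ann.effect
        for source in DEFAULT_AF_SOURCES:
            af = ann.population_afs.get(source)
            row[f"af_{source}"] = "." if af is None else f"{af:.6g}"
        row["control_maf"] = "." if ann.control_maf is None else f"{ann.control_maf:.6g}"
        row["cadd_phred"] = "." if ann.cadd_phred is None else f"{ann.cadd_phred:g}"
        row["is_indel"] = ann.is_indel
        rows.append(row)
    pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS)).to_csv(dest, sep="\t", index=False)


def parse_variant_table(
    vcf_source: PathOrStream,
    annotation_source: PathOrStream,
) -> list[AnnotatedVariant]:
    """Read a VCF, decompose multiallelic sites, and join annotations.

    Variants with no annotation row are retained with an all-missing
    annotation; missing genotypes stay missing (never imputed to 0).
    """
    from .variant_prep import decompose_multiallelic  # deferred: avoids cycle

    _, sites = read_vcf(vcf_source)
    annotations = read_annotation_table(annotation_source)
    out: list[AnnotatedVariant] = []
    for site in sites:
        for rec in decompose_multiallelic(site):
            ann = annotations.get(rec.key, VariantAnnotation.all_missing())
            out.append((rec, ann))
    return out


# ---------------------------------------------------------------------------
# BED


def read_bed(bed_source: PathOrStream) -> dict[str, list[tuple[int, int]]]:
    """Read BED3 into 0-based half-open intervals per chromosome."""
    stream, owned = _open_text(bed_source)
    intervals: dict[str, list[tuple[int, int]]] = {}
    try:
        for lineno, line in enumerate(stream, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise FormatError(f"BED line {lineno}: expected at least 3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise FormatError(f"BED line {lineno}: start {start} >= end {end}")
            intervals.setdefault(chrom, []).append((start, end))
    finally:
        if owned:
            stream.close()
    return intervals


def write_bed(intervals: Mapping[str, Sequence[tuple[int, int]]], dest: PathOrStream) -> None:
    stream, owned = (dest, False) if hasattr(dest, "write") else (open(os.fspath(dest), "wt"), True)
    try:
        for chrom in sorted(intervals, key=_chrom_sort_key):
            for start, end in sorted(intervals[chrom]):
                stream.write(f"{chrom}\t{start}\t{end}\n")
    finally:
        if owned:
            stream.close()
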