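"""Shared domain types plus VCF / metadata / report I-O.

Genotypes are carried as allele *dosages*: the number of copies (0, 1, 2, or
missing) of the cDNA variant allele at each of the two loci.  The cDNA
orientation is the reporting surface of the pharmacogenomics literature
("c.388A>G", "c.521T>C"); the mapping from cDNA alleles to VCF REF/ALT is an
explicit, checked configuration — an unexpected REF/ALT pair is a hard error,
never a silent strand flip.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from cyvcf2 import VCF

_NUCLEOTIDES = frozenset("ACGT")

#: Missing dosage sentinel used throughout (None in records, -1 in arrays).
MISSING = None


class VariantMatchError(ValueError):
    """A configured variant could not be matched (or validated) in the VCF."""


@dataclass(frozen=True)
class VariantSpec:
    """One of the two assayed SNPs, identified in cDNA orientation."""

    rsid: str
    chrom: str
    pos: int  # 1-based
    cdna_label: str
    ancestral_allele: str
    variant_allele: str
    effect_label: str = ""

    def __post_init__(self) -> None:
        if self.ancestral_allele not in _NUCLEOTIDES or self.variant_allele not in _NUCLEOTIDES:
            raise ValueError(f"{self.rsid}: alleles must be A/C/G/T")
        if self.ancestral_allele == self.variant_allele:
            raise ValueError(f"{self.rsid}: ancestral and variant allele identical")


# GRCh37 coordinates; carried as data, matched by rsID first at read time.
DEFAULT_VARIANTS = (
    VariantSpec(
        rsid="rs2306283",
        chrom="12",
        pos=21329738,
        cdna_label="c.388A>G",
        ancestral_allele="A",
        variant_allele="G",
        effect_label="increased transport",
    ),
    VariantSpec(
        rsid="rs4149056",
        chrom="12",
        pos=21331549,
        cdna_label="c.521T>C",
        ancestral_allele="T",
        variant_allele="C",
        effect_label="reduced transport",
    ),
)


def default_variant_specs() -> tuple[VariantSpec, VariantSpec]:
    """The (c.388A>G, c.521T>C) pair with default GRCh37 coordinates."""
    return DEFAULT_VARIANTS


#: Default cDNA->VCF orientation: ancestral allele is REF, variant allele ALT.
#: SLCO1B1 is on the plus strand of chromosome 12, so cDNA and genomic
#: alleles coincide; a config may override per rsID with {"ref": .., "alt": ..}.
def default_allele_map(specs: Sequence[VariantSpec]) -> dict[str, dict[str, str]]:
    return {s.rsid: {"ref": s.ancestral_allele, "alt": s.variant_allele} for s in specs}


@dataclass
class SampleRecord:
    """Per-sample dosages of 388G and 521C, plus the ancestry-group label."""

    sample_id: str
    group: str
    dosage_388: Optional[int]
    dosage_521: Optional[int]

    def __post_init__(self) -> None:
        for d in (self.dosage_388, self.dosage_521):
            if d is not None and d not in (0, 1, 2):
                raise ValueError(f"{self.sample_id}: dosage {d!r} not in {{0,1,2,missing}}")


@dataclass
class GenotypeTable:
    """The cohort: two variants, ordered samples, ordered group labels."""

    variants: tuple[VariantSpec, VariantSpec]
    samples: list[SampleRecord]
    groups: list[str]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_ids in GenotypeTable")
        known = set(self.groups)
        for s in self.samples:
            if s.group not in known:
                raise ValueError(f"sample {s.sample_id}: unknown group {s.group!r}")

    def subset(self, group: str) -> list[SampleRecord]:
        """Samples in one group, or the whole cohort for ``"Total"``."""
        if group == "Total":
            return list(self.samples)
        if group not in self.groups:
            raise KeyError(f"unknown group {group!r}")
        return [s for s in self.samples if s.group == group]

    def group_sizes(self) -> dict[str, int]:
        sizes = {g: 0 for g in self.groups}
        for s in self.samples:
            sizes[s.group] += 1
        return sizes


@dataclass(frozen=True)
class GroupedCounts:
    """Sample and chromosome denominators for one group (or the pooled Total)."""

    group: str
    n_samples: int
    n_chromosomes: int


def read_vcf_genotypes(
    vcf_path: str | Path,
    specs: Sequence[VariantSpec] = DEFAULT_VARIANTS,
    allele_map: Optional[Mapping[str, Mapping[str, str]]] = None,
) -> GenotypeTable:
    """Read dosages of the two cDNA variant alleles from a VCF.

    Each spec must match exactly one biallelic record, by rsID primarily and
    by (chrom, pos) as a fallback.  Dosage is the count of the ALT allele the
    ``allele_map`` declares to carry the cDNA variant allele; any half-missing
    or fully missing genotype (``./.``) is recorded as missing at that locus.
    Samples are returned in VCF column order with the placeholder group
    ``"all"`` — attach real labels with :func:`apply_sample_groups`.
    """
    if len(specs) != 2:
        raise ValueError("exactly two VariantSpecs required")
    amap = allele_map if allele_map is not None else default_allele_map(specs)

    vcf = VCF(str(vcf_path))
    sample_ids = list(vcf.samples)
    found: dict[str, list[Optional[int]]] = {}
    for record in vcf:
        for spec in specs:
            if record.ID == spec.rsid or (record.CHROM == spec.chrom and record.POS == spec.pos):
                if spec.rsid in found:
                    raise VariantMatchError(f"{spec.rsid}: matched more than one VCF record")
                if len(record.ALT) != 1:
                    raise VariantMatchError(
                        f"{spec.rsid}: multi-allelic record (ALT={record.ALT}) not supported"
                    )
                want = amap[spec.rsid]
                if record.REF != want["ref"] or record.ALT[0] != want["alt"]:
                    raise VariantMatchError(
                        f"{spec.rsid}: VCF alleles {record.REF}>{record.ALT[0]} do not match "
                        f"configured {want['ref']}>{want['alt']}; refusing to flip"
                    )
                dosages: list[Optional[int]] = []
                for gt in record.genotypes:  # [allele0, allele1, phased]
                    a = gt[:-1]
                    dosages.append(None if any(x < 0 for x in a) else int(sum(x == 1 for x in a)))
                found[spec.rsid] = dosages
    for spec in specs:
        if spec.rsid not in found:
            raise VariantMatchError(f"variant {spec.rsid} not found in {vcf_path}")

    d388, d521 = found[specs[0].rsid], found[specs[1].rsid]
    samples = [
        SampleRecord(sample_id=sid, group="all", dosage_388=d388[i], dosage_521=d521[i])
        for i, sid in enumerate(sample_ids)
    ]
    return GenotypeTable(variants=(specs[0], specs[1]), samples=samples, groups=["all"])


def read_sample_groups(path: str | Path) -> dict[str, str]:
    """Read the two-column ``sample_id,group`` metadata table (TSV or CSV)."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    if list(df.columns) != ["sample_id", "group"]:
        raise ValueError(f"{path}: expected header 'sample_id,group', got {list(df.columns)}")
    if len(df) == 0:
        raise ValueError(f"{path}: empty metadata file")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"{path}: duplicate sample_ids {dups}")
    return dict(zip(df["sample_id"], df["group"]))


def apply_sample_groups(
    table: GenotypeTable,
    mapping: Mapping[str, str],
    group_order: Optional[Sequence[str]] = None,
) -> tuple[GenotypeTable, list[str]]:
    """Attach group labels; VCF samples absent from the metadata are dropped.

    Returns the relabelled table and the list of excluded sample ids (also
    surfaced as a warning so pipelines cannot miss it).
    """
    excluded = [s.sample_id for s in table.samples if s.sample_id not in mapping]
    if excluded:
        warnings.warn(f"{len(excluded)} VCF sample(s) absent from metadata; excluded", stacklevel=2)
    kept = [
        SampleRecord(s.sample_id, mapping[s.sample_id], s.dosage_388, s.dosage_521)
        for s in table.samples
        if s.sample_id in mapping
    ]
    if group_order is None:
        seen: list[str] = []
        for s in kept:
            if s.group not in seen:
                seen.append(s.group)
        group_order = seen
    return GenotypeTable(table.variants, kept, list(group_order)), excluded


def format_frequency(x: float, decimals: int = 2) -> str:
    return f"{x:.{decimals}f}"


def write_frequency_report(
    rows: Iterable[Mapping[str, object]],
    groups: Sequence[str],
    out_prefix: str | Path,
    decimals: int = 2,
    p_decimals: int = 4,
) -> tuple[Path, Path]:
    """Write the assembled per-group report as TSV (rounded) + JSON (full).

    ``rows`` are mappings with keys ``section``, ``row`` and one numeric entry
    per column; columns are ordered Total first, then the configured groups.
    Returns the (tsv_path, json_path) pair.
    """
    import json

    rows = list(rows)
    cols = ["Total"] + [g for g in groups if g != "Total"]
    out_prefix = Path(out_prefix)
    tsv_path = out_prefix.with_suffix(".tsv")
    json_path = out_prefix.with_suffix(".json")

    with open(tsv_path, "w") as fh:
        fh.write("\t".join(["section", "row"] + cols + ["p_value", "method"]) + "\n")
        for r in rows:
            cells = [str(r.get("section", "")), str(r.get("row", ""))]
            for c in cols:
                v = r.get(c)
                cells.append("" if v is None else format_frequency(float(v), decimals))
            p = r.get("p_value")
            cells.append("" if p is None else format_frequency(float(p), p_decimals))
            cells.append(str(r.get("method", "")))
            fh.write("\t".join(cells) + "\n")

    with open(json_path, "w") as fh:
        json.dump(rows, fh, indent=2, default=float)
        fh.write("\n")
    return tsv_path, json_path
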