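"""Synthetic multi-ancestry cohort generator with known haplotype truth.

Each group has its own haplotype-frequency 4-vector over (*1a,*1b,*5,*15).
A sample's two haplotypes are drawn independently under random mating,
except that with probability F (the inbreeding coefficient) the two are
identical by descent — a single draw duplicated — which produces the
homozygote excess characteristic of consanguineous cohorts.  Dosages follow
deterministically from the haplotype pair; each locus is then independently
masked missing at the configured rate.

Reproducibility: one root seed; group k draws from a child stream
``SeedSequence(seed, spawn_key=(k,))``, so appending a group never perturbs
earlier groups' cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import reference
from .haplotypes import HAPLOTYPE_NAMES
from .io_formats import DEFAULT_VARIANTS, GenotypeTable, SampleRecord, VariantSpec

# haplotype index -> (counts toward 388G dosage, counts toward 521C dosage)
_HAS_G = np.array([0, 1, 0, 1])  # *1b, *15 carry 388G
_HAS_C = np.array([0, 0, 1, 1])  # *5, *15 carry 521C

PRESETS = ("hf-table", "maf-consistent")


@dataclass(frozen=True)
class GroupConfig:
    label: str
    n_samples: int
    hap_freqs: tuple[float, float, float, float]  # (*1a, *1b, *5, *15)
    inbreeding_f: float = 0.0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        f = np.asarray(self.hap_freqs, dtype=float)
        if f.shape != (4,) or (f < 0).any() or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError(f"{self.label}: hap_freqs must be a simplex 4-vector")
        if not (0.0 <= self.inbreeding_f <= 1.0):
            raise ValueError("inbreeding_f must be in [0,1]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0,1)")


@dataclass(frozen=True)
class CohortConfig:
    groups: tuple[GroupConfig, ...]
    variants: tuple[VariantSpec, VariantSpec] = DEFAULT_VARIANTS
    seed: int = 0

    def __post_init__(self) -> None:
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError("group labels must be unique")


def generate_cohort(cfg: CohortConfig) -> tuple[GenotypeTable, dict]:
    """Draw the cohort; returns the genotype table and the truth record.

    The truth record carries the config, the per-sample haplotype pairs (star
    names, by sample id) and per-group haplotype tallies, so downstream
    estimates can be scored against the exact generative truth.
    """
    samples: list[SampleRecord] = []
    truth_pairs: dict[str, tuple[str, str]] = {}
    tallies: dict[str, dict[str, int]] = {}

    for k, g in enumerate(cfg.groups):
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(cfg.seed, spawn_key=(k,))))
        n = g.n_samples
        f = np.asarray(g.hap_freqs, dtype=float)
        f = f / f.sum()
        haps = rng.choice(4, size=(n, 2), p=f)
        if g.inbreeding_f > 0:
            ibd = rng.random(n) < g.inbreeding_f
            haps[ibd, 1] = haps[ibd, 0]
        d388 = _HAS_G[haps].sum(axis=1)
        d521 = _HAS_C[haps].sum(axis=1)
        miss388 = rng.random(n) < g.missing_rate if g.missing_rate > 0 else np.zeros(n, bool)
        miss521 = rng.random(n) < g.missing_rate if g.missing_rate > 0 else np.zeros(n, bool)

        tally = {name: 0 for name in HAPLOTYPE_NAMES}
        for i in range(n):
            sid = f"G{k}_{i:05d}"
            pair = (HAPLOTYPE_NAMES[haps[i, 0]], HAPLOTYPE_NAMES[haps[i, 1]])
            truth_pairs[sid] = pair
            tally[pair[0]] += 1
            tally[pair[1]] += 1
            samples.append(
                SampleRecord(
                    sample_id=sid,
                    group=g.label,
                    dosage_388=None if miss388[i] else int(d388[i]),
                    dosage_521=None if miss521[i] else int(d521[i]),
                )
            )
        tallies[g.label] = tally

    table = GenotypeTable(
        variants=cfg.variants, samples=samples, groups=[g.label for g in cfg.groups]
    )
    truth = {
        "seed": cfg.seed,
        "groups": [
            {
                "label": g.label,
                "n_samples": g.n_samples,
                "hap_freqs": dict(zip(HAPLOTYPE_NAMES, g.hap_freqs)),
                "inbreeding_f": g.inbreeding_f,
                "missing_rate": g.missing_rate,
            }
            for g in cfg.groups
        ],
        "haplotype_pairs": truth_pairs,
        "haplotype_tallies": tallies,
    }
    return table, truth


def write_cohort(table: GenotypeTable, truth: dict, out_dir: str | Path) -> dict[str, Path]:
    """Emit cohort.vcf (v4.2, GT-only), samples.tsv and truth.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vcf_path = out_dir / "cohort.vcf"
    tsv_path = out_dir / "samples.tsv"
    truth_path = out_dir / "truth.json"

    v388, v521 = table.variants
    records = sorted([(v388, "dosage_388"), (v521, "dosage_521")], key=lambda x: x[0].pos)
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=slco1b1-synthetic-cohort\n")
        contigs = {v.chrom for v, _ in records}
        for c in sorted(contigs):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        sample_ids = [s.sample_id for s in table.samples]
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids) + "\n")
        gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", None: "./."}
        for spec, attr in records:
            gts = [gt_strings[getattr(s, attr)] for s in table.samples]
            fh.write(
                f"{spec.chrom}\t{spec.pos}\t{spec.rsid}\t{spec.ancestral_allele}\t"
                f"{spec.variant_allele}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )

    with open(tsv_path, "w") as fh:
        fh.write("sample_id\tgroup\n")
        for s in table.samples:
            fh.write(f"{s.sample_id}\t{s.group}\n")

    with open(truth_path, "w") as fh:
        json.dump(truth, fh, indent=2)
        fh.write("\n")
    return {"vcf": vcf_path, "metadata": tsv_path, "truth": truth_path}


def _maf_consistent_freqs(group: str) -> tuple[float, float, float, float]:
    """Per-group haplotype frequencies consistent with the published MAFs and
    phenotype counts: f_5 + f_15 equals the phenotype-implied 521C frequency,
    f_1b + f_15 the printed 388G frequency; the *5/*15 split of the 521C mass
    follows the published per-group *5:*15 ratio (the one degree of freedom
    the published marginals leave open)."""
    c521 = reference.implied_521_frequency(group)
    g388 = reference.PRINTED_MAF["c.388A>G"][group]
    r5 = reference.PRINTED_HF_PCT["*5"][group]
    r15 = reference.PRINTED_HF_PCT["*15"][group]
    f15 = c521 * r15 / (r5 + r15)
    f5 = c521 - f15
    f1b = g388 - f15
    f1a = 1.0 - f1b - f5 - f15
    if min(f1a, f1b, f5, f15) < 0:
        raise ValueError(f"{group}: published marginals admit no valid frequency vector")
    return (f1a, f1b, f5, f15)


def qatari_preset(preset: str, seed: int = 0, n_samples: Optional[dict[str, int]] = None) -> CohortConfig:
    """Cohort configs mirroring the published three-group Qatari cohort.

    ``"hf-table"`` uses the published per-group haplotype frequencies
    directly; ``"maf-consistent"`` uses frequencies consistent with the
    published MAFs and phenotype counts instead (the two published row-sets
    are mutually inconsistent, so a preset must be named explicitly).  Group
    sizes default to the published 587/387/76; override via ``n_samples``.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; available: {', '.join(PRESETS)}")
    groups = []
    for label in reference.GROUPS:
        n = (n_samples or {}).get(label, reference.N_SAMPLES[label])
        if preset == "hf-table":
            raw = np.array([reference.PRINTED_HF_PCT[h][label] for h in HAPLOTYPE_NAMES])
            f = tuple(raw / raw.sum())  # printed percentages, renormalised
        else:
            f = _maf_consistent_freqs(label)
        groups.append(GroupConfig(label=label, n_samples=n, hap_freqs=f))
    return CohortConfig(groups=tuple(groups), seed=seed)
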