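"""End-to-end analysis: genotype table in, published-style tables out.

Runs, per variant and per group (plus the pooled Total): allele counts, MAF
and the exact HWE test; then the haplotype EM per group and pooled; then
phenotype classification; and finally across-group significance tests for
each MAF, haplotype and phenotype row (test chosen by the recorded
``select_test`` policy).  Deterministic except for the Monte-Carlo Fisher
fallback, whose seed is part of the configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .compare import ContingencyTable, compare_variant_mafs, select_test
from .haplotypes import (
    HAPLOTYPE_NAMES,
    HaplotypeFrequencies,
    em_haplotype_frequencies,
    two_locus_counts,
)
from .io_formats import GenotypeTable
from .phenotypes import PHENOTYPE_NAMES, PhenotypeCounts, phenotype_frequencies
from .popgen import allele_counts, genotype_counts, hwe_exact_test, minor_allele_frequency


@dataclass
class AnalysisResult:
    rows: list[dict[str, object]] = field(default_factory=list)
    details: dict[str, object] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


def analyze(
    table: GenotypeTable,
    mc_draws: int = 100_000,
    seed: int = 0,
    min_expected: float = 5.0,
) -> AnalysisResult:
    res = AnalysisResult()
    groups = list(table.groups)
    scopes = ["Total"] + groups
    multi_group = len(groups) > 1
    mc_seed = seed

    # ---- per-variant allele frequencies and HWE --------------------------
    maf_details: dict[str, dict] = {}
    # Report rows carry the cDNA variant-allele frequency (the published
    # convention, even where that allele is locally the major one); the
    # strict second-most-common MAF sits alongside it in the JSON details.
    for variant in table.variants:
        per_group: dict[str, dict] = {}
        row: dict[str, object] = {
            "section": "variant_allele_frequency",
            "row": f"{variant.cdna_label} {variant.variant_allele} allele",
        }
        usable_groups = []
        for scope in scopes:
            ac = allele_counts(table, variant, scope)
            if ac.n_chromosomes == 0:
                res.warnings.append(
                    f"{variant.cdna_label}/{scope}: all genotypes missing; MAF unavailable"
                )
                per_group[scope] = {"unavailable": True, "n_missing": ac.n_missing_samples}
                row[scope] = None
                continue
            maf, minor = minor_allele_frequency(ac)
            hwe = hwe_exact_test(genotype_counts(table, variant, scope))
            per_group[scope] = {
                "n_ancestral": ac.n_ancestral,
                "n_variant": ac.n_variant,
                "n_missing_samples": ac.n_missing_samples,
                "variant_allele_frequency": ac.n_variant / ac.n_chromosomes,
                "maf": maf,
                "minor_allele": minor,
                "hwe_p": hwe.p_value,
                "hwe_in_equilibrium": hwe.p_value >= 0.05,
            }
            row[scope] = ac.n_variant / ac.n_chromosomes
            if scope != "Total":
                usable_groups.append(scope)
        if multi_group and len(usable_groups) > 1:
            cells = np.array(
                [
                    [per_group[g]["n_variant"] for g in usable_groups],
                    [per_group[g]["n_ancestral"] for g in usable_groups],
                ]
            )
            t = select_test(
                ContingencyTable(cells, rows=["variant", "ancestral"], cols=usable_groups),
                min_expected=min_expected,
                n_draws=mc_draws,
                seed=mc_seed,
            )
            row["p_value"], row["method"] = t.p_value, t.method
            per_group["across_groups"] = {"p": t.p_value, "method": t.method}
        maf_details[variant.cdna_label] = per_group
        res.rows.append(row)
    res.details["maf"] = maf_details

    ac388 = allele_counts(table, table.variants[0], "Total")
    ac521 = allele_counts(table, table.variants[1], "Total")
    if ac388.n_chromosomes and ac521.n_chromosomes:
        between = compare_variant_mafs(ac388, ac521)
        res.details["maf_388_vs_521"] = {
            "p": between.p_value,
            "method": between.method,
            "note": between.note,
        }

    # ---- haplotype EM ----------------------------------------------------
    em_by_group: dict[str, HaplotypeFrequencies] = {}
    chromosomes: dict[str, int] = {}
    for scope in scopes:
        tlc = two_locus_counts(table, scope)
        if tlc.n_samples == 0:
            res.warnings.append(f"haplotype EM/{scope}: no samples with both loci observed")
            continue
        hf = em_haplotype_frequencies(tlc)
        for w in hf.warnings:
            res.warnings.append(f"haplotype EM/{scope}: {w}")
        em_by_group[scope] = hf
        chromosomes[scope] = 2 * tlc.n_samples
    res.details["haplotype_em"] = {
        scope: {
            "frequencies": dict(zip(HAPLOTYPE_NAMES, hf.as_array().tolist())),
            "loglik": hf.loglik,
            "n_iter": hf.n_iter,
            "converged": hf.converged,
            "n_chromosomes": chromosomes[scope],
        }
        for scope, hf in em_by_group.items()
    }
    real_groups = [g for g in groups if g in em_by_group]
    for i, hap in enumerate(HAPLOTYPE_NAMES):
        row = {"section": "haplotype_frequency_pct", "row": hap}
        for scope, hf in em_by_group.items():
            row[scope] = 100.0 * float(hf.as_array()[i])
        if multi_group and len(real_groups) > 1:
            # EM-expected chromosome counts, rounded for the count-based test
            cells = np.array(
                [
                    [int(round(float(em_by_group[g].as_array()[i]) * chromosomes[g])) for g in real_groups],
                    [chromosomes[g] - int(round(float(em_by_group[g].as_array()[i]) * chromosomes[g]))
                     for g in real_groups],
                ]
            )
            if cells.sum(axis=0).min() > 0:
                t = select_test(
                    ContingencyTable(cells, rows=[hap, "other"], cols=real_groups),
                    min_expected=min_expected,
                    n_draws=mc_draws,
                    seed=mc_seed,
                )
                row["p_value"], row["method"] = t.p_value, t.method
                row["note"] = "test on EM-expected rounded chromosome counts"
        res.rows.append(row)

    # ---- phenotypes ------------------------------------------------------
    pheno = phenotype_frequencies(table)
    res.details["phenotypes"] = {
        scope: {
            "n_normal": pc.n_normal,
            "n_intermediate": pc.n_intermediate,
            "n_low": pc.n_low,
            "n_excluded": pc.n_excluded,
            "percentages": pc.percentages(),
        }
        for scope, pc in pheno.items()
    }
    for name in PHENOTYPE_NAMES:
        row = {"section": "phenotype_frequency_pct", "row": name}
        for scope in scopes:
            pc = pheno[scope]
            row[scope] = pc.percentages()[name] if pc.n_classified else None
        classified = [g for g in groups if pheno[g].n_classified > 0]
        if multi_group and len(classified) > 1:
            count_of = {"normal": "n_normal", "intermediate": "n_intermediate", "low": "n_low"}[name]
            cells = np.array(
                [
                    [getattr(pheno[g], count_of) for g in classified],
                    [pheno[g].n_classified - getattr(pheno[g], count_of) for g in classified],
                ]
            )
            if cells.sum(axis=0).min() > 0 and cells.sum(axis=1).min() > 0:
                t = select_test(
                    ContingencyTable(cells, rows=[name, "other"], cols=classified),
                    min_expected=min_expected,
                    n_draws=mc_draws,
                    seed=mc_seed,
                )
                row["p_value"], row["method"] = t.p_value, t.method
        res.rows.append(row)

    return res
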