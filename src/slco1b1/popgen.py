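"""Allele counting, MAF, Hardy-Weinberg exact test, count reconstruction.

The HWE test is the exact conditional test for a biallelic autosomal SNP:
conditioning on the observed allele counts, the number of heterozygotes n_Aa
takes values of the same parity as the minor-allele count, with

    P(n_Aa | n, n_a)  propto  n! / (n_AA! n_Aa! n_aa!) * 2**n_Aa

and the p-value is the sum of the probabilities of all configurations no more
probable than the observed one (the standard two-sided tail-sum definition).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .io_formats import GenotypeTable, VariantSpec


@dataclass(frozen=True)
class AlleleCounts:
    """Chromosome counts of the ancestral and cDNA-variant allele in a group."""

    variant: VariantSpec
    group: str
    n_ancestral: int
    n_variant: int
    n_missing_samples: int = 0

    def __post_init__(self) -> None:
        if min(self.n_ancestral, self.n_variant, self.n_missing_samples) < 0:
            raise ValueError("negative counts")

    @property
    def n_chromosomes(self) -> int:
        return self.n_ancestral + self.n_variant


@dataclass(frozen=True)
class GenotypeCounts:
    n_hom_ancestral: int
    n_het: int
    n_hom_variant: int

    def __post_init__(self) -> None:
        if min(self.n_hom_ancestral, self.n_het, self.n_hom_variant) < 0:
            raise ValueError("negative genotype counts")

    @property
    def n(self) -> int:
        return self.n_hom_ancestral + self.n_het + self.n_hom_variant


@dataclass(frozen=True)
class TestResult:
    """A significance test outcome with its method tag.

    ``df`` is populated only for chi-square tests; ``mc_se`` only for the
    Monte-Carlo Fisher estimator.
    """

    method: str
    p_value: float
    statistic: Optional[float] = None
    df: Optional[int] = None
    mc_se: Optional[float] = None
    note: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside [0,1]")


def _dosage_attr(table: GenotypeTable, variant: VariantSpec) -> str:
    if variant.rsid == table.variants[0].rsid:
        return "dosage_388"
    if variant.rsid == table.variants[1].rsid:
        return "dosage_521"
    raise KeyError(f"variant {variant.rsid} not in table")


def allele_counts(table: GenotypeTable, variant: VariantSpec, group: str = "Total") -> AlleleCounts:
    """Count ancestral / variant chromosomes at one locus within one group.

    Samples missing at the locus contribute nothing to either allele count
    and are tallied in ``n_missing_samples``; denominators are therefore
    chromosomes actually observed (2 x non-missing samples).
    """
    subset = table.subset(group)
    attr = _dosage_attr(table, variant)
    n_var = n_obs = n_miss = 0
    for s in subset:
        d = getattr(s, attr)
        if d is None:
            n_miss += 1
        else:
            n_obs += 1
            n_var += d
    return AlleleCounts(
        variant=variant,
        group=group,
        n_ancestral=2 * n_obs - n_var,
        n_variant=n_var,
        n_missing_samples=n_miss,
    )


def genotype_counts(table: GenotypeTable, variant: VariantSpec, group: str = "Total") -> GenotypeCounts:
    """Genotype-class counts (hom-ancestral / het / hom-variant) for HWE."""
    subset = table.subset(group)
    attr = _dosage_attr(table, variant)
    tally = [0, 0, 0]
    for s in subset:
        d = getattr(s, attr)
        if d is not None:
            tally[d] += 1
    return GenotypeCounts(*tally)


def minor_allele_frequency(counts: AlleleCounts) -> tuple[float, str]:
    """Frequency of the second-most-common allele, with the allele itself.

    On an exact 50/50 tie the cDNA variant allele is reported as minor (a
    documented, arbitrary convention).
    """
    total = counts.n_chromosomes
    if total == 0:
        raise ValueError(f"{counts.variant.rsid}/{counts.group}: zero observed chromosomes")
    if counts.n_variant <= counts.n_ancestral:
        return counts.n_variant / total, counts.variant.variant_allele
    return counts.n_ancestral / total, counts.variant.ancestral_allele


def hwe_exact_test(g: GenotypeCounts) -> TestResult:
    """Exact conditional Hardy-Weinberg test (two-sided tail sum).

    Enumerates every heterozygote count compatible with the observed allele
    counts (same parity as the minor-allele count) and sums the conditional
    probabilities of all configurations no more probable than the observed
    one.  Monomorphic samples have a single attainable configuration, p = 1.
    """
    n = g.n
    if n == 0:
        raise ValueError("empty genotype table")
    n_a = 2 * g.n_hom_variant + g.n_het  # variant-allele chromosomes
    rare = min(n_a, 2 * n - n_a)

    # log unnormalised weight of a configuration with h heterozygotes
    def logw(h: int) -> float:
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        return (
            h * math.log(2.0)
            - math.lgamma(hom_rare + 1)
            - math.lgamma(h + 1)
            - math.lgamma(hom_common + 1)
        )

    hets = range(rare % 2, rare + 1, 2)
    logs = {h: logw(h) for h in hets}
    m = max(logs.values())
    weights = {h: math.exp(lw - m) for h, lw in logs.items()}
    total = sum(weights.values())
    w_obs = weights[g.n_het]
    p = sum(w for w in weights.values() if w <= w_obs * (1.0 + 1e-12)) / total
    return TestResult(method="hwe_exact", p_value=min(1.0, max(0.0, p)))


def hwe_chisq_test(g: GenotypeCounts) -> TestResult:
    """Chi-square goodness-of-fit alternative to the exact HWE test (df=1)."""
    from scipy.stats import chi2

    n = g.n
    if n == 0:
        raise ValueError("empty genotype table")
    q = (2 * g.n_hom_variant + g.n_het) / (2 * n)
    expected = [n * (1 - q) ** 2, 2 * n * q * (1 - q), n * q**2]
    observed = [g.n_hom_ancestral, g.n_het, g.n_hom_variant]
    if any(e == 0 for e in expected):
        return TestResult(method="chi_square", p_value=1.0, statistic=0.0, df=1,
                          note="monomorphic; test degenerate")
    stat = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    return TestResult(
        method="chi_square", p_value=float(chi2.sf(stat, 1)), statistic=stat, df=1
    )


def reconstruct_counts(
    percentages: Sequence[float], denominators: Sequence[int]
) -> tuple[list[int], list[float]]:
    """Recover integer counts behind printed percentages.

    count = round(pct * N / 100), half away from zero.  The returned residuals
    |count - pct*N/100| flag cells whose printed percentage cannot have come
    from an integer count over the stated denominator (residual > 0.5).
    """
    if len(percentages) != len(denominators):
        raise ValueError("percentages and denominators differ in length")
    counts, residuals = [], []
    for pct, n in zip(percentages, denominators):
        if not (0.0 <= pct <= 100.0):
            raise ValueError(f"percentage {pct} outside [0,100]")
        if n <= 0:
            raise ValueError("denominator must be positive")
        exact = pct * n / 100.0
        c = math.floor(exact + 0.5) if exact >= 0 else -math.floor(-exact + 0.5)
        counts.append(int(c))
        residuals.append(abs(c - exact))
    return counts, residuals
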