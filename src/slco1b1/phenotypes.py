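"""OATP1B1 transport-phenotype calling (CPIC 2014 simvastatin rules).

The phenotype is a function of the number of reduced-function alleles
(*5, *15 — the 521C-bearing haplotypes) in the diplotype:

    0 reduced alleles -> normal function
    1 reduced allele  -> intermediate function
    2 reduced alleles -> low function

Because both reduced alleles carry 521C and both functional alleles carry
521T, the count of reduced alleles equals the 521C dosage whatever the phase
of the double heterozygote: phenotypes are therefore called directly from the
unphased 521 dosage, and the diplotype route is retained as a cross-check.
The 2014 normal/intermediate/low labels are kept as the primary surface; a
mapping to the later normal/decreased/poor nomenclature is provided.
"""

from __future__ import annotations

from dataclasses import dataclass

from .haplotypes import Diplotype
from .io_formats import GenotypeTable

PHENOTYPE_NAMES = ("normal", "intermediate", "low")

PHENOTYPE_DEFINITIONS = {
    "normal": "two functional alleles",
    "intermediate": "one reduced-function allele",
    "low": "two reduced-function alleles",
}

#: CPIC 2014 label -> post-2014 nomenclature
MODERN_LABELS = {"normal": "normal", "intermediate": "decreased", "low": "poor"}


@dataclass(frozen=True)
class PhenotypeCounts:
    group: str
    n_normal: int
    n_intermediate: int
    n_low: int
    n_excluded: int  # samples missing a genotype at either locus

    @property
    def n_classified(self) -> int:
        return self.n_normal + self.n_intermediate + self.n_low

    def percentages(self) -> dict[str, float]:
        n = self.n_classified
        if n == 0:
            return {name: float("nan") for name in PHENOTYPE_NAMES}
        return {
            "normal": 100.0 * self.n_normal / n,
            "intermediate": 100.0 * self.n_intermediate / n,
            "low": 100.0 * self.n_low / n,
        }


def phenotype_from_dosage(dosage_521: int) -> str:
    """Phenotype class from the unphased 521C dosage."""
    if dosage_521 not in (0, 1, 2):
        raise ValueError(f"dosage_521 must be 0/1/2, got {dosage_521!r}")
    return PHENOTYPE_NAMES[dosage_521]


def phenotype_of(d: Diplotype) -> str:
    """Phenotype class of a called diplotype (count of reduced alleles)."""
    return PHENOTYPE_NAMES[d.n_reduced()]


def phenotype_frequencies(table: GenotypeTable) -> dict[str, PhenotypeCounts]:
    """Per-group and pooled phenotype counts.

    Samples missing either locus are excluded (and tallied), matching the
    exclusion set of the diplotype route, so the two routes classify exactly
    the same samples.
    """
    out: dict[str, PhenotypeCounts] = {}
    for group in ["Total"] + list(table.groups):
        tally = {name: 0 for name in PHENOTYPE_NAMES}
        excluded = 0
        for s in table.subset(group):
            if s.dosage_388 is None or s.dosage_521 is None:
                excluded += 1
            else:
                tally[phenotype_from_dosage(s.dosage_521)] += 1
        out[group] = PhenotypeCounts(
            group=group,
            n_normal=tally["normal"],
            n_intermediate=tally["intermediate"],
            n_low=tally["low"],
            n_excluded=excluded,
        )
    return out
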