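"""Two-locus star-allele haplotype inference.

The four haplotypes over (c.388, c.521) are the classical star alleles

    *1a = 388A + 521T   (wild type, functional)
    *1b = 388G + 521T   (functional)
    *5  = 388A + 521C   (reduced transport)
    *15 = 388G + 521C   (reduced transport)

Of the nine two-locus genotype classes, only the double heterozygote
(388 A/G, 521 T/C) is phase-ambiguous: it is either *1a/*15 or *1b/*5.
The EM algorithm resolves this under random mating (gametic-phase EM in the
Excoffier-Slatkin tradition): the E-step splits the double-heterozygote
count between the two phases in proportion to f_1a*f_15 vs f_1b*f_5, the
M-step re-estimates each frequency as its expected haplotype count over 2N.
All other cells contribute fixed gamete counts, so EM preserves the observed
marginal allele frequencies exactly at every iterate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .io_formats import GenotypeTable

HAPLOTYPE_NAMES = ("*1a", "*1b", "*5", "*15")


@dataclass(frozen=True)
class StarAllele:
    name: str
    allele_388: str
    allele_521: str
    functional_class: str  # "functional" | "reduced"


STAR_ALLELES = {
    "*1a": StarAllele("*1a", "A", "T", "functional"),
    "*1b": StarAllele("*1b", "G", "T", "functional"),
    "*5": StarAllele("*5", "A", "C", "reduced"),
    "*15": StarAllele("*15", "G", "C", "reduced"),
}


def star_allele(a388: str, a521: str) -> StarAllele:
    """Map a (388, 521) allele pair to its star allele."""
    if a388 not in ("A", "G"):
        raise ValueError(f"388 allele must be A or G, got {a388!r}")
    if a521 not in ("T", "C"):
        raise ValueError(f"521 allele must be T or C, got {a521!r}")
    name = {("A", "T"): "*1a", ("G", "T"): "*1b", ("A", "C"): "*5", ("G", "C"): "*15"}[(a388, a521)]
    return STAR_ALLELES[name]


# index of each haplotype in frequency vectors, fixed order (*1a,*1b,*5,*15)
_IDX = {name: i for i, name in enumerate(HAPLOTYPE_NAMES)}

# haplotype-pair composition of the eight unambiguous genotype classes,
# keyed by (dosage_388, dosage_521)
_UNAMBIGUOUS = {
    (0, 0): ("*1a", "*1a"),
    (0, 1): ("*1a", "*5"),
    (0, 2): ("*5", "*5"),
    (1, 0): ("*1a", "*1b"),
    (2, 0): ("*1b", "*1b"),
    (1, 2): ("*5", "*15"),
    (2, 1): ("*1b", "*15"),
    (2, 2): ("*15", "*15"),
}


@dataclass
class TwoLocusCounts:
    """3x3 genotype-class counts: n[i][j] samples with i copies of 388G and
    j copies of 521C; samples missing either locus are excluded and tallied."""

    n: np.ndarray
    group: str = "Total"
    n_missing: int = 0

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=np.int64)
        if self.n.shape != (3, 3):
            raise ValueError("counts must be 3x3")
        if (self.n < 0).any():
            raise ValueError("negative counts")

    @property
    def n_samples(self) -> int:
        return int(self.n.sum())


def two_locus_counts(table: GenotypeTable, group: str = "Total") -> TwoLocusCounts:
    """Tabulate the 3x3 two-locus genotype classes for one group."""
    n = np.zeros((3, 3), dtype=np.int64)
    missing = 0
    for s in table.subset(group):
        if s.dosage_388 is None or s.dosage_521 is None:
            missing += 1
        else:
            n[s.dosage_388, s.dosage_521] += 1
    return TwoLocusCounts(n=n, group=group, n_missing=missing)


@dataclass
class HaplotypeFrequencies:
    f_1a: float
    f_1b: float
    f_5: float
    f_15: float
    loglik: float = math.nan
    n_iter: int = 0
    converged: bool = False
    warnings: list[str] = field(default_factory=list)

    def as_array(self) -> np.ndarray:
        return np.array([self.f_1a, self.f_1b, self.f_5, self.f_15])

    def __post_init__(self) -> None:
        f = self.as_array()
        if (f < -1e-12).any() or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError(f"haplotype frequencies not on the simplex: {f}")


def _genotype_class_logprobs(f: np.ndarray) -> np.ndarray:
    """log P(genotype class (i,j) | f) under random mating, 3x3 array."""
    f1a, f1b, f5, f15 = f
    p = np.empty((3, 3))
    p[0, 0] = f1a**2
    p[0, 1] = 2 * f1a * f5
    p[0, 2] = f5**2
    p[1, 0] = 2 * f1a * f1b
    p[2, 0] = f1b**2
    p[1, 2] = 2 * f5 * f15
    p[2, 1] = 2 * f1b * f15
    p[2, 2] = f15**2
    p[1, 1] = 2 * (f1a * f15 + f1b * f5)
    with np.errstate(divide="ignore"):
        return np.log(p)


def _loglik(counts: np.ndarray, f: np.ndarray) -> float:
    logp = _genotype_class_logprobs(f)
    mask = counts > 0
    if np.any(np.isneginf(logp[mask])):
        return -math.inf
    return float((counts[mask] * logp[mask]).sum())


def _expected_haplotype_counts(counts: np.ndarray, f: np.ndarray) -> tuple[np.ndarray, Optional[str]]:
    """E-step: expected haplotype counts given f; returns (counts4, warning)."""
    h = np.zeros(4)
    warn = None
    for (i, j), (a, b) in _UNAMBIGUOUS.items():
        c = counts[i, j]
        if c:
            h[_IDX[a]] += c
            h[_IDX[b]] += c
    n11 = counts[1, 1]
    if n11:
        num = f[_IDX["*1a"]] * f[_IDX["*15"]]
        den = num + f[_IDX["*1b"]] * f[_IDX["*5"]]
        if den == 0.0:
            share = 0.5
            warn = "E-step denominator zero with double heterozygotes present; split 50/50"
        else:
            share = num / den
        h[_IDX["*1a"]] += n11 * share
        h[_IDX["*15"]] += n11 * share
        h[_IDX["*1b"]] += n11 * (1 - share)
        h[_IDX["*5"]] += n11 * (1 - share)
    return h, warn


def _le_init(counts: np.ndarray) -> np.ndarray:
    """Linkage-equilibrium start: product of observed marginal allele freqs."""
    n = counts.sum()
    p_g = (counts[1, :].sum() + 2 * counts[2, :].sum()) / (2 * n)
    p_c = (counts[:, 1].sum() + 2 * counts[:, 2].sum()) / (2 * n)
    return np.array(
        [(1 - p_g) * (1 - p_c), p_g * (1 - p_c), (1 - p_g) * p_c, p_g * p_c]
    )


def em_haplotype_frequencies(
    counts: TwoLocusCounts,
    init: Union[str, Sequence[float]] = "LE",
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> HaplotypeFrequencies:
    """Maximum-likelihood haplotype frequencies by EM.

    ``init`` is either ``"LE"`` (deterministic linkage-equilibrium start, the
    default — no RNG is involved in inference) or an explicit simplex
    4-vector.  Iterates until ``max |Δf| < tol`` or ``max_iter``.  When the
    only occupied class is the double heterozygote the likelihood is flat
    along a ridge; this is detected structurally and flagged rather than
    iterated over.
    """
    n_tab = counts.n
    n = counts.n_samples
    if n == 0:
        raise ValueError("no samples with both loci observed")

    if isinstance(init, str):
        if init != "LE":
            raise ValueError(f"unknown init {init!r}")
        f = _le_init(n_tab)
    else:
        f = np.asarray(init, dtype=float)
        if f.shape != (4,) or (f < 0).any() or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("init must be a simplex 4-vector")

    warnings_: list[str] = []
    non_identifiable = n_tab[1, 1] > 0 and n_tab[1, 1] == n
    if non_identifiable:
        warnings_.append(
            "only double heterozygotes observed: phase split non-identifiable "
            "(flat likelihood ridge); reporting the initialisation point"
        )

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        h, warn = _expected_haplotype_counts(n_tab, f)
        if warn and warn not in warnings_:
            warnings_.append(warn)
        f_new = h / (2 * n)
        delta = float(np.max(np.abs(f_new - f)))
        f = f_new
        if delta < tol:
            converged = True
            break
    return HaplotypeFrequencies(
        f_1a=float(f[0]),
        f_1b=float(f[1]),
        f_5=float(f[2]),
        f_15=float(f[3]),
        loglik=_loglik(n_tab, f),
        n_iter=it,
        converged=converged or non_identifiable,
        warnings=warnings_,
    )


def haplotype_frequency_se(counts: TwoLocusCounts, f: HaplotypeFrequencies) -> np.ndarray:
    """Asymptotic standard errors of the four frequency estimates.

    Inverts the observed information matrix (numerical Hessian of the
    log-likelihood in the three free coordinates f_1a, f_1b, f_5, central
    differences, step 1e-5); the *15 variance follows by the delta method
    from f_15 = 1 - f_1a - f_1b - f_5.  Requires an interior optimum —
    estimates at the simplex boundary have no finite-information SE and
    raise.
    """
    x0 = f.as_array()[:3]
    if (f.as_array() < 1e-6).any():
        raise ValueError("boundary estimate: observed-information SE undefined")

    def ll(x: np.ndarray) -> float:
        return _loglik(counts.n, np.array([x[0], x[1], x[2], 1.0 - x.sum()]))

    h = 1e-5
    hess = np.zeros((3, 3))
    for i in range(3):
        for j in range(i, 3):
            ei = np.eye(3)[i] * h
            ej = np.eye(3)[j] * h
            if i == j:
                hess[i, i] = (ll(x0 + ei) - 2.0 * ll(x0) + ll(x0 - ei)) / h**2
            else:
                hess[i, j] = hess[j, i] = (
                    ll(x0 + ei + ej) - ll(x0 + ei - ej) - ll(x0 - ei + ej) + ll(x0 - ei - ej)
                ) / (4.0 * h**2)
    cov = np.linalg.inv(-hess)
    ones = np.ones(3)
    var = np.append(np.diag(cov), ones @ cov @ ones)
    if (var <= 0).any():
        raise ValueError("observed information not positive definite")
    return np.sqrt(var)


@dataclass(frozen=True)
class Diplotype:
    """Unordered star-allele pair with the posterior of the reported phase."""

    alleles: tuple[StarAllele, StarAllele]
    phase_posterior: float
    ambiguous: bool

    @property
    def name(self) -> str:
        return "/".join(a.name for a in self.alleles)

    def n_reduced(self) -> int:
        return sum(a.functional_class == "reduced" for a in self.alleles)


def assign_diplotype(dosage_388: int, dosage_521: int, f: HaplotypeFrequencies) -> Diplotype:
    """Call the star-allele pair for one sample.

    Eight genotype classes force the phase (posterior 1).  The double
    heterozygote is assigned the more probable of *1a/*15 and *1b/*5 under
    ``f``, with the phase posterior attached; an exact tie (including the
    degenerate all-zero case) goes to *1a/*15.
    """
    if dosage_388 is None or dosage_521 is None:
        raise ValueError("missing dosage: filter samples before diplotype assignment")
    if dosage_388 not in (0, 1, 2) or dosage_521 not in (0, 1, 2):
        raise ValueError("dosages must be in {0,1,2}")
    key = (dosage_388, dosage_521)
    if key in _UNAMBIGUOUS:
        a, b = _UNAMBIGUOUS[key]
        return Diplotype((STAR_ALLELES[a], STAR_ALLELES[b]), 1.0, False)
    p_cis = f.f_1a * f.f_15  # *1a/*15 phase
    p_trans = f.f_1b * f.f_5
    total = p_cis + p_trans
    if total == 0.0 or p_cis >= p_trans:
        post = 0.5 if total == 0.0 else p_cis / total
        return Diplotype((STAR_ALLELES["*1a"], STAR_ALLELES["*15"]), post, True)
    return Diplotype((STAR_ALLELES["*1b"], STAR_ALLELES["*5"]), p_trans / total, True)


def haplotype_frequency_table(
    freqs: dict[str, HaplotypeFrequencies], chromosomes: dict[str, int]
) -> list[dict[str, object]]:
    """Report rows: per-haplotype percentages and EM-expected counts per group.

    Expected counts (f x n_chromosomes) are for display; inference always
    carries real-valued frequencies.
    """
    rows = []
    for name in HAPLOTYPE_NAMES:
        i = _IDX[name]
        row: dict[str, object] = {"section": "haplotype_frequency_pct", "row": name}
        for group, hf in freqs.items():
            f = float(hf.as_array()[i])
            row[group] = 100.0 * f
            row[f"{group}_expected_count"] = f * chromosomes[group]
        rows.append(row)
    return rows
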