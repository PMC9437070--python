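"""Contingency-table tests for cross-group frequency comparisons.

Three methods, selected by a recorded policy: Pearson chi-square (no
continuity correction), the exact two-sided 2x2 Fisher test, and a seeded
Monte-Carlo Fisher test for larger tables (tables sampled from the
conditional null given both margins by sequential hypergeometric fill, as in
R's ``r2dtable``).  Raw p-values, alpha = 0.05, no multiplicity adjustment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np
from scipy.stats import chi2 as chi2_dist

from .popgen import AlleleCounts, TestResult


@dataclass
class ContingencyTable:
    cells: np.ndarray
    rows: Optional[Sequence[str]] = None
    cols: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.int64)
        if self.cells.ndim != 2 or min(self.cells.shape) < 2:
            raise ValueError("contingency table must be at least 2x2")
        if (self.cells < 0).any():
            raise ValueError("negative cell counts")

    @property
    def shape(self) -> tuple[int, int]:
        return self.cells.shape


def _expected(cells: np.ndarray) -> np.ndarray:
    n = cells.sum()
    return np.outer(cells.sum(axis=1), cells.sum(axis=0)) / n


def chi_square_test(t: ContingencyTable) -> TestResult:
    """Pearson chi-square test of homogeneity, no continuity correction."""
    cells = t.cells
    if (cells.sum(axis=1) == 0).any() or (cells.sum(axis=0) == 0).any():
        raise ValueError("zero margin: use fisher_exact_2x2 or fisher_rxc_montecarlo")
    e = _expected(cells)
    stat = float(((cells - e) ** 2 / e).sum())
    r, c = cells.shape
    df = (r - 1) * (c - 1)
    return TestResult(
        method="chi_square", p_value=float(chi2_dist.sf(stat, df)), statistic=stat, df=df
    )


def fisher_exact_2x2(t: ContingencyTable) -> TestResult:
    """Two-sided Fisher exact test: sum of hypergeometric probabilities of
    all tables with the observed margins no more probable than the observed
    one.  Weights are exact integers (products of binomial coefficients), so
    probability ties are resolved exactly rather than through a float
    tolerance."""
    cells = t.cells
    if cells.shape != (2, 2):
        raise ValueError("fisher_exact_2x2 requires a 2x2 table")
    a = int(cells[0, 0])
    r1, r2 = (int(x) for x in cells.sum(axis=1))
    c1 = int(cells[:, 0].sum())
    n = int(cells.sum())
    if n == 0:
        return TestResult(method="fisher_2x2", p_value=1.0)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = [math.comb(r1, x) * math.comb(r2, c1 - x) for x in range(lo, hi + 1)]
    w_obs = weights[a - lo]
    num = sum(w for w in weights if w <= w_obs)
    p = float(Fraction(num, sum(weights)))
    return TestResult(method="fisher_2x2", p_value=min(1.0, max(0.0, p)))


def _log_table_prob(cells: np.ndarray) -> float:
    """Log conditional probability of a table given both margins."""
    rows = cells.sum(axis=1)
    cols = cells.sum(axis=0)
    n = cells.sum()
    return float(
        sum(math.lgamma(r + 1) for r in rows)
        + sum(math.lgamma(c + 1) for c in cols)
        - math.lgamma(n + 1)
        - sum(math.lgamma(x + 1) for x in cells.ravel())
    )


def _sample_table(rng: np.random.Generator, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """One table from the null given both margins (sequential hypergeometric)."""
    r, c = len(rows), len(cols)
    out = np.zeros((r, c), dtype=np.int64)
    col_rem = cols.astype(np.int64).copy()
    for i in range(r - 1):
        row_rem = int(rows[i])
        tail = int(col_rem.sum())
        for j in range(c - 1):
            tail -= int(col_rem[j])  # capacity strictly right of column j
            # support bounds max(0, row_rem - tail) <= x <= min(col_rem[j],
            # row_rem) keep every later completion non-negative
            x = int(rng.hypergeometric(col_rem[j], tail, row_rem)) if row_rem else 0
            out[i, j] = x
            row_rem -= x
            col_rem[j] -= x
        out[i, c - 1] = row_rem
        col_rem[c - 1] -= row_rem
    out[r - 1, :] = col_rem
    return out


def fisher_rxc_montecarlo(t: ContingencyTable, n_draws: int = 100_000, seed: int = 0) -> TestResult:
    """Monte-Carlo Fisher test for r x c tables.

    p_hat = (1 + #{simulated tables at most as probable as observed}) /
    (n_draws + 1); deterministic given ``seed``; the standard binomial Monte
    Carlo standard error is attached.
    """
    if n_draws < 1000:
        raise ValueError("n_draws must be >= 1000")
    cells = t.cells
    rows = cells.sum(axis=1)
    cols = cells.sum(axis=0)
    logp_obs = _log_table_prob(cells)
    rng = np.random.Generator(np.random.PCG64(seed))
    hits = 0
    for _ in range(n_draws):
        sim = _sample_table(rng, rows, cols)
        if _log_table_prob(sim) <= logp_obs + 1e-7:
            hits += 1
    p = (1 + hits) / (n_draws + 1)
    se = math.sqrt(p * (1 - p) / n_draws)
    return TestResult(method="fisher_mc", p_value=p, mc_se=se)


def compare_variant_mafs(c1: AlleleCounts, c2: AlleleCounts) -> TestResult:
    """Chi-square comparison of the variant-allele frequencies at two loci.

    Treats the two loci's chromosome sets as independent samples even though
    they come from the same individuals — the result is flagged accordingly.
    """
    if c1.n_chromosomes == 0 or c2.n_chromosomes == 0:
        raise ValueError("zero observed chromosomes")
    table = ContingencyTable(
        np.array(
            [[c1.n_variant, c1.n_ancestral], [c2.n_variant, c2.n_ancestral]]
        ),
        rows=[c1.variant.rsid, c2.variant.rsid],
        cols=["variant", "ancestral"],
    )
    if (table.cells.sum(axis=0) == 0).any():
        res = fisher_exact_2x2(table)
    else:
        res = chi_square_test(table)
    return TestResult(
        method=res.method,
        p_value=res.p_value,
        statistic=res.statistic,
        df=res.df,
        note="unpaired comparison: within-sample pairing of the two loci ignored",
    )


def select_test(
    t: ContingencyTable,
    min_expected: float = 5.0,
    n_draws: int = 100_000,
    seed: int = 0,
) -> TestResult:
    """Default test-selection policy, recorded in the result's method tag.

    Chi-square when every expected cell is >= ``min_expected``; otherwise the
    exact Fisher test for 2x2 tables, and the seeded Monte-Carlo Fisher test
    for anything larger.
    """
    zero_margin = (t.cells.sum(axis=1) == 0).any() or (t.cells.sum(axis=0) == 0).any()
    if not zero_margin and (_expected(t.cells) >= min_expected).all():
        return chi_square_test(t)
    if t.shape == (2, 2):
        return fisher_exact_2x2(t)
    return fisher_rxc_montecarlo(t, n_draws=n_draws, seed=seed)
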