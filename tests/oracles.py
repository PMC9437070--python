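"""Independent brute-force oracles used to validate the inference code.

Everything here is deliberately written from first principles — exact
integer/rational arithmetic for the conditional tests, a dense likelihood
grid for the EM — and shares no code path with the implementation under
test.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np


def hwe_exact_oracle(n_hom_ancestral: int, n_het: int, n_hom_variant: int) -> Fraction:
    """Exact-rational HWE tail sum by enumerating every genotype configuration
    compatible with the observed allele counts."""
    n = n_hom_ancestral + n_het + n_hom_variant
    n_var = 2 * n_hom_variant + n_het
    weights: dict[int, int] = {}
    for h in range(0, n + 1):
        if (n_var - h) % 2:
            continue
        x_vv = (n_var - h) // 2
        x_aa = n - h - x_vv
        if x_vv < 0 or x_aa < 0:
            continue
        weights[h] = (2**h) * comb(n, h) * comb(n - h, x_vv)
    w_obs = weights[n_het]
    return Fraction(sum(w for w in weights.values() if w <= w_obs), sum(weights.values()))


def fisher_2x2_oracle(a: int, b: int, c: int, d: int) -> Fraction:
    """Exact-rational two-sided Fisher p by enumerating all tables with the
    observed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    ws = {x: comb(r1, x) * comb(r2, c1 - x) for x in range(max(0, c1 - r2), min(r1, c1) + 1)}
    return Fraction(sum(w for w in ws.values() if w <= ws[a]), sum(ws.values()))


def _loglik_vec(n: np.ndarray, a, b, c, d):
    """Random-mating two-locus genotype-class log-likelihood, vectorised over
    candidate frequency vectors (a,b,c,d) = (f_1a, f_1b, f_5, f_15)."""
    terms = {
        (0, 0): a * a,
        (0, 1): 2 * a * c,
        (0, 2): c * c,
        (1, 0): 2 * a * b,
        (2, 0): b * b,
        (1, 2): 2 * c * d,
        (2, 1): 2 * b * d,
        (2, 2): d * d,
        (1, 1): 2 * (a * d + b * c),
    }
    ll = np.zeros_like(np.asarray(a, dtype=float))
    with np.errstate(divide="ignore", invalid="ignore"):
        for (i, j), p in terms.items():
            if n[i, j]:
                ll = ll + n[i, j] * np.log(p)
    return ll


def grid_search_haplotype_ml(
    counts: np.ndarray, coarse: float = 0.01, refinements: int = 3
) -> tuple[np.ndarray, float]:
    """Dense grid maximisation of the two-locus likelihood over the 3-simplex.

    A vectorised coarse grid (step ``coarse``) followed by ``refinements``
    local ten-fold refinements, reaching 1e-5 resolution at the optimum with
    the defaults.  Returns (f 4-vector, loglik).
    """
    counts = np.asarray(counts)
    step = coarse
    vals = np.arange(0.0, 1.0 + step / 2, step)
    grids = np.meshgrid(vals, vals, vals, indexing="ij")
    best = None
    for _ in range(refinements + 1):
        A, B, C = grids
        m = A + B + C <= 1 + 1e-12
        a, b, c = A[m], B[m], C[m]
        d = np.clip(1 - a - b - c, 0, None)
        ll = _loglik_vec(counts, a, b, c, d)
        k = int(np.nanargmax(ll))
        best = np.array([a[k], b[k], c[k]])
        new_step = step / 10
        ranges = [
            np.arange(max(0, best[i] - step), min(1, best[i] + step) + new_step / 2, new_step)
            for i in range(3)
        ]
        grids = np.meshgrid(*ranges, indexing="ij")
        step = new_step
    f = np.array([best[0], best[1], best[2], max(0.0, 1 - best.sum())])
    ll = float(_loglik_vec(counts, *[np.array([x]) for x in f])[0])
    return f, ll


def random_mating_table(rng: np.random.Generator, f: np.ndarray, n: int) -> np.ndarray:
    """Multinomial 3x3 genotype-class counts under random mating at f."""
    a, b, c, d = f
    p = np.zeros((3, 3))
    p[0, 0] = a * a
    p[0, 1] = 2 * a * c
    p[0, 2] = c * c
    p[1, 0] = 2 * a * b
    p[2, 0] = b * b
    p[1, 2] = 2 * c * d
    p[2, 1] = 2 * b * d
    p[2, 2] = d * d
    p[1, 1] = 2 * (a * d + b * c)
    return rng.multinomial(n, p.ravel()).reshape(3, 3)
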