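"""Independent brute-force oracles used by the test suite.

Everything here is deliberately implemented from first principles (exact
rational arithmetic, naive enumeration, grid search, hand-rolled Newton) so
the tests compare the package against a second, independent route.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np


def hwe_exact_oracle(n_aa: int, n_het: int, n_bb: int) -> float:
    """Exact two-sided HWE P by direct enumeration in rational arithmetic."""
    n = n_aa + n_het + n_bb
    rare = min(2 * n_aa + n_het, 2 * n_bb + n_het)
    ways = {}
    for het in range(rare % 2, rare + 1, 2):
        n_rr = (rare - het) // 2
        n_cc = n - het - n_rr
        ways[het] = Fraction(comb(n, het) * comb(n - het, n_rr) * 2**het)
    total = sum(ways.values())
    probs = {h: w / total for h, w in ways.items()}
    obs = probs[n_het]
    return float(sum(pr for pr in probs.values() if pr <= obs))


def bh_oracle(pvalues) -> np.ndarray:
    """Step-up BH from the definition: sort, scale by m/rank, cumulative min."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    running = np.inf
    for i in range(m - 1, -1, -1):
        running = min(running, p[order[i]] * m / (i + 1))
        adj_sorted[i] = min(running, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def hypergeom_upper_tail_oracle(k: int, n_draw: int, K: int, N: int) -> float:
    """P(X >= k) by exact rational enumeration of the hypergeometric pmf."""
    denom = comb(N, n_draw)
    total = Fraction(0)
    for x in range(k, min(n_draw, K) + 1):
        total += Fraction(comb(K, x) * comb(N - K, n_draw - x), denom)
    return float(total)


def newton_logistic(X: np.ndarray, y: np.ndarray, n_starts: int = 5,
                    seed: int = 0, tol: float = 1e-12) -> np.ndarray:
    """Multi-start Newton-Raphson MLE for logistic regression (X includes intercept)."""
    rng = np.random.default_rng(seed)
    best, best_ll = None, -np.inf
    p_dim = X.shape[1]
    starts = [np.zeros(p_dim)] + [rng.normal(0, 0.5, p_dim) for _ in range(n_starts - 1)]
    for beta in starts:
        beta = beta.copy()
        for _ in range(200):
            eta = np.clip(X @ beta, -500, 500)
            mu = 1.0 / (1.0 + np.exp(-eta))
            grad = X.T @ (y - mu)
            W = mu * (1 - mu)
            H = X.T @ (X * W[:, None])
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                break
            beta = beta + step
            if np.max(np.abs(step)) < tol:
                break
        eta = X @ beta
        ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        if np.isfinite(ll) and ll > best_ll:
            best_ll, best = ll, beta
    return best


def grid_logistic_slope(dosage: np.ndarray, y: np.ndarray) -> float:
    """Brute-force ML slope for y ~ intercept + beta * dosage by nested grid search."""
    def nll(a, b):
        eta = a + b * dosage
        return float(np.sum(np.logaddexp(0.0, eta) - y * eta))

    a_lo, a_hi, b_lo, b_hi = -5.0, 5.0, -5.0, 5.0
    best = (0.0, 0.0)
    for _ in range(6):  # successive 41x41 refinements: final cell < 1e-6
        aa = np.linspace(a_lo, a_hi, 41)
        bb = np.linspace(b_lo, b_hi, 41)
        vals = [(nll(a, b), a, b) for a in aa for b in bb]
        _, a0, b0 = min(vals)
        da, db = (a_hi - a_lo) / 40, (b_hi - b_lo) / 40
        a_lo, a_hi = a0 - 2 * da, a0 + 2 * da
        b_lo, b_hi = b0 - 2 * db, b0 + 2 * db
        best = (a0, b0)
    return best[1]


def nnls_grid_2signature(m: np.ndarray, s1: np.ndarray, s2: np.ndarray):
    """Grid-search least squares over non-negative 2-signature weights.

    Coarse-to-fine search of (w1, w2) on [0, 1.2]^2; returns (w1, w2, residual).
    """
    lo1, hi1, lo2, hi2 = 0.0, 1.2, 0.0, 1.2
    best = (np.inf, 0.0, 0.0)
    for _ in range(6):
        g1 = np.linspace(lo1, hi1, 25)
        g2 = np.linspace(lo2, hi2, 25)
        for w1 in g1:
            r1 = m - w1 * s1
            for w2 in g2:
                r = r1 - w2 * s2
                val = float(r @ r)
                if val < best[0]:
                    best = (val, w1, w2)
        d1, d2 = (hi1 - lo1) / 24, (hi2 - lo2) / 24
        lo1, hi1 = max(0.0, best[1] - 2 * d1), best[1] + 2 * d1
        lo2, hi2 = max(0.0, best[2] - 2 * d2), best[2] + 2 * d2
    return best[1], best[2], np.sqrt(best[0])
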