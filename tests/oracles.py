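"""Independent reference implementations used to cross-check the package.

Everything here deliberately avoids the code paths under test: the penalized
posterior mode is found by generic numerical optimization of the objective
written out directly; binomial p-values are summed from the probability mass
function; Tajima's D is recomputed from explicit pairwise differences; ROC
AUC is counted over all score pairs.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
from scipy.optimize import minimize


def penalized_objective(beta, x, y, m):
    """Direct transcription of the penalized log-likelihood (no augmentation)."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    if x is None:
        eta = np.full(len(y), beta[0])
    else:
        eta = beta[0] + beta[1] * np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ll = np.sum(y * eta - np.logaddexp(0.0, eta))
    pen = sum(m * (0.5 * b - np.logaddexp(0.0, b)) for b in beta)
    return ll + pen


def numeric_mode(x, y, m):
    """Posterior mode by quasi-Newton optimization of the objective above."""
    k = 1 if x is None else 2

    def neg(beta):
        return -penalized_objective(beta, x, y, m)

    def grad(beta):
        beta = np.atleast_1d(beta)
        if x is None:
            X = np.ones((len(y), 1))
        else:
            X = np.column_stack([np.ones(len(y)), np.asarray(x, dtype=float)])
        eta = X @ beta
        pi = 1.0 / (1.0 + np.exp(-eta))
        g = X.T @ (np.asarray(y, dtype=float) - pi)
        g += m * (0.5 - 1.0 / (1.0 + np.exp(-beta)))
        return -g

    best = None
    for start in ([0.0] * k, [1.0] * k, [-1.0, 1.0][:k]):
        r = minimize(neg, start, jac=grad, method="BFGS",
                     options={"gtol": 1e-12, "maxiter": 500})
        if best is None or r.fun < best.fun:
            best = r
    return best.x, -best.fun


def table_vectors(s0, n0, s1, n1):
    """Expand a 2x2 haplotype table into x/y vectors."""
    x = np.array([0] * n0 + [1] * n1)
    y = np.array([1] * s0 + [0] * (n0 - s0) + [1] * s1 + [0] * (n1 - s1))
    return x, y


def binom_pvalue_two_sided(k, n, p):
    """Two-sided exact binomial p-value by enumeration (minimum-likelihood)."""
    pmf = [math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(n + 1)]
    pk = pmf[k]
    return min(1.0, sum(q for q in pmf if q <= pk * (1 + 1e-12)))


def tajimas_d_reference(matrix):
    """Tajima's D from explicit pairwise Hamming distances."""
    matrix = np.asarray(matrix)
    n, S_all = matrix.shape
    seg = [
        j for j in range(S_all) if 0 < matrix[:, j].sum() < n
    ]
    S = len(seg)
    if S == 0:
        return math.nan
    sub = matrix[:, seg]
    total = sum(
        int(np.sum(sub[i] != sub[j])) for i, j in combinations(range(n), 2)
    )
    pi = total / (n * (n - 1) / 2)
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def auc_reference(selected, neutral):
    """ROC AUC by comparing every (selected, neutral) pair; ties count half."""
    wins = 0.0
    for s in selected:
        for u in neutral:
            wins += 1.0 if s > u else (0.5 if s == u else 0.0)
    return wins / (len(selected) * len(neutral))


def greedy_peaks_reference(records, exclusion_bp, k):
    """Peak calling by repeated full scans of a plain record list."""
    remaining = sorted(records, key=lambda r: (-r[2], r[0], r[1]))
    accepted = []
    for chrom, pos, value in remaining:
        ok = all(
            c != chrom or abs(pos - p) > exclusion_bp / 2 for c, p, _ in accepted
        )
        if ok:
            accepted.append((chrom, pos, value))
            if len(accepted) == k:
                break
    return accepted
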