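"""LD-ABF: penalized logistic regression, approximate Bayes factors, windowed score.

The statistic asks how well a phased test SNP x predicts each neighboring
variant y within a window.  For each neighbor a logistic regression
P(y=1 | x) = logit^-1(b0 + b1 x) is fit at its posterior mode under
independent logF(m, m) priors on the coefficients, which is the same as
maximizing the penalized log-likelihood

    l(b) + sum_coeff [ (m/2) b_c - m log(1 + e^{b_c}) ].

The log approximate Bayes factor of the slope model against the
intercept-only model is the difference of the two penalized objectives at
their modes (the slope model carries one extra prior factor; no logF
normalizing constant is added, so an independent pair contributes
-log 2 per neighbor at m = 1).  The windowed LD-ABF score is the sum of
log-ABFs over all segregating neighbors within W/2 bp of the test SNP,
divided by the window size W: positions without a segregating variant
contribute log(1) = 0, so denser, more strongly linked windows score higher.

Fitting uses the data-augmentation representation of the logF(m, m) prior:
each penalized coefficient adds one pseudo-observation with m trials and
m/2 successes at a design row that is 1 for that coefficient and 0
elsewhere, after which the augmented likelihood is maximized by Newton
iteration.  At the mode the augmented log-likelihood equals the penalized
objective exactly, and m = 0 recovers maximum likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = [
    "WindowConfig",
    "PenalizedLogisticFit",
    "LdAbfScore",
    "ConvergenceError",
    "logf_log_prior",
    "fit_penalized_logistic",
    "log_abf",
    "ld_abf_at_site",
]

MAX_ITER = 100
GRAD_TOL = 1e-8


class ConvergenceError(RuntimeError):
    """Newton iteration failed; carries the last iterate in ``last_beta``."""

    def __init__(self, msg: str, last_beta: np.ndarray):
        super().__init__(msg)
        self.last_beta = np.asarray(last_beta, dtype=float)


@dataclass(frozen=True)
class WindowConfig:
    """Scan window: total width in bp, centered on the test SNP.

    Neighbors at 0 < |delta pos| <= width_bp/2 are included (closed at the
    boundary); the score is always normalized by the full ``width_bp``.
    """

    width_bp: int = 1000
    include_self: bool = False

    def __post_init__(self):
        if self.width_bp <= 0 or self.width_bp % 2 != 0:
            raise ValueError(f"width_bp must be positive and even, got {self.width_bp}")

    @property
    def half_width(self) -> int:
        return self.width_bp // 2


@dataclass(frozen=True)
class PenalizedLogisticFit:
    beta0: float
    beta1: float | None
    objective: float
    converged: bool
    n_iter: int


@dataclass(frozen=True)
class LdAbfScore:
    pos: int
    score: float
    n_neighbors: int


def logf_log_prior(beta: float, m: float) -> float:
    """Unnormalized logF(m, m) log-density: (m/2)·b − m·log(1 + e^b).

    Even in b; overflow-safe for large |b|.  No normalizing constant is
    included, matching how the prior enters the Bayes factor.
    """
    if m < 0:
        raise ValueError(f"m must be >= 0, got {m}")
    b = float(beta)
    return m * (0.5 * b - float(np.logaddexp(0.0, b)))


def _as_binary(v, name: str) -> np.ndarray:
    a = np.asarray(v)
    if a.ndim != 1 or a.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-D vector")
    if not np.isin(a, (0, 1)).all():
        raise ValueError(f"{name} must be binary (0/1)")
    return a.astype(np.float64)


def _binom_loglik(beta: np.ndarray, X: np.ndarray, trials: np.ndarray,
                  succ: np.ndarray) -> float:
    eta = X @ beta
    # succ*eta - trials*log(1+e^eta), overflow-safe
    return float(np.sum(succ * eta - trials * np.logaddexp(0.0, eta)))


def _newton_fit(X: np.ndarray, trials: np.ndarray, succ: np.ndarray,
                max_iter: int = MAX_ITER, tol: float = GRAD_TOL):
    """Maximize the aggregated binomial log-likelihood by damped Newton."""
    beta = np.zeros(X.shape[1])
    obj = _binom_loglik(beta, X, trials, succ)
    for it in range(1, max_iter + 1):
        eta = X @ beta
        pi = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (succ - trials * pi)
        if np.max(np.abs(grad)) < tol:
            return beta, obj, True, it - 1
        w = trials * pi * (1.0 - pi)
        # guard against exactly-flat weights under extreme eta
        w = np.maximum(w, 1e-300)
        hess = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            raise ConvergenceError("singular Hessian in Newton fit", beta)
        # step-halving line search
        for _ in range(60):
            cand = beta + step
            cand_obj = _binom_loglik(cand, X, trials, succ)
            if cand_obj >= obj - 1e-13:
                break
            step = 0.5 * step
        else:
            raise ConvergenceError("line search failed", beta)
        beta, obj = cand, cand_obj
    eta = X @ beta
    pi = 1.0 / (1.0 + np.exp(-eta))
    grad = X.T @ (succ - trials * pi)
    if np.max(np.abs(grad)) < tol:
        return beta, obj, True, max_iter
    raise ConvergenceError(
        f"no convergence after {max_iter} Newton iterations "
        f"(max |grad| = {np.max(np.abs(grad)):.3g})",
        beta,
    )


def _fit_counts_intercept(sy: float, n: float, m: float):
    """Closed-form posterior mode of the intercept-only model.

    The augmented counts are (sy + m/2) successes in (n + m) trials, so the
    mode is logit of the augmented success fraction.
    """
    num, den = sy + 0.5 * m, n + m
    if num <= 0 or num >= den:
        raise ConvergenceError(
            "intercept-only mode is infinite (m = 0 with degenerate outcome)",
            np.array([np.inf if num >= den else -np.inf]),
        )
    b0 = float(np.log(num) - np.log(den - num))
    obj = sy * b0 - n * float(np.logaddexp(0.0, b0)) + logf_log_prior(b0, m)
    return b0, obj


@lru_cache(maxsize=200_000)
def _log_abf_counts(s0: int, n0: int, s1: int, n1: int, m: float) -> float:
    """log-ABF from the 2x2 table: among n0 haplotypes with x=0, s0 carry y=1;
    among n1 with x=1, s1 carry y=1."""
    sy, n = s0 + s1, n0 + n1
    if sy == 0 or sy == n:
        return 0.0  # monomorphic neighbor: uninformative, ABF = 1
    _, obj0 = _fit_counts_intercept(sy, n, m)
    X = np.array([[1.0, 0.0], [1.0, 1.0], [1.0, 0.0], [0.0, 1.0]])
    trials = np.array([n0, n1, m, m], dtype=float)
    succ = np.array([s0, s1, 0.5 * m, 0.5 * m], dtype=float)
    if m == 0:
        X, trials, succ = X[:2], trials[:2], succ[:2]
    keep = trials > 0
    _, obj1, _, _ = _newton_fit(X[keep], trials[keep], succ[keep])
    return obj1 - obj0


def fit_penalized_logistic(
    x,
    y,
    m: float = 1.0,
    max_iter: int = MAX_ITER,
    tol: float = GRAD_TOL,
) -> PenalizedLogisticFit:
    """Posterior mode of the (optionally slope-augmented) logistic model.

    ``x`` may be None for the intercept-only model.  Each penalized
    coefficient contributes its own logF(m, m) prior via one pseudo-
    observation of m trials with m/2 successes.  The reported ``objective``
    is the penalized log-likelihood at the mode.
    """
    if m < 0:
        raise ValueError(f"m must be >= 0, got {m}")
    yv = _as_binary(y, "y")
    n, sy = yv.size, float(yv.sum())
    if x is None:
        if m > 0 or (0 < sy < n):
            b0, obj = _fit_counts_intercept(sy, n, m)
            return PenalizedLogisticFit(b0, None, obj, True, 0)
        raise ConvergenceError(
            "maximum-likelihood intercept is infinite for constant y",
            np.array([np.inf if sy == n else -np.inf]),
        )
    xv = _as_binary(x, "x")
    if xv.size != n:
        raise ValueError(f"length mismatch: x has {xv.size}, y has {n}")
    n1 = float(xv.sum())
    n0 = n - n1
    s1 = float(yv[xv == 1].sum())
    s0 = sy - s1
    X = np.array([[1.0, 0.0], [1.0, 1.0], [1.0, 0.0], [0.0, 1.0]])
    trials = np.array([n0, n1, m, m], dtype=float)
    succ = np.array([s0, s1, 0.5 * m, 0.5 * m], dtype=float)
    if m == 0:
        X, trials, succ = X[:2], trials[:2], succ[:2]
    keep = trials > 0
    beta, obj, conv, it = _newton_fit(X[keep], trials[keep], succ[keep],
                                      max_iter=max_iter, tol=tol)
    return PenalizedLogisticFit(float(beta[0]), float(beta[1]), obj, conv, it)


def log_abf(x, y, m: float = 1.0) -> float:
    """Log approximate Bayes factor of the slope model for one SNP pair.

    Returns 0 exactly when the neighbor ``y`` is monomorphic (an ABF of 1,
    so absent or invariant positions are uninformative).  Finite for every
    binary configuration when m > 0, including perfect LD (complete
    separation).
    """
    xv = _as_binary(x, "x")
    yv = _as_binary(y, "y")
    if xv.size != yv.size:
        raise ValueError(f"length mismatch: x has {xv.size}, y has {yv.size}")
    n1 = int(xv.sum())
    s1 = int(yv[xv == 1].sum())
    s0 = int(yv.sum()) - s1
    return _log_abf_counts(s0, xv.size - n1, s1, n1, float(m))


def ld_abf_at_site(
    H,
    site_index: int,
    window: WindowConfig | None = None,
    m: float = 1.0,
) -> LdAbfScore:
    """Windowed LD-ABF score of one test SNP.

    Sums log-ABFs over segregating neighbors within ``window.half_width`` bp
    on either side and divides by the full window width, so the score grows
    with both local polymorphism density and LD strength.
    """
    window = window or WindowConfig()
    if not 0 <= site_index < H.n_sites:
        raise IndexError(f"site_index {site_index} out of range [0, {H.n_sites})")
    x = H.column(site_index)
    neighbors = H.neighbor_indices(site_index, window.half_width)
    total = sum(log_abf(x, H.column(j), m) for j in neighbors)
    n_nb = len(neighbors)
    if window.include_self:
        total += log_abf(x, x, m)
        n_nb += 1
    return LdAbfScore(H.sites[site_index].pos, total / window.width_bp, n_nb)
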