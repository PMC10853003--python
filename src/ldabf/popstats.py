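"""Comparator statistics computed in the same per-site windows as LD-ABF.

Tajima's D contrasts mean pairwise diversity with Watterson's estimator and
shifts positive when intermediate-frequency variants are in excess, the
classic balancing-selection signature.  D_ng sums the squared Pearson
correlation of the test variant with each segregating neighbor, a direct
haplotype-LD analogue of the windowed score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import WindowConfig

__all__ = [
    "TajimaComponents",
    "DngScore",
    "tajima_constants",
    "tajimas_d",
    "tajimas_d_at_site",
    "d_ng",
]


@dataclass(frozen=True)
class TajimaComponents:
    """Normalization constants of the D statistic for n haplotypes."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def tajima_constants(n: int) -> TajimaComponents:
    if n < 4:
        raise ValueError(f"Tajima's D needs >= 4 haplotypes, got {n}")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return TajimaComponents(n, a1, a2, b1, b2, c1, c2, e1, e2)


def mean_pairwise_diversity(counts: Sequence[int], n: int) -> float:
    """Unbiased mean pairwise differences: sum of 2c(n-c)/(n(n-1)) over sites."""
    return float(sum(2.0 * c * (n - c) for c in counts) / (n * (n - 1)))


def tajimas_d(H, site_indices: Sequence[int] | None = None) -> float:
    """Tajima's D over a set of matrix columns (default: all sites).

    Returns NaN when no site segregates in the chosen window — the statistic
    is undefined there, not zero.
    """
    n = H.n_haplotypes
    const = tajima_constants(n)
    idx = range(H.n_sites) if site_indices is None else list(site_indices)
    counts = [H.sites[j].alt_count for j in idx]
    counts = [c for c in counts if 0 < c < n]
    S = len(counts)
    if S == 0:
        return math.nan
    pi = mean_pairwise_diversity(counts, n)
    var = const.e1 * S + const.e2 * S * (S - 1)
    return (pi - S / const.a1) / math.sqrt(var)


def tajimas_d_at_site(H, site_index: int, window: WindowConfig | None = None):
    """Windowed Tajima's D centered on a test SNP.

    Returns ``(value, n_window_sites)`` where the window includes the test
    site itself plus all segregating sites within half the window width.
    """
    window = window or WindowConfig()
    idx = H.neighbor_indices(site_index, window.half_width) + [site_index]
    return tajimas_d(H, idx), len(idx)


@dataclass(frozen=True)
class DngScore:
    pos: int
    value: float
    n_neighbors: int


def _pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    n = x.size
    nx, ny = int(x.sum()), int(y.sum())
    n11 = int(np.sum((x == 1) & (y == 1)))
    den = nx * (n - nx) * ny * (n - ny)
    if den == 0:
        return 0.0
    return (n * n11 - nx * ny) / math.sqrt(den)


def d_ng(
    H,
    site_index: int,
    window: WindowConfig | None = None,
    measure: str = "r2",
) -> DngScore:
    """Neighbor-correlation statistic: sum of the LD of the test SNP with
    each segregating neighbor in the window.

    ``measure`` selects the per-neighbor contribution: squared Pearson
    correlation ``r2`` (default, sign-free and bounded by the neighbor
    count), signed ``r``, or ``abs_r``.  Monomorphic neighbors contribute 0.
    """
    if measure not in ("r2", "r", "abs_r"):
        raise ValueError(f"unknown measure {measure!r}")
    window = window or WindowConfig()
    x = H.column(site_index).astype(np.int64)
    total = 0.0
    neighbors = H.neighbor_indices(site_index, window.half_width)
    for j in neighbors:
        r = _pearson_r(x, H.column(j).astype(np.int64))
        total += r * r if measure == "r2" else (abs(r) if measure == "abs_r" else r)
    return DngScore(H.sites[site_index].pos, total, len(neighbors))
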