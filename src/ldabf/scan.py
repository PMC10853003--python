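"""Genome scans, percentile thresholds, greedy peak calling, and annotation.

A scan produces one row per retained site per statistic (the score table);
peaks are then called greedily, highest score first, with an exclusion
neighborhood around each accepted peak so one extended-LD region cannot
contribute multiple peaks.  Every operation is deterministic and per-site
independent, so a scan may be chunked arbitrarily and concatenated.
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np
import pandas as pd

from .core import WindowConfig, ld_abf_at_site
from .hapio import HaplotypeMatrix, filter_by_maf
from .popstats import d_ng, tajimas_d_at_site

__all__ = [
    "SCAN_STATS",
    "scan_region",
    "percentile_threshold",
    "find_peaks",
    "read_bed_annotation",
    "intersect_intervals",
    "shared_polymorphism_fraction",
]

SCAN_STATS = ("ld_abf", "d_ng", "tajimas_d")

SCORE_COLUMNS = ["chrom", "pos", "stat", "value", "n_neighbors"]


def scan_region(
    H: HaplotypeMatrix,
    stats: Sequence[str] = ("ld_abf",),
    window: WindowConfig | None = None,
    m: float = 1.0,
    min_maf: float = 0.0,
) -> pd.DataFrame:
    """Score every retained site with each requested statistic.

    Returns a tidy table (chrom, pos, stat, value, n_neighbors) sorted by
    position within chromosome.  ``min_maf`` applies the strict MAF filter
    before scanning; windows are evaluated on the filtered matrix.
    """
    unknown = [s for s in stats if s not in SCAN_STATS]
    if unknown:
        raise ValueError(f"unknown statistic(s) {unknown}; choose from {SCAN_STATS}")
    window = window or WindowConfig()
    if min_maf > 0:
        H = filter_by_maf(H, min_maf)
    rows = []
    for j in range(H.n_sites):
        site = H.sites[j]
        for stat in stats:
            if stat == "ld_abf":
                r = ld_abf_at_site(H, j, window, m)
                value, n_nb = r.score, r.n_neighbors
            elif stat == "d_ng":
                r = d_ng(H, j, window)
                value, n_nb = r.value, r.n_neighbors
            else:
                value, n_win = tajimas_d_at_site(H, j, window)
                n_nb = n_win - 1
            rows.append(
                {
                    "chrom": site.chrom,
                    "pos": site.pos,
                    "stat": stat,
                    "value": value,
                    "n_neighbors": n_nb,
                }
            )
    return pd.DataFrame(rows, columns=SCORE_COLUMNS)


def percentile_threshold(scores, q: float = 0.999) -> float:
    """q-quantile of the score values (linear interpolation on sorted values)."""
    values = np.asarray(
        scores["value"] if isinstance(scores, pd.DataFrame) else scores, dtype=float
    )
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise ValueError("cannot take a percentile of an empty score table")
    if not 0 <= q <= 1:
        raise ValueError(f"q must be in [0, 1], got {q}")
    return float(np.quantile(values, q))


def find_peaks(
    scores: pd.DataFrame,
    exclusion_bp: int,
    k: int = 100,
    full_exclusion_each_side: bool = False,
) -> pd.DataFrame:
    """Greedy peak calling with exclusion neighborhoods.

    Repeatedly accept the highest remaining score whose distance to every
    previously accepted peak on the same chromosome exceeds half the
    exclusion width (total excluded width = ``exclusion_bp``; with
    ``full_exclusion_each_side`` the full width is excluded on each side).
    Ties are broken by (chrom, pos) ascending.  Stops at ``k`` peaks or
    exhaustion; output is invariant to input row order.
    """
    if "stat" in scores.columns and scores["stat"].nunique() > 1:
        raise ValueError("find_peaks requires a single statistic per call")
    radius = exclusion_bp if full_exclusion_each_side else exclusion_bp / 2
    df = scores.dropna(subset=["value"]).sort_values(
        ["value", "chrom", "pos"], ascending=[False, True, True], kind="mergesort"
    )
    accepted: dict[str, list[int]] = {}
    out = []
    for row in df.itertuples(index=False):
        taken = accepted.setdefault(row.chrom, [])
        if all(abs(row.pos - p) > radius for p in taken):
            taken.append(row.pos)
            out.append(
                {"chrom": row.chrom, "pos": row.pos, "value": row.value,
                 "rank": len(out) + 1}
            )
            if len(out) == k:
                break
    return pd.DataFrame(out, columns=["chrom", "pos", "value", "rank"])


def read_bed_annotation(path: str | os.PathLike) -> pd.DataFrame:
    """Read a BED file with a name column (BED4: chrom, start, end, name)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(
                    f"{path}: line {lineno}: BED annotation needs 4 columns "
                    f"(chrom, start, end, name), got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer interval bounds"
                ) from exc
            rows.append(
                {"chrom": fields[0], "start": start, "end": end, "name": fields[3]}
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def intersect_intervals(peaks: pd.DataFrame, annot: pd.DataFrame) -> pd.DataFrame:
    """Label each peak with every annotation interval containing it.

    Containment tests the peak's 0-based coordinate (pos - 1) against
    half-open [start, end).  Peaks inside no interval are labeled
    ``intergenic``.  Returns one row per (peak, label).
    """
    out = []
    for row in peaks.itertuples(index=False):
        hits = annot[
            (annot["chrom"] == row.chrom)
            & (annot["start"] <= row.pos - 1)
            & (row.pos - 1 < annot["end"])
        ]
        labels = list(hits["name"]) or ["intergenic"]
        for label in labels:
            rec = row._asdict()
            rec["label"] = label
            out.append(rec)
    return pd.DataFrame(out, columns=[*peaks.columns, "label"])


def shared_polymorphism_fraction(
    peak_pos: int,
    sites_primary: Sequence[int],
    sites_replication: Sequence[int],
    window_bp: int = 1000,
) -> float:
    """Fraction of the peak-window polymorphisms replicated in a second call set.

    Among primary-set positions within ``window_bp/2`` of the peak, the
    fraction also present in the replication set; a cross-platform peak
    sanity check (NaN when the window holds no primary site).  Callers
    typically require at least half the sites to replicate.
    """
    half = window_bp / 2
    in_window = [p for p in sites_primary if abs(p - peak_pos) <= half]
    if not in_window:
        return float("nan")
    rep = set(sites_replication)
    return sum(p in rep for p in in_window) / len(in_window)
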