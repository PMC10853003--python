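"""Phased-VCF input, haplotype matrices, and site-level filters.

The whole toolkit operates on a :class:`HaplotypeMatrix`: a binary matrix with
one row per phased haplotype and one column per biallelic, segregating SNP.
Coordinates are 1-based (VCF convention) internally; BED masks are 0-based
half-open (BED convention) and converted at the boundary.
"""

from __future__ import annotations

import os
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SiteRecord",
    "HaplotypeMatrix",
    "RegionMask",
    "read_phased_vcf",
    "filter_by_maf",
    "apply_region_mask",
    "matrix_from_arrays",
    "write_vcf",
    "write_tsv",
]

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class SiteRecord:
    """One biallelic SNP: coordinates, alleles and sample allele counts."""

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    alt_count: int
    n_haplotypes: int

    @property
    def maf(self) -> float:
        """Minor allele frequency, min(p, 1-p) in [0, 0.5]."""
        n = self.n_haplotypes
        return min(self.alt_count, n - self.alt_count) / n


class HaplotypeMatrix:
    """Binary matrix of phased haplotypes (rows) by segregating sites (columns).

    ``alleles[i, j]`` is 1 when haplotype ``i`` carries the alternate allele of
    site ``j``, coded as read from the VCF (no minor-allele recoding).
    Positions are strictly increasing within each chromosome.
    """

    def __init__(
        self,
        sites: Sequence[SiteRecord],
        alleles: np.ndarray,
        sample_ids: Sequence[str],
    ):
        alleles = np.asarray(alleles, dtype=np.uint8)
        if alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D matrix")
        if alleles.shape[1] != len(sites):
            raise ValueError(
                f"{alleles.shape[1]} allele columns but {len(sites)} site records"
            )
        if alleles.shape[0] != len(sample_ids):
            raise ValueError("one sample_id per haplotype row required")
        if not np.isin(alleles, (0, 1)).all():
            raise ValueError("alleles must be binary")
        self.sites = list(sites)
        self.alleles = alleles
        self.sample_ids = list(sample_ids)
        self._validate()

    def _validate(self) -> None:
        n = self.n_haplotypes
        prev: tuple[str, int] | None = None
        seen_chroms: set[str] = set()
        for j, s in enumerate(self.sites):
            if s.n_haplotypes != n:
                raise ValueError(f"site {s.chrom}:{s.pos} has wrong haplotype count")
            col = int(self.alleles[:, j].sum())
            if col != s.alt_count:
                raise ValueError(
                    f"site {s.chrom}:{s.pos}: stored alt_count {s.alt_count} "
                    f"!= column sum {col}"
                )
            if prev is not None and s.chrom == prev[0] and s.pos <= prev[1]:
                raise ValueError(
                    f"positions not strictly increasing at {s.chrom}:{s.pos}"
                )
            if prev is not None and s.chrom != prev[0]:
                if s.chrom in seen_chroms:
                    raise ValueError(f"chromosome {s.chrom} blocks are not contiguous")
                seen_chroms.add(prev[0])
            prev = (s.chrom, s.pos)

    # -- basic accessors ---------------------------------------------------

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.sites], dtype=np.int64)

    @property
    def chroms(self) -> list[str]:
        return [s.chrom for s in self.sites]

    def column(self, j: int) -> np.ndarray:
        return self.alleles[:, j]

    def take_sites(self, indices: Iterable[int]) -> "HaplotypeMatrix":
        idx = list(indices)
        return HaplotypeMatrix(
            [self.sites[j] for j in idx], self.alleles[:, idx], self.sample_ids
        )

    def neighbor_indices(self, site_index: int, half_width: int) -> list[int]:
        """Column indices within ``half_width`` bp of the test site (excluding it)."""
        site = self.sites[site_index]
        lo, hi = self._chrom_block(site.chrom)
        pos = [self.sites[j].pos for j in range(lo, hi)]
        a = lo + bisect_left(pos, site.pos - half_width)
        b = lo + bisect_right(pos, site.pos + half_width)
        return [j for j in range(a, b) if j != site_index]

    def _chrom_block(self, chrom: str) -> tuple[int, int]:
        chroms = self.chroms
        lo = chroms.index(chrom)
        hi = lo
        while hi < len(chroms) and chroms[hi] == chrom:
            hi += 1
        return lo, hi

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HaplotypeMatrix):
            return NotImplemented
        return (
            self.sites == other.sites
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.alleles, other.alleles)
        )

    def __repr__(self) -> str:
        return (
            f"HaplotypeMatrix({self.n_haplotypes} haplotypes x "
            f"{self.n_sites} sites)"
        )


class RegionMask:
    """Set of genomic intervals in BED convention (0-based, half-open)."""

    def __init__(self, intervals: Iterable[tuple[str, int, int]] = ()):
        self.intervals: list[tuple[str, int, int]] = []
        for chrom, start, end in intervals:
            self.add(chrom, start, end)

    def add(self, chrom: str, start: int, end: int) -> None:
        if end < start:
            raise ValueError(f"interval end < start: {chrom}:{start}-{end}")
        self.intervals.append((str(chrom), int(start), int(end)))

    @classmethod
    def from_bed(cls, path: str | os.PathLike) -> "RegionMask":
        mask = cls()
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(f"{path}: malformed BED line {lineno}: {line!r}")
                try:
                    mask.add(fields[0], int(fields[1]), int(fields[2]))
                except ValueError as exc:
                    raise ValueError(
                        f"{path}: malformed BED line {lineno}: {line!r}"
                    ) from exc
        return mask

    def contains(self, chrom: str, pos0: int) -> bool:
        """Membership of a 0-based coordinate (start inclusive, end exclusive)."""
        return any(
            c == chrom and start <= pos0 < end for c, start, end in self.intervals
        )

    def chrom_names(self) -> set[str]:
        return {c for c, _, _ in self.intervals}

    def union(self, other: "RegionMask") -> "RegionMask":
        return RegionMask(self.intervals + other.intervals)


# -- VCF input -------------------------------------------------------------


def read_phased_vcf(
    path: str | os.PathLike,
    region: str | None = None,
    missing_as_ref: bool = True,
) -> HaplotypeMatrix:
    """Read a phased diploid VCF into a haplotype matrix.

    Only biallelic SNPs segregating in the sample are kept; multiallelic
    records, indels and monomorphic-in-sample columns are dropped silently.
    Missing genotypes (``./.``) become ``0|0`` when ``missing_as_ref`` is true,
    otherwise the whole record is dropped.  An unphased genotype (``/``
    separator) on a retained record is a hard error: the statistics need
    haplotype-resolved data.
    """
    from cyvcf2 import VCF

    vcf = VCF(os.fspath(path))
    sample_ids = [f"{s}_{k}" for s in vcf.samples for k in (1, 2)]
    sites: list[SiteRecord] = []
    columns: list[np.ndarray] = []
    it = vcf(region) if region else vcf
    for v in it:
        if len(v.ALT) != 1:
            continue  # multiallelic
        ref, alt = v.REF.upper(), v.ALT[0].upper()
        if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
            continue  # indel / symbolic
        col = np.empty(2 * len(v.genotypes), dtype=np.uint8)
        drop = False
        for i, gt in enumerate(v.genotypes):
            if len(gt) != 3:
                raise ValueError(
                    f"haploid genotype at {v.CHROM}:{v.POS}; only phased diploid "
                    "input is supported"
                )
            a, b, phased = gt[0], gt[1], gt[2]
            if a < 0 or b < 0:
                if missing_as_ref:
                    a, b = 0, 0
                else:
                    drop = True
                    break
            elif not phased:
                raise ValueError(
                    f"unphased genotype ('/') at {v.CHROM}:{v.POS} "
                    f"(sample {vcf.samples[i]}); phase the data first"
                )
            col[2 * i] = a
            col[2 * i + 1] = b
        if drop:
            continue
        ac = int(col.sum())
        if ac == 0 or ac == len(col):
            continue  # monomorphic in sample
        sites.append(
            SiteRecord(v.CHROM, v.POS, ref, alt, ac, len(col))
        )
        columns.append(col)
    if not sites:
        raise ValueError(
            f"{path}: no biallelic segregating SNPs retained"
            + (f" in region {region}" if region else "")
        )
    alleles = np.stack(columns, axis=1)
    return HaplotypeMatrix(sites, alleles, sample_ids)


def matrix_from_arrays(
    alleles: np.ndarray,
    positions: Sequence[int],
    chrom: str = "1",
    ref: str = "A",
    alt: str = "T",
    sample_prefix: str = "hap",
) -> HaplotypeMatrix:
    """Build a matrix directly from a binary array and 1-based positions."""
    alleles = np.asarray(alleles, dtype=np.uint8)
    order = np.argsort(positions, kind="stable")
    alleles = alleles[:, order]
    positions = [int(positions[i]) for i in order]
    n = alleles.shape[0]
    sites = [
        SiteRecord(chrom, p, ref, alt, int(alleles[:, j].sum()), n)
        for j, p in enumerate(positions)
    ]
    ids = [f"{sample_prefix}{i // 2}_{i % 2 + 1}" for i in range(n)]
    return HaplotypeMatrix(sites, alleles, ids)


# -- site-level filters ----------------------------------------------------


def filter_by_maf(H: HaplotypeMatrix, min_maf: float) -> HaplotypeMatrix:
    """Retain sites with minor allele frequency strictly above ``min_maf``."""
    if not 0 <= min_maf < 0.5:
        raise ValueError(f"min_maf must be in [0, 0.5), got {min_maf}")
    keep = [j for j, s in enumerate(H.sites) if s.maf > min_maf]
    return H.take_sites(keep)


def _strip_chr(name: str) -> str:
    return name[3:] if name.lower().startswith("chr") else name


def apply_region_mask(
    H: HaplotypeMatrix,
    mask: RegionMask,
    normalize_chroms: bool = False,
) -> HaplotypeMatrix:
    """Drop sites whose 0-based coordinate falls inside any mask interval.

    With ``normalize_chroms`` the leading ``chr`` prefix is ignored when
    matching chromosome names; otherwise a ``chr6`` vs ``6`` dialect mismatch
    between the VCF and the BED raises.
    """
    mask_chroms = mask.chrom_names()
    mat_chroms = set(H.chroms)
    if mask_chroms and mat_chroms:
        if normalize_chroms:
            norm_ivals = [(_strip_chr(c), s, e) for c, s, e in mask.intervals]
            mask = RegionMask(norm_ivals)
            key = _strip_chr
        else:
            if not (mask_chroms & mat_chroms) and (
                {_strip_chr(c) for c in mask_chroms}
                & {_strip_chr(c) for c in mat_chroms}
            ):
                raise ValueError(
                    "chromosome naming mismatch between matrix and mask "
                    f"({sorted(mat_chroms)} vs {sorted(mask_chroms)}); "
                    "pass normalize_chroms=True to reconcile"
                )
            key = str
    else:
        key = str
    keep = [
        j for j, s in enumerate(H.sites) if not mask.contains(key(s.chrom), s.pos - 1)
    ]
    return H.take_sites(keep)


# -- output ----------------------------------------------------------------


def write_vcf(H: HaplotypeMatrix, path: str | os.PathLike) -> None:
    """Serialize the matrix as a phased diploid VCF 4.2 file."""
    if H.n_haplotypes % 2 != 0:
        raise ValueError("odd haplotype count cannot be written as diploid VCF")
    samples = []
    for i in range(0, H.n_haplotypes, 2):
        sid = H.sample_ids[i]
        samples.append(sid[:-2] if sid.endswith("_1") else f"s{i // 2}")
    contigs: dict[str, int] = {}
    for s in H.sites:
        contigs[s.chrom] = max(contigs.get(s.chrom, 0), s.pos)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=ldabf\n")
        for chrom, length in contigs.items():
            fh.write(f"##contig=<ID={chrom},length={length + 1000}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for j, s in enumerate(H.sites):
            col = H.alleles[:, j]
            gts = "\t".join(
                f"{col[2 * i]}|{col[2 * i + 1]}" for i in range(len(samples))
            )
            fh.write(
                f"{s.chrom}\t{s.pos}\t.\t{s.ref_allele}\t{s.alt_allele}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_tsv(H: HaplotypeMatrix, path: str | os.PathLike) -> None:
    """Write the retained site table (no genotypes) as TSV."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\talt_count\tn_haplotypes\tmaf\n")
        for s in H.sites:
            fh.write(
                f"{s.chrom}\t{s.pos}\t{s.ref_allele}\t{s.alt_allele}"
                f"\t{s.alt_count}\t{s.n_haplotypes}\t{s.maf:.6g}\n"
            )
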