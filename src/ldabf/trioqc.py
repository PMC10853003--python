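"""Family-based variant QC filters applied before scanning.

Paralogous or collapsed-repeat sequence tends to produce variants that look
heterozygous in essentially every family, transmit to homozygous offspring at
non-Mendelian rates, or have flipped reference/alternate coding.  These
filters flag such variants from trio/duo genotype tables; each is a pure
set-valued function, so the union of flags is independent of the order in
which filters run.

Genotypes are coded 0 = hom-ref, 1 = het, 2 = hom-alt; missing genotypes are
NaN and make a family incomplete (excluded from that filter's denominator).
"""

from __future__ import annotations

import math
import os
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import binomtest

__all__ = [
    "read_pedigree",
    "family_genotypes_from_vcf",
    "het_family_filter",
    "transmission_binomial_filter",
    "mendel_error_filter",
    "allele_flip_filter",
    "run_all_filters",
]

COLUMNS = ["variant_id", "family_id", "family_type", "proband", "mother", "father"]


def _check(T: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COLUMNS if c not in T.columns]
    if missing:
        raise ValueError(f"family genotype table lacks columns {missing}")
    bad = ~T["family_type"].isin(["trio", "duo"])
    if bad.any():
        raise ValueError(f"unknown family_type values: {set(T.loc[bad, 'family_type'])}")
    return T


def read_pedigree(path: str | os.PathLike) -> pd.DataFrame:
    """Read a PED-like TSV (family_id, individual_id, father_id, mother_id).

    '0' or '.' denote a missing parent; a row with exactly one genotyped
    parent is a duo, with both a trio.
    """
    ped = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        usecols=[0, 1, 2, 3],
        names=["family_id", "individual_id", "father_id", "mother_id"],
        dtype=str,
    )
    for col in ("father_id", "mother_id"):
        ped[col] = ped[col].replace({"0": pd.NA, ".": pd.NA})
    return ped


def family_genotypes_from_vcf(
    vcf_path: str | os.PathLike, pedigree: pd.DataFrame
) -> pd.DataFrame:
    """Build the per-variant family genotype table from a VCF and pedigree.

    Probands are the pedigree rows naming at least one parent present in the
    VCF.  Genotype codes count alternate alleles; phase is irrelevant here
    (these filters run before phasing).
    """
    from cyvcf2 import VCF

    vcf = VCF(os.fspath(vcf_path))
    sample_idx = {s: i for i, s in enumerate(vcf.samples)}
    units = []  # (family_id, proband_idx, mother_idx|None, father_idx|None, type)
    for row in pedigree.itertuples(index=False):
        if row.individual_id not in sample_idx:
            continue
        m = sample_idx.get(row.mother_id) if pd.notna(row.mother_id) else None
        f = sample_idx.get(row.father_id) if pd.notna(row.father_id) else None
        if m is None and f is None:
            continue
        ftype = "trio" if (m is not None and f is not None) else "duo"
        units.append((row.family_id, sample_idx[row.individual_id], m, f, ftype))
    if not units:
        raise ValueError("pedigree names no proband with a genotyped parent")

    rows = []
    for v in vcf:
        if len(v.ALT) != 1:
            continue
        vid = f"{v.CHROM}:{v.POS}:{v.REF}:{v.ALT[0]}"
        codes = []
        for gt in v.genotypes:
            alleles = gt[:-1]
            codes.append(math.nan if any(a < 0 for a in alleles) else float(sum(alleles)))
        for fam, p, m, f, ftype in units:
            rows.append(
                {
                    "variant_id": vid,
                    "family_id": fam,
                    "family_type": ftype,
                    "proband": codes[p],
                    "mother": codes[m] if m is not None else math.nan,
                    "father": codes[f] if f is not None else math.nan,
                }
            )
    return pd.DataFrame(rows, columns=COLUMNS)


def _genotyped_members(row) -> list[float]:
    roles = (
        ["proband", "mother", "father"]
        if row.family_type == "trio"
        else ["proband", "mother" if not math.isnan(row.mother) else "father"]
    )
    return [getattr(row, r) for r in roles]


def het_family_filter(T: pd.DataFrame, threshold: float = 0.95) -> set[str]:
    """Flag variants where more than ``threshold`` of complete families are
    entirely heterozygous (every genotyped member het) — the signature of a
    collapsed paralog.  Variants with no complete family are skipped."""
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    _check(T)
    flagged = set()
    for vid, grp in T.groupby("variant_id", sort=False):
        complete = all_het = 0
        for row in grp.itertuples(index=False):
            members = _genotyped_members(row)
            if any(math.isnan(g) for g in members):
                continue
            complete += 1
            if all(g == 1 for g in members):
                all_het += 1
        if complete and all_het / complete > threshold:
            flagged.add(vid)
    return flagged


def transmission_binomial_filter(
    T: pd.DataFrame,
    p_threshold: float = 0.005,
    success: str = "hom_alt",
    alternative: str = "two-sided",
) -> set[str]:
    """Exact binomial test of homozygous transmission in het x het trios.

    With both parents heterozygous, a homozygous proband of either kind is
    expected 25% of the time.  Per variant, k successes among the n
    informative trios are tested against p = 0.25 (p = 0.5 for
    ``success='either'``); variants with p-value below ``p_threshold`` are
    flagged.  Variants with no informative trio are skipped.
    """
    if success not in ("hom_alt", "hom_ref", "either"):
        raise ValueError(f"unknown success class {success!r}")
    _check(T)
    p0 = 0.5 if success == "either" else 0.25
    flagged = set()
    trios = T[T["family_type"] == "trio"]
    for vid, grp in trios.groupby("variant_id", sort=False):
        inf = grp[(grp["mother"] == 1) & (grp["father"] == 1) & grp["proband"].notna()]
        n = len(inf)
        if n == 0:
            continue
        if success == "hom_alt":
            k = int((inf["proband"] == 2).sum())
        elif success == "hom_ref":
            k = int((inf["proband"] == 0).sum())
        else:
            k = int(inf["proband"].isin([0, 2]).sum())
        if binomtest(k, n, p0, alternative=alternative).pvalue < p_threshold:
            flagged.add(vid)
    return flagged


_MENDEL_POSSIBLE = {
    # (mother, father) -> possible proband genotypes
    (0, 0): {0},
    (0, 1): {0, 1},
    (1, 0): {0, 1},
    (0, 2): {1},
    (2, 0): {1},
    (1, 1): {0, 1, 2},
    (1, 2): {1, 2},
    (2, 1): {1, 2},
    (2, 2): {2},
}


def mendel_error_filter(T: pd.DataFrame, max_rate: float = 0.01) -> set[str]:
    """Flag variants whose Mendelian-inconsistency rate across complete trios
    exceeds ``max_rate``."""
    _check(T)
    flagged = set()
    trios = T[T["family_type"] == "trio"]
    for vid, grp in trios.groupby("variant_id", sort=False):
        complete = errors = 0
        for row in grp.itertuples(index=False):
            if any(math.isnan(g) for g in (row.proband, row.mother, row.father)):
                continue
            complete += 1
            if row.proband not in _MENDEL_POSSIBLE[(int(row.mother), int(row.father))]:
                errors += 1
        if complete and errors / complete > max_rate:
            flagged.add(vid)
    return flagged


def allele_flip_filter(T, max_freq: float = 0.95) -> set[str]:
    """Flag variants whose alternate-allele frequency exceeds ``max_freq``
    (reference/alternate coding flipped; equivalent to a MAF floor).

    Accepts either a family genotype table (frequency over all genotyped
    alleles) or a :class:`~ldabf.hapio.HaplotypeMatrix`.
    """
    if hasattr(T, "sites"):  # HaplotypeMatrix
        return {
            f"{s.chrom}:{s.pos}:{s.ref_allele}:{s.alt_allele}"
            for s in T.sites
            if s.alt_count / s.n_haplotypes > max_freq
        }
    _check(T)
    flagged = set()
    for vid, grp in T.groupby("variant_id", sort=False):
        alt = alleles = 0
        for row in grp.itertuples(index=False):
            for g in (row.proband, row.mother, row.father):
                if not math.isnan(g):
                    alt += g
                    alleles += 2
        if alleles and alt / alleles > max_freq:
            flagged.add(vid)
    return flagged


def run_all_filters(
    T: pd.DataFrame,
    het_threshold: float = 0.95,
    p_threshold: float = 0.005,
    max_mendel_rate: float = 0.01,
    max_alt_freq: float = 0.95,
) -> pd.DataFrame:
    """Apply every filter and return a tidy table of (variant_id, filter)."""
    results: Mapping[str, Iterable[str]] = {
        "het_family": het_family_filter(T, het_threshold),
        "transmission_binomial": transmission_binomial_filter(T, p_threshold),
        "mendel_error": mendel_error_filter(T, max_mendel_rate),
        "allele_flip": allele_flip_filter(T, max_alt_freq),
    }
    rows = [
        {"variant_id": vid, "filter": name}
        for name, vids in results.items()
        for vid in sorted(vids)
    ]
    return pd.DataFrame(rows, columns=["variant_id", "filter"])
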