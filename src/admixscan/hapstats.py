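"""Haplotype-based selection statistics: EHH, iHH, iHS, XP-EHH, H12/G12.

EHH at genetic distance x from a core site is the probability that two
randomly drawn carrier haplotypes are identical over the whole stretch
from the core to x. Its integral over genetic distance (iHH), compared
between ancestral and derived alleles (iHS) or between populations
(XP-EHH), measures the haplotype-length footprint of recent positive
selection. H12/G12 are expected-homozygosity statistics pooling the two
most frequent haplotype (multilocus genotype) classes, sensitive to soft
sweeps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import HaplotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "EhhCurve",
    "ehh",
    "ihh",
    "ihs",
    "xpehh",
    "haplotype_homozygosity",
    "h12_scan",
]

TRUNCATION_DEFAULT = 0.05


@dataclass
class EhhCurve:
    """EHH decay curve from one core site.

    ``left``/``right`` are (distance_cM, ehh) arrays per direction,
    starting at (0, 1) on the core itself; distances grow outward.
    ``left_at_edge``/``right_at_edge`` flag sides that ran into the end of
    the data before decaying below ``stop_at``.
    """

    core_idx: int
    core_allele: int | None
    n_carriers: int
    left: tuple[np.ndarray, np.ndarray]
    right: tuple[np.ndarray, np.ndarray]
    left_at_edge: bool
    right_at_edge: bool


def _walk(alleles: np.ndarray, cm: np.ndarray, carriers: np.ndarray, core_idx: int,
          step: int, stop_at: float) -> tuple[np.ndarray, np.ndarray, bool]:
    """EHH values outward from the core in one direction.

    Haplotype groups are refined site by site; EHH = sum_h C(n_h,2) /
    C(n_c,2) over groups of identical extended haplotypes. The walk stops
    once EHH falls below ``stop_at`` or every group is a singleton.
    """
    n = carriers.size
    denom = n * (n - 1) / 2.0
    ids = np.zeros(n, dtype=np.int64)
    dists = [0.0]
    vals = [1.0]
    j = core_idx + step
    at_edge = True
    m = alleles.shape[0]
    while 0 <= j < m:
        ids = ids * 2 + alleles[j, carriers]
        _, ids, counts = np.unique(ids, return_inverse=True, return_counts=True)
        hom = float(np.sum(counts * (counts - 1)) / 2.0 / denom)
        dists.append(abs(cm[j] - cm[core_idx]))
        vals.append(hom)
        if hom < stop_at or counts.max() == 1:
            at_edge = False
            break
        j += step
    return np.asarray(dists), np.asarray(vals), at_edge


def ehh(matrix: HaplotypeMatrix, cm: np.ndarray, core_idx: int,
        core_allele: int | None, stop_at: float = 0.0) -> EhhCurve:
    """EHH decay around ``core_idx`` among carriers of ``core_allele``.

    ``core_allele`` None means no allele conditioning (all haplotypes; the
    XP-EHH convention). ``stop_at`` > 0 truncates the walk early once EHH
    falls below it (use the iHH truncation value for scans). EHH is
    non-increasing outward by construction.
    """
    alleles = matrix.alleles
    if core_allele is None:
        carriers = np.arange(matrix.n_hap)
    else:
        carriers = np.flatnonzero(alleles[core_idx] == core_allele)
    if carriers.size < 2:
        raise ValueError("fewer than 2 carrier haplotypes at the core")
    ld, lv, le = _walk(alleles, cm, carriers, core_idx, -1, stop_at)
    rd, rv, re_ = _walk(alleles, cm, carriers, core_idx, +1, stop_at)
    return EhhCurve(core_idx, core_allele, carriers.size, (ld, lv), (rd, rv), le, re_)


def _side_integral(dist: np.ndarray, vals: np.ndarray, truncation: float) -> float:
    """Trapezoidal integral of one EHH side over cM, truncated below ``truncation``.

    Trapezoids are accumulated while the left point is at or above the
    truncation level; the trapezoid crossing the level is included, then
    integration stops.
    """
    total = 0.0
    for i in range(1, dist.size):
        if vals[i - 1] < truncation:
            break
        total += 0.5 * (vals[i - 1] + vals[i]) * (dist[i] - dist[i - 1])
    return total


def ihh(curve: EhhCurve, truncation: float = TRUNCATION_DEFAULT) -> tuple[float, bool]:
    """Integrated EHH (cM), both directions summed.

    Returns (iHH, edge_truncated); the flag marks cores whose curve hit
    the end of the contig before decaying below the truncation level.
    """
    if curve.left[0].size < 2 and curve.right[0].size < 2:
        raise ValueError("degenerate EHH curve (no flanking points)")
    total = _side_integral(*curve.left, truncation) + _side_integral(*curve.right, truncation)
    edge = (curve.left_at_edge and (curve.left[1][-1] >= truncation)) or \
           (curve.right_at_edge and (curve.right[1][-1] >= truncation))
    return float(total), bool(edge)


def ihs(matrix: HaplotypeMatrix, cm: np.ndarray, derived_is_alt: np.ndarray,
        maf_min: float = 0.05, bin_width: float = 0.02,
        min_bin_count: int = 20,
        truncation: float = TRUNCATION_DEFAULT) -> pd.DataFrame:
    """Standardized iHS per site.

    u = ln(iHH_ancestral / iHH_derived), standardized to mean 0, sd 1
    within derived-allele-frequency bins of width ``bin_width``; adjacent
    bins holding fewer than ``min_bin_count`` sites are merged so the
    bin moments are not dominated by noise. Sites with unknown ancestral
    allele, minor-allele frequency below ``maf_min``, fewer than two
    carriers of either allele, or a zero iHH are skipped (logged).
    """
    p_alt = matrix.alt_freq()
    derived_is_alt = np.asarray(derived_is_alt)
    rows = []
    n_skipped = 0
    for s in range(matrix.n_sites):
        if derived_is_alt[s] < 0:
            continue
        daf = p_alt[s] if derived_is_alt[s] == 1 else 1.0 - p_alt[s]
        if min(p_alt[s], 1 - p_alt[s]) < maf_min:
            continue
        der_allele = 1 if derived_is_alt[s] == 1 else 0
        try:
            c_der = ehh(matrix, cm, s, der_allele, stop_at=truncation)
            c_anc = ehh(matrix, cm, s, 1 - der_allele, stop_at=truncation)
            ihh_der, edge_d = ihh(c_der, truncation)
            ihh_anc, edge_a = ihh(c_anc, truncation)
        except ValueError:
            n_skipped += 1
            continue
        if ihh_der <= 0 or ihh_anc <= 0:
            n_skipped += 1
            continue
        rows.append({"site": s, "daf": daf, "u": np.log(ihh_anc / ihh_der),
                     "edge": edge_d or edge_a})
    if n_skipped:
        logger.info("ihs: skipped %d sites (too few carriers or zero iHH)", n_skipped)
    out = pd.DataFrame(rows)
    if len(out) == 0:
        return out
    bins = np.floor(out["daf"].to_numpy() / bin_width).astype(int)
    # merge sparse adjacent frequency bins (left to right) so each group
    # standardizing u holds at least min_bin_count sites
    group = np.zeros_like(bins)
    gid = 0
    count = 0
    for b in sorted(set(bins)):
        sel = bins == b
        group[sel] = gid
        count += int(sel.sum())
        if count >= min_bin_count:
            gid += 1
            count = 0
    if count and gid > 0:   # fold a trailing undersized group into its neighbour
        group[group == gid] = gid - 1
    out["ihs"] = np.nan
    for g in np.unique(group):
        idx = out.index[group == g]
        u = out.loc[idx, "u"]
        sd = u.std(ddof=0)
        out.loc[idx, "ihs"] = (u - u.mean()) / sd if sd > 0 else 0.0
    return out


def xpehh(matrix1: HaplotypeMatrix, matrix2: HaplotypeMatrix, cm: np.ndarray,
          cores: np.ndarray | None = None,
          truncation: float = TRUNCATION_DEFAULT,
          standardize: bool = True) -> pd.DataFrame:
    """Cross-population EHH score per core site.

    Both populations' EHH is computed over all haplotypes from a shared
    core (no allele conditioning); u = ln(iHH_pop1 / iHH_pop2) is
    standardized genome-wide. Swapping populations negates u; identical
    inputs give u = 0 everywhere.
    """
    if matrix1.n_sites != matrix2.n_sites:
        raise ValueError("populations must share the site table")
    if cores is None:
        cores = np.arange(matrix1.n_sites)
    rows = []
    for s in cores:
        try:
            i1, e1 = ihh(ehh(matrix1, cm, int(s), None, stop_at=truncation), truncation)
            i2, e2 = ihh(ehh(matrix2, cm, int(s), None, stop_at=truncation), truncation)
        except ValueError:
            continue
        if i1 <= 0 or i2 <= 0:
            continue
        rows.append({"site": int(s), "u": np.log(i1 / i2), "edge": e1 or e2})
    out = pd.DataFrame(rows)
    if len(out) and standardize:
        sd = out["u"].std(ddof=0)
        out["xpehh"] = (out["u"] - out["u"].mean()) / sd if sd > 0 else 0.0
    return out


def haplotype_homozygosity(columns: np.ndarray) -> dict[str, float]:
    """H1, H12 and H2/H1 from class frequencies of identical columns.

    With class frequencies p1 >= p2 >= ...: H1 = sum p_i^2; H12 =
    (p1+p2)^2 + sum_{i>=3} p_i^2; H2/H1 = (H1 - p1^2)/H1. Applied to
    haplotype columns this is H12, to diploid multilocus genotype columns
    it is the G12 analogue.
    """
    n = columns.shape[1]
    if n < 2:
        raise ValueError("need at least two columns")
    if columns.shape[0] == 0:
        raise ValueError("empty window")
    _, counts = np.unique(columns, axis=1, return_counts=True)
    p = np.sort(counts / n)[::-1]
    h1 = float(np.sum(p * p))
    if p.size >= 2:
        h12 = float((p[0] + p[1]) ** 2 + np.sum(p[2:] ** 2))
    else:
        h12 = h1
    h2_h1 = float((h1 - p[0] ** 2) / h1)
    return {"H1": h1, "H12": h12, "H2_H1": h2_h1, "n_classes": float(p.size)}


def h12_scan(matrix: HaplotypeMatrix, window_snps: int = 200,
             step_snps: int = 25) -> pd.DataFrame:
    """Sliding n-SNP windows of H1/H12/H2-H1 plus the diploid G12 analogue."""
    dosage = matrix.dosage()
    rows = []
    for start in range(0, matrix.n_sites - window_snps + 1, step_snps):
        sl = slice(start, start + window_snps)
        st = haplotype_homozygosity(matrix.alleles[sl])
        g = haplotype_homozygosity(dosage[sl])
        rows.append({"start_snp": start, "end_snp": start + window_snps,
                     "H1": st["H1"], "H12": st["H12"], "H2_H1": st["H2_H1"],
                     "G12": g["H12"]})
    return pd.DataFrame(rows)
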