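"""Reconstruction of ancestral populations from admixed haplotype segments.

Allele frequencies of an ancestral source (e.g. aEAS) are recomputed over
only the admixed haplotypes whose local ancestry at each site is that
source, then compared against a contemporary reference population; window
regions where the reconstructed and contemporary frequencies have diverged
point to post-admixture change on one side, such as the relaxation of a
selective pressure in the admixed population.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import HaplotypeMatrix, LocalAncestryTrack, SiteTable
from .freq import fst_site_hudson
from .windows import window_site_indices

__all__ = ["reconstructed_af", "differentiation_scan"]

MIN_CARRIERS_DEFAULT = 10


def reconstructed_af(matrix: HaplotypeMatrix, track: LocalAncestryTrack,
                     ancestry: str | int, min_carriers: int = MIN_CARRIERS_DEFAULT) -> pd.DataFrame:
    """Per-site allele frequency over haplotypes assigned one ancestry.

    Returns columns ``carriers`` (haplotypes whose local ancestry at the
    site is ``ancestry``), ``alt_count``, ``af`` (NaN when no carriers) and
    ``masked`` (carriers < min_carriers). Lowering ``min_carriers`` can
    only unmask additional sites, never mask previously unmasked ones.
    """
    if matrix.alleles.shape != track.codes.shape:
        raise ValueError("matrix and track are not aligned")
    if isinstance(ancestry, str):
        if ancestry not in track.labels:
            raise ValueError(f"ancestry label {ancestry!r} absent from track")
        ancestry = track.labels.index(ancestry)
    mask = track.codes == ancestry
    carriers = mask.sum(axis=1)
    alt = np.where(mask, matrix.alleles, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(carriers > 0, alt / np.maximum(carriers, 1), np.nan)
    return pd.DataFrame({
        "carriers": carriers,
        "alt_count": alt,
        "af": af,
        "masked": carriers < min_carriers,
    })


def differentiation_scan(recon: pd.DataFrame, reference_af: np.ndarray,
                         reference_n_hap: int, sites: SiteTable,
                         windows: pd.DataFrame, min_sites: int = 10,
                         top_quantile: float = 0.01,
                         outlier_stat: str = "fst") -> pd.DataFrame:
    """Windowed differentiation between a reconstructed and a reference AF.

    Masked sites are excluded; a window needs >= ``min_sites`` unmasked
    sites. Differentiation is reported both as the mean |dAF| and as a
    windowed Hudson F_ST (ratio-of-averages with per-site reconstructed
    sample sizes); outliers are the genome-wide top ``top_quantile`` by
    ``outlier_stat`` ('fst' default, or 'mean_abs_daf'). Whether an
    outlier reflects relaxation in the admixed population or
    reference-side selection is left to interpretation.
    """
    ref_af = np.asarray(reference_af, dtype=float)
    usable = (~recon["masked"].to_numpy()) & ~np.isnan(ref_af) & (recon["carriers"].to_numpy() >= 2)
    if not usable.any():
        raise ValueError("no unmasked sites genome-wide")
    rec_af = recon["af"].to_numpy()
    carriers = recon["carriers"].to_numpy()
    idx_lists = window_site_indices(sites, windows)
    out = windows[["chrom", "start", "end"]].copy()
    mean_abs = np.full(len(windows), np.nan)
    fst = np.full(len(windows), np.nan)
    n_used = np.zeros(len(windows), dtype=int)
    for w, rows in enumerate(idx_lists):
        rows = rows[usable[rows]]
        n_used[w] = rows.size
        if rows.size < min_sites:
            continue
        d = rec_af[rows] - ref_af[rows]
        mean_abs[w] = np.mean(np.abs(d))
        nums = np.empty(rows.size)
        dens = np.empty(rows.size)
        for j, s in enumerate(rows):
            num, den = fst_site_hudson(rec_af[s], int(carriers[s]), ref_af[s], reference_n_hap)
            nums[j], dens[j] = num, den
        tot = dens.sum()
        if tot > 0:
            fst[w] = nums.sum() / tot
    out["n_sites_used"] = n_used
    out["mean_abs_daf"] = mean_abs
    out["fst"] = fst
    stat = fst if outlier_stat == "fst" else mean_abs
    valid = np.flatnonzero(~np.isnan(stat))
    k = int(np.ceil(top_quantile * valid.size))
    flag = np.zeros(len(windows), dtype=bool)
    if k > 0 and valid.size:
        top = valid[np.argsort(-stat[valid], kind="stable")[:k]]
        flag[top] = True
    out["outlier"] = flag
    return out
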