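"""'Rules of admixture' frequency machinery.

Under neutral admixture the allele frequency of an admixed population is
the average of the source-population frequencies weighted by the global
admixture proportions, AF_exp = sum_k alpha_k AF_k. This module computes
that expectation, the per-site deviation AFd_e = |AF_obs - AF_exp|, site
frequency spectra, Hudson (and Weir-Cockerham) F_ST, and the selection of
ancestry-divergent sites.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import AdmixtureModel

__all__ = [
    "expected_af",
    "afde",
    "sfs",
    "fst_site_hudson",
    "fst_site_weir_cockerham",
    "fst_global",
    "select_divergent_sites",
]


def expected_af(af_by_ancestry: np.ndarray, model: AdmixtureModel) -> np.ndarray:
    """AF expected under the admixture model: sum_k alpha_k AF_k per site.

    ``af_by_ancestry`` is (K, m) with rows ordered like ``model.labels``.
    """
    af = np.asarray(af_by_ancestry, dtype=float)
    if af.ndim != 2 or af.shape[0] != model.k:
        raise ValueError("af_by_ancestry must be (K ancestries, m sites)")
    return model.alpha @ af


def afde(af_obs: np.ndarray, af_exp: np.ndarray, threshold: float = 0.1) -> pd.DataFrame:
    """Per-site deviation from the admixture expectation.

    Returns columns ``af_obs, af_exp, signed, afde, exceeds``; the frame's
    ``attrs['exceed_fraction']`` holds the fraction of sites with
    AFd_e > threshold (the headline genome-wide summary).
    """
    af_obs = np.asarray(af_obs, dtype=float)
    af_exp = np.asarray(af_exp, dtype=float)
    if af_obs.shape != af_exp.shape:
        raise ValueError("misaligned AF vectors")
    signed = af_obs - af_exp
    out = pd.DataFrame({
        "af_obs": af_obs,
        "af_exp": af_exp,
        "signed": signed,
        "afde": np.abs(signed),
        "exceeds": np.abs(signed) > threshold,
    })
    out.attrs["threshold"] = threshold
    out.attrs["exceed_fraction"] = float(out["exceeds"].mean())
    return out


def sfs(afs: np.ndarray, n_bins: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Binned site-frequency spectrum over (0, 1), monomorphic sites excluded.

    Returns (bin_edges, counts); total mass equals the number of
    polymorphic sites. Observed and expected spectra computed with the
    same ``n_bins`` share their binning.
    """
    afs = np.asarray(afs, dtype=float)
    poly = afs[(afs > 0) & (afs < 1)]
    if poly.size == 0:
        raise ValueError("all sites monomorphic")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(poly, bins=edges)
    return edges, counts


def fst_site_hudson(p1, n1: int, p2, n2: int) -> tuple[np.ndarray, np.ndarray]:
    """Hudson per-site F_ST components (numerator, denominator).

    num = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1);
    den = p1(1-p2) + p2(1-p1). Sample sizes are in haplotypes. Negative
    per-site estimates are possible and retained.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 haplotypes per population")
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def fst_site_weir_cockerham(p1, n1: int, p2, n2: int) -> tuple[np.ndarray, np.ndarray]:
    """Weir-Cockerham (1984) two-population components from haplotype counts.

    Haploid-sample form (each haplotype an allele draw): returns (a, a+b)
    where a is the among-population variance component.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 haplotypes per population")
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n = n1 + n2
    nbar = n / 2.0
    nc = (n - (n1 * n1 + n2 * n2) / n)  # r-1 = 1 divisor folded in
    pbar = (n1 * p1 + n2 * p2) / n
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
    a = nbar / nc * (s2 - 1.0 / (2 * nbar - 1) * (pbar * (1 - pbar) - s2 / 2.0))
    b = nbar / (2 * nbar - 1) * (pbar * (1 - pbar) - s2 / 2.0)
    return a, a + b


def fst_global(num: np.ndarray, den: np.ndarray) -> float:
    """Ratio-of-averages global F_ST: sum(num)/sum(den), not mean of ratios."""
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    total = den.sum()
    if total <= 0:
        raise ValueError("denominator sums to zero (no informative sites)")
    return float(num.sum() / total)


def select_divergent_sites(af1, af2, min_diff: float | None = 0.45,
                           top_quantile: float | None = None) -> pd.DataFrame:
    """Sites with extreme frequency difference between two source populations.

    Reports |AF1-AF2| per site with boolean columns for the absolute
    threshold (``selected_min_diff``, default 0.45) and/or for membership
    in the top quantile by |diff| (``selected_top_quantile``, ceil(q*m)
    sites). Either criterion may be disabled by passing None.
    """
    diff = np.abs(np.asarray(af1, dtype=float) - np.asarray(af2, dtype=float))
    out = pd.DataFrame({"abs_diff": diff})
    if min_diff is not None:
        out["selected_min_diff"] = diff > min_diff
    if top_quantile is not None:
        k = int(np.ceil(top_quantile * diff.size))
        sel = np.zeros(diff.size, dtype=bool)
        if k > 0:
            sel[np.argsort(-diff, kind="stable")[:k]] = True
        out["selected_top_quantile"] = sel
    return out
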