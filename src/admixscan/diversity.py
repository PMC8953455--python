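"""Windowed genetic-diversity statistics with subsample balancing.

Per window: nucleotide diversity theta_pi (per Kb), Watterson's theta_K
(per Kb), haplotype diversity H, Tajima's D, segregating sites S and the
rare-SNV fraction; optionally recomputed on repeated random subsamples of
individuals (to balance sample size across populations) with the median
over replicates reported.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import HaplotypeMatrix, SiteTable
from .windows import window_site_indices

__all__ = [
    "theta_pi",
    "theta_watterson",
    "haplotype_diversity",
    "tajimas_d",
    "rare_fraction",
    "window_scan",
    "ne_from_theta",
]


def theta_pi(alleles: np.ndarray, length_bp: float) -> float:
    """Nucleotide diversity per Kb.

    theta_pi = 1000/L * sum_s 2 p_s (1-p_s) n/(n-1), the unbiased per-site
    heterozygosity summed over sites; identical to the mean pairwise
    difference count divided by L.
    """
    n = alleles.shape[1]
    if n < 2:
        raise ValueError("need at least two haplotypes")
    if length_bp <= 0:
        raise ValueError("window length must be positive")
    p = alleles.mean(axis=1)
    return float(1000.0 / length_bp * np.sum(2.0 * p * (1.0 - p)) * n / (n - 1))


def theta_watterson(n_seg: int, n: int, length_bp: float) -> float:
    """Watterson's theta per Kb: S / a_1 scaled to Kb, a_1 = sum_{i<n} 1/i."""
    if n < 2:
        raise ValueError("need at least two haplotypes")
    a1 = np.sum(1.0 / np.arange(1, n))
    return float(1000.0 / length_bp * n_seg / a1)


def haplotype_diversity(alleles: np.ndarray) -> float:
    """H = n/(n-1) (1 - sum_h f_h^2) over distinct window haplotype strings."""
    n = alleles.shape[1]
    if n < 2:
        raise ValueError("need at least two haplotypes")
    if alleles.shape[0] == 0:
        return 0.0
    _, counts = np.unique(alleles.astype(np.int8), axis=1, return_counts=True)
    f = counts / n
    return float(n / (n - 1) * (1.0 - np.sum(f * f)))


def _tajima_constants(n: int) -> tuple[float, float]:
    a1 = np.sum(1.0 / np.arange(1, n))
    a2 = np.sum(1.0 / np.arange(1, n) ** 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return e1, e2


def tajimas_d(alleles: np.ndarray) -> float:
    """Tajima's D of one window; NaN when n < 4 or no segregating sites."""
    n = alleles.shape[1]
    p = alleles.mean(axis=1)
    seg = (p > 0) & (p < 1)
    s = int(seg.sum())
    if n < 4 or s < 1:
        return float("nan")
    a1 = np.sum(1.0 / np.arange(1, n))
    pi = np.sum(2.0 * p[seg] * (1.0 - p[seg])) * n / (n - 1)
    e1, e2 = _tajima_constants(n)
    var = e1 * s + e2 * s * (s - 1)
    return float((pi - s / a1) / np.sqrt(var))


def rare_fraction(afs: np.ndarray, cutoff: float = 0.05, folded: bool = True) -> float:
    """Fraction of segregating sites with (minor-)allele frequency below cutoff.

    Folding (the default) takes min(AF, 1-AF), so an alt frequency of 0.97
    counts as rare; unfolded mode thresholds the alt-allele frequency
    directly. Monomorphic sites are excluded; NaN when nothing segregates.
    """
    afs = np.asarray(afs, dtype=float)
    seg = (afs > 0) & (afs < 1)
    if not seg.any():
        return float("nan")
    f = afs[seg]
    if folded:
        f = np.minimum(f, 1.0 - f)
    return float(np.mean(f < cutoff))


def ne_from_theta(theta_per_site: float, mu: float) -> float:
    """Effective population size N_e = theta / (4 mu) for a per-site theta."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    return theta_per_site / (4.0 * mu)


_STATS = ("theta_pi_kb", "theta_k_kb", "hap_div", "tajima_d", "rare_frac")


def _window_stats(alleles: np.ndarray, length_bp: float, rare_cutoff: float,
                  folded: bool) -> dict[str, float]:
    p = alleles.mean(axis=1)
    seg = (p > 0) & (p < 1)
    s = int(seg.sum())
    n = alleles.shape[1]
    return {
        "S": float(s),
        "theta_pi_kb": theta_pi(alleles, length_bp),
        "theta_k_kb": theta_watterson(s, n, length_bp),
        "hap_div": haplotype_diversity(alleles),
        "tajima_d": tajimas_d(alleles),
        "rare_frac": rare_fraction(p, rare_cutoff, folded),
    }


def window_scan(sites: SiteTable, matrix: HaplotypeMatrix, windows: pd.DataFrame,
                subsample_n: int = 50, replicates: int = 100,
                seed: int | np.random.Generator = 0,
                rare_cutoff: float = 0.05, folded: bool = True) -> pd.DataFrame:
    """Windowed diversity scan with subsample balancing.

    Per replicate, ``subsample_n`` individuals are drawn without
    replacement, site frequencies are recomputed within the subsample and
    all statistics evaluated; the per-window median across replicates is
    reported (columns ``<stat>``) together with the replicate interquartile
    range (``<stat>_iqr``). When ``subsample_n >= N`` the full sample is
    used once. Windows with no analyzed sites get NaN (not zero), except S.
    """
    if subsample_n > matrix.n_ind:
        raise ValueError("subsample_n exceeds the number of individuals")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    full = subsample_n >= matrix.n_ind
    reps = 1 if full else replicates
    idx_lists = window_site_indices(sites, windows)
    n_win = len(windows)
    acc = {s: np.full((reps, n_win), np.nan) for s in _STATS + ("S",)}
    for r in range(reps):
        sub = matrix if full else matrix.take_individuals(
            rng.choice(matrix.n_ind, size=subsample_n, replace=False))
        for w, rows in enumerate(idx_lists):
            if rows.size == 0:
                acc["S"][r, w] = 0.0
                continue
            length = float(windows["end"].iat[w] - windows["start"].iat[w])
            st = _window_stats(sub.alleles[rows], length, rare_cutoff, folded)
            for name in _STATS + ("S",):
                acc[name][r, w] = st[name]
    out = windows[["chrom", "start", "end"]].copy()
    out["n_sites"] = [rows.size for rows in idx_lists]
    out["n_hap"] = 2 * (matrix.n_ind if full else subsample_n)
    import warnings
    for name in _STATS + ("S",):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows
            out[name] = np.nanmedian(acc[name], axis=0)
            if reps > 1:
                q75, q25 = np.nanpercentile(acc[name], [75, 25], axis=0)
                out[name + "_iqr"] = q75 - q25
    return out
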