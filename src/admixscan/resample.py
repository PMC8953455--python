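"""Diversity-vs-ancestry resampling curves.

Within each window, haplotypes of single ancestral origin are pooled by
ancestry; samples of fixed size are then drawn at controlled ancestry
mixtures (target fraction of the first ancestry from 0 to 1 in steps of
0.05 by default) and the diversity statistics of each mixture are
recorded. The median curve across windows shows how nucleotide diversity
and the rare-variant fraction depend on the ancestry composition, and a
low-order polynomial fit locates the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import HaplotypeMatrix, LocalAncestryTrack, SiteTable
from .diversity import rare_fraction, theta_pi
from .windows import window_site_indices

__all__ = ["classify_window_haplotypes", "resample_curve", "fit_curve", "AncestryCurve"]


def classify_window_haplotypes(track: LocalAncestryTrack, window_rows: np.ndarray,
                               purity: float = 1.0) -> dict[str, np.ndarray]:
    """Assign haplotypes to ancestry pools within one window.

    A haplotype joins pool k when at least ``purity`` of its window sites
    carry ancestry k; at purity 1.0 only single-ancestry haplotypes are
    used and mixed ones are excluded.
    """
    if window_rows.size == 0:
        raise ValueError("window has no analyzed sites")
    sub = track.codes[window_rows]
    pools = {}
    for k, lab in enumerate(track.labels):
        frac = (sub == k).mean(axis=0)
        pools[lab] = np.flatnonzero(frac >= purity)
    return pools


@dataclass
class AncestryCurve:
    """Median diversity statistics across windows on an ancestry-fraction grid."""

    grid: np.ndarray
    theta_pi_kb: np.ndarray
    rare_frac: np.ndarray
    n_windows: int
    focal_label: str

    def fit(self, stat: str = "theta_pi_kb", degree: int = 2) -> tuple[np.ndarray, float]:
        y = getattr(self, stat)
        return fit_curve(self.grid, y, degree)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"grid": self.grid, "theta_pi_kb": self.theta_pi_kb,
                             "rare_frac": self.rare_frac})


def resample_curve(matrix: HaplotypeMatrix, track: LocalAncestryTrack,
                   sites: SiteTable, windows: pd.DataFrame,
                   n_hap_sample: int = 40, grid_step: float = 0.05,
                   replicates: int = 20, seed: int | np.random.Generator = 0,
                   purity: float = 1.0, rare_cutoff: float = 0.05,
                   min_windows: int = 5) -> AncestryCurve:
    """Diversity at controlled ancestry mixtures by within-window resampling.

    Per usable window (both pools at least ``n_hap_sample`` deep) and grid
    point f, round(f*n) haplotypes are drawn from the first ancestry's
    pool and the rest from the second, without replacement;
    nucleotide diversity (per Kb) and the folded rare-variant fraction of
    the sample are computed, the median over replicates is taken, then the
    median over windows. f = 0 and f = 1 are the pure second-/first-
    ancestry endpoints.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if len(track.labels) < 2:
        raise ValueError("need two ancestries")
    lab_a, lab_b = track.labels[0], track.labels[1]
    grid = np.round(np.arange(0.0, 1.0 + 1e-9, grid_step), 10)
    idx_lists = window_site_indices(sites, windows)
    per_window_pi = []
    per_window_rare = []
    for w, rows in enumerate(idx_lists):
        if rows.size == 0:
            continue
        pools = classify_window_haplotypes(track, rows, purity)
        pa, pb = pools[lab_a], pools[lab_b]
        if pa.size < n_hap_sample or pb.size < n_hap_sample:
            continue
        length = float(windows["end"].iat[w] - windows["start"].iat[w])
        al = matrix.alleles[rows]
        pi_f = np.empty(grid.size)
        rare_f = np.empty(grid.size)
        for i, f in enumerate(grid):
            n_a = int(round(f * n_hap_sample))
            reps_pi = np.empty(replicates)
            reps_rare = np.empty(replicates)
            for r in range(replicates):
                cols = np.concatenate([
                    rng.choice(pa, size=n_a, replace=False),
                    rng.choice(pb, size=n_hap_sample - n_a, replace=False),
                ])
                sub = al[:, cols]
                reps_pi[r] = theta_pi(sub, length)
                reps_rare[r] = rare_fraction(sub.mean(axis=1), rare_cutoff)
            pi_f[i] = np.median(reps_pi)
            rare_f[i] = np.nanmedian(reps_rare) if not np.all(np.isnan(reps_rare)) else np.nan
        per_window_pi.append(pi_f)
        per_window_rare.append(rare_f)
    if len(per_window_pi) < min_windows:
        raise ValueError(f"only {len(per_window_pi)} usable windows (need {min_windows})")
    return AncestryCurve(
        grid=grid,
        theta_pi_kb=np.median(np.vstack(per_window_pi), axis=0),
        rare_frac=np.nanmedian(np.vstack(per_window_rare), axis=0),
        n_windows=len(per_window_pi),
        focal_label=lab_a,
    )


def fit_curve(grid: np.ndarray, values: np.ndarray, degree: int = 2) -> tuple[np.ndarray, float]:
    """Least-squares polynomial fit and its argmax on [0, 1].

    Returns (coefficients, argmax); coefficients are highest power first
    (numpy.polyfit order). The argmax is taken over the fitted polynomial
    restricted to [0, 1] (stationary points plus the endpoints), so
    monotone data yields a boundary argmax.
    """
    grid = np.asarray(grid, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = ~np.isnan(values)
    if ok.sum() < degree + 1:
        raise ValueError("not enough grid points for the requested degree")
    if np.unique(grid[ok]).size < degree + 1:
        raise ValueError("singular design (duplicate grid points)")
    coeffs = np.polyfit(grid[ok], values[ok], degree)
    crit = [0.0, 1.0]
    roots = np.roots(np.polyder(coeffs))
    for r in roots:
        if abs(r.imag) < 1e-12 and 0.0 <= r.real <= 1.0:
            crit.append(float(r.real))
    vals = np.polyval(coeffs, crit)
    return coeffs, float(crit[int(np.argmax(vals))])
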