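"""Local-ancestry scans: regional ancestry proportions, empirical P values,
the population branch statistic, and the ancestry-biased (AB) /
admixture-representative (AR) taxonomy.

A region is *ancestry-biased* when its local ancestry proportion is an
outlier of the genome-wide window distribution (empirical P in either
tail); it is *admixture-representative* when its local ancestry matches
the global proportions and its focal-population PBS shows no excess
differentiation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import LocalAncestryTrack, SiteTable
from .freq import fst_global, fst_site_hudson
from .windows import window_site_indices

__all__ = [
    "ancestry_proportion",
    "empirical_p",
    "pbs",
    "window_pbs",
    "ancestry_scan",
    "classify_components",
]


def ancestry_proportion(track: LocalAncestryTrack, sites: SiteTable,
                        windows: pd.DataFrame) -> pd.DataFrame:
    """Per-window ancestry proportions alpha_hat_k.

    alpha_hat_k = fraction of (site, haplotype) ancestry calls equal to k
    within the window; NaN for windows without analyzed sites. Columns are
    ``alpha_<label>`` plus ``n_sites``.
    """
    idx_lists = window_site_indices(sites, windows)
    k = len(track.labels)
    out = windows[["chrom", "start", "end"]].copy()
    props = np.full((len(windows), k), np.nan)
    for w, rows in enumerate(idx_lists):
        if rows.size == 0:
            continue
        sub = track.codes[rows]
        counts = np.bincount(sub.ravel(), minlength=k)
        props[w] = counts / sub.size
    for j, lab in enumerate(track.labels):
        out[f"alpha_{lab}"] = props[:, j]
    out["n_sites"] = [r.size for r in idx_lists]
    return out


def empirical_p(value: float, background: np.ndarray, tail: str = "two_sided") -> float:
    """Rank-based empirical P with the add-one convention (never 0).

    upper P = (1 + #{bg >= value}) / (1 + n_bg); lower analogously;
    two-sided = min(1, 2 min(upper, lower)). Requires >= 100 background
    values.
    """
    bg = np.asarray(background, dtype=float)
    bg = bg[~np.isnan(bg)]
    if bg.size < 100:
        raise ValueError("background too small (< 100 values)")
    n = bg.size
    upper = (1 + np.sum(bg >= value)) / (1 + n)
    lower = (1 + np.sum(bg <= value)) / (1 + n)
    if tail == "upper":
        return float(upper)
    if tail == "lower":
        return float(lower)
    if tail == "two_sided":
        return float(min(1.0, 2.0 * min(upper, lower)))
    raise ValueError("tail must be 'upper', 'lower' or 'two_sided'")


def _empirical_p_vec(values: np.ndarray, background: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized upper/lower add-one empirical P of each value vs background."""
    bg = np.sort(background[~np.isnan(background)])
    n = bg.size
    if n < 100:
        raise ValueError("background too small (< 100 values)")
    ge = n - np.searchsorted(bg, values, side="left")   # #{bg >= v}
    le = np.searchsorted(bg, values, side="right")      # #{bg <= v}
    upper = (1 + ge) / (1 + n)
    lower = (1 + le) / (1 + n)
    return upper, lower


def pbs(fst_ab: float, fst_ac: float, fst_bc: float) -> float:
    """Population branch statistic of population A.

    T_xy = -ln(1 - F_xy); PBS_A = (T_AB + T_AC - T_BC)/2. Negative F_ST
    inputs are clamped to 0; an input of 1 (infinite branch) yields NaN.
    """
    f = np.array([fst_ab, fst_ac, fst_bc], dtype=float)
    f = np.maximum(f, 0.0)
    if np.any(f >= 1.0):
        return float("nan")
    t = -np.log(1.0 - f)
    return float((t[0] + t[1] - t[2]) / 2.0)


def window_pbs(p_focal: np.ndarray, n_focal: int, p_b: np.ndarray, n_b: int,
               p_c: np.ndarray, n_c: int, sites: SiteTable,
               windows: pd.DataFrame) -> np.ndarray:
    """Windowed PBS of the focal population against references B and C.

    Per window the three pairwise Hudson F_ST values are formed as
    ratio-of-averages over the window's sites, then combined into PBS.
    """
    comp = {
        "ab": fst_site_hudson(p_focal, n_focal, p_b, n_b),
        "ac": fst_site_hudson(p_focal, n_focal, p_c, n_c),
        "bc": fst_site_hudson(p_b, n_b, p_c, n_c),
    }
    idx_lists = window_site_indices(sites, windows)
    out = np.full(len(windows), np.nan)
    for w, rows in enumerate(idx_lists):
        if rows.size == 0:
            continue
        f = {}
        ok = True
        for key, (num, den) in comp.items():
            d = den[rows].sum()
            if d <= 0:
                ok = False
                break
            f[key] = num[rows].sum() / d
        if ok:
            out[w] = pbs(f["ab"], f["ac"], f["bc"])
    return out


def ancestry_scan(track: LocalAncestryTrack, sites: SiteTable, windows: pd.DataFrame,
                  pbs_values: np.ndarray | None = None,
                  focal_label: str | None = None) -> pd.DataFrame:
    """Assemble per-window scan records: alpha_hat, empirical P, PBS.

    The empirical-P background is the genome-wide distribution of window
    proportions of ``focal_label`` (default: the track's first label).
    """
    focal = focal_label or track.labels[0]
    rec = ancestry_proportion(track, sites, windows)
    vals = rec[f"alpha_{focal}"].to_numpy()
    bg = vals[~np.isnan(vals)]
    upper = np.full(vals.size, np.nan)
    lower = np.full(vals.size, np.nan)
    mask = ~np.isnan(vals)
    upper[mask], lower[mask] = _empirical_p_vec(vals[mask], bg)
    rec["p_upper"] = upper
    rec["p_lower"] = lower
    rec["p_two_sided"] = np.minimum(1.0, 2.0 * np.minimum(upper, lower))
    rec["pbs"] = pbs_values if pbs_values is not None else np.nan
    rec.attrs["focal_label"] = focal
    return rec


def classify_components(records: pd.DataFrame, alpha_global: float,
                        focal_label: str, other_label: str,
                        p_bias: float = 0.05, ar_band: float = 0.05,
                        pbs_quantile: float = 0.5) -> pd.Series:
    """AB/AR taxonomy of scan records.

    ``<focal>-biased`` where the two-sided empirical P is below ``p_bias``
    with the excess in the focal (upper) tail; ``<other>-biased`` for the
    lower tail; ``admixture-representative`` where |alpha_hat -
    alpha_global| <= ar_band AND the window PBS is at or below the
    genome-wide ``pbs_quantile``; otherwise ``unclassified``. Deterministic
    given records and thresholds.
    """
    alpha_hat = records[f"alpha_{focal_label}"].to_numpy()
    upper = records["p_upper"].to_numpy()
    lower = records["p_lower"].to_numpy()
    pbs_vals = records["pbs"].to_numpy(dtype=float)
    out = np.full(len(records), "unclassified", dtype=object)
    two_up = np.minimum(1.0, 2.0 * upper)
    two_lo = np.minimum(1.0, 2.0 * lower)
    out[(two_up < p_bias) & (upper <= lower)] = f"{focal_label}-biased"
    out[(two_lo < p_bias) & (lower < upper)] = f"{other_label}-biased"
    with np.errstate(invalid="ignore"):
        finite = np.isfinite(pbs_vals)
        cut = np.nanquantile(pbs_vals, pbs_quantile) if finite.any() else np.nan
        ar = (np.abs(alpha_hat - alpha_global) <= ar_band) & finite & (pbs_vals <= cut)
    ar &= out == "unclassified"
    out[ar] = "admixture-representative"
    return pd.Series(out, index=records.index, name="component_class")
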