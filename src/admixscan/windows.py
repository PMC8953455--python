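"""Genome-window construction and site <-> gene interval mapping."""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .datatypes import GeneModel, SiteTable

logger = logging.getLogger(__name__)

__all__ = ["make_windows", "window_site_indices", "map_sites_to_genes"]

DEFAULT_WINDOW_SIZE = 50_000
DEFAULT_WINDOW_STEP = 25_000


def make_windows(contig_lengths: Mapping[str, int],
                 size: int = DEFAULT_WINDOW_SIZE,
                 step: int = DEFAULT_WINDOW_STEP) -> pd.DataFrame:
    """Sliding windows [i*step, i*step+size) fully inside each contig.

    Returns a DataFrame with columns chrom, start, end (0-based half-open),
    sorted by (chrom insertion order, start). Defaults are 50 kb windows
    advanced by 25 kb.
    """
    if size <= 0 or step <= 0:
        raise ValueError("size and step must be positive")
    if step > size:
        raise ValueError("step must not exceed size")
    rows = []
    for chrom, length in contig_lengths.items():
        n = (length - size) // step + 1 if length >= size else 0
        starts = np.arange(n, dtype=np.int64) * step
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": starts + size}))
    if not rows:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    return pd.concat(rows, ignore_index=True)


def window_site_indices(site_table: SiteTable, windows: pd.DataFrame) -> list[np.ndarray]:
    """Per window, the site-row indices falling inside it (vectorized lookup)."""
    out: list[np.ndarray] = []
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in pd.unique(site_table.chrom):
        rows = site_table.chrom_index(chrom)
        by_chrom[chrom] = (rows, site_table.pos[rows] - 1)  # 0-based positions
    for chrom, start, end in windows[["chrom", "start", "end"]].itertuples(index=False):
        if chrom not in by_chrom:
            out.append(np.empty(0, dtype=np.int64))
            continue
        rows, pos0 = by_chrom[chrom]
        lo = np.searchsorted(pos0, start, side="left")
        hi = np.searchsorted(pos0, end, side="left")
        out.append(rows[lo:hi])
    return out


def map_sites_to_genes(site_table: SiteTable, genes: GeneModel,
                       flank_bp: int = 0) -> dict[str, np.ndarray]:
    """Map each site to every gene whose [start-flank, end+flank) contains it.

    Returns ``{symbol: sorted site-row indices}``; genes with no mapped site
    are omitted (logged). Sites may map to zero or several genes.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be non-negative")
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end, symbol in genes.df[["chrom", "start", "end", "symbol"]].itertuples(index=False):
        trees.setdefault(chrom, IntervalTree()).addi(start - flank_bp, end + flank_bp, symbol)
    mapping: dict[str, list[int]] = {}
    for row, (chrom, pos) in enumerate(zip(site_table.chrom, site_table.pos)):
        tree = trees.get(chrom)
        if tree is None:
            continue
        for iv in tree.at(pos - 1):  # 1-based pos -> 0-based coordinate
            mapping.setdefault(iv.data, []).append(row)
    n_empty = len(genes) - len(mapping)
    if n_empty:
        logger.info("map_sites_to_genes: %d genes with no mapped site dropped", n_empty)
    return {sym: np.asarray(rows, dtype=np.int64) for sym, rows in mapping.items()}
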