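"""Core data containers shared by every analysis stage.

Coordinate conventions
----------------------
VCF positions are 1-based; every internal interval (windows, gene bodies,
local-ancestry segments) is 0-based half-open, matching BED. A site with
1-based position ``pos`` lies in interval ``[start0, end0)`` iff
``start0 <= pos - 1 < end0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SiteTable",
    "HaplotypeMatrix",
    "GeneticMap",
    "LocalAncestryTrack",
    "AdmixtureModel",
    "GeneModel",
    "GeneSetCollection",
    "VariantScoreTable",
]

_BASES = frozenset("ACGT")


class SiteTable:
    """Table of biallelic SNVs, sorted by (chrom, pos), positions 1-based.

    Wraps a :class:`pandas.DataFrame` with columns ``chrom, pos, ref, alt,
    anc, id``. ``anc`` is the ancestral allele and must equal ``ref``,
    ``alt`` or ``"."`` (unknown); ``id`` is the variant identifier or ``"."``.
    """

    COLUMNS = ("chrom", "pos", "ref", "alt", "anc", "id")

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        df = df.reset_index(drop=True)
        for col in ("anc", "id"):
            if col not in df.columns:
                df[col] = "."
        self.df = df[list(self.COLUMNS)]
        if validate:
            self._validate()

    def _validate(self) -> None:
        df = self.df
        if len(df) == 0:
            raise ValueError("empty site table")
        if not df["ref"].isin(_BASES).all() or not df["alt"].isin(_BASES).all():
            raise ValueError("ref/alt must be single bases (biallelic SNVs only)")
        if (df["ref"] == df["alt"]).any():
            raise ValueError("ref == alt at some site")
        bad_anc = ~(df["anc"].eq(df["ref"]) | df["anc"].eq(df["alt"]) | df["anc"].eq("."))
        if bad_anc.any():
            raise ValueError("anc must be ref, alt or '.'")
        key = df[["chrom", "pos"]]
        if key.duplicated().any():
            raise ValueError("duplicate (chrom, pos)")
        grouped = df.groupby("chrom", sort=False)["pos"]
        if not grouped.apply(lambda s: s.is_monotonic_increasing).all():
            raise ValueError("sites not sorted by pos within chrom")

    @classmethod
    def from_arrays(cls, chrom, pos, ref, alt, anc=None, ids=None) -> "SiteTable":
        n = len(pos)
        df = pd.DataFrame(
            {
                "chrom": np.asarray(chrom, dtype=object),
                "pos": np.asarray(pos, dtype=np.int64),
                "ref": np.asarray(ref, dtype=object),
                "alt": np.asarray(alt, dtype=object),
                "anc": np.full(n, ".", dtype=object) if anc is None else np.asarray(anc, dtype=object),
                "id": np.full(n, ".", dtype=object) if ids is None else np.asarray(ids, dtype=object),
            }
        )
        return cls(df)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def chrom(self) -> np.ndarray:
        return self.df["chrom"].to_numpy()

    @property
    def pos(self) -> np.ndarray:
        return self.df["pos"].to_numpy()

    def chrom_index(self, chrom: str) -> np.ndarray:
        """Row indices of sites on ``chrom`` (contiguous by the sort invariant)."""
        return np.flatnonzero(self.chrom == chrom)

    def sites_in_interval(self, chrom: str, start0: int, end0: int) -> np.ndarray:
        """Row indices of sites on ``chrom`` inside 0-based half-open [start0, end0)."""
        idx = self.chrom_index(chrom)
        if idx.size == 0:
            return idx
        pos0 = self.pos[idx] - 1  # to 0-based
        lo = np.searchsorted(pos0, start0, side="left")
        hi = np.searchsorted(pos0, end0, side="left")
        return idx[lo:hi]

    def derived_indicator(self) -> np.ndarray:
        """Per site: 1 if alt is the derived allele, 0 if ref is derived, -1 unknown."""
        anc = self.df["anc"].to_numpy()
        out = np.full(len(self.df), -1, dtype=np.int8)
        out[anc == self.df["ref"].to_numpy()] = 1
        out[anc == self.df["alt"].to_numpy()] = 0
        return out


class HaplotypeMatrix:
    """Phased 0/1 alleles, sites x haplotypes, row-aligned to a SiteTable.

    Columns are ordered ``(sample_0, hap 0), (sample_0, hap 1), (sample_1,
    hap 0), ...``; 0 codes the reference allele, 1 the alternate.
    """

    def __init__(self, alleles: np.ndarray, samples: Sequence[str]):
        alleles = np.asarray(alleles, dtype=np.int8)
        if alleles.ndim != 2:
            raise ValueError("alleles must be 2-D (sites x haplotypes)")
        if alleles.shape[1] != 2 * len(samples):
            raise ValueError("column count must equal 2 * n samples")
        if alleles.size and not np.isin(alleles, (0, 1)).all():
            raise ValueError("alleles must be 0/1 (no missing values)")
        self.alleles = alleles
        self.samples = list(samples)

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_hap(self) -> int:
        return self.alleles.shape[1]

    @property
    def n_ind(self) -> int:
        return len(self.samples)

    def column_labels(self) -> list[tuple[str, int]]:
        return [(s, h) for s in self.samples for h in (0, 1)]

    def dosage(self) -> np.ndarray:
        """Diploid alt-allele dosage, sites x individuals, values in {0,1,2}."""
        return self.alleles[:, 0::2] + self.alleles[:, 1::2]

    def alt_freq(self) -> np.ndarray:
        """Alternate-allele frequency per site."""
        return self.alleles.mean(axis=1)

    def take_individuals(self, ind_idx: np.ndarray) -> "HaplotypeMatrix":
        ind_idx = np.asarray(ind_idx)
        cols = np.empty(2 * ind_idx.size, dtype=np.int64)
        cols[0::2] = 2 * ind_idx
        cols[1::2] = 2 * ind_idx + 1
        return HaplotypeMatrix(self.alleles[:, cols], [self.samples[i] for i in ind_idx])


class GeneticMap:
    """Piecewise-linear bp -> cM map per contig.

    Anchors are (1-based bp, cM) pairs with non-decreasing cM; interpolation
    is linear between anchors, and positions beyond the anchored range are
    extrapolated at the nearest interval's local rate.
    """

    def __init__(self, anchors: Mapping[str, tuple[np.ndarray, np.ndarray]]):
        self._anchors: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (pos, cm) in anchors.items():
            pos = np.asarray(pos, dtype=np.float64)
            cm = np.asarray(cm, dtype=np.float64)
            if pos.size < 2:
                raise ValueError(f"{chrom}: need >=2 anchor points")
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"{chrom}: anchor positions not strictly increasing")
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"{chrom}: cM must be non-decreasing")
            self._anchors[chrom] = (pos, cm)

    @classmethod
    def uniform(cls, contig_lengths: Mapping[str, int], rate_cm_per_mb: float = 1.0) -> "GeneticMap":
        anchors = {
            c: (np.array([1.0, float(L)]), np.array([0.0, (L - 1) * rate_cm_per_mb / 1e6]))
            for c, L in contig_lengths.items()
        }
        return cls(anchors)

    @property
    def contigs(self) -> list[str]:
        return list(self._anchors)

    def cm(self, chrom: str, pos) -> np.ndarray:
        """Genetic position in cM of 1-based bp coordinate(s) ``pos``."""
        if chrom not in self._anchors:
            raise KeyError(f"contig {chrom!r} absent from genetic map")
        p, c = self._anchors[chrom]
        pos = np.atleast_1d(np.asarray(pos, dtype=np.float64))
        out = np.interp(pos, p, c)
        left = pos < p[0]
        right = pos > p[-1]
        if left.any():
            rate = (c[1] - c[0]) / (p[1] - p[0])
            out[left] = c[0] + (pos[left] - p[0]) * rate
        if right.any():
            rate = (c[-1] - c[-2]) / (p[-1] - p[-2])
            out[right] = c[-1] + (pos[right] - p[-1]) * rate
        return out

    def bp(self, chrom: str, cm) -> np.ndarray:
        """Inverse lookup: bp coordinate of genetic position(s) ``cm``.

        Where the map is flat the left edge of the plateau is returned.
        """
        if chrom not in self._anchors:
            raise KeyError(f"contig {chrom!r} absent from genetic map")
        p, c = self._anchors[chrom]
        cm = np.atleast_1d(np.asarray(cm, dtype=np.float64))
        return np.interp(cm, c, p)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom, (p, c) in self._anchors.items():
            rows.append(pd.DataFrame({"chrom": chrom, "pos": p.astype(np.int64), "cM": c}))
        return pd.concat(rows, ignore_index=True)


@dataclass
class AdmixtureModel:
    """Global admixture model: ancestry labels and proportions alpha_k."""

    labels: tuple[str, ...]
    alpha: np.ndarray

    def __post_init__(self):
        self.labels = tuple(self.labels)
        self.alpha = np.asarray(self.alpha, dtype=np.float64)
        if len(self.labels) != self.alpha.size:
            raise ValueError("labels/alpha length mismatch")
        if np.any(self.alpha < 0):
            raise ValueError("alpha_k must be non-negative")
        if abs(self.alpha.sum() - 1.0) > 1e-9:
            raise ValueError("alpha must sum to 1")

    @property
    def k(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)


class LocalAncestryTrack:
    """Per-(site, haplotype) ancestry codes, aligned to a SiteTable/HaplotypeMatrix.

    ``codes[s, h]`` is the integer ancestry (index into ``labels``) of
    haplotype ``h`` at site ``s``. Column order matches
    :meth:`HaplotypeMatrix.column_labels`. An optional segment table
    (``chrom, start, end, sample, hap, ancestry``; 0-based half-open) is kept
    when the track was built from, or for, interval form.
    """

    def __init__(self, codes: np.ndarray, labels: Sequence[str], samples: Sequence[str],
                 segments: pd.DataFrame | None = None):
        codes = np.asarray(codes, dtype=np.int8)
        if codes.ndim != 2 or codes.shape[1] != 2 * len(samples):
            raise ValueError("codes must be sites x (2*n samples)")
        if codes.size and (codes.min() < 0 or codes.max() >= len(labels)):
            raise ValueError("ancestry code outside label range")
        self.codes = codes
        self.labels = tuple(labels)
        self.samples = list(samples)
        self.segments = segments

    @property
    def n_sites(self) -> int:
        return self.codes.shape[0]

    @property
    def n_hap(self) -> int:
        return self.codes.shape[1]

    def indicator(self, k: int | str) -> np.ndarray:
        """Boolean sites x haplotypes mask of ancestry ``k``."""
        if isinstance(k, str):
            k = self.labels.index(k)
        return self.codes == k

    def global_fraction(self) -> np.ndarray:
        """Genome-wide fraction of (site, haplotype) calls per ancestry."""
        counts = np.array([(self.codes == k).sum() for k in range(len(self.labels))], dtype=float)
        return counts / self.codes.size

    def relabeled(self, order: Sequence[int]) -> "LocalAncestryTrack":
        """Track with ancestries permuted: new code i = old code order[i]."""
        inv = np.empty(len(order), dtype=np.int8)
        for new, old in enumerate(order):
            inv[old] = new
        return LocalAncestryTrack(inv[self.codes], [self.labels[o] for o in order],
                                  self.samples)

    @classmethod
    def from_segments(cls, segments: pd.DataFrame, site_table: SiteTable,
                      samples: Sequence[str], labels: Sequence[str]) -> "LocalAncestryTrack":
        """Densify a segment table onto the sites of ``site_table``.

        Every analyzed site must be covered by exactly one segment per
        haplotype; gaps and overlaps raise ``ValueError``.
        """
        labels = list(labels)
        label_code = {lab: k for k, lab in enumerate(labels)}
        hap_col = {(s, h): j for j, (s, h) in
                   enumerate((s, h) for s in samples for h in (0, 1))}
        m = len(site_table)
        codes = np.full((m, 2 * len(samples)), -1, dtype=np.int8)
        chrom_rows: dict[str, np.ndarray] = {c: site_table.chrom_index(c)
                                             for c in pd.unique(site_table.chrom)}
        for (sample, hap), seg in segments.groupby(["sample", "hap"], sort=False):
            if (sample, hap) not in hap_col:
                raise ValueError(f"unknown haplotype {(sample, hap)} in ancestry file")
            j = hap_col[(sample, hap)]
            for chrom, cseg in seg.groupby("chrom", sort=False):
                cseg = cseg.sort_values("start")
                starts = cseg["start"].to_numpy()
                ends = cseg["end"].to_numpy()
                if np.any(starts[1:] < ends[:-1]):
                    raise ValueError(f"overlapping segments on {sample} hap {hap} {chrom}")
                rows = chrom_rows.get(chrom)
                if rows is None or rows.size == 0:
                    continue
                pos0 = site_table.pos[rows] - 1
                seg_idx = np.searchsorted(starts, pos0, side="right") - 1
                ok = (seg_idx >= 0) & (pos0 < ends[np.clip(seg_idx, 0, None)])
                for lab in pd.unique(cseg["ancestry"]):
                    if lab not in label_code:
                        raise ValueError(f"unknown ancestry label {lab!r}")
                anc_codes = cseg["ancestry"].map(label_code).to_numpy()
                codes[rows[ok], j] = anc_codes[seg_idx[ok]]
        if (codes < 0).any():
            s, h = np.argwhere(codes < 0)[0]
            raise ValueError(
                f"site {site_table.chrom[s]}:{site_table.pos[s]} uncovered for haplotype column {h}"
            )
        return cls(codes, labels, samples, segments=segments)


class GeneModel:
    """Gene intervals: chrom, start (0-based), end (half-open), symbol, strand."""

    def __init__(self, df: pd.DataFrame):
        df = df.reset_index(drop=True)
        if "strand" not in df.columns:
            df["strand"] = "+"
        if (df["end"] <= df["start"]).any():
            raise ValueError("gene interval with end <= start")
        if df["symbol"].duplicated().any():
            raise ValueError("duplicate gene symbols")
        self.df = df[["chrom", "start", "end", "symbol", "strand"]]

    def __len__(self) -> int:
        return len(self.df)

    @property
    def symbols(self) -> np.ndarray:
        return self.df["symbol"].to_numpy()


class GeneSetCollection:
    """Named gene sets (GMT semantics): set name -> frozenset of symbols."""

    def __init__(self, sets: Mapping[str, Iterable[str]],
                 descriptions: Mapping[str, str] | None = None):
        self.sets: dict[str, frozenset[str]] = {}
        for name, genes in sets.items():
            genes = frozenset(genes)
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            self.sets[name] = genes
        self.descriptions = dict(descriptions or {})

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


class VariantScoreTable:
    """Per-variant deleteriousness annotation keyed by (chrom, pos, ref, alt).

    ``impact`` is a VEP-style class in {high, moderate, low, modifier};
    ``weight`` is a non-negative deleteriousness score (e.g. CADD- or
    GERP-derived), consumed as given.
    """

    IMPACTS = ("high", "moderate", "low", "modifier")

    def __init__(self, df: pd.DataFrame):
        df = df.reset_index(drop=True)
        if not df["impact"].isin(self.IMPACTS).all():
            raise ValueError("impact must be one of " + "/".join(self.IMPACTS))
        w = df["weight"].to_numpy(dtype=float)
        if not np.isfinite(w).all() or (w < 0).any():
            raise ValueError("weights must be finite and non-negative")
        if df[["chrom", "pos", "ref", "alt"]].duplicated().any():
            raise ValueError("duplicate variant key in score table")
        self.df = df[["chrom", "pos", "ref", "alt", "impact", "weight"]]

    def aligned_to(self, site_table: SiteTable) -> pd.DataFrame:
        """Scores merged onto the site table's row order (NaN where absent)."""
        key = site_table.df[["chrom", "pos", "ref", "alt"]].copy()
        key["_row"] = np.arange(len(key))
        merged = key.merge(self.df, on=["chrom", "pos", "ref", "alt"], how="left")
        return merged.sort_values("_row")[["impact", "weight"]].reset_index(drop=True)
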