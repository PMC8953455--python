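"""Per-individual genetic load under dominant/additive/recessive models,
pathway-level population comparisons, and load-vs-ancestry association.

Load counts deleterious variants per individual by carrier status
(dominant: any alt allele), allele dosage (additive) or homozygosity
(recessive), optionally weighted by a per-variant deleteriousness score,
restricted to VEP-style impact classes (default: high + moderate).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import GeneSetCollection, HaplotypeMatrix, SiteTable, VariantScoreTable

logger = logging.getLogger(__name__)

__all__ = ["individual_load", "pathway_load_compare", "load_vs_ancestry"]

MODELS = ("dominant", "additive", "recessive")
DEFAULT_IMPACTS = frozenset({"high", "moderate"})


def _model_matrix(dosage: np.ndarray, model: str) -> np.ndarray:
    if model == "dominant":
        return (dosage >= 1).astype(np.float64)
    if model == "additive":
        return dosage.astype(np.float64)
    if model == "recessive":
        return (dosage == 2).astype(np.float64)
    raise ValueError(f"unknown inheritance model {model!r}")


def individual_load(matrix: HaplotypeMatrix, sites: SiteTable,
                    scores: VariantScoreTable, weighted: bool = False,
                    impact_filter: frozenset[str] = DEFAULT_IMPACTS,
                    site_subset: np.ndarray | None = None) -> pd.DataFrame:
    """Per-individual load under all three inheritance models.

    dominant = sum_v w_v 1[g_v >= 1]; additive = sum_v w_v g_v;
    recessive = sum_v w_v 1[g_v = 2]; w_v = 1 when unweighted. Variants
    are restricted to ``impact_filter`` classes (and optionally to
    ``site_subset`` row indices, e.g. one pathway's sites). On the count
    scale additive >= dominant >= recessive for every individual.
    """
    aligned = scores.aligned_to(sites)
    keep = aligned["impact"].isin(impact_filter).to_numpy()
    if site_subset is not None:
        sub = np.zeros(len(sites), dtype=bool)
        sub[np.asarray(site_subset)] = True
        keep &= sub
    if weighted and aligned["weight"][keep].isna().any():
        raise ValueError("weighting requested but some analyzed variants lack scores")
    w = aligned["weight"].to_numpy(dtype=float) if weighted else np.ones(len(sites))
    w = np.where(keep, np.nan_to_num(w), 0.0)
    dosage = matrix.dosage()
    out = pd.DataFrame({"sample": matrix.samples})
    for model in MODELS:
        out[model] = w @ _model_matrix(dosage, model)
    out["n_variants"] = int(keep.sum())
    return out


def pathway_load_compare(matrices: dict[str, tuple[HaplotypeMatrix, SiteTable]] | dict,
                         scores: VariantScoreTable,
                         gene_sets: GeneSetCollection,
                         gene_map: dict[str, np.ndarray],
                         admixed: str, model: str = "dominant",
                         weighted: bool = False,
                         impact_filter: frozenset[str] = DEFAULT_IMPACTS) -> pd.DataFrame:
    """Per-gene-set load comparison of the admixed population vs each reference.

    ``matrices`` maps population name -> (HaplotypeMatrix, SiteTable); the
    site tables must describe the same variants. For each set, the load is
    recomputed over the set genes' sites and compared admixed-vs-reference
    with a two-sample Wilcoxon rank-sum test (normal approximation with
    tie correction; exact for fewer than 20 per group), then BH-adjusted
    across sets per reference. Empty pathways are skipped with a log entry.
    """
    if model not in MODELS:
        raise ValueError(f"unknown inheritance model {model!r}")
    pops = list(matrices)
    if admixed not in pops or len(pops) < 2:
        raise ValueError("need the admixed population plus at least one reference")
    refs = [p for p in pops if p != admixed]
    rows = []
    for set_name, genes in gene_sets.items():
        site_rows = [gene_map[g] for g in genes if g in gene_map]
        if not site_rows:
            logger.info("pathway_load_compare: set %r empty after mapping, skipped", set_name)
            continue
        subset = np.unique(np.concatenate(site_rows))
        loads = {}
        for pop in pops:
            mat, st = matrices[pop]
            loads[pop] = individual_load(mat, st, scores, weighted=weighted,
                                         impact_filter=impact_filter,
                                         site_subset=subset)[model].to_numpy()
        row = {"set": set_name, "n_sites": int(subset.size)}
        for ref in refs:
            a, b = loads[admixed], loads[ref]
            method = "exact" if min(a.size, b.size) < 20 else "asymptotic"
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
            p = float(res.pvalue)
            row[f"p_vs_{ref}"] = p
            row[f"direction_vs_{ref}"] = float(np.median(a) - np.median(b))
        rows.append(row)
    out = pd.DataFrame(rows)
    for ref in refs:
        if len(out):
            out[f"q_vs_{ref}"] = multipletests(out[f"p_vs_{ref}"], method="fdr_bh")[1]
    return out


def load_vs_ancestry(loads: np.ndarray, global_ancestry: np.ndarray) -> tuple[float, float]:
    """OLS of per-individual load on global ancestry proportion.

    Returns (slope, two-sided P of the slope). Requires >= 10 individuals
    and non-degenerate ancestry values.
    """
    loads = np.asarray(loads, dtype=float)
    a = np.asarray(global_ancestry, dtype=float)
    if loads.size < 10:
        raise ValueError("need at least 10 individuals")
    if np.allclose(a, a[0]):
        raise ValueError("zero variance in global ancestry")
    res = stats.linregress(a, loads)
    return float(res.slope), float(res.pvalue)
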