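"""Synthetic admixed-cohort generator with truth tracks.

The generator emulates the statistical structure the downstream analyses
assume: two (optionally K) ancestral populations whose allele frequencies
diverge under a Balding-Nichols model with parameter ``F_div``; a
hybrid-isolation (single-pulse) admixture ``g`` generations ago producing
exponential-length ancestry tracts along the genetic map with stationary
proportions alpha; optional ancestry-biased "spikes" at focal loci where
the focal ancestry probability is raised to alpha'; an optional rare-variant
excess in one ancestry; deleterious-variant annotations; and tiled gene /
gene-set tracks. Truth (tract labels, parameters, spiked sets) is recorded
so parameter-recovery tests can compare estimates against it.

Genotype modes
--------------
``frequency``
    Alleles drawn Bernoulli(AF of the haplotype's local ancestry),
    independently across sites: no within-ancestry linkage disequilibrium.
``panel``
    Each ancestry tract copies a haplotype from a finite simulated
    ancestral panel, so alleles within a tract share a panel haplotype and
    carry LD; distant tracts are independent. This mode exists for the
    EHH-family statistics, which need haplotype structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    AdmixtureModel,
    GeneModel,
    GeneSetCollection,
    GeneticMap,
    HaplotypeMatrix,
    LocalAncestryTrack,
    SiteTable,
    VariantScoreTable,
)
from . import io as asio

__all__ = [
    "SimScenario",
    "SimBundle",
    "simulate_ancestral_frequencies",
    "simulate_ancestry_tracts",
    "simulate_reference_panels",
    "simulate_genotypes",
    "simulate_bundle",
    "simulate_cohort",
]


@dataclass
class SimScenario:
    """Parameters of one synthetic cohort.

    Defaults reflect the admixture setting the analyses target: a roughly
    half/half two-way mixture (alpha = 0.5 EAS-like), tens of generations of
    recombination since the pulse (g = 40), and source-population divergence
    matching an EAS/EUR-scale global FST (F_div = 0.11).
    """

    n_admixed: int = 100          # diploid individuals in the admixed cohort
    n_ref: int = 100              # diploid individuals per reference panel
    m_sites: int = 20_000
    contig_length: int = 20_000_000
    chrom: str = "1"
    rate_cm_per_mb: float = 1.0
    labels: tuple[str, ...] = ("EAS", "EUR")
    alpha: float | tuple[float, ...] = 0.5   # EAS-like global proportion (or full vector)
    g: float = 40.0               # generations since the admixture pulse
    f_div: float = 0.11           # Balding-Nichols divergence of the sources
    spikes: tuple[tuple[float, float], ...] = ()   # (focal bp, alpha' for labels[0])
    rare_skew: float = 0.0        # fraction of sites forced rare in one ancestry
    rare_skew_ancestry: str = "EAS"
    mode: str = "frequency"       # "frequency" | "panel"
    panel_size: int = 20          # haplotypes per ancestral panel (panel mode)
    sweep: tuple[str, float, float, float] | None = None  # (ancestry, center bp, radius bp, panel freq)
    gene_tile_step: int = 50_000
    gene_length: int = 20_000
    n_gene_sets: int = 10
    gene_set_size: int = 20
    deleterious_eas_excess: float = 0.0   # AF bump of high/moderate sites in labels[0]
    load_spike_gain: float = 0.0  # extra per-hap alt gain at deleterious sites in spiked-set genes (admixed only)
    seed: int = 0

    def __post_init__(self):
        a = self.alpha_vector()
        if np.any(a <= 0) or np.any(a >= 1):
            raise ValueError("all alpha_k must lie strictly in (0, 1)")
        if self.g < 1:
            raise ValueError("g must be >= 1")
        if not 0 < self.f_div < 1:
            raise ValueError("F_div must lie in (0, 1)")
        for pos, ap in self.spikes:
            if not 0 <= ap <= 1:
                raise ValueError("spike alpha' must lie in [0, 1]")
            if not 0 < pos <= self.contig_length:
                raise ValueError("spike position outside contig")
        if self.mode not in ("frequency", "panel"):
            raise ValueError("mode must be 'frequency' or 'panel'")

    def alpha_vector(self) -> np.ndarray:
        if np.isscalar(self.alpha):
            if len(self.labels) != 2:
                raise ValueError("scalar alpha requires exactly two ancestries")
            return np.array([float(self.alpha), 1.0 - float(self.alpha)])
        a = np.asarray(self.alpha, dtype=float)
        if a.size != len(self.labels):
            raise ValueError("alpha vector length must match labels")
        return a


@dataclass
class SimBundle:
    """In-memory result of one simulation: data, truth and annotations."""

    scenario: SimScenario
    sites: SiteTable
    admixed: HaplotypeMatrix
    references: dict[str, HaplotypeMatrix]
    track: LocalAncestryTrack          # truth tracts of the admixed cohort
    ancestral_af: np.ndarray           # (K, m) true source allele frequencies
    gmap: GeneticMap
    model: AdmixtureModel
    genes: GeneModel
    gene_sets: GeneSetCollection
    scores: VariantScoreTable
    truth: dict = field(default_factory=dict)

    def individual_ancestry(self) -> np.ndarray:
        """Realized global fraction of ancestry labels[0] per admixed individual."""
        ind = self.track.indicator(0)
        per_hap = ind.mean(axis=0)
        return 0.5 * (per_hap[0::2] + per_hap[1::2])


def simulate_ancestral_frequencies(m: int, f_div: float, rng: np.random.Generator,
                                   rare_skew: float = 0.0, skew_pop: int = 0,
                                   k: int = 2) -> np.ndarray:
    """Per-ancestry allele frequencies under the Balding-Nichols model.

    A shared ancestral frequency p is drawn from a uniform/beta mixture
    (70% Uniform(0.05, 0.95), 30% Beta(0.2, 2) clipped to [0.005, 0.95] --
    the beta component supplies a realistic rare-variant tail); each
    population's AF is then Beta(p(1-F)/F, (1-p)(1-F)/F). With
    ``rare_skew`` > 0, that fraction of sites has population ``skew_pop``'s
    AF replaced by a Uniform(0.001, 0.049) draw, creating a rare-variant
    excess in that ancestry while leaving the other marginals untouched.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 < f_div < 1:
        raise ValueError("F_div must lie in (0, 1)")
    use_beta = rng.random(m) < 0.3
    p = rng.uniform(0.05, 0.95, size=m)
    p[use_beta] = np.clip(rng.beta(0.2, 2.0, size=use_beta.sum()), 0.005, 0.95)
    c = (1.0 - f_div) / f_div
    afs = rng.beta(np.maximum(p * c, 1e-9), np.maximum((1.0 - p) * c, 1e-9), size=(k, m))
    afs = np.clip(afs, 0.0, 1.0)
    if rare_skew > 0:
        skew = rng.random(m) < rare_skew
        afs[skew_pop, skew] = rng.uniform(0.001, 0.049, size=skew.sum())
    return afs


def _simulate_hap_segments(rng: np.random.Generator, total_m: float, alpha: np.ndarray,
                           g: float, spike: tuple[float, np.ndarray] | None) -> list[tuple[float, float, int]]:
    """One haplotype's ancestry segments in Morgans, [0, total_m).

    The jump process leaves state k at rate g*(1 - alpha_k) per Morgan and
    lands on j != k with probability alpha_j / (1 - alpha_k); its stationary
    law is alpha and, for K = 2, the A->B / B->A rates are g(1-alpha) and
    g*alpha. The chain is reversible, so with a spike the state is drawn at
    the focal position and the same dynamics are run outward both ways.
    """
    k = alpha.size

    def _next_state(state: int) -> int:
        w = alpha.copy()
        w[state] = 0.0
        w /= w.sum()
        return int(rng.choice(k, p=w))

    def _run(x0: float, state: int, limit: float) -> list[tuple[float, float, int]]:
        segs = []
        x = x0
        while x < limit:
            rate = g * (1.0 - alpha[state])
            step = rng.exponential(1.0 / rate) if rate > 0 else np.inf
            end = min(x + step, limit)
            segs.append((x, end, state))
            x = end
            if x < limit:
                state = _next_state(state)
        return segs

    if spike is None:
        state0 = int(rng.choice(k, p=alpha))
        return _run(0.0, state0, total_m)
    x0, probs = spike
    state0 = int(rng.choice(k, p=probs))
    right = _run(x0, state0, total_m)
    # mirror: run the reversible chain from x0 toward 0
    left_rev = _run(0.0, state0, x0)
    left = [(x0 - e, x0 - s, st) for (s, e, st) in left_rev]
    left.reverse()
    # stitch; the two segments adjoining x0 share state0 and merge
    if left and right and left[-1][2] == right[0][2]:
        merged = (left[-1][0], right[0][1], state0)
        return left[:-1] + [merged] + right[1:]
    return left + right


def simulate_ancestry_tracts(sites: SiteTable, gmap: GeneticMap, n_hap: int,
                             alpha: np.ndarray, g: float,
                             spikes: tuple[tuple[float, float], ...],
                             rng: np.random.Generator,
                             samples: list[str] | None = None,
                             labels: tuple[str, ...] = ("EAS", "EUR"),
                             chrom: str | None = None,
                             contig_length: int | None = None) -> LocalAncestryTrack:
    """Hybrid-isolation ancestry tracts for ``n_hap`` haplotypes on one contig.

    ``spikes`` are (focal bp, alpha') pairs: at the focal position the
    probability of ancestry ``labels[0]`` is alpha' instead of alpha[0];
    at most one spike per contig is supported. Returns a dense track plus
    the segment table in bp (truth for recovery tests).
    """
    if n_hap % 2:
        raise ValueError("n_hap must be even (diploid columns)")
    alpha = np.asarray(alpha, dtype=float)
    if chrom is None:
        chrom = sites.chrom[0]
    if contig_length is None:
        contig_length = int(sites.pos.max())
    if len(spikes) > 1:
        raise ValueError("at most one ancestry spike per contig is supported")
    if samples is None:
        samples = [f"ADM{i:04d}" for i in range(n_hap // 2)]

    cm0 = float(gmap.cm(chrom, 1)[0])
    total_m = (float(gmap.cm(chrom, contig_length)[0]) - cm0) / 100.0
    spike = None
    if spikes:
        pos, ap = spikes[0]
        probs = np.empty(alpha.size)
        probs[0] = ap
        rest = alpha[1:] / alpha[1:].sum() if alpha.size > 1 else np.array([])
        probs[1:] = (1.0 - ap) * rest
        spike = ((float(gmap.cm(chrom, pos)[0]) - cm0) / 100.0, probs)

    site_m = (gmap.cm(chrom, sites.pos) - cm0) / 100.0
    m = len(sites)
    codes = np.empty((m, n_hap), dtype=np.int8)
    seg_rows = []
    for h in range(n_hap):
        segs = _simulate_hap_segments(rng, total_m, alpha, g, spike)
        ends_m = np.array([e for _, e, _ in segs])
        states = np.array([st for _, _, st in segs], dtype=np.int8)
        idx = np.clip(np.searchsorted(ends_m, site_m, side="right"), 0, len(segs) - 1)
        codes[:, h] = states[idx]
        sample, hap = samples[h // 2], h % 2
        bp_ends = np.round(gmap.bp(chrom, ends_m * 100.0 + cm0)).astype(np.int64)
        bp_starts = np.concatenate([[0], bp_ends[:-1]])
        bp_ends[-1] = contig_length
        for s0, e0, st in zip(bp_starts, bp_ends, states):
            if e0 > s0:
                seg_rows.append((chrom, int(s0), int(e0), sample, hap, labels[st]))
    segments = pd.DataFrame(seg_rows, columns=["chrom", "start", "end", "sample", "hap", "ancestry"])
    return LocalAncestryTrack(codes, labels, samples, segments=segments)


def simulate_reference_panels(afs: np.ndarray, panel_size: int,
                              rng: np.random.Generator) -> np.ndarray:
    """Finite ancestral haplotype panels: (K, P, m) 0/1 draws from the source AFs."""
    k, m = afs.shape
    u = rng.random((k, panel_size, m))
    return (u < afs[:, None, :]).astype(np.int8)


def _apply_sweep(panels: np.ndarray, sites: SiteTable, labels: tuple[str, ...],
                 sweep: tuple[str, float, float, float],
                 rng: np.random.Generator) -> int:
    """Overwrite a panel region with one shared haplotype (a swept background).

    A fraction ``freq`` of ancestry ``anc``'s panel haplotypes copy panel
    haplotype 0 over [center-radius, center+radius]; at the site nearest the
    center the derived (alt) allele is placed on exactly the swept
    haplotypes and removed everywhere else, so the core allele tags the
    sweep. Returns the core site row.
    """
    anc, center, radius, freq = sweep
    k = labels.index(anc)
    pos = sites.pos
    region = np.flatnonzero(np.abs(pos - center) <= radius)
    if region.size == 0:
        raise ValueError("sweep region contains no sites")
    n_swept = max(2, int(round(freq * panels.shape[1])))
    carriers = np.arange(n_swept)
    template = panels[k, 0, region].copy()
    panels[k, carriers[:, None], region[None, :]] = template[None, :]
    core = int(region[np.argmin(np.abs(pos[region] - center))])
    panels[:, :, core] = 0
    panels[k, carriers, core] = 1
    return core


def simulate_genotypes(track: LocalAncestryTrack, afs: np.ndarray,
                       rng: np.random.Generator, mode: str = "frequency",
                       panels: np.ndarray | None = None,
                       samples: list[str] | None = None) -> HaplotypeMatrix:
    """Draw admixed haplotypes given truth tracts and source AFs.

    Frequency mode draws each allele Bernoulli(AF of the local ancestry);
    panel mode copies one panel haplotype per contiguous tract.
    """
    m, n_hap = track.codes.shape
    samples = samples if samples is not None else track.samples
    if mode == "frequency":
        af_at = afs[track.codes, np.arange(m)[:, None]]
        alleles = (rng.random((m, n_hap)) < af_at).astype(np.int8)
        return HaplotypeMatrix(alleles, samples)
    if mode != "panel":
        raise ValueError("mode must be 'frequency' or 'panel'")
    if panels is None:
        raise ValueError("panel mode requires panels")
    p = panels.shape[1]
    alleles = np.empty((m, n_hap), dtype=np.int8)
    for h in range(n_hap):
        col = track.codes[:, h]
        breaks = np.flatnonzero(np.diff(col)) + 1
        starts = np.concatenate([[0], breaks])
        ends = np.concatenate([breaks, [m]])
        for s, e in zip(starts, ends):
            j = rng.integers(p)
            alleles[s:e, h] = panels[col[s], j, s:e]
    return HaplotypeMatrix(alleles, samples)


def _simulate_scores(sites: SiteTable, rng: np.random.Generator) -> VariantScoreTable:
    """Deleteriousness annotations: VEP-like impact classes plus a weight.

    Class probabilities (high 0.5%, moderate 3%, low 6%, modifier rest)
    caricature exome-wide proportions; weights are gamma-distributed for
    damaging classes and near zero otherwise.
    """
    m = len(sites)
    u = rng.random(m)
    impact = np.where(u < 0.005, "high",
                      np.where(u < 0.035, "moderate",
                               np.where(u < 0.095, "low", "modifier")))
    weight = np.where(np.isin(impact, ("high", "moderate")),
                      rng.gamma(2.0, 1.0, size=m), rng.uniform(0.0, 0.1, size=m))
    df = sites.df[["chrom", "pos", "ref", "alt"]].copy()
    df["impact"] = impact
    df["weight"] = np.round(weight, 6)
    return VariantScoreTable(df)


def _tile_genes(scenario: SimScenario) -> GeneModel:
    starts = np.arange(0, scenario.contig_length - scenario.gene_length,
                       scenario.gene_tile_step, dtype=np.int64)
    df = pd.DataFrame({
        "chrom": scenario.chrom,
        "start": starts,
        "end": starts + scenario.gene_length,
        "symbol": [f"G{i:05d}" for i in range(starts.size)],
        "strand": "+",
    })
    return GeneModel(df)


def _make_gene_sets(scenario: SimScenario, genes: GeneModel,
                    rng: np.random.Generator) -> tuple[GeneSetCollection, str | None]:
    symbols = list(genes.symbols)
    sets: dict[str, list[str]] = {}
    spiked_name = None
    if scenario.spikes:
        pos = scenario.spikes[0][0]
        centers = (genes.df["start"] + genes.df["end"]).to_numpy() / 2.0
        order = np.argsort(np.abs(centers - pos))
        sets["spiked_set"] = [symbols[i] for i in order[: scenario.gene_set_size]]
        spiked_name = "spiked_set"
    n_random = scenario.n_gene_sets - len(sets)
    for i in range(n_random):
        members = rng.choice(len(symbols), size=min(scenario.gene_set_size, len(symbols)),
                             replace=False)
        sets[f"set_{i:03d}"] = [symbols[j] for j in members]
    return GeneSetCollection(sets), spiked_name


def simulate_bundle(scenario: SimScenario) -> SimBundle:
    """Run the full generator in memory; deterministic given ``scenario.seed``."""
    rng = np.random.default_rng(scenario.seed)
    alpha = scenario.alpha_vector()
    k = len(scenario.labels)
    m = scenario.m_sites
    skew_pop = scenario.labels.index(scenario.rare_skew_ancestry)

    pos = np.linspace(1, scenario.contig_length, m).round().astype(np.int64)
    pos = np.unique(pos)
    m = pos.size
    ref_alt = rng.integers(0, 4, size=(2, m))
    bases = np.array(list("ACGT"))
    alt = (ref_alt[0] + 1 + ref_alt[1] % 3) % 4
    sites = SiteTable.from_arrays(
        np.full(m, scenario.chrom, dtype=object), pos,
        bases[ref_alt[0]], bases[alt], anc=bases[ref_alt[0]],
        ids=[f"sv{i:07d}" for i in range(m)],
    )
    gmap = GeneticMap.uniform({scenario.chrom: scenario.contig_length},
                              scenario.rate_cm_per_mb)

    afs = simulate_ancestral_frequencies(m, scenario.f_div, rng,
                                         rare_skew=scenario.rare_skew,
                                         skew_pop=skew_pop, k=k)
    scores = _simulate_scores(sites, rng)
    if scenario.deleterious_eas_excess > 0:
        deleterious = scores.df["impact"].isin(("high", "moderate")).to_numpy()
        afs[0, deleterious] = np.clip(
            afs[0, deleterious] + scenario.deleterious_eas_excess, 0.0, 1.0)

    panels = None
    core_site = None
    if scenario.mode == "panel":
        panels = simulate_reference_panels(afs, scenario.panel_size, rng)
        if scenario.sweep is not None:
            core_site = _apply_sweep(panels, sites, scenario.labels, scenario.sweep, rng)

    track = simulate_ancestry_tracts(
        sites, gmap, 2 * scenario.n_admixed, alpha, scenario.g, scenario.spikes,
        rng, labels=scenario.labels, chrom=scenario.chrom,
        contig_length=scenario.contig_length,
    )
    admixed = simulate_genotypes(track, afs, rng, mode=scenario.mode, panels=panels)

    references: dict[str, HaplotypeMatrix] = {}
    for kk, lab in enumerate(scenario.labels):
        names = [f"{lab}{i:04d}" for i in range(scenario.n_ref)]
        draw = (rng.random((m, 2 * scenario.n_ref)) < afs[kk][:, None]).astype(np.int8)
        references[lab] = HaplotypeMatrix(draw, names)

    genes = _tile_genes(scenario)
    gene_sets, spiked_name = _make_gene_sets(scenario, genes, rng)

    if scenario.load_spike_gain > 0 and spiked_name is not None:
        from .windows import map_sites_to_genes
        gene_map = map_sites_to_genes(sites, genes)
        rows = np.unique(np.concatenate(
            [gene_map[g] for g in gene_sets[spiked_name] if g in gene_map]))
        deleterious = scores.df["impact"].isin(("high", "moderate")).to_numpy()
        rows = rows[deleterious[rows]]
        gain = rng.random((rows.size, admixed.n_hap)) < scenario.load_spike_gain
        al = admixed.alleles.copy()
        al[rows[:, None], np.arange(admixed.n_hap)[None, :]] |= gain.astype(np.int8)
        admixed = HaplotypeMatrix(al, admixed.samples)

    model = AdmixtureModel(scenario.labels, alpha)
    truth = {
        "alpha": alpha.tolist(),
        "g": scenario.g,
        "f_div": scenario.f_div,
        "spikes": [list(s) for s in scenario.spikes],
        "sweep": list(scenario.sweep) if scenario.sweep else None,
        "sweep_core_site": core_site,
        "spiked_gene_set": spiked_name,
        "rare_skew": scenario.rare_skew,
        "rare_skew_ancestry": scenario.rare_skew_ancestry,
        "seed": scenario.seed,
    }
    return SimBundle(scenario, sites, admixed, references, track, afs, gmap,
                     model, genes, gene_sets, scores, truth)


def simulate_cohort(scenario: SimScenario, outdir) -> SimBundle:
    """Generate a complete, mutually consistent input bundle on disk.

    Emits phased VCF (admixed + both references in one file), truth
    ancestry BED, genetic-map TSV, gene BED, GMT, score TSV and a truth
    JSON. Byte-identical across runs with the same scenario.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    b = simulate_bundle(scenario)

    all_samples = list(b.admixed.samples)
    mats = [b.admixed.alleles]
    populations = {"ADMIXED": list(b.admixed.samples)}
    for lab, mat in b.references.items():
        all_samples += mat.samples
        mats.append(mat.alleles)
        populations[lab] = list(mat.samples)
    merged = HaplotypeMatrix(np.hstack(mats), all_samples)
    asio.write_phased_vcf(outdir / "cohort.vcf", b.sites, merged,
                          {scenario.chrom: scenario.contig_length})
    asio.write_local_ancestry(outdir / "ancestry_truth.bed", b.track.segments)
    asio.write_genetic_map(outdir / "genetic_map.tsv", b.gmap)
    asio.write_gene_bed(outdir / "genes.bed", b.genes)
    asio.write_gmt(outdir / "gene_sets.gmt", b.gene_sets)
    asio.write_scores(outdir / "scores.tsv", b.scores)
    truth = dict(b.truth)
    truth["populations"] = populations
    truth["individual_ancestry"] = {
        s: round(float(a), 6)
        for s, a in zip(b.admixed.samples, b.individual_ancestry())
    }
    truth["scenario"] = {k: (list(v) if isinstance(v, tuple) else v)
                         for k, v in asdict(scenario).items()}
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return b
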