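# Methods

This note documents the statistical models behind each analysis stage,
the conventions chosen where several were defensible, what the synthetic
cohort generator does and does not emulate, and the problem sizes used by
the test suite and `scripts/acceptance.py`.

## Coordinates and data model

VCF positions are 1-based; all internal intervals — windows, gene bodies,
local-ancestry segments — are 0-based half-open (BED convention). A site
at 1-based position `pos` lies in `[start, end)` iff `start <= pos-1 <
end`. Haplotype matrices are fully phased 0/1 arrays (sites ×
2·individuals); sites with any missing or unphased genotype are dropped
at load time rather than imputed, because every downstream statistic
assumes complete phased columns. Multiallelic records are dropped, not
split: the analyses are defined over biallelic SNVs. Strand is ignored
throughout (allele codes are reference-strand literals).

## The admixture expectation and AFd_e

For ancestries `k` with global proportions `α_k` summing to one,
`AF_exp = Σ_k α_k AF_k` per site and `AFd_e = |AF_obs − AF_exp|`. The
signed deviation is retained for directionality; the headline summary is
the fraction of sites with AFd_e above a threshold (default 0.1). The
expectation is two-way by default; with more components the user supplies
the collapse mapping (e.g. renormalizing four-way proportions onto the
two source panels actually available). Reference AFs are taken from the
panels as provided — sampling noise in the references therefore
contributes to AFd_e, which is why the calibration experiments compare
cohorts of matched size.

## Diversity statistics

Per window of length L (full window size; no accessibility mask — a
deliberate simplification, noted as an extension point):

- θ_π = 1000/L · Σ_s 2p_s(1−p_s)·n/(n−1), identical to the mean pairwise
  difference count per kb (asserted against an O(n²) oracle).
- θ_K = 1000/L · S/a₁, a₁ = Σ_{i<n} 1/i.
- H = n/(n−1)(1 − Σ f_h²) over distinct window haplotype strings.
- Tajima's D with the 1989 constants; undefined (NaN) for n < 4 or S = 0.
  Windows with no analyzed sites report NaN, not zero.
- Rare-variant fraction: share of segregating sites with *folded*
  frequency min(AF, 1−AF) < 0.05. Folding is the default because a bare
  "AF < 0.05" rule is sensitive to reference-allele polarity; an unfolded
  option exists.

Sample-size balancing follows the repeated-subsampling design: draw
`subsample_n` individuals (default 50) without replacement, recompute
site frequencies within the subsample, evaluate all statistics, repeat
(default 100 replicates) and report the per-window **median** (plus IQR).
N_e is reported as θ/(4μ) — a placeholder convention, since no standard
method is implied by the statistic list itself; it is exposed but not
used by any other stage.

## F_ST, PBS and component classification

The default F_ST is Hudson's estimator, accumulated as a ratio of
averages (Σnum/Σden) — robust to unequal sample sizes and invariant to
site duplication; negative per-site values are retained.
Weir–Cockerham (haploid form) is available as an option. PBS uses
T = −ln(1−F_ST) with negative inputs clamped to zero; F_ST = 1 yields an
undefined branch (NaN).

Window ancestry proportions α̂ are fractions of (site, haplotype) calls.
Empirical P values use the add-one rank convention, upper P =
(1+#{bg ≥ x})/(1+n_bg), so no P is ever zero; the background is the
genome-wide distribution of *window* values (region-level, matching how
region-level calls are reported; at least 100 background values are
required). Classification: a window is called biased toward the focal
ancestry when the two-sided empirical P is below `p_bias` (default 0.05)
with the excess in the corresponding tail; it is admixture-representative
when |α̂ − α_global| ≤ 0.05 *and* its PBS is at or below the genome-wide
median — an operationalization of "local ancestry consistent with global
ancestry, without excess branch differentiation". Both thresholds are
parameters, because the underlying notion is verbal rather than formulaic.

## Ancestral reconstruction

aEAS/aEUR frequencies are computed per site over only the haplotypes
whose local ancestry at that site is the target; sites with fewer than
`min_carriers` (default 10) carriers are masked to keep high-variance
estimates out of the outlier tail (lowering the threshold can only
unmask). Windowed differentiation against a contemporary reference is
reported both as mean |ΔAF| and as Hudson F_ST with per-site carrier
counts; outlier calls default to the F_ST version for sample-size
robustness. The scan is symmetric evidence: whether an outlier reflects
relaxation in the admixed population or selection on the reference side
is an interpretation, not an output.

## Genetic load

For genotype dosage g over scored variants with weights w (1 when
unweighted), dominant = Σ w·1[g≥1], additive = Σ w·g, recessive =
Σ w·1[g=2]; restricted by VEP-style impact class (default high +
moderate). The deleterious allele is the alternate allele of scored
variants; when ancestral alleles are known a derived-allele polarity can
be substituted upstream. Weights are consumed as given (one column; any
CADD/GERP combination is the annotator's business). Pathway comparisons
recompute loads over each set's sites and use the two-sample Wilcoxon
rank-sum test (exact below 20 per group, asymptotic with tie correction
otherwise), BH-corrected across sets per reference. Load-vs-ancestry
association is a simple OLS slope with its two-sided P.

## mGSEA and Fisher enrichment

Per-gene scores aggregate a per-site statistic (max by default; mean and
95th percentile available) over the gene's mapped sites (gene body ±
configurable flank; flank 0 by default). Genes are ranked by decreasing
score, ties broken by genome order for determinism. The running sum
increments at set members by |score|^p (p = 1 default) normalized over
members, and decrements at non-members by 1/(N−|S|); the ES is the
signed maximum deviation and the leading edge is the set members at or
before the peak (after it, for negative ES). Significance randomizes set
membership with size preserved — the natural null for a per-gene
statistic with no per-sample phenotype. Because that null depends only on
the fixed ranked scores and the set size, sets of equal size share one
permutation null; this is statistically identical to per-set permutation
and makes thousand-set calibrations cheap. P values are add-one,
one-sided on the observed ES sign; BH across sets. No NES normalization
across set sizes is attempted. Fisher enrichment uses the two-sided exact
test on the (hit × in-set) table with a Haldane +0.5 odds-ratio
correction when a cell is zero.

## Haplotype statistics

EHH at distance x from a core is Σ_h C(n_h,2)/C(n_c,2) over groups of
carrier haplotypes identical from the core to x, computed at site
resolution (no gap scaling) by successive group refinement — exactly the
all-pairs identity probability, and non-increasing outward by
construction. iHH integrates EHH over cM by trapezoid, both directions,
truncating once EHH falls below 0.05 (the crossing trapezoid is
included); cores whose curve hits the end of the data above the
truncation level are flagged edge-truncated. iHS is
ln(iHH_anc/iHH_der) standardized to mean 0, sd 1 within 2%
derived-allele-frequency bins; adjacent bins holding fewer than
`min_bin_count` (default 20) scored sites are merged left-to-right so bin
moments are not noise-dominated. XP-EHH computes each population's EHH
over all haplotypes from the shared core (no allele conditioning — the
standard definition; an allele-conditioned variant is available through
`ehh` directly) and standardizes ln(iHH₁/iHH₂) genome-wide. H12/H1/H2-H1
follow the usual class-frequency definitions; G12 applies the same
formula to diploid multilocus genotype columns. H12 windows default to
200 SNPs stepped by 25.

## Diversity-vs-ancestry curves

Within each window, haplotypes whose ancestry calls are at least
`purity` (default 1.0 — single-origin only) one ancestry form that
ancestry's pool; windows with both pools at least `n_hap_sample` deep
(default 40) are used. For each target fraction f on a 5% grid,
round(f·n) haplotypes come from the first pool and the rest from the
second; θ_π and the rare fraction of the sample are recorded, medians
taken over replicates (default 20) then over windows. A degree-2
polynomial (configurable) is fitted by least squares and its argmax
located on [0, 1] (stationary points plus endpoints, so monotone curves
give boundary optima). The interior θ_π maximum is the mixture effect:
heterozygosity of a pooled sample exceeds the within-pool average by the
between-pool variance term.

## The synthetic cohort generator

What it emulates: two (optionally K) source populations with
Balding–Nichols AF divergence around a shared ancestral frequency
(uniform/beta mixture: 70% Uniform(0.05, 0.95), 30% Beta(0.2, 2) for a
rare tail); a single-pulse (hybrid-isolation) admixture g generations ago
producing a reversible Markov ancestry process along the genetic map with
switch rates g(1−α_k) out of state k and stationary law α, hence
exponential tract lengths; optional ancestry spikes (the focal state
drawn with probability α′ and the chain run outward both ways, valid by
reversibility); a rare-variant excess in one ancestry; deleterious-impact
annotations with gamma-distributed weights; tiled genes and gene sets,
with a "spiked" set placed over the selection spike, and an optional
deleterious-excess knob that adds rare alternate alleles in the spiked
set's genes of the admixed cohort only.

Genotypes come in two modes. *Frequency* mode draws alleles
Bernoulli(AF of the local ancestry) independently across sites — no
within-ancestry LD, which is exactly right for frequency-level statistics
and calibrations. *Panel* mode copies one haplotype of a finite simulated
ancestral panel per tract, giving within-tract haplotype structure for
the EHH family; sweeps are planted by forcing a fraction of one panel's
haplotypes to share a single haplotype over a region, with a core allele
tagging the swept background. Defaults: α = 0.5 and g = 40 (a roughly
half-and-half mixture a few tens of generations old), F_div = 0.11
(matching an EAS/EUR-scale global F_ST).

What it does not emulate — and hence what passing tests do not show
about real data: multi-wave or continuous admixture, coalescent LD and
realistic recombination-rate variation, background selection,
genotype/phasing/local-ancestry-inference error (truth tracks are exact),
and rare-variant spectra produced by genuine demographic growth. The
generator exists to provide controllable truth for recovery, calibration
and power tests, not to be a population-genetic forward simulator.

## Problem sizes and numerical conventions

The acceptance experiments run at: 50,000 sites / 100 diploids per
population for the AFd_e calibration (with 50 and 200 for the
monotonicity check); 1,000 admixed diploids on 50 Mb with a spike at
25 Mb, 20 replicate cohorts, for scan power (5 no-spike cohorts for null
calibration); 200 diploids / 20,000 sites for reconstruction; 2,000
genes, 2,000 null sets (shared-null permutations) and 25 spiked-set
replicates for mGSEA; 100 diploids per population for load; 75 diploids,
2,000 sites, 150-haplotype panels and 5 replicate cohorts for the iHS
sweep scan (the focal site's genome-wide |iHS| rank is summarized as the
median across replicates, since individual sweep realizations compete
with their own hitchhikers); and 120 diploids / 120 usable windows for
the resampling curve. These sizes were chosen to give each check clear
statistical resolution while keeping a full run to a couple of minutes.

Other conventions: empirical and permutation P values never return zero
(add-one); GSEA ranking ties break by genome order; monomorphic sites are
excluded from SFS mass and rare-fraction denominators; windows without
sites propagate NaN; all stochastic APIs accept either a seed or a
`numpy.random.Generator`, and file emission is byte-deterministic given a
scenario.

## Known limitations

No accessibility masks or callable-span window lengths; no LD- or
IBD-based N_e; no multi-chromosome genetic-map-aware CLI conveniences
beyond per-contig processing; XP-EHH and iHS assume a single contig per
call (run per chromosome); the AR/AB thresholds are conventions to be
tuned on real data rather than universal constants.
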