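"""Synthetic-cohort generator: parameter recovery and truth consistency."""

import json
import filecmp

import numpy as np
import pytest
from scipy import stats

import admixscan as asc
from admixscan import SimScenario, simulate_bundle, simulate_cohort
from admixscan.simulate import (
    simulate_ancestral_frequencies,
    simulate_ancestry_tracts,
    simulate_genotypes,
)
from admixscan.freq import fst_global, fst_site_hudson


class TestAncestralFrequencies:
    def test_low_divergence_limit(self, rng):
        """As F_div -> 0 both populations' AFs collapse to the shared p."""
        afs = simulate_ancestral_frequencies(5000, 1e-6, rng)
        assert np.abs(afs[0] - afs[1]).max() < 0.01

    def test_fst_recovery(self, rng):
        """Hudson global F_ST between panels drawn from the simulated AFs
        recovers F_div = 0.1 within +-0.02 (200 haplotypes per panel)."""
        afs = simulate_ancestral_frequencies(50_000, 0.1, rng)
        n = 200
        p1 = rng.binomial(n, afs[0]) / n
        p2 = rng.binomial(n, afs[1]) / n
        num, den = fst_site_hudson(p1, n, p2, n)
        assert fst_global(num, den) == pytest.approx(0.1, abs=0.02)

    def test_rare_skew_one_sided(self, rng):
        """rare_skew inflates the AF<0.05 fraction in the skewed ancestry
        only; the other ancestry's rare fraction is unchanged."""
        base = simulate_ancestral_frequencies(20_000, 0.1, np.random.default_rng(5))
        skew = simulate_ancestral_frequencies(20_000, 0.1, np.random.default_rng(5),
                                              rare_skew=0.3, skew_pop=0)
        rare = lambda a: np.mean(a < 0.05)
        assert rare(skew[0]) > rare(base[0]) + 0.15
        assert rare(skew[1]) == pytest.approx(rare(base[1]), abs=0.02)

    def test_invalid_f(self, rng):
        with pytest.raises(ValueError):
            simulate_ancestral_frequencies(10, 0.0, rng)


class TestAncestryTracts:
    def _track(self, seed, n_hap=2000, alpha=0.5, g=40.0, spikes=(),
               contig=50_000_000, m=500):
        pos = np.linspace(1, contig, m).round().astype(np.int64)
        sites = asc.SiteTable.from_arrays(["1"] * m, pos, ["A"] * m, ["G"] * m)
        gmap = asc.GeneticMap.uniform({"1": contig})
        return sites, simulate_ancestry_tracts(
            sites, gmap, n_hap, np.array([alpha, 1 - alpha]), g, spikes,
            np.random.default_rng(seed), contig_length=contig)

    def test_stationary_alpha(self):
        """Genome-wide ancestry-A fraction matches alpha = 0.5 within 0.02."""
        _, track = self._track(0)
        assert track.global_fraction()[0] == pytest.approx(0.5, abs=0.02)

    def test_tract_lengths_exponential(self):
        """A-tract genetic lengths follow Exp(g(1-alpha)): KS p > 0.01.

        Interior tracts only (edge tracts are length-censored)."""
        _, track = self._track(3, n_hap=1000, contig=100_000_000, m=200)
        seg = track.segments
        a = seg[seg["ancestry"] == "EAS"]
        interior = a[(a["start"] > 0) & (a["end"] < 100_000_000)]
        lengths_m = (interior["end"] - interior["start"]).to_numpy() / 1e8  # bp -> Morgan at 1 cM/Mb
        lengths_m = lengths_m[:10_000]
        rate = 40.0 * 0.5
        p = stats.kstest(lengths_m, "expon", args=(0, 1.0 / rate)).pvalue
        assert p > 0.01

    def test_mean_tract_length(self):
        """alpha=0.5, g=40: mean interior A-tract length ~ 1/(g(1-alpha)) = 5 cM."""
        _, track = self._track(4, n_hap=1000, contig=100_000_000, m=100)
        seg = track.segments
        a = seg[(seg["ancestry"] == "EAS") & (seg["start"] > 0) & (seg["end"] < 100_000_000)]
        mean_cm = (a["end"] - a["start"]).mean() / 1e6
        assert mean_cm == pytest.approx(5.0, rel=0.1)

    def test_spike_raises_local_proportion(self):
        """A spike (alpha'=0.8) fixes the focal ancestry-A proportion at 0.8
        +-0.03 and decays toward alpha = 0.5 away from the focus."""
        sites, track = self._track(1, spikes=((25_000_000, 0.8),))
        pos = sites.pos
        prop = track.indicator(0).mean(axis=1)
        focal = np.argmin(np.abs(pos - 25_000_000))
        assert prop[focal] == pytest.approx(0.8, abs=0.03)
        far = (pos < 5_000_000) | (pos > 45_000_000)
        assert prop[far].mean() == pytest.approx(0.5, abs=0.05)

    def test_spike_outside_contig_raises(self):
        with pytest.raises(ValueError):
            SimScenario(contig_length=1_000_000, spikes=((2_000_000, 0.8),))

    def test_segments_cover_contig(self):
        """Per haplotype, segments tile [0, L) without gaps or overlaps."""
        _, track = self._track(9, n_hap=20, contig=10_000_000, m=50)
        for (_, _), seg in track.segments.groupby(["sample", "hap"]):
            seg = seg.sort_values("start")
            assert seg["start"].iloc[0] == 0
            assert seg["end"].iloc[-1] == 10_000_000
            assert (seg["start"].iloc[1:].to_numpy() == seg["end"].iloc[:-1].to_numpy()).all()


class TestGenotypes:
    def test_diagnostic_site_limit(self, rng):
        """With fully divergent AFs (1 vs 0) the allele equals the ancestry
        indicator at every (site, haplotype)."""
        scenario = SimScenario(n_admixed=20, n_ref=5, m_sites=500,
                               contig_length=5_000_000, seed=2)
        b = simulate_bundle(scenario)
        afs = np.zeros_like(b.ancestral_af)
        afs[0, :] = 1.0
        mat = simulate_genotypes(b.track, afs, rng)
        assert np.array_equal(mat.alleles == 1, b.track.indicator(0))

    def test_admixed_af_is_mixture(self):
        """Frequency mode, alpha=0.5: the admixed AF matches
        0.5 AF_A + 0.5 AF_B up to binomial noise (global regression slope ~ 1)."""
        b = simulate_bundle(SimScenario(n_admixed=100, n_ref=10, m_sites=20_000,
                                        contig_length=20_000_000, seed=6))
        expect = 0.5 * b.ancestral_af[0] + 0.5 * b.ancestral_af[1]
        obs = b.admixed.alt_freq()
        assert np.mean(obs - expect) == pytest.approx(0.0, abs=0.005)
        slope = np.polyfit(expect, obs, 1)[0]
        assert slope == pytest.approx(1.0, abs=0.02)

    def test_panel_mode_ld_structure(self):
        """Panel mode: nearby sites inside tracts carry LD, distant sites do
        not (mean r^2 within 0.1 cM exceeds mean r^2 at > 10 cM)."""
        b = simulate_bundle(SimScenario(n_admixed=50, n_ref=10, m_sites=2000,
                                        contig_length=20_000_000, seed=8,
                                        mode="panel", panel_size=8, g=40))
        al = b.admixed.alleles.astype(float)
        p = al.mean(axis=1)
        poly = np.flatnonzero((p > 0.1) & (p < 0.9))
        al = al[poly]
        def mean_r2(pairs):
            vals = []
            for i, j in pairs:
                r = np.corrcoef(al[i], al[j])[0, 1]
                if not np.isnan(r):
                    vals.append(r * r)
            return np.mean(vals)
        near = [(i, i + 1) for i in range(0, len(poly) - 1, 7)]
        far = [(i, i + 800) for i in range(0, len(poly) - 800, 7)]
        assert mean_r2(near) > 3 * mean_r2(far)


class TestCohortBundle:
    def test_deterministic_outputs(self, tmp_path):
        """Same seed twice: byte-identical files."""
        scenario = SimScenario(n_admixed=5, n_ref=5, m_sites=200,
                               contig_length=2_000_000, seed=42)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_cohort(scenario, d1)
        simulate_cohort(scenario, d2)
        for name in ("cohort.vcf", "ancestry_truth.bed", "genetic_map.tsv",
                     "genes.bed", "gene_sets.gmt", "scores.tsv", "truth.json"):
            assert filecmp.cmp(d1 / name, d2 / name, shallow=False), name

    def test_truth_records_spikes_and_sets(self, tmp_path):
        scenario = SimScenario(n_admixed=5, n_ref=5, m_sites=300,
                               contig_length=3_000_000, seed=1,
                               spikes=((1_500_000, 0.9),))
        b = simulate_cohort(scenario, tmp_path / "c")
        truth = json.loads((tmp_path / "c" / "truth.json").read_text())
        assert truth["spikes"] == [[1_500_000, 0.9]]
        assert truth["spiked_gene_set"] == "spiked_set"
        # the spiked set's genes sit nearest the focal position
        genes = b.gene_sets["spiked_set"]
        gdf = b.genes.df.set_index("symbol")
        centers = [(gdf.loc[g, "start"] + gdf.loc[g, "end"]) / 2 for g in genes]
        assert max(abs(c - 1_500_000) for c in centers) < 1_000_000

    def test_no_spikes_truth_empty(self, tmp_path):
        scenario = SimScenario(n_admixed=4, n_ref=4, m_sites=100,
                               contig_length=1_000_000, seed=3)
        simulate_cohort(scenario, tmp_path / "n")
        truth = json.loads((tmp_path / "n" / "truth.json").read_text())
        assert truth["spikes"] == []
        assert truth["spiked_gene_set"] is None
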