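"""Data model, format round trips, windows and site-to-gene mapping."""

import numpy as np
import pandas as pd
import pytest

import admixscan as asc
from admixscan import (
    GeneModel,
    GeneticMap,
    HaplotypeMatrix,
    LocalAncestryTrack,
    SiteTable,
    make_windows,
    map_sites_to_genes,
    read_local_ancestry,
    read_phased_vcf,
    write_local_ancestry,
    write_phased_vcf,
)

VCF_TEXT = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB
1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0|1\t1|1
1\t200\trs1\tC\tT\t.\tPASS\t.\tGT\t0|0\t0|1
1\t300\t.\tG\tA\t.\tPASS\t.\tGT\t0/1\t0|0
1\t400\t.\tT\tC\t.\tPASS\t.\tGT\t.|.\t0|0
1\t500\t.\tA\tAT\t.\tPASS\t.\tGT\t0|1\t0|0
1\t600\t.\tG\tC,T\t.\tPASS\t.\tGT\t0|1\t0|0
1\t700\t.\tG\tC\t.\tPASS\t.\tGT\t1|0\t0|0
"""


class TestReadPhasedVcf:
    def test_filters_and_transcription(self, tmp_path):
        """Unphased, missing, indel and multiallelic records are dropped;
        surviving phased SNVs transcribe to a 0/1 matrix."""
        path = tmp_path / "toy.vcf"
        path.write_text(VCF_TEXT)
        sites, matrix = read_phased_vcf(path)
        assert list(sites.pos) == [100, 200, 700]
        assert matrix.alleles.shape == (3, 4)
        assert matrix.alleles[0].tolist() == [0, 1, 1, 1]
        assert matrix.alleles[2].tolist() == [1, 0, 0, 0]
        assert sites.df["id"].tolist() == [".", "rs1", "."]

    def test_round_trip_identity(self, tmp_path, rng):
        """write -> read preserves sites and alleles on random fixtures."""
        n_ind, m = 5, 40
        alleles = (rng.random((m, 2 * n_ind)) < 0.3).astype(np.int8)
        pos = np.sort(rng.choice(np.arange(1, 10_000), size=m, replace=False))
        sites = SiteTable.from_arrays(["1"] * m, pos, ["A"] * m, ["C"] * m,
                                      anc=["A"] * m)
        matrix = HaplotypeMatrix(alleles, [f"S{i}" for i in range(n_ind)])
        path = tmp_path / "rt.vcf"
        write_phased_vcf(path, sites, matrix)
        sites2, matrix2 = read_phased_vcf(path)
        pd.testing.assert_frame_equal(sites.df, sites2.df)
        assert np.array_equal(matrix.alleles, matrix2.alleles)
        assert matrix.samples == matrix2.samples

    def test_empty_after_filtering_raises(self, tmp_path):
        path = tmp_path / "bad.vcf"
        path.write_text(VCF_TEXT.replace("0|1", "0/1").replace("1|1", "1/1")
                        .replace("0|0", "0/0").replace("1|0", "1/0"))
        with pytest.raises(ValueError):
            read_phased_vcf(path)


class TestSiteTable:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            SiteTable.from_arrays(["1", "1"], [5, 5], ["A", "A"], ["G", "G"])
        with pytest.raises(ValueError):
            SiteTable.from_arrays(["1", "1"], [10, 5], ["A", "A"], ["G", "G"])
        with pytest.raises(ValueError):
            SiteTable.from_arrays(["1"], [5], ["A"], ["G"], anc=["T"])

    def test_derived_indicator(self):
        st = SiteTable.from_arrays(["1"] * 3, [10, 20, 30], ["A"] * 3, ["G"] * 3,
                                   anc=["A", "G", "."])
        assert st.derived_indicator().tolist() == [1, 0, -1]


class TestLocalAncestry:
    def _sites(self):
        return SiteTable.from_arrays(["1"] * 3, [500_000, 1_000_000, 1_500_000],
                                     ["A"] * 3, ["G"] * 3)

    def test_interval_lookup_half_open(self, tmp_path):
        """Site at 1-based pos 1,000,000 (0-based 999,999) is in [0, 1e6),
        while pos 1,500,000 falls in the [1e6, 2e6) EUR segment."""
        seg = pd.DataFrame({
            "chrom": ["1", "1"], "start": [0, 1_000_000],
            "end": [1_000_000, 2_000_000],
            "sample": ["S0", "S0"], "hap": [0, 0],
            "ancestry": ["EAS", "EUR"],
        })
        seg = pd.concat([seg, seg.assign(hap=1)], ignore_index=True)
        path = tmp_path / "la.bed"
        write_local_ancestry(path, seg)
        track = read_local_ancestry(path, self._sites(), ["S0"], labels=["EAS", "EUR"])
        assert [track.labels[c] for c in track.codes[:, 0]] == ["EAS", "EAS", "EUR"]

    def test_uncovered_site_raises(self):
        seg = pd.DataFrame({
            "chrom": ["1"], "start": [0], "end": [1_200_000],
            "sample": ["S0"], "hap": [0], "ancestry": ["EAS"],
        })
        seg = pd.concat([seg, seg.assign(hap=1)], ignore_index=True)
        with pytest.raises(ValueError, match="uncovered"):
            LocalAncestryTrack.from_segments(seg, self._sites(), ["S0"], ["EAS", "EUR"])

    def test_overlap_raises(self):
        seg = pd.DataFrame({
            "chrom": ["1", "1"], "start": [0, 900_000],
            "end": [1_000_000, 2_000_000],
            "sample": ["S0", "S0"], "hap": [0, 0],
            "ancestry": ["EAS", "EUR"],
        })
        with pytest.raises(ValueError, match="overlap"):
            LocalAncestryTrack.from_segments(seg, self._sites(), ["S0"], ["EAS", "EUR"])

    def test_dense_codes_one_ancestry_per_call(self, small_bundle):
        """Each (site, haplotype) call carries exactly one ancestry: the
        per-ancestry indicators sum to one everywhere."""
        track = small_bundle.track
        total = sum(track.indicator(k).astype(int) for k in range(len(track.labels)))
        assert (total == 1).all()


class TestGeneticMap:
    def test_interpolation_and_extrapolation(self):
        gmap = GeneticMap({"1": ([1, 1_000_000], [0.0, 1.0])})
        assert gmap.cm("1", 500_000)[0] == pytest.approx(0.5, abs=1e-6)
        assert gmap.cm("1", 1_000_000)[0] == pytest.approx(1.0)
        # beyond the last anchor: extrapolate at the last interval's rate
        assert gmap.cm("1", 1_500_000)[0] == pytest.approx(1.5, abs=1e-6)
        with pytest.raises(KeyError):
            gmap.cm("2", 100)

    def test_inverse(self):
        gmap = GeneticMap({"1": ([1, 1_000_000], [0.0, 1.0])})
        assert gmap.bp("1", 0.5)[0] == pytest.approx(500_000, rel=1e-6)


class TestMakeWindows:
    def test_enumeration(self):
        w = make_windows({"1": 100_000})
        assert list(map(tuple, w[["start", "end"]].to_numpy())) == [
            (0, 50_000), (25_000, 75_000), (50_000, 100_000)]

    def test_no_full_window(self):
        assert len(make_windows({"1": 49_999})) == 0

    def test_count_10mb(self):
        assert len(make_windows({"1": 10_000_000})) == 399

    def test_coverage_bound(self):
        """Every bp of the truncated span is in at most ceil(size/step) windows."""
        w = make_windows({"1": 333_333}, size=50_000, step=20_000)
        cover = np.zeros(333_333, dtype=int)
        for s, e in w[["start", "end"]].to_numpy():
            cover[s:e] += 1
        assert cover.max() <= int(np.ceil(50_000 / 20_000))

    def test_bad_args(self):
        with pytest.raises(ValueError):
            make_windows({"1": 100_000}, size=0)
        with pytest.raises(ValueError):
            make_windows({"1": 100_000}, size=100, step=200)


class TestSiteGeneMapping:
    def _genes(self):
        return GeneModel(pd.DataFrame({
            "chrom": ["1"], "start": [100], "end": [200], "symbol": ["GENE1"],
            "strand": ["+"],
        }))

    @pytest.mark.parametrize("pos,flank,mapped", [
        (150, 0, True),    # inside
        (100, 0, False),   # 1-based 100 = index 99, before [100, 200)
        (101, 0, True),    # first covered base
        (200, 0, True),    # index 199, last covered base
        (201, 0, False),
        (90, 50, True),    # flank extends the interval
    ])
    def test_boundaries(self, pos, flank, mapped):
        st = SiteTable.from_arrays(["1"], [pos], ["A"], ["G"])
        out = map_sites_to_genes(st, self._genes(), flank_bp=flank)
        assert ("GENE1" in out) is mapped

    def test_negative_flank_raises(self, toy_sites):
        with pytest.raises(ValueError):
            map_sites_to_genes(toy_sites, self._genes(), flank_bp=-1)


class TestAncestryBedRoundTrip:
    def test_round_trip(self, tmp_path, small_bundle):
        path = tmp_path / "truth.bed"
        write_local_ancestry(path, small_bundle.track.segments)
        track = read_local_ancestry(path, small_bundle.sites,
                                    small_bundle.admixed.samples,
                                    labels=list(small_bundle.track.labels))
        assert np.array_equal(track.codes, small_bundle.track.codes)
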