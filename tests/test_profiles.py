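import math

import numpy as np
import pandas as pd
import pytest

from chromatlas.genomic import GenomeLayout, GenomicInterval, ValidationError
from chromatlas.profiles import (
    BinnedTrack,
    abundance,
    bin_normalize,
    binned_difference,
    mask_anomalous,
    percent_recovery,
    read_binned_bedgraph,
    runmean,
    select_top_decile,
    tss_metaprofile,
    tss_windows,
    write_binned_bedgraph,
)


class TestMaskAnomalous:
    def test_constant_coverage_empty_mask(self):
        reads = {"chr1": np.repeat(np.arange(100), 2)}  # every position x2
        assert mask_anomalous(reads).n_masked() == 0

    def test_spike_masked_by_direct_z(self):
        rng = np.random.default_rng(0)
        pos = rng.integers(0, 10_000, 20_000)
        spike = np.full(500, 123)  # one position far above mean + 10 sd
        m = mask_anomalous({"chr1": np.concatenate([pos, spike])})
        counts = np.bincount(np.concatenate([pos, spike]))
        mu, sd = None, None
        upos = np.flatnonzero(counts)
        mu = counts[upos].mean()
        sd = counts[upos].std()
        assert (counts[123] - mu) / sd > 7
        assert 123 in m.positions["chr1"]

    def test_infinite_threshold_empty(self):
        rng = np.random.default_rng(1)
        reads = {"chr1": rng.integers(0, 1000, 5000)}
        assert mask_anomalous(reads, math.inf).n_masked() == 0


class TestBinNormalize:
    def test_stated_normalization_arithmetic(self, layout):
        reads = {"chr1": np.array([0, 100, 200, 499])}
        t = bin_normalize(reads, layout, 500, library_size=2_000_000)
        assert t.values["chr1"][0] == pytest.approx(2.0)
        assert t.values["chr1"][1] == 0.0

    def test_matches_naive_binning_oracle(self, layout):
        rng = np.random.default_rng(2)
        reads = {c: rng.integers(0, layout.length_of(c), 5000)
                 for c in layout.chrom_names}
        t = bin_normalize(reads, layout, 500)
        lib = sum(len(v) for v in reads.values())
        for c in layout.chrom_names:
            naive = np.zeros(math.ceil(layout.length_of(c) / 500))
            for p in reads[c]:
                naive[p // 500] += 1
            assert np.allclose(t.values[c], naive * 1e6 / lib)

    def test_sum_invariant(self, layout):
        rng = np.random.default_rng(3)
        reads = {"chr1": rng.integers(0, 100_000, 10_000)}
        t = bin_normalize(reads, layout, 500)
        total = sum(v.sum() for v in t.values.values())
        assert total == pytest.approx(1e6)

    def test_masked_reads_dropped_but_library_kept(self, layout):
        reads = {"chr1": np.concatenate(
            [np.zeros(10, dtype=int), np.full(990, 750)])}
        from chromatlas.profiles import PositionMask
        mask = PositionMask({"chr1": np.array([750])})
        t = bin_normalize(reads, layout, 500, mask)
        assert t.library_size == 1000
        assert t.values["chr1"][1] == 0.0
        assert t.values["chr1"][0] == pytest.approx(10 * 1e6 / 1000)

    def test_bad_bin_width(self, layout):
        with pytest.raises(ValidationError):
            bin_normalize({"chr1": np.array([1])}, layout, 0)

    def test_bedgraph_roundtrip(self, layout, tmp_path):
        rng = np.random.default_rng(4)
        reads = {c: rng.integers(0, layout.length_of(c), 2000)
                 for c in layout.chrom_names}
        t = bin_normalize(reads, layout, 500)
        p = tmp_path / "t.bedgraph"
        write_binned_bedgraph(t, p)
        t2 = read_binned_bedgraph(p, layout, 500, t.library_size)
        for c in layout.chrom_names:
            assert np.allclose(t.values[c], t2.values[c], rtol=1e-5)


def _track(layout, chrom_vals, bin_width=500):
    vals = {c: np.zeros(math.ceil(layout.length_of(c) / bin_width))
            for c in layout.chrom_names}
    for c, v in chrom_vals.items():
        vals[c][: len(v)] = v
    return BinnedTrack(vals, bin_width, 1_000_000)


class TestAbundance:
    def test_subtraction_and_antisymmetry(self, layout):
        chip = _track(layout, {"chr1": [5.0]})
        inp = _track(layout, {"chr1": [2.0]})
        regions = {"r": GenomicInterval("chr1", 0, 500)}
        assert abundance(chip, inp, regions)["r"] == pytest.approx(3.0)
        assert abundance(inp, chip, regions)["r"] == pytest.approx(-3.0)

    def test_window_bin_enumeration(self, layout):
        # TSS at 2250: window [250, 4250) overlaps bins 0..8 (9 bins)
        rng = np.random.default_rng(5)
        v = rng.random(40)
        chip = _track(layout, {"chr1": v})
        inp = _track(layout, {"chr1": np.zeros(40)})
        regions = {"r": GenomicInterval("chr1", 250, 4250)}
        got = abundance(chip, inp, regions)["r"]
        assert got == pytest.approx(v[0:9].mean())

    def test_mismatched_grids_rejected(self, layout):
        chip = _track(layout, {"chr1": [1.0]}, 500)
        inp = _track(layout, {"chr1": [1.0]}, 250)
        with pytest.raises(ValidationError):
            binned_difference(chip, inp)

    def test_gene_overlap_exclusion(self, layout):
        from chromatlas.atlas import TSSRecord

        tss = [TSSRecord("t1", "g1", "chr1", "+", 5000),
               TSSRecord("t2", "g2", "chr1", "+", 20_000)]
        spans = {"g1": GenomicInterval("chr1", 5000, 9000),
                 "g2": GenomicInterval("chr1", 6500, 25_000)}  # overlaps t1 win
        w = tss_windows(tss, layout, 2000, spans)
        assert "t1" not in w and "t2" in w


class TestTopDecile:
    def test_exact_count(self):
        rng = np.random.default_rng(6)
        ids = [f"r{i}" for i in range(100)]
        a = pd.Series(rng.random(100), index=ids)
        b = pd.Series(rng.random(100), index=ids)
        assert len(select_top_decile(a, b)) == 10

    def test_all_ties_deterministic(self):
        ids = [f"r{i}" for i in range(10)]
        a = pd.Series(1.0, index=ids)
        b = pd.Series(0.0, index=ids)
        got = select_top_decile(a, b, 0.25)
        assert got == sorted(ids)[:3]  # ceil(0.25 * 10) = 3, id order

    def test_planted_recovery_and_shift_invariance(self):
        rng = np.random.default_rng(7)
        ids = [f"r{i}" for i in range(200)]
        base = pd.Series(rng.normal(0, 0.3, 200), index=ids)
        b = pd.Series(rng.normal(0, 0.3, 200), index=ids)
        planted = set(rng.choice(ids, 20, replace=False))
        a = base.copy()
        a[list(planted)] += 2.0
        got = set(select_top_decile(a, b))
        assert got == planted
        shifted = set(select_top_decile(a + 5.0, b + 5.0))
        assert shifted == planted

    def test_empty_universe_rejected(self):
        with pytest.raises(ValidationError):
            select_top_decile(pd.Series(dtype=float), pd.Series(dtype=float))


class TestMetaprofile:
    def test_runmean_delta_plateau(self):
        x = np.zeros(101)
        x[50] = 1.0
        sm = runmean(x, 15)
        assert np.allclose(sm[43:58], 1 / 15)
        assert sm[30] == 0.0

    def test_runmean_conserves_window_mean(self):
        rng = np.random.default_rng(8)
        x = rng.random(200)
        sm = runmean(x, 15)
        i = 100
        assert sm[i] == pytest.approx(x[i - 7:i + 8].mean())

    def test_flat_region_gives_flat_profile(self, layout):
        vals = {c: np.full(math.ceil(layout.length_of(c) / 10), 3.0)
                for c in layout.chrom_names}
        chip = BinnedTrack(vals, 10, 1000)
        inp = BinnedTrack({c: np.zeros_like(v) for c, v in vals.items()},
                          10, 1000)
        prof = tss_metaprofile([chip], [inp], [("chr1", 50_000)], layout)
        assert len(prof.offsets) == 400
        assert np.allclose(prof.mean, 3.0)

    def test_group_shift_recovered(self, layout):
        rng = np.random.default_rng(9)
        n = math.ceil(100_000 / 10)
        mk = lambda level: BinnedTrack(
            {"chr1": level + rng.normal(0, 0.05, n),
             "chr2": np.zeros(math.ceil(50_000 / 10))}, 10, 1000)
        zero = BinnedTrack(
            {c: np.zeros(math.ceil(layout.length_of(c) / 10))
             for c in layout.chrom_names}, 10, 1000)
        tss = [("chr1", p) for p in range(10_000, 90_000, 10_000)]
        p_a = tss_metaprofile([mk(1.0)], [zero], tss, layout)
        p_b = tss_metaprofile([mk(3.0)], [zero], tss, layout)
        diff = p_b.mean - p_a.mean
        assert np.all(np.abs(diff - 2.0) < (p_a.ci_high - p_a.ci_low)
                      + (p_b.ci_high - p_b.ci_low) + 0.05)


class TestPercentRecovery:
    def test_worked_example(self):
        assert percent_recovery(20, 25, 1 / 8) == pytest.approx(25.0)

    def test_exponent_zero_gives_100(self):
        assert percent_recovery(18, 18 - math.log2(0.1), 0.1) == pytest.approx(100.0)
        assert percent_recovery(18, 18, 1.0) == pytest.approx(100.0)

    def test_bad_dilution(self):
        with pytest.raises(ValidationError):
            percent_recovery(20, 25, 0.0)
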