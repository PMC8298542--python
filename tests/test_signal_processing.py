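"""Normalization, GC-wave removal, deviation series and segmentation."""

import numpy as np
import pytest

import mcascreen as m
from mcascreen.signal_processing import _split_scan

from conftest import naive_split_scan


class TestQuantileNormalize:
    def test_identical_samples_unchanged(self):
        rng = np.random.default_rng(0)
        row = rng.normal(0, 1, 500)
        mat = np.vstack([row, row])
        out = m.quantile_normalize_lrr(mat)
        np.testing.assert_allclose(out, mat)

    def test_monotone_transform_rows_equal(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 400)
        b = np.exp(0.5 * a) - 1.0   # strictly monotone transform of a
        out = m.quantile_normalize_lrr(np.vstack([a, b]))
        np.testing.assert_allclose(out[0], out[1], atol=1e-12)

    def test_sorted_rows_identical(self):
        rng = np.random.default_rng(2)
        mat = rng.normal(0, 1, (5, 300))
        out = m.quantile_normalize_lrr(mat)
        ref = np.sort(out[0])
        for row in out:
            np.testing.assert_allclose(np.sort(row), ref)

    def test_single_sample_identity(self):
        mat = np.random.default_rng(3).normal(0, 1, (1, 100))
        np.testing.assert_array_equal(m.quantile_normalize_lrr(mat), mat)


class TestGcWaveCorrect:
    def test_independent_lrr_barely_changed(self):
        rng = np.random.default_rng(4)
        gc = rng.uniform(0.3, 0.6, 4000)
        lrr = rng.normal(0, 0.1, 4000)
        out = m.gc_wave_correct(lrr, gc)
        # fit standard error of the null smoother ~ sd/sqrt(window)
        assert np.abs(out - lrr).max() < 3 * 0.1 / np.sqrt(1001) * 10

    def test_planted_wave_removed(self):
        rng = np.random.default_rng(5)
        gc = rng.uniform(0.2, 0.7, 5000)
        lrr = 0.8 * gc + rng.normal(0, 0.05, 5000)
        out = m.gc_wave_correct(lrr, gc)
        assert abs(np.corrcoef(out, gc)[0, 1]) < 0.05

    def test_signal_preserved_on_wave(self, full_probe_map):
        """A planted loss offset survives correction of an additive GC wave
        (the event occupies a realistically small fraction of the genome)."""
        f = 0.5
        ev = m.EventSpec("1", 10**7, 4 * 10**7, "LOSS", f)
        sig = m.simulate_sample(full_probe_map, [ev], lrr_sd=0.05, baf_sd=0.01,
                                seed=6)
        gc = full_probe_map.table.gc_fraction.to_numpy()
        wavy = sig.lrr + 0.6 * (gc - gc.mean())
        out = m.gc_wave_correct(wavy, gc)
        t = full_probe_map.table
        mask = ((t.chromosome == "1") & (t.position >= ev.start_bp)
                & (t.position <= ev.end_bp)).to_numpy()
        assert np.median(out[mask]) == pytest.approx(np.log2((2 - f) / 2), abs=0.03)

    def test_linear_idempotent(self):
        rng = np.random.default_rng(7)
        gc = rng.uniform(0.2, 0.7, 2000)
        lrr = 0.5 * gc + rng.normal(0, 0.1, 2000)
        once = m.gc_wave_correct(lrr, gc, method="linear")
        twice = m.gc_wave_correct(once, gc, method="linear")
        assert np.abs(twice - once).max() < 1e-6

    def test_constant_gc_centers(self):
        lrr = np.array([1.0, 2.0, 3.0])
        out = m.gc_wave_correct(lrr, np.full(3, 0.4))
        np.testing.assert_allclose(out, lrr - 2.0)


class TestDeviationSeries:
    def test_definition_and_flags(self, small_probe_map):
        sig = m.simulate_sample(small_probe_map, [], lrr_sd=0, baf_sd=0, seed=8)
        series = m.build_deviation_series(sig)
        for ds in series.values():
            assert not ds.low_information
            np.testing.assert_array_equal(ds.delta, 0.0)
            assert (np.diff(ds.probe_indices) > 0).all()
        # a single AB probe at BAF 0.3 has delta 0.2
        sig.baf[ds.probe_indices[0]] = 0.3
        series = m.build_deviation_series(sig)
        assert series[ds.chromosome].delta[0] == pytest.approx(0.2)

    def test_mirror_invariance(self, small_probe_map):
        sig = m.simulate_sample(small_probe_map, [], seed=9)
        mirrored = m.SampleSignal(sig.sample_id, sig.lrr, 1 - sig.baf,
                                  sig.genotype, sig.probe_map)
        a = m.build_deviation_series(sig)
        b = m.build_deviation_series(mirrored)
        for chrom in a:
            np.testing.assert_allclose(a[chrom].delta, b[chrom].delta, atol=1e-12)

    def test_no_het_probes_low_information(self, small_probe_map):
        sig = m.simulate_sample(small_probe_map, [], seed=10)
        sig.genotype[sig.probe_map.chrom_index("2")] = "AA"
        series = m.build_deviation_series(sig)
        assert series["2"].low_information
        assert not series["1"].low_information


class TestSegmentSeries:
    def test_constant_series_no_breakpoints(self):
        assert m.segment_series(np.full(300, 0.02), seed=0) == []

    def test_single_step_located(self):
        rng = np.random.default_rng(11)
        v = np.concatenate([rng.normal(0, 0.03, 100), rng.normal(0.25, 0.03, 100)])
        v = np.abs(v)
        bps = m.segment_series(v, seed=1)
        assert len(bps) == 1 and abs(bps[0] - 100) <= 3
        k, _ = naive_split_scan(v, 10)
        assert bps[0] == k   # first accepted split is the exhaustive argmax

    def test_two_steps_located(self):
        rng = np.random.default_rng(12)
        v = np.abs(np.concatenate([rng.normal(0, 0.03, 100),
                                   rng.normal(0.2, 0.03, 100),
                                   rng.normal(0, 0.03, 100)]))
        bps = m.segment_series(v, seed=2)
        assert len(bps) == 2
        assert abs(bps[0] - 100) <= 3 and abs(bps[1] - 200) <= 3

    def test_short_series_no_breakpoints(self):
        assert m.segment_series(np.random.default_rng(0).normal(0, 1, 15),
                                min_points=10) == []

    def test_deterministic(self):
        rng = np.random.default_rng(13)
        v = np.abs(rng.normal(0.05, 0.05, 250))
        assert (m.segment_series(v, seed=5) == m.segment_series(v, seed=5))

    def test_scan_matches_naive_oracle(self):
        rng = np.random.default_rng(14)
        for _ in range(25):
            n = int(rng.integers(25, 200))
            v = rng.normal(0, 1, n)
            if rng.random() < 0.5:
                v[n // 2:] += rng.uniform(0.5, 2)
            k_fast, t_fast = _split_scan(v, 10)
            k_naive, t_naive = naive_split_scan(v, 10)
            assert k_fast == k_naive
            assert t_fast == pytest.approx(t_naive, rel=1e-10)


class TestSummarizeSegments:
    def test_no_breakpoints_whole_chromosome(self, small_probe_map):
        sig = m.simulate_sample(small_probe_map, [], seed=15)
        series = m.build_deviation_series(sig)
        segs = m.summarize_segments(sig, series, {})
        assert len(segs) == 2   # one per chromosome
        t = small_probe_map.table
        for seg in segs:
            sub = t[t.chromosome == seg.chromosome]
            assert seg.start_bp == sub.position.iloc[0]
            assert seg.end_bp == sub.position.iloc[-1]

    def test_noiseless_cnloh_summary(self, small_probe_map):
        ev = m.EventSpec("1", 10**7, 4 * 10**7, "CNLOH", 0.5)
        sig = m.simulate_sample(small_probe_map, [ev], lrr_sd=0, baf_sd=0, seed=16)
        series = m.build_deviation_series(sig)
        ds = series["1"]
        bps = m.segment_series(ds.delta, seed=3)
        segs = [s for s in m.summarize_segments(sig, series, {"1": bps})
                if s.chromosome == "1"]
        event_seg = max(segs, key=lambda s: s.delta)
        assert event_seg.delta == pytest.approx(0.25, abs=1e-12)
        assert event_seg.median_lrr == pytest.approx(0.0, abs=1e-12)

    def test_boundaries_are_probe_positions(self, small_probe_map):
        sig = m.simulate_sample(small_probe_map,
                                [m.EventSpec("1", 10**7, 4 * 10**7, "CNLOH", 0.6)],
                                seed=17)
        series = m.build_deviation_series(sig)
        bps = {c: m.segment_series(ds.delta, seed=4) for c, ds in series.items()}
        positions = set(small_probe_map.table.position)
        for seg in m.summarize_segments(sig, series, bps):
            assert seg.start_bp in positions and seg.end_bp in positions
            assert seg.n_het <= seg.n_snps
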