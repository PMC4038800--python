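import numpy as np
import pytest

from sfxreduce.corrections import FLAG_BAD, FLAG_PEAK_MASKED, Frame
from sfxreduce.geometry import DetectorLayout, PixelMap, radius_map
from sfxreduce.peakfind import (PeakFindParams, connected_cluster,
                                find_peaks_local_snr, find_peaks_pf8,
                                find_peaks_static, prescreen_region,
                                radial_stats)

SHAPE = (8, 16)


def flood_fill_oracle(data, seed, threshold, bounds):
    """Recursive 4-connected flood fill within bounds (r0, r1, c0, c1)."""
    r0, r1, c0, c1 = bounds
    seen, stack = set(), [seed]
    while stack:
        r, c = stack.pop()
        if (r, c) in seen or not (r0 <= r < r1 and c0 <= c < c1):
            continue
        if data[r, c] <= threshold:
            continue
        seen.add((r, c))
        stack.extend([(r + 1, c), (r - 1, c), (r, c + 1), (r, c - 1)])
    return seen


class TestConnectedCluster:
    def test_isolated_pixel(self, toy_layout):
        data = np.zeros(SHAPE)
        data[3, 3] = 10.0
        assert connected_cluster(data, (3, 3), 5.0, toy_layout) == {(3, 3)}

    def test_l_shaped_blob_matches_flood_fill(self, toy_layout):
        data = np.zeros(SHAPE)
        blob = [(2, 2), (3, 2), (4, 2), (4, 3), (4, 4)]
        for r, c in blob:
            data[r, c] = 20.0
        got = connected_cluster(data, (2, 2), 5.0, toy_layout)
        assert got == flood_fill_oracle(data, (2, 2), 5.0, (0, 8, 0, 8))
        assert got == set(blob)

    def test_blob_never_crosses_module_boundary(self, toy_layout, examples):
        got = connected_cluster(examples.boundary_blob, (3, 7), 5.0, toy_layout)
        assert got == {(3, 6), (3, 7), (4, 7)}  # seed-side (module 0) half only
        got2 = connected_cluster(examples.boundary_blob, (3, 8), 5.0, toy_layout)
        assert got2 == {(3, 8), (3, 9), (2, 8)}


class TestFindPeaksStatic:
    def test_blank_frame_yields_nothing(self, toy_layout):
        params = PeakFindParams(adc_threshold=10.0)
        assert find_peaks_static(Frame(np.zeros(SHAPE)), params, toy_layout) == []

    def test_weighted_centroid_and_intensity(self, toy_layout):
        data = np.zeros(SHAPE)
        data[2, 4], data[2, 5], data[2, 6] = 10.0, 20.0, 10.0
        params = PeakFindParams(adc_threshold=5.0, n_min=2, n_max=10)
        peaks = find_peaks_static(Frame(data), params, toy_layout)
        assert len(peaks) == 1
        p = peaks[0]
        assert p.intensity == 40.0
        assert p.centroid_col == pytest.approx(5.0)
        assert p.centroid_row == pytest.approx(2.0)
        assert p.npix == 3

    def test_strict_size_bounds(self, toy_layout):
        params = PeakFindParams(adc_threshold=5.0, n_min=2, n_max=5)
        # exactly n_max pixels: rejected as overly diffuse (strict <)
        data = np.zeros(SHAPE)
        data[3, 2:7] = 50.0
        assert find_peaks_static(Frame(data), params, toy_layout) == []
        # exactly n_min pixels: rejected as outlier-like (strict >)
        data = np.zeros(SHAPE)
        data[3, 2:4] = 50.0
        assert find_peaks_static(Frame(data), params, toy_layout) == []
        # n_min + 1: accepted
        data = np.zeros(SHAPE)
        data[3, 2:5] = 50.0
        assert len(find_peaks_static(Frame(data), params, toy_layout)) == 1

    def test_peak_mask_excludes_region(self, toy_layout):
        data = np.zeros(SHAPE)
        data[2, 4:7] = 50.0
        flags = np.zeros(SHAPE, np.uint8)
        flags[2, 4:7] = FLAG_PEAK_MASKED
        params = PeakFindParams(adc_threshold=5.0, n_min=2, n_max=10)
        assert find_peaks_static(Frame(data, flags=flags), params, toy_layout) == []


class TestRadialStats:
    def setup_method(self):
        self.lay = DetectorLayout((16, 16), (1, 1))
        self.pm = PixelMap.from_layout(self.lay, center=(7.5, 7.5))
        self.rpx = radius_map(self.pm)

    def test_radially_constant_image(self):
        prof = radial_stats(np.full((16, 16), 5.0), self.rpx)
        filled = prof.counts > 0
        np.testing.assert_allclose(prof.mean[filled], 5.0)
        np.testing.assert_allclose(prof.sigma[filled], 0.0)

    def test_outlier_excluded_iteratively(self):
        data = np.full((16, 16), 5.0)
        data[2, 2] = 1e6
        prof = radial_stats(data, self.rpx)
        b = prof.bin_index[2, 2]
        assert prof.mean[b] == pytest.approx(5.0)
        assert prof.counts[b] == np.count_nonzero(prof.bin_index == b) - 1

    def test_matches_grouped_statistics_oracle(self, rng):
        data = rng.uniform(0, 10, size=(16, 16))
        prof = radial_stats(data, self.rpx, clip_sigma=1e9)  # no exclusion
        for b in range(len(prof.bin_edges) - 1):
            sel = prof.bin_index == b
            if not sel.any():
                assert prof.counts[b] == 0
                continue
            assert prof.mean[b] == pytest.approx(data[sel].mean())
            assert prof.sigma[b] == pytest.approx(data[sel].std())


class TestFindPeaksPf8:
    def setup_method(self):
        self.lay = DetectorLayout((16, 16), (1, 1))
        self.pm = PixelMap.from_layout(self.lay, center=(7.5, 7.5))
        self.rpx = radius_map(self.pm)

    def test_blank_frame_produces_no_peaks(self):
        params = PeakFindParams(adc_threshold=30.0, snr_threshold=7.0)
        f = Frame(np.zeros((16, 16)))
        assert find_peaks_pf8(f, params, self.rpx, layout=self.lay) == []

    def test_floor_guards_almost_empty_frames(self, rng):
        # tiny noise, sigma ~ 0.01: without the 30-ADU floor the threshold
        # would sit at ~0.07 and fire everywhere
        f = Frame(rng.normal(0, 0.01, size=(16, 16)))
        params = PeakFindParams(adc_threshold=30.0, snr_threshold=7.0)
        assert find_peaks_pf8(f, params, self.rpx, layout=self.lay) == []

    def test_threshold_arithmetic(self):
        """mean 50, sigma 5, SNR 6: the pf8 threshold is 80 ADU."""
        from sfxreduce.peakfind import RadialProfile
        nb = 12
        prof = RadialProfile(mean=np.full(nb, 50.0), sigma=np.full(nb, 5.0),
                             counts=np.full(nb, 10), bin_edges=np.arange(nb + 1.0),
                             bin_index=np.clip(self.rpx.astype(int), 0, nb - 1))
        tmap = prof.threshold_map(snr=6.0, floor=30.0)
        np.testing.assert_allclose(tmap, 80.0)
        # strict >: 85 passes, 78 fails
        assert 85.0 > tmap[0, 0] and not (78.0 > tmap[0, 0])

    def test_degenerates_to_static_when_sigma_zero(self):
        """With sigma = 0 and mean = 0 the pf8 threshold is exactly the ADU
        floor, and pf8 equals the static finder."""
        data = np.zeros((16, 16))
        data[4, 4:7] = 100.0
        data[10, 10], data[10, 11], data[11, 10] = 60.0, 55.0, 50.0
        f = Frame(data)
        params = PeakFindParams(adc_threshold=30.0, snr_threshold=7.0,
                                n_min=2, n_max=10)
        from sfxreduce.peakfind import RadialProfile
        nb = 12
        prof = RadialProfile(mean=np.zeros(nb), sigma=np.zeros(nb),
                             counts=np.full(nb, 10), bin_edges=np.arange(nb + 1.0),
                             bin_index=np.clip(self.rpx.astype(int), 0, nb - 1))
        got8 = find_peaks_pf8(f, params, self.rpx, layout=self.lay, profile=prof)
        got_s = find_peaks_static(f, params, layout=self.lay, radius_px=self.rpx)
        assert [(p.centroid, p.npix, p.intensity) for p in got8] == \
               [(p.centroid, p.npix, p.intensity) for p in got_s]
        assert len(got8) == 2


class TestFindPeaksLocalSnr:
    def test_monotone_ramp_has_no_peaks(self, toy_layout):
        data = np.tile(np.arange(16.0) * 5, (8, 1))
        params = PeakFindParams(adc_threshold=30.0, snr_threshold=6.0)
        assert find_peaks_local_snr(Frame(data), params, toy_layout) == []

    def test_compact_spike_accepted_via_annulus_stats(self, toy_layout):
        data = np.full(SHAPE, 10.0)
        data[3, 3], data[3, 4], data[4, 3] = 110.0, 90.0, 80.0
        params = PeakFindParams(adc_threshold=40.0, snr_threshold=6.0,
                                n_min=2, n_max=10, local_bg_radius=1)
        peaks = find_peaks_local_snr(Frame(data), params, toy_layout)
        assert len(peaks) == 1
        assert peaks[0].npix == 3
        # SNR guarded by the sigma floor on a noiseless annulus
        assert np.isfinite(peaks[0].snr) and peaks[0].snr > 1e6

    def test_nearby_peaks_keep_highest_snr(self, toy_layout):
        # two compact spikes 3 px apart on flat background; annulus chosen to
        # clear both spikes' footprints so each is individually accepted
        data = np.full(SHAPE, 10.0)
        data[3, 4], data[4, 4] = 200.0, 150.0
        data[3, 7], data[4, 7] = 300.0, 250.0
        params = PeakFindParams(adc_threshold=30.0, snr_threshold=6.0,
                                n_min=1, n_max=10, min_peak_separation=5.0)
        peaks = find_peaks_local_snr(Frame(data), params, toy_layout,
                                     annulus_inner=3.5, annulus_width=2.0)
        assert len(peaks) == 1
        # the brighter (higher-SNR) spike at column ~7 is the one retained
        assert peaks[0].centroid_col == pytest.approx(7.0, abs=0.5)


class TestAlgorithmAgreement:
    def test_all_three_finders_agree_on_clean_spots(self):
        """Well-separated high-contrast compact spots on zero background are
        found identically by all three procedures."""
        lay = DetectorLayout((32, 32), (1, 1))
        pm = PixelMap.from_layout(lay, center=(15.5, 15.5))
        rpx = radius_map(pm)
        data = np.zeros((32, 32))
        for r, c in ((8, 8), (8, 24), (24, 8), (24, 24)):
            data[r, c] = 500.0
            data[r + 1, c] = data[r - 1, c] = data[r, c + 1] = data[r, c - 1] = 300.0
        f = Frame(data)
        params = PeakFindParams(adc_threshold=100.0, snr_threshold=6.0,
                                n_min=2, n_max=20, local_bg_radius=2)
        results = [
            find_peaks_static(f, params, lay, radius_px=rpx),
            find_peaks_pf8(f, params, rpx, layout=lay),
            find_peaks_local_snr(f, params, lay, radius_px=rpx),
        ]
        keys = [sorted((round(p.centroid_row, 3), round(p.centroid_col, 3), p.npix)
                       for p in res) for res in results]
        assert keys[0] == keys[1] == keys[2]
        assert len(keys[0]) == 4

    def test_peak_count_monotone_in_thresholds(self, crystal_stream):
        from sfxreduce.corrections import correct_frame
        spec, frames, truth, cal, pm = crystal_stream
        rpx = radius_map(pm)
        rec = next(r for r in truth if r.label == "hit")
        f = correct_frame(frames[rec.event_id], cal, layout=spec.layout)
        counts_adc = []
        for adc in (20.0, 30.0, 60.0, 120.0):
            params = PeakFindParams(adc_threshold=adc, snr_threshold=7.0)
            counts_adc.append(len(find_peaks_pf8(f, params, rpx, layout=spec.layout)))
        assert counts_adc == sorted(counts_adc, reverse=True)
        counts_snr = []
        for snr in (5.0, 7.0, 10.0, 15.0):
            params = PeakFindParams(adc_threshold=30.0, snr_threshold=snr)
            counts_snr.append(len(find_peaks_pf8(f, params, rpx, layout=spec.layout)))
        assert counts_snr == sorted(counts_snr, reverse=True)

    def test_no_peak_touches_masked_pixels_and_no_sharing(self, crystal_stream):
        from sfxreduce.corrections import correct_frame
        spec, frames, truth, cal, pm = crystal_stream
        rpx = radius_map(pm)
        rec = next(r for r in truth if r.label == "hit")
        f = correct_frame(frames[rec.event_id], cal, layout=spec.layout)
        params = PeakFindParams()
        peaks = find_peaks_pf8(f, params, rpx, layout=spec.layout)
        assert peaks
        bad = ~f.good_mask()
        seen = set()
        for p in peaks:
            r, c = int(round(p.centroid_row)), int(round(p.centroid_col))
            assert not bad[r, c]
            assert (r, c) not in seen
            seen.add((r, c))

    def test_module_processing_is_order_independent(self, crystal_stream):
        """Peaks found in a module do not depend on the other modules'
        content: zeroing the others leaves the module's peaks unchanged."""
        from sfxreduce.corrections import correct_frame
        from sfxreduce.peakfind import RadialProfile
        spec, frames, truth, cal, pm = crystal_stream
        rpx = radius_map(pm)
        rec = next(r for r in truth if r.label == "hit")
        f = correct_frame(frames[rec.event_id], cal, layout=spec.layout)
        params = PeakFindParams()
        prof = radial_stats(f, rpx, good=f.good_mask())
        full = find_peaks_pf8(f, params, rpx, layout=spec.layout, profile=prof)
        m = 1
        sl = spec.layout.module_slice(m)
        iso = f.copy()
        mask = np.ones(iso.data.shape, bool)
        mask[sl] = False
        iso.flags[mask] |= FLAG_BAD
        only_m = find_peaks_pf8(iso, params, rpx, layout=spec.layout, profile=prof)
        key = lambda ps: sorted((round(p.centroid_row, 6), round(p.centroid_col, 6))
                                for p in ps)
        assert key(only_m) == key([p for p in full if p.module_id == m])


class TestPrescreen:
    def test_blank_frame_skipped_after_region_pass(self, toy_layout):
        f = Frame(np.zeros(SHAPE))
        region = np.zeros(SHAPE, bool)
        region[:, :8] = True
        params = PeakFindParams(algorithm="static", adc_threshold=10.0,
                                n_min=1, n_max=10)
        decision, peaks = prescreen_region(f, region, params, min_region_peaks=1,
                                           layout=toy_layout)
        assert decision == "skip" and peaks == []

    def test_peaks_inside_region_continue(self, toy_layout):
        data = np.zeros(SHAPE)
        data[3, 3:5] = 100.0
        region = np.zeros(SHAPE, bool)
        region[:, :8] = True
        params = PeakFindParams(algorithm="static", adc_threshold=10.0,
                                n_min=1, n_max=10)
        decision, _ = prescreen_region(data_frame(data), region, params,
                                       min_region_peaks=1, layout=toy_layout)
        assert decision == "continue"

    def test_peaks_only_outside_region_skipped(self, toy_layout):
        """The documented false-negative mode: peaks outside the prescreen
        region never trigger the full search."""
        data = np.zeros(SHAPE)
        data[3, 12:14] = 100.0
        region = np.zeros(SHAPE, bool)
        region[:, :8] = True
        params = PeakFindParams(algorithm="static", adc_threshold=10.0,
                                n_min=1, n_max=10)
        decision, peaks = prescreen_region(data_frame(data), region, params,
                                           min_region_peaks=1, layout=toy_layout)
        assert decision == "skip" and peaks == []


def data_frame(data):
    return Frame(np.asarray(data, dtype=float))
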