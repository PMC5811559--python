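"""Movie conditioning chain and weight-mask construction."""

import numpy as np
import pytest
from scipy import ndimage
from scipy.signal import freqz

from panomap.errors import SignalError
from panomap.signal_conditioning import (
    OpticalMovie,
    build_weight_mask,
    condition_movie,
    design_lowpass,
    filter_temporal,
    mask_region,
    normalize_traces,
    remove_drift,
    spatial_bin,
)


def _movie(frames, fs=1000.0, mask=None):
    return OpticalMovie(frames=np.asarray(frames, dtype=float),
                        sampling_rate=fs, mask=mask)


class TestNormalize:
    def test_affine_map_to_unit_interval(self):
        mv = _movie(np.array([[[2.0, 4.0, 6.0]]]))
        out = normalize_traces(mv)
        assert np.allclose(out.frames[0, 0], [0, 0.5, 1])

    def test_idempotent_on_unit_traces(self):
        rng = np.random.default_rng(0)
        fr = rng.random((4, 4, 50))
        fr = (fr - fr.min(axis=2, keepdims=True)) / (
            fr.max(axis=2, keepdims=True) - fr.min(axis=2, keepdims=True)
        )
        out = normalize_traces(_movie(fr))
        assert np.allclose(out.frames, fr)

    def test_every_pixel_spans_unit_interval(self):
        rng = np.random.default_rng(1)
        out = normalize_traces(_movie(rng.normal(size=(6, 5, 40))))
        assert np.allclose(out.frames.min(axis=2), 0)
        assert np.allclose(out.frames.max(axis=2), 1)

    def test_constant_trace_moved_to_background(self):
        fr = np.random.default_rng(2).random((3, 3, 10))
        fr[1, 1] = 0.7
        with pytest.warns(UserWarning, match="constant"):
            out = normalize_traces(_movie(fr))
        assert out.mask[1, 1] == 0
        assert np.all(out.frames[1, 1] == 0)


class TestSpatialBin:
    def test_kernel_one_is_identity(self):
        fr = np.random.default_rng(0).random((5, 5, 8))
        out = spatial_bin(_movie(fr), 1)
        assert np.array_equal(out.frames, fr)

    def test_uniform_frame_unchanged(self):
        out = spatial_bin(_movie(np.full((7, 7, 3), 4.2)), 3)
        assert np.allclose(out.frames, 4.2)

    def test_hot_pixel_hand_convolution(self):
        fr = np.zeros((5, 5, 2))
        fr[2, 2, :] = 9.0
        out = spatial_bin(_movie(fr), 3)
        assert np.allclose(out.frames[1:4, 1:4, 0], 1.0)
        assert np.allclose(out.frames[0, :, 0], 0.0)

    def test_background_never_contaminates(self):
        mask = np.zeros((5, 5), dtype=np.uint8)
        mask[:, :2] = 1
        fr = np.where(mask[..., None].astype(bool), 1.0, 100.0)
        fr = np.repeat(fr[..., None] if fr.ndim == 2 else fr, 2, axis=2)
        out = spatial_bin(_movie(fr, mask=mask), 3)
        assert np.allclose(out.frames[mask.astype(bool)], 1.0)

    def test_even_kernel_rejected(self):
        with pytest.raises(SignalError):
            spatial_bin(_movie(np.zeros((3, 3, 2))), 4)


class TestTemporalFilter:
    def test_dc_gain_unity(self):
        out = filter_temporal(_movie(np.full((2, 2, 400), 3.0)))
        assert np.abs(out.frames - 3.0).max() < 1e-6

    def test_stopband_attenuation_at_150hz(self):
        taps = design_lowpass(100, 100.0, 1000.0)
        _, h = freqz(taps, worN=np.array([150.0]) / 500.0 * np.pi)
        assert -20 * np.log10(np.abs(h[0])) >= 20.0

    def test_passband_sinusoid_preserved_zero_phase(self):
        t = np.arange(1000) / 1000.0
        sig = np.sin(2 * np.pi * 10 * t)
        out = filter_temporal(_movie(sig[None, None, :]))
        mid = slice(100, 900)  # away from edge effects
        err = out.frames[0, 0, mid] - sig[mid]
        assert np.abs(err).max() < 0.02  # amplitude within 2%, no shift

    def test_nyquist_violation_raises(self):
        with pytest.raises(SignalError):
            filter_temporal(_movie(np.zeros((2, 2, 100)), fs=150.0))


class TestRemoveDrift:
    def test_pure_line_becomes_its_mean(self):
        t = np.arange(100, dtype=float)
        line = 0.3 * t + 2.0
        out = remove_drift(_movie(line[None, None, :]))
        assert np.allclose(out.frames[0, 0], line.mean())

    def test_driftfree_oscillation_unchanged(self):
        # a cosine with whole periods symmetric about the record center
        # is exactly orthogonal to the fitted line (odd x even sum)
        n = np.arange(1001)
        sig = np.cos(2 * np.pi * 8 * n / 1000.0)  # period 125, center 500
        out = remove_drift(_movie(sig[None, None, :]))
        assert np.abs(out.frames[0, 0] - sig).max() < 1e-9

    def test_recovers_oscillation_under_linear_drift(self):
        n = np.arange(1001)
        sig = np.cos(2 * np.pi * 8 * n / 1000.0)
        drift = 1.7 * n / 1000.0 - 0.4
        out = remove_drift(_movie((sig + drift)[None, None, :]))
        resid = out.frames[0, 0] - (sig + drift.mean())
        assert np.sqrt(np.mean(resid ** 2)) < 1e-6


class TestMaskRegion:
    def test_whole_frame_polygon_empties_mask(self):
        mv = _movie(np.ones((10, 10, 3)))
        out = mask_region(mv, [(-1, -1), (11, -1), (11, 11), (-1, 11)])
        assert out.mask.sum() == 0

    def test_degenerate_polygon_is_noop(self):
        mv = _movie(np.ones((10, 10, 3)))
        out = mask_region(mv, [(2, 2), (2, 2)])
        assert np.array_equal(out.mask, mv.mask)

    def test_halfplane_matches_raycast_oracle(self):
        mv = _movie(np.ones((20, 20, 2)))
        poly = np.array([(-0.5, -0.5), (9.2, -0.5), (9.2, 19.5),
                         (-0.5, 19.5)])
        out = mask_region(mv, poly)

        def inside(px, py):  # ray casting
            cnt = 0
            n = len(poly)
            for i in range(n):
                x1, y1 = poly[i]
                x2, y2 = poly[(i + 1) % n]
                if (y1 > py) != (y2 > py):
                    xs = x1 + (py - y1) / (y2 - y1) * (x2 - x1)
                    if xs > px:
                        cnt += 1
            return cnt % 2 == 1

        expect = sum(inside(u, v) for v in range(20) for u in range(20))
        assert int(mv.mask.sum() - out.mask.sum()) == expect

    def test_self_intersecting_polygon_rejected(self):
        mv = _movie(np.ones((10, 10, 2)))
        with pytest.raises(SignalError):
            mask_region(mv, [(0, 0), (5, 5), (5, 0), (0, 5)])

    def test_idempotent(self):
        mv = _movie(np.random.default_rng(0).random((12, 12, 3)))
        poly = [(2, 2), (8, 2), (8, 8), (2, 8)]
        once = mask_region(mv, poly)
        twice = mask_region(once, poly)
        assert np.array_equal(once.mask, twice.mask)
        assert np.array_equal(once.frames, twice.frames)


class TestWeightMask:
    def test_single_pixel_gets_weight_one(self):
        mask = np.zeros((5, 5), dtype=np.uint8)
        mask[2, 2] = 1
        wm = build_weight_mask(mask)
        assert wm.weights[2, 2] == 1.0

    def test_disk_edge_half_center_one(self):
        yy, xx = np.mgrid[0:101, 0:101]
        disk = ((xx - 50) ** 2 + (yy - 50) ** 2 <= 40 ** 2).astype(np.uint8)
        wm = build_weight_mask(disk)
        edge = disk.astype(bool) & ~ndimage.binary_erosion(disk)
        assert np.all(wm.weights[edge] == 0.5)
        assert wm.weights[50, 50] == 1.0

    def test_matches_distance_transform_formula(self):
        rng = np.random.default_rng(3)
        mask = ndimage.binary_dilation(rng.random((30, 30)) > 0.9,
                                       iterations=3)
        if not mask.any():
            pytest.skip("degenerate random mask")
        wm = build_weight_mask(mask)
        d = ndimage.distance_transform_edt(mask)
        dmin, dmax = d[mask].min(), d[mask].max()
        expect = np.zeros_like(d)
        if dmax > dmin:
            expect[mask] = 0.5 + 0.5 * (d[mask] - dmin) / (dmax - dmin)
        else:
            expect[mask] = 1.0
        assert np.allclose(wm.weights, expect)

    def test_monotone_in_depth(self):
        yy, xx = np.mgrid[0:41, 0:41]
        disk = ((xx - 20) ** 2 + (yy - 20) ** 2 <= 15 ** 2).astype(np.uint8)
        wm = build_weight_mask(disk)
        d = ndimage.distance_transform_edt(disk)
        order = np.argsort(d[disk.astype(bool)])
        w = wm.weights[disk.astype(bool)][order]
        assert np.all(np.diff(w) >= -1e-12)

    def test_empty_mask_raises(self):
        with pytest.raises(SignalError):
            build_weight_mask(np.zeros((4, 4), dtype=np.uint8))


class TestConditionChain:
    def test_preserves_shape_and_mask(self):
        rng = np.random.default_rng(0)
        mask = np.ones((8, 8), dtype=np.uint8)
        mask[0, 0] = 0
        mv = _movie(rng.random((8, 8, 300)), mask=mask)
        out = condition_movie(mv)
        assert out.frames.shape == mv.frames.shape
        assert np.array_equal(out.mask, mask)

    def test_deterministic(self):
        rng = np.random.default_rng(1)
        fr = rng.random((6, 6, 256))
        a = condition_movie(_movie(fr))
        b = condition_movie(_movie(fr))
        assert np.array_equal(a.frames, b.frames)
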