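import numpy as np
import pytest
from scipy import ndimage
from scipy.spatial.distance import cdist

import t1rho_moco as tm
from t1rho_moco.metrics import _contours


def _annulus(shape=(40, 40), center=(20, 20), r_in=6.0, r_out=12.0):
    yy, xx = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    r = np.hypot(yy - center[0], xx - center[1])
    return (r > r_in) & (r <= r_out)


def _brute_hausdorff(pts_a, pts_b, spacing=(1.0, 1.0)):
    """Brute-force symmetric Hausdorff on scaled coordinates."""
    sa = pts_a * np.asarray(spacing)[None, :]
    sb = pts_b * np.asarray(spacing)[None, :]
    d = cdist(sa, sb)
    return max(d.min(axis=1).max(), d.min(axis=0).max())


def _brute_mpd(masks, spacing):
    worst = 0.0
    cs = [_contours(m) for m in masks]
    for i in range(len(masks)):
        for j in range(i + 1, len(masks)):
            endo_i, epi_i = cs[i]
            endo_j, epi_j = cs[j]
            d = _brute_hausdorff(epi_i, epi_j, spacing)
            if len(endo_i) and len(endo_j):
                d = max(d, _brute_hausdorff(endo_i, endo_j, spacing))
            worst = max(worst, d)
    return worst


class TestDicePair:
    def test_identical_masks_one(self):
        m = _annulus()
        assert tm.dice_pair(m, m) == 1.0

    def test_disjoint_masks_zero(self):
        a = np.zeros((10, 10), bool)
        b = np.zeros((10, 10), bool)
        a[:2] = True
        b[5:] = True
        assert tm.dice_pair(a, b) == 0.0

    def test_half_overlap(self):
        a = np.zeros((20, 20), bool)
        b = np.zeros((20, 20), bool)
        a.flat[:100] = True
        b.flat[50:150] = True
        assert tm.dice_pair(a, b) == pytest.approx(0.50)

    def test_symmetric(self):
        rng = np.random.default_rng(0)
        a = rng.random((15, 15)) > 0.5
        b = rng.random((15, 15)) > 0.5
        assert tm.dice_pair(a, b) == tm.dice_pair(b, a)

    def test_both_empty_rejected(self):
        z = np.zeros((5, 5), bool)
        with pytest.raises(ValueError):
            tm.dice_pair(z, z)


class TestDiceSeries:
    def test_all_identical_is_100(self):
        m = _annulus()
        masks = tm.MaskSeries(np.stack([m] * 5))
        assert tm.dice_series(masks) == pytest.approx(100.0)

    def test_all_disjoint_is_0(self):
        stack = np.zeros((3, 12, 12), bool)
        stack[0, :3] = True
        stack[1, 4:7] = True
        stack[2, 8:] = True
        assert tm.dice_series(tm.MaskSeries(stack)) == 0.0

    def test_three_mask_average(self):
        # construct pairwise dice {0.8, 0.6, 0.7} -> mean 70%
        n = 100
        a = np.zeros((3, 20, 20), bool)
        # |A|=|B|=|C|=100; overlaps: AB 80, AC 60, BC 70
        flat = [m.ravel() for m in a]
        flat[0][:100] = True
        flat[1][20:120] = True          # AB overlap 80
        flat[2][40:100] = True           # AC overlap 60
        flat[2][120:160] = True          # |C| = 100
        # BC overlap: indices 40..100 and 120..160 vs 20..120 -> 60 + 0 = 60?
        a0, a1, a2 = a
        d01 = tm.dice_pair(a0, a1)
        d02 = tm.dice_pair(a0, a2)
        d12 = tm.dice_pair(a1, a2)
        expected = 100.0 * (d01 + d02 + d12) / 3.0
        assert tm.dice_series(tm.MaskSeries(a)) == pytest.approx(expected)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(3)
        base = _annulus()
        stack = np.stack([np.roll(base, k, axis=0) for k in range(4)])
        d1 = tm.dice_series(tm.MaskSeries(stack))
        d2 = tm.dice_series(tm.MaskSeries(stack[::-1].copy()))
        assert d1 == pytest.approx(d2)

    def test_range_and_equality_condition(self):
        base = _annulus()
        stack = np.stack([base, np.roll(base, 2, axis=1)])
        val = tm.dice_series(tm.MaskSeries(stack))
        assert 0.0 <= val < 100.0


class TestMpd:
    def test_identical_masks_zero(self):
        m = _annulus()
        assert tm.mpd(tm.MaskSeries(np.stack([m, m, m]))) == 0.0

    def test_translated_annulus_exact(self):
        m = _annulus(shape=(48, 48), center=(20, 24))
        shifted = np.roll(m, 5, axis=0)
        val = tm.mpd(tm.MaskSeries(np.stack([m, shifted]), spacing=(1.4, 1.4)))
        assert val == pytest.approx(7.0)

    def test_matches_bruteforce_on_random_masks(self):
        rng = np.random.default_rng(5)
        for _ in range(8):
            blobs = rng.random((2, 24, 24)) > 0.75
            blobs = np.stack([
                ndimage.binary_fill_holes(ndimage.binary_dilation(b))
                for b in blobs
            ])
            # ensure non-empty
            blobs[:, 12, 12] = True
            ms = tm.MaskSeries(blobs, spacing=(1.3, 0.9))
            assert tm.mpd(ms) == pytest.approx(
                _brute_mpd(blobs, (1.3, 0.9)), abs=1e-12
            )

    def test_matches_bruteforce_on_random_annuli(self):
        rng = np.random.default_rng(9)
        yy, xx = np.meshgrid(np.arange(30), np.arange(30), indexing="ij")
        for _ in range(6):
            stack = []
            for _ in range(2):
                cy, cx = rng.uniform(12, 18, 2)
                r = np.hypot(yy - cy, xx - cx)
                stack.append((r > rng.uniform(3, 5)) & (r <= rng.uniform(8, 11)))
            stack = np.stack(stack)
            ms = tm.MaskSeries(stack, spacing=(1.4, 1.4))
            assert tm.mpd(ms) == pytest.approx(
                _brute_mpd(stack, (1.4, 1.4)), abs=1e-12
            )

    def test_reorder_invariant(self):
        m = _annulus()
        stack = np.stack([m, np.roll(m, 3, axis=0), np.roll(m, 1, axis=1)])
        a = tm.mpd(tm.MaskSeries(stack))
        b = tm.mpd(tm.MaskSeries(stack[::-1].copy()))
        assert a == pytest.approx(b)

    def test_metric_properties_on_pairs(self):
        m1 = _annulus()
        m2 = np.roll(m1, 2, axis=0)
        m3 = np.roll(m1, 4, axis=0)

        def pair_mpd(a, b):
            return tm.mpd(tm.MaskSeries(np.stack([a, b])))

        assert pair_mpd(m1, m1) == 0.0
        assert pair_mpd(m1, m2) == pair_mpd(m2, m1)
        assert pair_mpd(m1, m3) <= pair_mpd(m1, m2) + pair_mpd(m2, m3) + 1e-9

    def test_translation_equivariance(self):
        m = _annulus(shape=(48, 48))
        stack = np.stack([m, np.roll(m, 3, axis=1)])
        moved = np.stack([np.roll(s, (2, 2), axis=(0, 1)) for s in stack])
        assert tm.mpd(tm.MaskSeries(stack)) == pytest.approx(
            tm.mpd(tm.MaskSeries(moved))
        )
        assert tm.dice_series(tm.MaskSeries(stack)) == pytest.approx(
            tm.dice_series(tm.MaskSeries(moved))
        )

    def test_empty_mask_rejected(self):
        m = _annulus()
        with pytest.raises(ValueError):
            tm.mpd(tm.MaskSeries(np.stack([m, np.zeros_like(m)])))

    def test_endo_epi_separation(self):
        # enlarging only the hole moves the endo contour, not the epi one
        m1 = _annulus(r_in=5.0, r_out=14.0)
        m2 = _annulus(r_in=8.0, r_out=14.0)
        val = tm.mpd(tm.MaskSeries(np.stack([m1, m2])))
        assert val >= 2.0  # endo contour moved by ~3 px


class TestRoiStats:
    def test_uniform_region(self):
        pm = tm.ParameterMap(np.full((8, 8), 48.8), np.ones((8, 8)))
        s = tm.roi_stats(pm, np.ones((8, 8), bool))
        assert s.mean == pytest.approx(48.8)
        assert s.sd == pytest.approx(0.0, abs=1e-12)
        assert s.n_pixels == 64

    def test_hand_computed_sd(self):
        t = np.zeros((2, 3))
        t[0] = [40.0, 50.0, 60.0]
        pm = tm.ParameterMap(t, np.ones((2, 3)),
                             np.array([[True, True, True], [False] * 3]))
        s = tm.roi_stats(pm, np.ones((2, 3), bool))
        assert s.mean == pytest.approx(50.0)
        assert s.sd == pytest.approx(10.0)  # sample SD
        assert s.n_pixels == 3

    def test_empty_roi_rejected(self):
        pm = tm.ParameterMap(np.full((4, 4), 50.0), np.ones((4, 4)))
        with pytest.raises(ValueError):
            tm.roi_stats(pm, np.zeros((4, 4), bool))


class TestTwoSdPositive:
    def _map_with(self, remote_vals, segment_vals):
        n = len(remote_vals) + len(segment_vals)
        t = np.zeros((1, n))
        t[0, : len(remote_vals)] = remote_vals
        t[0, len(remote_vals):] = segment_vals
        pm = tm.ParameterMap(t, np.ones((1, n)))
        remote = np.zeros((1, n), bool)
        remote[0, : len(remote_vals)] = True
        segment = np.zeros((1, n), bool)
        segment[0, len(remote_vals):] = True
        return pm, remote, segment

    def test_elevated_segment_positive(self):
        # remote 48.8 +- 6.5 -> threshold 61.8; segment at 68.4 is positive
        rng = np.random.default_rng(0)
        remote_vals = rng.normal(48.8, 6.5, 200)
        pm, remote, segment = self._map_with(remote_vals, [68.4] * 50)
        stats = tm.roi_stats(pm, remote)
        assert 68.4 >= stats.mean + 2 * stats.sd  # sanity of the setup
        assert tm.two_sd_positive(pm, remote, segment)

    def test_equal_means_negative(self):
        pm, remote, segment = self._map_with([48.0, 49.6], [48.8, 48.8])
        assert not tm.two_sd_positive(pm, remote, segment)

    def test_boundary_exactly_two_sd_positive(self):
        pm, remote, segment = self._map_with([40.0, 60.0], [50.0 + 2 * np.std([40.0, 60.0], ddof=1)] * 2)
        assert tm.two_sd_positive(pm, remote, segment)

    def test_zero_sd_equal_means_negative(self):
        pm, remote, segment = self._map_with([50.0, 50.0], [50.0, 50.0])
        assert not tm.two_sd_positive(pm, remote, segment)
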