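"""Unit and property tests for the low-level image operators."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skimage.draw import disk

from plateletquant import imops
from plateletquant.imops import (
    DegenerateImageError,
    ImagePlane,
    ParameterError,
    erode,
    fill_holes,
    gaussian_blur,
    label_components,
    measure_regions,
    min_error_threshold,
    moment_threshold,
    rolling_ball_subtract,
    watershed_split,
)

from conftest import make_plane


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def oracle_kittler_bin(hist):
    """Exhaustive J(t) evaluation with explicit loops (mid-plateau tie rule)."""
    p = np.asarray(hist, float) / np.sum(hist)
    n = len(p)
    i = np.arange(n, dtype=float)
    J = np.full(n - 1, np.inf)
    for t in range(n - 1):
        P1 = p[: t + 1].sum()
        P2 = 1.0 - P1
        if P1 <= 0 or P2 <= 0:
            continue
        mu1 = (p[: t + 1] * i[: t + 1]).sum() / P1
        mu2 = (p[t + 1:] * i[t + 1:]).sum() / P2
        v1 = max((p[: t + 1] * (i[: t + 1] - mu1) ** 2).sum() / P1, 1 / 12)
        v2 = max((p[t + 1:] * (i[t + 1:] - mu2) ** 2).sum() / P2, 1 / 12)
        J[t] = 1 + P1 * np.log(v1) + P2 * np.log(v2) \
            - 2 * (P1 * np.log(P1) + P2 * np.log(P2))
    t = int(np.argmin(J))
    lo = hi = t
    while lo > 0 and J[lo - 1] <= J[t] + 1e-12:
        lo -= 1
    while hi < len(J) - 1 and J[hi + 1] <= J[t] + 1e-12:
        hi += 1
    return (lo + hi) // 2


def oracle_tsai_bin(hist):
    """Closed-form moment-preservation equations, evaluated independently."""
    p = np.asarray(hist, float) / np.sum(hist)
    z = np.arange(len(p), dtype=float)
    m1, m2, m3 = (p * z).sum(), (p * z**2).sum(), (p * z**3).sum()
    cd = m2 - m1 * m1
    c0 = (m1 * m3 - m2 * m2) / cd
    c1 = (m1 * m2 - m3) / cd
    z0 = 0.5 * (-c1 - np.sqrt(c1 * c1 - 4 * c0))
    z1 = 0.5 * (-c1 + np.sqrt(c1 * c1 - 4 * c0))
    p0 = (z1 - m1) / (z1 - z0)
    cum = np.cumsum(p)
    best, best_d = 0, np.inf
    for t in range(len(p)):
        d = abs(cum[t] - p0)
        if d < best_d:
            best, best_d = t, d
    return min(best, len(p) - 2)


def random_bimodal_histograms(n, seed):
    rng = np.random.default_rng(seed)
    for _ in range(n):
        h = np.zeros(256)
        mu1, mu2 = rng.uniform(20, 90), rng.uniform(140, 230)
        s1, s2 = rng.uniform(3, 15), rng.uniform(3, 20)
        w = rng.uniform(0.2, 0.8)
        x1 = rng.normal(mu1, s1, int(5000 * w)).clip(0, 255).astype(int)
        x2 = rng.normal(mu2, s2, int(5000 * (1 - w))).clip(0, 255).astype(int)
        np.add.at(h, x1, 1)
        np.add.at(h, x2, 1)
        yield h


# ---------------------------------------------------------------------------
# background and smoothing
# ---------------------------------------------------------------------------

class TestRollingBall:
    def test_constant_image_becomes_zero(self):
        img = make_plane(np.full((40, 40), 17.0))
        out = rolling_ball_subtract(img, 5)
        assert np.allclose(out.pixels, 0.0)

    def test_small_disc_peak_on_ramp_is_preserved(self):
        # bright disc (diameter << ball radius) riding a linear ramp
        h = w = 96
        ramp = np.linspace(0, 30, w)[None, :].repeat(h, axis=0)
        img = ramp.copy()
        rr, cc = disk((48, 48), 4)
        img[rr, cc] += 100.0
        out = rolling_ball_subtract(make_plane(img), 20)
        peak = out.pixels[48, 48]
        assert peak == pytest.approx(100.0, rel=0.10)
        # the ramp itself is background: far from the disc, the residual is small
        assert out.pixels[10, 70] < 5.0

    def test_quadratic_background_removed(self):
        h = w = 256
        rr, cc = np.mgrid[0:h, 0:w].astype(float)
        bg = 40.0 * ((rr - h / 2) ** 2 + (cc - w / 2) ** 2) / (h / 2) ** 2 / 2
        out = rolling_ball_subtract(make_plane(bg), 20)
        assert out.pixels.std() < 0.10 * (bg.max() - bg.min())

    def test_output_bounded_by_input_and_zero(self):
        rng = np.random.default_rng(0)
        img = make_plane(rng.uniform(0, 100, (64, 64)))
        out = rolling_ball_subtract(img, 10)
        assert (out.pixels >= 0).all()
        assert (out.pixels <= img.pixels + 1e-9).all()

    def test_bad_radius_rejected(self):
        with pytest.raises(ParameterError):
            rolling_ball_subtract(make_plane(np.ones((5, 5))), 0)


class TestGaussianBlur:
    def test_sigma_zero_is_identity(self):
        img = make_plane(np.random.default_rng(1).uniform(0, 9, (20, 20)))
        assert np.array_equal(gaussian_blur(img, 0).pixels, img.pixels)

    def test_constant_unchanged(self):
        img = make_plane(np.full((30, 30), 4.2))
        assert np.allclose(gaussian_blur(img, 2.0).pixels, 4.2)

    def test_delta_spread_variance_matches_sigma(self):
        img = np.zeros((101, 101))
        img[50, 50] = 1.0
        for s in (1.5, 3.0):
            out = gaussian_blur(make_plane(img), s).pixels
            rr, cc = np.mgrid[0:101, 0:101].astype(float)
            var = (out * ((rr - 50) ** 2)).sum() / out.sum()
            assert var == pytest.approx(s**2, rel=0.02)

    def test_total_intensity_conserved_for_interior_mass(self):
        img = np.zeros((80, 80))
        rr, cc = disk((40, 40), 10)
        img[rr, cc] = 7.0
        out = gaussian_blur(make_plane(img), 2.0).pixels
        assert out.sum() == pytest.approx(img.sum(), rel=1e-3)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ParameterError):
            gaussian_blur(make_plane(np.ones((4, 4))), -1.0)


# ---------------------------------------------------------------------------
# thresholding
# ---------------------------------------------------------------------------

class TestMinErrorThreshold:
    def test_matches_exhaustive_oracle_on_random_histograms(self):
        for h in random_bimodal_histograms(25, seed=7):
            assert imops.kittler_illingworth_bin(h) == oracle_kittler_bin(h)

    def test_gaussian_mixture_threshold_in_gap(self):
        rng = np.random.default_rng(0)
        data = np.concatenate([rng.normal(50, 5, 2000),
                               rng.normal(200, 10, 2000)]).clip(0)
        thr = min_error_threshold(make_plane(data.reshape(40, 100)))
        assert 80 < thr < 170

    def test_two_valued_image(self):
        img = make_plane(np.array([[10.0, 240.0] * 8] * 4))
        thr = min_error_threshold(img)
        assert 10 < thr < 240
        assert set(np.unique(img.pixels[img.pixels > thr])) == {240.0}

    def test_constant_image_raises(self):
        with pytest.raises(DegenerateImageError):
            min_error_threshold(make_plane(np.full((8, 8), 3.0)))


class TestMomentThreshold:
    def test_binary_image_reproduced_exactly(self):
        rng = np.random.default_rng(5)
        px = np.where(rng.random((50, 50)) < 0.3, 0.0, 255.0)
        img = make_plane(px)
        thr = moment_threshold(img)
        assert np.array_equal(px > thr, px == 255.0)

    def test_matches_closed_form_oracle_on_three_mass_histogram(self):
        h = np.zeros(256)
        h[100], h[150], h[220] = 600, 300, 100
        assert imops.tsai_moment_bin(h) == oracle_tsai_bin(h)

    def test_matches_oracle_on_random_histograms(self):
        for h in random_bimodal_histograms(25, seed=11):
            assert imops.tsai_moment_bin(h) == oracle_tsai_bin(h)

    @pytest.mark.parametrize("offset", [5.0, 37.5, 120.0])
    def test_shift_covariance_of_foreground_partition(self, offset):
        rng = np.random.default_rng(2)
        data = np.concatenate([rng.normal(30, 4, 1500),
                               rng.normal(120, 12, 500)]).clip(0).reshape(40, 50)
        a = make_plane(data)
        b = make_plane(data + offset)
        fg_a = a.pixels > moment_threshold(a)
        fg_b = b.pixels > moment_threshold(b)
        assert np.array_equal(fg_a, fg_b)

    def test_constant_image_raises(self):
        with pytest.raises(DegenerateImageError):
            moment_threshold(make_plane(np.zeros((6, 6))))


# ---------------------------------------------------------------------------
# binary morphology
# ---------------------------------------------------------------------------

def oracle_fill(mask):
    """Flood-fill background from the border; everything unreachable is hole."""
    from scipy import ndimage as ndi

    bg_labels, _ = ndi.label(~mask, structure=np.array([[0, 1, 0],
                                                        [1, 1, 1],
                                                        [0, 1, 0]]))
    border = set(np.unique(np.concatenate([
        bg_labels[0, :], bg_labels[-1, :], bg_labels[:, 0], bg_labels[:, -1]])))
    border.discard(0)
    return mask | (~mask & ~np.isin(bg_labels, sorted(border)))


class TestFillHoles:
    def test_solid_disc_unchanged(self):
        m = np.zeros((40, 40), bool)
        rr, cc = disk((20, 20), 10)
        m[rr, cc] = True
        assert np.array_equal(fill_holes(m), m)

    def test_annulus_becomes_solid_disc(self):
        m = np.zeros((40, 40), bool)
        rr, cc = disk((20, 20), 12)
        m[rr, cc] = True
        rr, cc = disk((20, 20), 7)
        m[rr, cc] = False
        filled = fill_holes(m)
        solid = np.zeros_like(m)
        rr, cc = disk((20, 20), 12)
        solid[rr, cc] = True
        assert np.array_equal(filled, solid)

    def test_nested_rings_match_flood_fill_oracle(self):
        m = np.zeros((60, 60), bool)
        for r_out, r_in in [(25, 21), (14, 10)]:
            rr, cc = disk((30, 30), r_out)
            m[rr, cc] = True
            rr, cc = disk((30, 30), r_in)
            m[rr, cc] = False
        assert np.array_equal(fill_holes(m), oracle_fill(m))


class TestWatershedSplit:
    def test_single_disc_one_label(self):
        m = np.zeros((50, 50), bool)
        rr, cc = disk((25, 25), 12)
        m[rr, cc] = True
        ws = watershed_split(m)
        assert ws.n_objects == 1
        assert np.array_equal(ws.labels > 0, m)

    def test_two_overlapping_discs_split_near_equidistance(self):
        m = np.zeros((80, 100), bool)
        c1, c2 = (40.0, 38.0), (40.0, 62.0)
        for c in (c1, c2):
            rr, cc = disk(c, 15)
            m[rr, cc] = True
        ws = watershed_split(m)
        assert ws.n_objects == 2
        # boundary pixels between the two labels sit near the analytic
        # equidistance line (the vertical line col = 50)
        lab = ws.labels
        boundary_cols = []
        for r in range(80):
            row = lab[r]
            for c in range(99):
                if row[c] > 0 and row[c + 1] > 0 and row[c] != row[c + 1]:
                    boundary_cols.append(c + 0.5)
        assert boundary_cols
        assert np.all(np.abs(np.array(boundary_cols) - 50.0) <= 2.0)

    def test_empty_mask_zero_labels(self):
        ws = watershed_split(np.zeros((10, 10), bool))
        assert ws.n_objects == 0
        assert not ws.labels.any()

    def test_conservation_on_random_blobs(self):
        rng = np.random.default_rng(9)
        m = gaussian_blur(make_plane(rng.random((96, 96))), 3).pixels > 0.5
        ws = watershed_split(m)
        assert np.array_equal(ws.labels > 0, m)  # no lines dropped, no leakage


class TestErode:
    def test_zero_iterations_identity(self):
        m = np.random.default_rng(3).random((20, 20)) > 0.5
        assert np.array_equal(erode(m, 0), m)

    @pytest.mark.parametrize("r,n", [(20, 3), (30, 5)])
    def test_disc_area_shrinks_as_expected(self, r, n):
        m = np.zeros((2 * r + 10, 2 * r + 10), bool)
        rr, cc = disk((r + 5, r + 5), r)
        m[rr, cc] = True
        area = erode(m, n).sum()
        # cross-element erosion: radius r-n along axes, r-n/sqrt(2) diagonally
        assert np.pi * (r - n) ** 2 <= area <= np.pi * (r - n / np.sqrt(2)) ** 2 * 1.03

    def test_mask_smaller_than_element_vanishes(self):
        m = np.zeros((10, 10), bool)
        m[5, 5] = True
        assert not erode(m, 1).any()

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 4), st.integers(0, 2**32 - 1))
    def test_monotone_in_iterations(self, n, seed):
        m = np.random.default_rng(seed).random((24, 24)) > 0.4
        a, b = erode(m, n), erode(m, n + 1)
        assert not (b & ~a).any()  # erode(n+1) subset of erode(n)


class TestLabelComponents:
    def test_two_disjoint_discs(self):
        m = np.zeros((40, 80), bool)
        for c in ((20, 20), (20, 60)):
            rr, cc = disk(c, 8)
            m[rr, cc] = True
        assert label_components(m, 8).n_objects == 2

    def test_diagonal_touching_depends_on_connectivity(self):
        m = np.zeros((4, 4), bool)
        m[1, 1] = m[2, 2] = True
        assert label_components(m, 8).n_objects == 1
        assert label_components(m, 4).n_objects == 2

    def test_empty_mask(self):
        assert label_components(np.zeros((5, 5), bool)).n_objects == 0


# ---------------------------------------------------------------------------
# region measurement
# ---------------------------------------------------------------------------

class TestMeasureRegions:
    def _metrics_of(self, mask, px=40.0):
        return measure_regions(label_components(mask), px)

    def test_disc_circularity_near_one(self):
        m = np.zeros((80, 80), bool)
        rr, cc = disk((40, 40), 30)
        m[rr, cc] = True
        (met,) = self._metrics_of(m)
        assert 0.90 <= met.circularity <= 1.05
        assert met.area_um2 == pytest.approx(m.sum() * 0.04**2)

    def test_square_circularity_near_pi_over_4(self):
        m = np.zeros((60, 60), bool)
        m[10:50, 10:50] = True
        (met,) = self._metrics_of(m)
        assert met.circularity == pytest.approx(np.pi / 4, rel=0.10)

    def test_thin_rectangle_circularity(self):
        m = np.zeros((40, 60), bool)
        m[10:13, 10:40] = True
        (met,) = self._metrics_of(m)
        assert met.circularity == pytest.approx(4 * np.pi * 90 / 66**2, rel=0.15)

    def test_translation_and_rotation_invariance(self):
        m = np.zeros((100, 100), bool)
        rr, cc = disk((30, 30), 14)
        m[rr, cc] = True
        m[20:26, 28:34] = True  # asymmetric bump
        (a,) = self._metrics_of(m)
        (b,) = self._metrics_of(np.roll(m, (25, 31), axis=(0, 1)))
        assert b.circularity == pytest.approx(a.circularity, abs=1e-12)
        (c,) = self._metrics_of(np.rot90(m))
        assert c.circularity == pytest.approx(a.circularity, rel=0.05)

    def test_empty_label_map_gives_empty_list(self):
        assert self._metrics_of(np.zeros((5, 5), bool)) == []
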