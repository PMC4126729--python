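"""Box-counting: exact tilings, analytic dimensions, oracle equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import afpq
from afpq.fractal_dimension import box_count, default_scales, fit_fd, local_fd_grid

from conftest import brute_force_box_count


def _image(grid):
    return afpq.RasterImage(np.asarray(grid, dtype=np.uint8), 1.0)


class TestBoxCount:
    def test_filled_square_exact_tiling(self):
        img = _image(np.ones((64, 64)))
        s = box_count(img, [2, 4, 8, 16, 32])
        np.testing.assert_array_equal(s.counts, [1024, 256, 64, 16, 4])

    def test_single_pixel(self):
        g = np.zeros((64, 64))
        g[10, 17] = 1
        s = box_count(_image(g), [2, 4, 8, 16, 32])
        np.testing.assert_array_equal(s.counts, 1)

    def test_carpet_recursion_oracle(self):
        """Carpet at its aligned scales: N(3^k) = 8^(levels-k)."""
        carpet5 = afpq.generate_sierpinski_carpet(5)
        s = box_count(carpet5, [1, 3, 9, 27, 81])
        np.testing.assert_array_equal(s.counts, [8**5, 8**4, 8**3, 8**2, 8])

    def test_matches_brute_force_on_random_images(self):
        rng = np.random.default_rng(99)
        for _ in range(5):
            g = (rng.random((48, 48)) < 0.2).astype(np.uint8)
            if g.sum() == 0:
                g[0, 0] = 1
            img = _image(g)
            s = box_count(img, [1, 2, 3, 4, 6, 8, 12], offsets="none")
            expected = [brute_force_box_count(g, e) for e in [1, 2, 3, 4, 6, 8, 12]]
            np.testing.assert_array_equal(s.counts, expected)

    def test_offset_minimum_never_exceeds_aligned_count(self):
        rng = np.random.default_rng(3)
        g = (rng.random((50, 50)) < 0.1).astype(np.uint8)
        g[0, 0] = 1
        a = box_count(_image(g), [2, 3, 4, 6, 8], offsets="corners").counts
        b = box_count(_image(g), [2, 3, 4, 6, 8], offsets="none").counts
        assert np.all(a <= b)

    def test_counts_non_increasing_and_cover_bound(self, carpet4):
        s = box_count(carpet4, [1, 2, 3, 4, 6, 9, 12])
        assert np.all(np.diff(s.counts) <= 0)
        assert np.all(s.counts * s.scales**2 >= carpet4.filled_count())

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        hnp.arrays(np.uint8, (40, 40), elements=st.integers(0, 1)),
        hnp.arrays(np.uint8, (40, 40), elements=st.integers(0, 1)),
    )
    def test_subset_monotonicity(self, a, b):
        """Adding filled pixels never decreases any box count."""
        if a.sum() == 0:
            a[5, 5] = 1
        union = ((a | b) != 0).astype(np.uint8)
        sa = box_count(_image(a), [2, 4, 5, 8, 10]).counts
        su = box_count(_image(union), [2, 4, 5, 8, 10]).counts
        assert np.all(su >= sa)

    def test_empty_image_rejected(self):
        with pytest.raises(afpq.ValidationError):
            box_count(_image(np.zeros((32, 32))), [2, 4, 8, 12, 16])

    def test_too_few_scales_rejected(self, carpet4):
        with pytest.raises(afpq.ValidationError):
            box_count(carpet4, [2, 4, 8])


class TestFitFD:
    def test_exact_power_law(self):
        scales = np.array([2, 4, 8, 16, 32])
        counts = np.array([2**15, 2**12, 2**9, 2**6, 2**3])  # N = C * eps^-3
        series = afpq.BoxCountSeries(scales, counts, 1)
        fit = fit_fd(series)
        assert fit.d_b == pytest.approx(3.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_filled_square_dimension_two(self):
        fit = fit_fd(box_count(_image(np.ones((64, 64))), [2, 4, 8, 16, 32]))
        assert fit.d_b == pytest.approx(2.0, abs=1e-9)

    def test_carpet_dimension(self):
        carpet5 = afpq.generate_sierpinski_carpet(5)
        fit = fit_fd(box_count(carpet5, [1, 3, 9, 27, 81]))
        assert fit.d_b == pytest.approx(np.log(8) / np.log(3), abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        # the default dyadic policy is approximate but must stay close
        assert abs(afpq.fd_entire(carpet5).d_b - np.log(8) / np.log(3)) < 0.05

    def test_line_dimension_one(self):
        g = np.zeros((128, 128))
        g[64, :] = 1
        fit = afpq.fd_entire(_image(g))
        assert fit.d_b == pytest.approx(1.0, abs=0.05)

    def test_degenerate_series_rejected(self):
        series = afpq.BoxCountSeries(
            np.array([2, 4, 8, 16, 32]), np.array([7, 7, 7, 7, 7]), 1
        )
        with pytest.raises(afpq.DegenerateSeriesError):
            fit_fd(series)

    def test_dimension_ordering_line_carpet_square(self):
        line = np.zeros((128, 128))
        line[40, :] = 1
        d_line = afpq.fd_entire(_image(line)).d_b
        d_carpet = afpq.fd_entire(afpq.generate_sierpinski_carpet(5)).d_b
        d_square = afpq.fd_entire(_image(np.ones((128, 128)))).d_b
        assert d_line < d_carpet < d_square


class TestROI:
    def test_roi_whole_image_identity(self, carpet4):
        h, w = carpet4.shape
        assert afpq.fd_roi(carpet4, (0, 0, w, h)).d_b == afpq.fd_entire(carpet4).d_b

    def test_roi_line_segment(self):
        g = np.zeros((256, 256))
        g[100, 64:192] = 1
        fit = afpq.fd_roi(_image(g), (64, 64, 192, 192))
        assert fit.d_b == pytest.approx(1.0, abs=0.05)

    def test_roi_differs_from_entire_on_mixed_image(self):
        """A filled corner block has higher FD than the sparse image holding it."""
        rng = np.random.default_rng(21)
        g = (rng.random((128, 128)) < 0.15).astype(np.uint8)
        g[:32, :32] = 1
        img = _image(g)
        d_roi = afpq.fd_roi(img, (0, 0, 32, 32)).d_b
        assert d_roi == pytest.approx(2.0, abs=1e-9)
        assert d_roi > afpq.fd_entire(img).d_b

    def test_empty_roi_rejected(self, carpet4):
        g = np.zeros((128, 128))
        g[0, 0] = 1
        with pytest.raises(afpq.ComputationError):
            afpq.fd_roi(_image(g), (64, 64, 128, 128))

    def test_bad_roi_rejected(self, carpet4):
        with pytest.raises(afpq.ValidationError):
            afpq.fd_roi(carpet4, (0, 0, 10, 10))


class TestLocalGrid:
    def test_beta_is_one_against_itself(self, base_cloud):
        img = afpq.rasterize(base_cloud, 384)
        base_grid = local_fd_grid(img)
        grid = local_fd_grid(img, baseline=base_grid)
        defined = ~np.isnan(grid.beta)
        assert defined.sum() >= 30
        np.testing.assert_allclose(grid.beta[defined], 1.0, atol=1e-12)

    def test_planted_void_tile_undefined_neighbors_unchanged(self):
        rng = np.random.default_rng(12)
        g = (rng.random((384, 384)) < 0.3).astype(np.uint8)
        ref = local_fd_grid(_image(g))
        g2 = g.copy()
        g2[64:128, 64:128] = 0  # empty exactly tile (1, 1)
        got = local_fd_grid(_image(g2))
        assert got.fits[1][1] is None
        assert got.fits[0][0].d_b == ref.fits[0][0].d_b
        assert got.fits[2][2].d_b == ref.fits[2][2].d_b

    def test_uniform_image_tiles_agree(self):
        rng = np.random.default_rng(5)
        g = (rng.random((384, 384)) < 0.5).astype(np.uint8)
        grid = local_fd_grid(_image(g))
        vals = grid.d_b_array()
        assert np.nanmax(vals) - np.nanmin(vals) < 0.02

    def test_tiles_too_small_rejected(self, carpet4):
        with pytest.raises(afpq.ValidationError):
            local_fd_grid(_image(np.ones((64, 64))), (6, 6))


def test_default_scales_enforces_minimum():
    assert default_scales((512, 512)).tolist() == [2, 4, 8, 16, 32, 64, 128]
    assert len(default_scales((40, 40))) >= 5
    with pytest.raises(afpq.ValidationError):
        default_scales((6, 6))
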