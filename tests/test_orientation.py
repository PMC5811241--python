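"""Gabor bank, per-pixel orientation, fiber axis and relative histograms."""

import math

import numpy as np
import pytest

from conftest import make_stripes
from fibermito.orientation import (
    DegenerateAxisWarning,
    EmptySegmentationError,
    GaborBankConfig,
    OrientationMap,
    analyze_fiber_orientation,
    build_gabor_bank,
    estimate_cell_mask,
    estimate_fiber_axis,
    longitudinal_transverse_fractions,
    max_projection,
    orientation_map,
    relative_orientation_histogram,
)
from fibermito.synthetic import FiberSimParams, simulate_fiber_stack

ORIENTATIONS = (0.0, 30.0, 60.0, 90.0, 120.0, 150.0)


class TestBank:
    def test_default_bank_has_36_kernels(self, gabor_bank):
        assert len(gabor_bank) == 36
        assert len({(k.theta_deg, k.sigma_x) for k in gabor_bank}) == 36

    def test_kernels_unit_norm_and_even_symmetric(self, gabor_bank):
        for k in gabor_bank:
            assert np.linalg.norm(k.array) == pytest.approx(1.0)
            assert np.allclose(k.array, k.array[::-1, ::-1], atol=1e-12)

    def test_rotating_0_degree_kernel_gives_90_degree_kernel(self, gabor_bank):
        by_key = {(k.theta_deg, k.sigma_x): k.array for k in gabor_bank}
        for sx in (1.1, 3.1, 5.1):
            rotated = np.rot90(by_key[(0.0, sx)])
            assert np.allclose(rotated, by_key[(90.0, sx)], atol=1e-6)

    def test_matched_grating_wins_among_orientations(self, gabor_bank):
        sx = 3.1
        lam = 4 * sx
        img = make_stripes(angle_deg=30.0, wavelength=lam)
        from scipy.signal import fftconvolve

        responses = {}
        for k in gabor_bank:
            if k.sigma_x != sx:
                continue
            r = np.abs(fftconvolve(img, k.array, mode="same"))
            responses[k.theta_deg] = r[40:-40, 40:-40].max()
        assert max(responses, key=responses.get) == 30.0

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            build_gabor_bank(GaborBankConfig(sigmas_x=(0.0, 1.0)))

    def test_custom_bank_cardinality(self):
        cfg = GaborBankConfig(orientations=(0.0, 45.0, 90.0, 135.0), sigmas_x=(1.0, 2.0))
        assert len(build_gabor_bank(cfg)) == cfg.size == 8


class TestOrientationMap:
    def test_uniform_image_has_no_fibers(self, gabor_bank):
        with pytest.raises(EmptySegmentationError):
            orientation_map(np.ones((64, 64)), gabor_bank)

    @pytest.mark.parametrize("angle", [0.0, 60.0, 150.0])
    def test_stripes_recover_modal_orientation(self, gabor_bank, angle):
        img = make_stripes(angle_deg=angle, wavelength=12.0)
        omap = orientation_map(img, gabor_bank, fiber_threshold="otsu")
        angles = omap.masked_angles()
        assert (angles == angle).mean() >= 0.90

    def test_rotation_equivariance_by_90_degrees(self, gabor_bank):
        img = make_stripes(angle_deg=30.0, wavelength=12.0)
        om1 = orientation_map(img, gabor_bank, fiber_threshold="otsu")
        om2 = orientation_map(np.rot90(img), gabor_bank, fiber_threshold="otsu")
        a1 = np.asarray(om1.orientations)[om1.orientation_index]
        a2 = np.asarray(om2.orientations)[om2.orientation_index]
        common = np.rot90(om1.fiber_mask) & om2.fiber_mask
        # ignore frame borders where the rotated field of view differs
        common[:16] = common[-16:] = False
        common[:, :16] = common[:, -16:] = False
        shifted = np.mod(np.rot90(a1) + 90.0, 180.0)
        assert (np.mod(shifted - a2, 180.0) == 0)[common].mean() > 0.99

    def test_tie_break_is_lowest_filter_index(self, gabor_bank):
        img = make_stripes(angle_deg=0.0, wavelength=12.0)
        omap = orientation_map(img, gabor_bank, fiber_threshold="otsu")
        assert omap.orientation_index.min() >= 0
        assert omap.orientation_index.max() < 6


class TestFiberAxis:
    def test_axis_aligned_rectangle(self):
        m = np.zeros((60, 140), bool)
        m[25:35, 20:120] = True
        assert estimate_fiber_axis(m) == pytest.approx(0.0, abs=1e-6)

    def test_rotated_rectangle(self):
        from scipy.ndimage import rotate

        m = np.zeros((200, 200))
        m[95:105, 50:150] = 1.0
        m30 = rotate(m, angle=-30.0, reshape=False, order=1) > 0.5
        est = estimate_fiber_axis(m30)
        assert min(abs(est - 30.0), 180 - abs(est - 30.0)) < 1.0

    def test_isotropic_mask_warns_but_returns(self):
        m = np.zeros((50, 50), bool)
        m[10:40, 10:40] = True
        with pytest.warns(DegenerateAxisWarning):
            angle = estimate_fiber_axis(m)
        assert 0.0 <= angle < 180.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            estimate_fiber_axis(np.zeros((10, 10), bool))

    def test_agrees_with_projected_variance_search(self, rng):
        """Oracle: scan 0.5 deg-spaced axes, maximize variance along the axis."""
        for _ in range(40):
            angle = rng.uniform(0, 180)
            length, width = rng.uniform(40, 80), rng.uniform(5, 15)
            n = 400
            t = rng.uniform(-length, length, n)
            s = rng.uniform(-width, width, n)
            th = math.radians(angle)
            x = 100 + t * math.cos(th) - s * math.sin(th)
            y = 100 + t * math.sin(th) + s * math.cos(th)
            m = np.zeros((200, 200), bool)
            m[np.clip(y.astype(int), 0, 199), np.clip(x.astype(int), 0, 199)] = True
            est = estimate_fiber_axis(m)
            rows, cols = np.nonzero(m)
            xc, yc = cols - cols.mean(), rows - rows.mean()
            cand = np.arange(0.0, 180.0, 0.5)
            proj_var = [
                np.var(xc * math.cos(math.radians(a)) + yc * math.sin(math.radians(a)))
                for a in cand
            ]
            brute = cand[int(np.argmax(proj_var))]
            d = abs(est - brute) % 180
            assert min(d, 180 - d) <= 1.0

    def test_simulated_fiber_axis_recovered(self, gabor_bank):
        params = FiberSimParams(fiber_axis_deg=120.0, seed=5)
        est_cell = estimate_fiber_axis(params.cell_mask())
        d = abs(est_cell - 120.0) % 180
        assert min(d, 180 - d) <= 2.0
        # image route: hull of the sparse mitochondrial texture is noisier, but
        # must stay well inside the 30-degree quantization of the bank
        stack, _, _ = simulate_fiber_stack(params)
        omap = orientation_map(max_projection(stack.voxels), gabor_bank, "otsu2")
        est = estimate_fiber_axis(estimate_cell_mask(omap.fiber_mask))
        d = abs(est - 120.0) % 180
        assert min(d, 180 - d) <= 15.0


def _omap_from_indices(idx, mask):
    return OrientationMap(
        max_response=np.ones_like(idx, dtype=float),
        orientation_index=idx.astype(np.int16),
        fiber_mask=mask,
        orientations=ORIENTATIONS,
    )


class TestHistogram:
    def test_all_parallel_mass_in_bin_zero(self):
        idx = np.zeros((10, 10), int)
        hist = relative_orientation_histogram(
            _omap_from_indices(idx, np.ones((10, 10), bool)), fiber_axis=0.0, n_bins=3
        )
        assert hist.percent_per_bin[0] == pytest.approx(100.0)
        assert hist.percent_per_bin.sum() == pytest.approx(100.0, abs=1e-6)

    def test_uniform_orientations_fold_as_expected(self):
        # equal mass on the 6 bank angles, axis 0: folded masses
        # {0: 1/6, 30: 2/6, 60: 2/6, 90: 1/6}
        idx = np.tile(np.arange(6), (6, 6))[:6, :6]
        hist = relative_orientation_histogram(
            _omap_from_indices(idx, np.ones((6, 6), bool)), fiber_axis=0.0, n_bins=3
        )
        lookup = dict(zip(hist.angle_values, hist.angle_percents))
        assert lookup[0.0] == pytest.approx(100 / 6)
        assert lookup[30.0] == pytest.approx(200 / 6)
        assert lookup[60.0] == pytest.approx(200 / 6)
        assert lookup[90.0] == pytest.approx(100 / 6)

    @pytest.mark.parametrize("n_bins", [3, 8])
    def test_bins_sum_to_100(self, n_bins, rng):
        idx = rng.integers(0, 6, (20, 20))
        hist = relative_orientation_histogram(
            _omap_from_indices(idx, rng.random((20, 20)) > 0.3), fiber_axis=17.0, n_bins=n_bins
        )
        assert hist.percent_per_bin.sum() == pytest.approx(100.0, abs=1e-6)
        assert len(hist.percent_per_bin) == n_bins

    def test_invalid_bin_count_rejected(self):
        with pytest.raises(ValueError):
            relative_orientation_histogram(
                _omap_from_indices(np.zeros((4, 4), int), np.ones((4, 4), bool)), 0.0, n_bins=5
            )


class TestFractions:
    def test_pure_longitudinal(self):
        idx = np.zeros((8, 8), int)
        hist = relative_orientation_histogram(
            _omap_from_indices(idx, np.ones((8, 8), bool)), 0.0, 3
        )
        assert longitudinal_transverse_fractions(hist) == (100.0, 0.0)

    def test_pure_transverse(self):
        idx = np.full((8, 8), 3)  # 90 degrees
        hist = relative_orientation_histogram(
            _omap_from_indices(idx, np.ones((8, 8), bool)), 0.0, 3
        )
        assert longitudinal_transverse_fractions(hist) == (0.0, 100.0)

    def test_end_to_end_mixture_recovery(self, gabor_bank):
        """One simulated fiber: recovered transverse mass close to truth."""
        params = FiberSimParams(
            transverse_fraction=0.3, fiber_axis_deg=77.0, seed=23, mix_assignment="stratified"
        )
        stack, _, truth = simulate_fiber_stack(params)
        r = analyze_fiber_orientation(stack.voxels, bank=gabor_bank)
        w = truth.groupby("is_transverse")["volume_vox"].sum()
        truth_pix = 100.0 * w.get(True, 0.0) / w.sum()
        assert r.percent_transverse == pytest.approx(truth_pix, abs=6.0)
        assert r.percent_longitudinal + r.percent_transverse <= 100.0 + 1e-9


def test_max_projection_shapes():
    v = np.arange(24).reshape(2, 3, 4)
    assert max_projection(v).shape == (3, 4)
    assert np.array_equal(max_projection(v[0]), v[0])
    with pytest.raises(ValueError):
        max_projection(np.zeros(5))
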