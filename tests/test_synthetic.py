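"""Generator ground truth: counts, reproducibility, mixtures, analytic truth."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fibermito.synthetic import (
    CapacityError,
    EMSimParams,
    FiberSimParams,
    TraceSimParams,
    simulate_em_scene,
    simulate_fiber_stack,
    simulate_trace,
    transient_peak_time,
)

SMALL = dict(
    n_mito=20,
    mean_volume_vox=80.0,
    stack_shape=(16, 128, 128),
    disjoint_in_projection=False,
    cell_semi_long_frac=0.7,
    cell_semi_short_frac=0.7,
)


class TestFiberStack:
    def test_empty_stack(self):
        img, lab, truth = simulate_fiber_stack(FiberSimParams(n_mito=0, stack_shape=(8, 32, 32)))
        assert lab.labels.max() == 0
        assert len(truth) == 0
        assert img.shape == (8, 32, 32)

    def test_label_count_matches_n_mito(self):
        _, lab, truth = simulate_fiber_stack(FiberSimParams(seed=7, **SMALL))
        labels = np.unique(lab.labels)
        assert set(labels) == set(range(21))
        assert len(truth) == 20

    def test_volume_truth_is_conserved(self):
        _, lab, truth = simulate_fiber_stack(FiberSimParams(seed=8, **SMALL))
        assert truth["volume_vox"].sum() == (lab.labels > 0).sum()
        counts = np.bincount(lab.labels.ravel())[1:]
        assert np.array_equal(np.sort(counts), np.sort(truth["volume_vox"].to_numpy()))

    def test_objects_do_not_touch_border(self):
        _, lab, _ = simulate_fiber_stack(FiberSimParams(seed=9, **SMALL))
        m = lab.labels
        assert m[0].max() == 0 and m[-1].max() == 0
        assert m[:, 0].max() == 0 and m[:, -1].max() == 0
        assert m[:, :, 0].max() == 0 and m[:, :, -1].max() == 0

    def test_seed_reproducibility_bit_identical(self):
        p = FiberSimParams(seed=11, **SMALL)
        a = simulate_fiber_stack(p)
        b = simulate_fiber_stack(p)
        assert np.array_equal(a[0].voxels, b[0].voxels)
        assert np.array_equal(a[1].labels, b[1].labels)
        pd.testing.assert_frame_equal(a[2], b[2])

    def test_orientation_mixture_within_binomial_ci(self):
        # 50/50 mixture of 0 and 90 degrees; 99% binomial CI for n=200
        p = FiberSimParams(
            n_mito=200,
            mean_volume_vox=40.0,
            orientation_mix=[(0.0, 0.5), (90.0, 0.5)],
            fiber_axis_deg=0.0,
            stack_shape=(16, 192, 192),
            disjoint_in_projection=False,
            cell_semi_long_frac=0.7,
            cell_semi_short_frac=0.7,
            seed=13,
        )
        _, _, truth = simulate_fiber_stack(p)
        frac = (truth["angle_deg"] == 90.0).mean()
        half = 2.576 * math.sqrt(0.25 / 200)
        assert abs(frac - 0.5) <= half

    def test_mixture_chi_square_goodness_of_fit(self):
        mix = [(0.0, 0.2), (60.0, 0.3), (90.0, 0.5)]
        p = FiberSimParams(
            n_mito=500,
            mean_volume_vox=20.0,
            orientation_mix=mix,
            fiber_axis_deg=0.0,
            stack_shape=(24, 224, 224),
            disjoint_in_projection=False,
            cell_semi_long_frac=0.7,
            cell_semi_short_frac=0.7,
            seed=17,
        )
        _, _, truth = simulate_fiber_stack(p)
        observed = truth["angle_deg"].value_counts().reindex([a for a, _ in mix]).to_numpy()
        expected = np.array([w for _, w in mix]) * 500
        assert stats.chisquare(observed, expected).pvalue > 0.01

    def test_transverse_fraction_override(self):
        p = FiberSimParams(transverse_fraction=0.25, fiber_axis_deg=40.0, seed=1, **SMALL)
        mix = p.resolved_mix()
        assert mix == [(40.0, 0.75), (130.0, 0.25)]
        _, _, truth = simulate_fiber_stack(p)
        assert set(truth["angle_deg"]) <= {40.0, 130.0}
        assert truth.loc[truth["is_transverse"], "angle_deg"].eq(130.0).all()

    def test_capacity_error(self):
        with pytest.raises(CapacityError):
            simulate_fiber_stack(
                FiberSimParams(
                    n_mito=100, mean_volume_vox=500.0, stack_shape=(8, 48, 48), max_retries=50
                )
            )

    @pytest.mark.parametrize(
        "bad",
        [
            dict(n_mito=-1),
            dict(orientation_mix=[(0.0, 0.7), (90.0, 0.7)]),
            dict(orientation_mix=[(0.0, -0.1), (90.0, 1.1)]),
            dict(transverse_fraction=1.5),
            dict(fiber_axis_deg=200.0),
            dict(mix_assignment="alternating"),
        ],
    )
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ValueError):
            simulate_fiber_stack(FiberSimParams(**{**SMALL, **bad}))


class TestEMScene:
    def test_gap_distribution_sets_pair_flags(self):
        scene, truth = simulate_em_scene(
            EMSimParams(n_mito=2, n_jsr=2, gap_distribution=[10.0, 100.0], seed=1)
        )
        assert truth.jsr["pair_flag"].tolist() == [True, False]
        assert len(scene.mito_contours) == 2 and len(scene.jsr_contours) == 2

    def test_no_jsr_means_no_interface(self):
        _, truth = simulate_em_scene(EMSimParams(n_mito=5, n_jsr=0, gap_distribution=[], seed=2))
        assert (truth.mito["interface_percent_true"] == 0).all()
        assert truth.percent_paired == 0.0

    def test_constructed_gap_is_exact(self):
        scene, truth = simulate_em_scene(
            EMSimParams(n_mito=3, n_jsr=3, gap_distribution=[10.0, 50.0, 80.0], seed=3)
        )
        from shapely.geometry import LineString, Polygon

        for _, row in truth.jsr.iterrows():
            poly = Polygon(scene.mito_contours[int(row["mito"])])
            line = LineString(scene.jsr_contours[int(row["jsr"])])
            gap_nm = poly.exterior.distance(line) * scene.nm_per_pixel
            assert gap_nm == pytest.approx(row["gap_nm"], abs=1e-6)

    def test_truth_interface_matches_dense_sampling_oracle(self):
        # brute force: sample each boundary at ~1 nm, exact point-to-segment distance
        scene, truth = simulate_em_scene(
            EMSimParams(n_mito=4, n_jsr=4, gap_distribution=[5.0, 20.0, 45.0, 49.0], seed=5)
        )
        for _, row in truth.mito.iterrows():
            contour = scene.mito_contours[int(row["mito"])] * scene.nm_per_pixel
            frac = _interface_oracle(contour, [
                scene.jsr_contours[int(r["jsr"])] * scene.nm_per_pixel
                for _, r in truth.jsr[truth.jsr["mito"] == row["mito"]].iterrows()
            ])
            assert frac == pytest.approx(row["interface_percent_true"], abs=0.2)

    def test_reproducibility(self):
        a, ta = simulate_em_scene(EMSimParams(seed=6))
        b, tb = simulate_em_scene(EMSimParams(seed=6))
        for ca, cb in zip(a.mito_contours, b.mito_contours):
            assert np.array_equal(ca, cb)
        pd.testing.assert_frame_equal(ta.jsr, tb.jsr)

    def test_scene_overflow_raises(self):
        with pytest.raises(CapacityError):
            simulate_em_scene(
                EMSimParams(n_mito=200, scene_shape=(512, 512), seed=1, max_retries=20)
            )


def _interface_oracle(contour_nm, jsr_list_nm, gap_nm=50.0, step_nm=1.0):
    closed = np.vstack([contour_nm, contour_nm[:1]])
    seglen = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    total = seglen.sum()
    n = int(np.ceil(total / step_nm))
    t = np.linspace(0.0, total, n, endpoint=False)
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    seg_idx = np.searchsorted(cum, t, side="right") - 1
    local = (t - cum[seg_idx]) / seglen[seg_idx]
    pts = closed[seg_idx] + local[:, None] * (closed[seg_idx + 1] - closed[seg_idx])
    within = np.zeros(n, dtype=bool)
    for jsr in jsr_list_nm:
        for p0, p1 in zip(jsr[:-1], jsr[1:]):
            within |= _point_segment_distance(pts, p0, p1) <= gap_nm
    return 100.0 * within.mean()


def _point_segment_distance(pts, p0, p1):
    d = p1 - p0
    t = np.clip(((pts - p0) @ d) / (d @ d), 0.0, 1.0)
    proj = p0 + t[:, None] * d
    return np.linalg.norm(pts - proj, axis=1)


class TestTrace:
    def test_flat_trace_without_transient_or_noise(self):
        trace, truth = simulate_trace(
            TraceSimParams(transient_amplitude=0.0, noise_sd=0.0, resting_ratio=1.3)
        )
        assert np.allclose(trace.ratio, 1.3)
        assert truth["amplitude"] == 0.0

    def test_noiseless_peak_matches_closed_form(self):
        p = TraceSimParams(noise_sd=0.0, rise_tau=10.0, decay_tau=60.0, transient_amplitude=0.4)
        trace, truth = simulate_trace(p)
        ratio = trace.ratio
        # peak height equals the amplitude exactly (unit-peak kinetics)
        assert ratio.max() - p.resting_ratio == pytest.approx(0.4, abs=1e-3)
        t_peak_analytic = p.stimulus_frame * p.dt + transient_peak_time(10.0, 60.0)
        assert trace.time[np.argmax(ratio)] == pytest.approx(t_peak_analytic, abs=p.dt)
        assert truth["t_peak"] == pytest.approx(t_peak_analytic)

    def test_channels_reproduce_ratio(self):
        trace, truth = simulate_trace(TraceSimParams(noise_sd=0.0, seed=3))
        assert np.allclose(trace.f490 / trace.f420, truth["ratio_true"])

    def test_seed_reproducibility(self):
        a, _ = simulate_trace(TraceSimParams(seed=21))
        b, _ = simulate_trace(TraceSimParams(seed=21))
        assert np.array_equal(a.f490, b.f490)

    @pytest.mark.parametrize(
        "bad",
        [dict(stimulus_frame=300), dict(rise_tau=0.0), dict(n_frames=0), dict(dt=0.0)],
    )
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ValueError):
            simulate_trace(TraceSimParams(**bad))
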