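"""Reusable benchmark protocols: simulate, analyze, compare to ground truth.

These functions define the package's standard recovery experiments on
synthetic data — the orientation-mixture recovery across many fibers, the
3D-morphometry count/volume recovery across seeds, and the Ca²⁺ estimator
calibration. They are used both by the test suite and by the reproduction
script, so the protocol (problem sizes, seeds derivation, estimators) is
defined in exactly one place.
"""

from __future__ import annotations



import numpy as np
import pandas as pd

from . import morphometry3d
from .calcium import transient_metrics
from .orientation import analyze_fiber_orientation, build_gabor_bank
from .synthetic import FiberSimParams, TraceSimParams, simulate_fiber_stack, simulate_trace


def _child_seeds(seed: int, n: int) -> np.ndarray:
    """n independent 31-bit seeds derived from one master seed."""
    return np.random.SeedSequence(int(seed)).generate_state(n) % (2**31)


def recover_transverse_percent(
    transverse_fraction: float,
    n_fibers: int = 96,
    seed: int = 0,
    n_bins: int = 3,
) -> pd.DataFrame:
    """Full orientation pipeline on ``n_fibers`` simulated fibers.

    Each fiber draws a uniform random main-axis angle and uses stratified
    mixture assignment (the expectation equals the requested transverse
    fraction exactly); the Gabor bank, fiber segmentation, cell-axis estimate
    and axis-relative histogram then recover the transverse percentage per
    fiber. Returns one row per fiber with the recovered and ground-truth
    percentages.
    """
    bank = build_gabor_bank()
    seeds = _child_seeds(seed, 2 * n_fibers)
    rows = []
    for i in range(n_fibers):
        axis_rng = np.random.default_rng(seeds[2 * i])
        params = FiberSimParams(
            transverse_fraction=transverse_fraction,
            fiber_axis_deg=float(axis_rng.uniform(0.0, 180.0)),
            seed=int(seeds[2 * i + 1]),
            mix_assignment="stratified",
        )
        stack, _, truth = simulate_fiber_stack(params)
        result = analyze_fiber_orientation(stack.voxels, bank=bank, n_bins=n_bins)
        w = truth.groupby("is_transverse")["volume_vox"].sum()
        rows.append(
            {
                "fiber": i,
                "fiber_axis_deg": params.fiber_axis_deg,
                "recovered_transverse_percent": result.percent_transverse,
                "recovered_longitudinal_percent": result.percent_longitudinal,
                "true_object_transverse_percent": 100.0 * truth["is_transverse"].mean(),
                "true_pixel_transverse_percent": 100.0 * w.get(True, 0.0) / w.sum(),
            }
        )
    return pd.DataFrame(rows)


#: study conditions of the 3D count/volume recovery benchmark: unblurred
#: stacks (thresholding then sees the rendered voxel truth), 50 objects, 3D
#: disjointness only (projection disjointness is an orientation-analysis
#: requirement and would force a sparse stack where a global threshold is
#: ill-conditioned), noise handled by the min-voxels filter
MORPHOMETRY_RECOVERY_PARAMS = dict(
    n_mito=50,
    mean_volume_vox=150.0,
    aspect_ratio=3.0,
    stack_shape=(32, 144, 144),
    apply_psf=False,
    disjoint_in_projection=False,
    # fill the whole frame: the elliptical cell outline matters for the
    # orientation analysis, not for 3D counting
    cell_semi_long_frac=0.7,
    cell_semi_short_frac=0.7,
    snr=10.0,
)


def morphometry_recovery(
    n_runs: int = 20,
    seed: int = 0,
    snr: float = 10.0,
    threshold: float | str = "otsu",
    connectivity: int = 26,
    min_voxels: int = 20,
) -> pd.DataFrame:
    """Object count and mean-volume recovery on simulated stacks.

    One row per run: true/recovered object count and mean volume after
    thresholding, connected-component labeling and small-object filtering.
    """
    seeds = _child_seeds(seed, n_runs)
    rows = []
    for i in range(n_runs):
        params = FiberSimParams(
            **MORPHOMETRY_RECOVERY_PARAMS | {"snr": snr, "seed": int(seeds[i])}
        )
        stack, labels_true, truth = simulate_fiber_stack(params)
        seg = morphometry3d.apply_threshold(stack, threshold)
        lab = morphometry3d.label_components(seg.mask, connectivity, params.voxel_size)
        lab = morphometry3d.remove_small_objects(lab, min_voxels)
        m = morphometry3d.compute_morphometry(lab)
        rows.append(
            {
                "run": i,
                "true_n_objects": len(truth),
                "recovered_n_objects": m.n_objects,
                "true_mean_volume_vox": float(truth["volume_vox"].mean()),
                "recovered_mean_volume_vox": m.mean_volume_vox,
            }
        )
    return pd.DataFrame(rows)


def calcium_recovery(
    n_traces: int = 100,
    seed: int = 0,
    amplitude: float = 0.5,
    noise_sd: float = 0.01,
) -> pd.DataFrame:
    """Resting/amplitude estimator recovery over simulated traces."""
    seeds = _child_seeds(seed, n_traces)
    rows = []
    for i in range(n_traces):
        params = TraceSimParams(
            transient_amplitude=amplitude, noise_sd=noise_sd, seed=int(seeds[i])
        )
        trace, truth = simulate_trace(params)
        m = transient_metrics(trace.ratio, trace.time, trace.stimulus_time)
        rows.append(
            {
                "trace": i,
                "true_resting": truth["resting"],
                "true_amplitude": truth["amplitude"],
                "resting": m.resting_level,
                "amplitude": m.peak_amplitude,
                "detected": m.detected,
            }
        )
    return pd.DataFrame(rows)


def calcium_null_detection_rate(
    n_traces: int = 1000, seed: int = 0, noise_sd: float = 0.01, k: float = 3.0
) -> float:
    """False-detection rate under the amplitude-0 (null) simulation."""
    seeds = _child_seeds(seed, n_traces)
    hits = 0
    for i in range(n_traces):
        trace, _ = simulate_trace(
            TraceSimParams(transient_amplitude=0.0, noise_sd=noise_sd, seed=int(seeds[i]))
        )
        m = transient_metrics(trace.ratio, trace.time, trace.stimulus_time, k=k)
        hits += int(m.detected)
    return hits / n_traces
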