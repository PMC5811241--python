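"""Measure mitochondrial orientation relative to the fiber axis.

Simulates a fiber whose mitochondria are 30% transverse (perpendicular to
the fiber axis) and 70% longitudinal, then runs the full Gabor pipeline:
36-filter bank, per-pixel maximal response, fiber segmentation, cell
main-axis estimate and the axis-relative orientation histogram.
"""

from fibermito import analyze_fiber_orientation
from fibermito.synthetic import FiberSimParams, simulate_fiber_stack

params = FiberSimParams(
    transverse_fraction=0.30, fiber_axis_deg=57.0, mix_assignment="stratified", seed=7
)
stack, _, truth = simulate_fiber_stack(params)

result = analyze_fiber_orientation(stack.voxels, n_bins=3)

print(f"estimated fiber axis: {result.fiber_axis:.1f} deg (true {params.fiber_axis_deg} deg)")
print("relative-orientation histogram (3 bins over 0-90 deg):")
for lo, hi, pct in zip(
    result.histogram.bin_edges[:-1], result.histogram.bin_edges[1:],
    result.histogram.percent_per_bin,
):
    print(f"  {lo:4.0f}-{hi:3.0f} deg : {pct:5.1f} %")
print(f"longitudinal (<30 deg): {result.percent_longitudinal:.1f} %")
print(f"transverse  (>=60 deg): {result.percent_transverse:.1f} %")
print(f"ground truth transverse objects: {100 * truth['is_transverse'].mean():.1f} %")
# A shift of histogram mass from bin 0 toward 90 deg is the signature of the
# striated, transversely-oriented mitochondrial arrangement.
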