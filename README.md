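# fibermito

Quantitative image analysis of mitochondria in skeletal muscle fibers:
3D morphometry of the mitochondrial network, per-pixel texture orientation
relative to the fiber axis, SR–mitochondria contact scoring on EM-style
traced scenes, and ratiometric Ca²⁺ trace metrics — plus a ground-truthed
synthetic-data generator that makes the whole chain testable without
microscope data.

It is written for muscle and mitochondria labs that quantify aging- or
disease-related remodeling of the mitochondrial network: fragmentation vs
fusion (object count and size), the shift between longitudinal and
transverse (striated) mitochondrial orientation, junctional-SR tethering,
and mitochondrial Ca²⁺ handling.

## What it computes

**3D morphometry** (`fibermito.morphometry3d`). A confocal stack is
optionally deconvolved by projected Landweber iterations
x_{k+1} = clip₊(x_k + τ·Hᵀ(y − H x_k)) with a known PSF H, thresholded
(numeric, Otsu, or sparse-foreground iterated Otsu), and contiguous voxels
are grouped into objects under 6/18/26-connectivity. Reported: object count
N, per-object volumes, total volume V (voxels and µm³), and average size
V/N.

**Orientation** (`fibermito.orientation`). A bank of 36 real Gabor filters —
6 orientations θ ∈ {0°, 30°, …, 150°} × 6 scales σx ∈ {0.1, …, 5.1} px,
σy = σx/γ with γ = 0.5, λ = 4σx — filters the max-intensity projection; at
each pixel the maximal |response| selects the fiber mask and the pixel's
orientation. The fiber main axis is the principal axis of the cell outline
(second central moments); per-pixel relative angles Δθ = fold(θ_pixel −
θ_axis) ∈ [0°, 90°] are histogrammed (3 or 8 bins), and the
longitudinal/transverse split is Δθ < 30° vs Δθ ≥ 60°.

**SR–mitochondria contacts** (`fibermito.em`). On calibrated traced
contours: counts per reference area (98 µm² default), per-object areas,
density (mito area / fiber area), tether detection at a boundary gap
≤ 50 nm, and the jSR interface as % of mitochondrial perimeter within that
gap (5 nm boundary resampling).

**Ca²⁺ traces** (`fibermito.calcium`). Pre-stimulus baseline subtraction,
ROI means, the 490/420 excitation ratio (or F/F₀ for single dyes), resting
level, stimulus-evoked peak amplitude and time to peak, with k·SD detection
(k = 3).

See `docs/methods.md` for models, defaults and numerical choices.

## Worked example

Simulate a fiber whose mitochondria are 30% transverse and recover that
fraction with the full orientation pipeline (`examples/03_orientation_analysis.py`):

```python
from fibermito import analyze_fiber_orientation
from fibermito.synthetic import FiberSimParams, simulate_fiber_stack

params = FiberSimParams(
    transverse_fraction=0.30, fiber_axis_deg=57.0, mix_assignment="stratified", seed=7
)
stack, _, truth = simulate_fiber_stack(params)
result = analyze_fiber_orientation(stack.voxels, n_bins=3)
```

This prints:

```
estimated fiber axis: 57.1 deg (true 57.0 deg)
relative-orientation histogram (3 bins over 0-90 deg):
     0- 30 deg :  71.0 %
    30- 60 deg :   0.0 %
    60- 90 deg :  29.0 %
longitudinal (<30 deg): 71.0 %
transverse  (>=60 deg): 29.0 %
ground truth transverse objects: 30.0 %
```

The estimated cell axis matches the generator's 57°; 29.0% of fiber pixels
are classified perpendicular to it, against a ground truth of 30% transverse
mitochondria — the remaining percent is per-pixel assignment noise at the
object tips.

The other examples follow the same pattern, one per capability:
`01_count_mitochondria_3d.py` (exact object-count and volume recovery on a
50-object stack), `02_deconvolve_stack.py` (monotone Landweber residuals),
`04_sr_mito_contacts.py` (pair flags and interface percentages vs analytic
truth), `05_calcium_transients.py` (resting/amplitude recovery), and
`06_group_pipeline.py` (the per-group mean ± SD summary table).

## Command line

A thin CLI wraps the library:

```bash
fibermito simulate fiber --seed 1 --out sim/            # + em | trace
fibermito morpho3d sim/intensity.tif --threshold otsu --connectivity 26 --out m/
fibermito orient sim/intensity.tif --bins 3 --out o/
fibermito em scene.json --gap 50 --ref-area 98 --out e/
fibermito calcium trace.csv --stimulus 60 --out c/
fibermito run --config pipeline.yaml                    # full simulated pipeline
```

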