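# Methods

`fibermito` quantifies mitochondrial organization in skeletal muscle fibers
from three kinds of input — confocal-like 3D stacks, EM-style traced 2D
scenes, and two-channel ratiometric Ca²⁺ records — and ships a synthetic-data
generator that produces all three with known ground truth, so every stage of
the analysis is testable end to end without microscope data. This note
documents the models, the parameters that matter, the numerical choices, and
what the synthetic benchmarks do and do not demonstrate.

## 3D morphometry (`fibermito.morphometry3d`)

The measurement chain is deconvolve → threshold → label → count:

* **Projected Landweber deconvolution.** With `H` the convolution by a
  known, sum-normalized PSF, iterates
  `x_{k+1} = clip_{≥0}(x_k + τ·Hᵀ(y − H x_k))`. The default step is
  `τ = 1 / max|FFT(psf)|²` — the classical convergent choice, equal to 1.0
  for any non-negative sum-1 PSF; a rule based on the sum of squared kernel
  *voxel* values would exceed the stability bound `2/‖H‖²` for any spread-out
  PSF and diverge. Non-negativity is projected each iterate because
  fluorescence is non-negative; with `τ ≤ 1/‖H‖²` the residual norm
  `‖y − H x_k‖` is non-increasing, which the tests assert. Divergence
  (residual growing 10× over its initial value, possible with a user-chosen
  step) raises an error naming the step. Default 25 iterations. The PSF is a
  configurable Gaussian, xy-isotropic and z-elongated (defaults σ = 0.2 µm
  lateral, 0.6 µm axial), built by `gaussian_psf`.
* **Thresholding.** `voxels > t` with `t` numeric, `"otsu"`, or `"otsu2"`.
  Otsu's criterion is the reproducible stand-in for a manual, blinded
  threshold. Single-stage Otsu fails when foreground occupies ≲1% of the
  volume (the between-class criterion then prefers a cut inside the
  background noise); `"otsu2"` reapplies Otsu to the tail above the previous
  cut until the foreground is sparse (<5% of the volume, at most 8 rounds) —
  appropriate for organelle stacks, wrong for balanced scenes, hence an
  explicit mode. All-background or all-foreground results set warning flags.
* **Labeling.** Contiguous foreground voxels are grouped by
  `scipy.ndimage.label` under 6-, 18- or 26-connectivity (default 26, the 3D
  object-counter convention) and relabelled consecutively in raster-scan
  order of each object's first voxel. An independent BFS flood-fill oracle in
  the tests checks exact agreement on random volumes. An optional
  `min_voxels` filter (default 0; the benchmarks use 20) rejects noise
  clusters; true objects are two orders of magnitude larger.
* **Statistics.** Object count; per-object voxel counts; total volume
  (= foreground voxel count, conserved exactly); mean volume = total/count,
  reported in voxels and in µm³ (voxel volume from the (z, y, x) calibration).
  An empty labeling reports `None` for the mean, never zero.

## Texture orientation (`fibermito.orientation`)

Mitochondrial orientation is measured per pixel on a single plane — by
default the maximum-intensity z-projection, appropriate for thin fibers —
with a Gabor filter bank: 6 stripe orientations (0°…150° in 30° steps) × 6
scales (σx = 0.1, 1.1, …, 5.1 px), γ = 0.5 (so σy = 2σx along the stripes),
carrier wavelength λ = 4σx, phase 0 (real, even-symmetric kernels), sampled
on a support capturing 3σ (minimum 3×3) and L2-normalized so responses are
comparable across scales. Responses are absolute-valued (stripe polarity is
irrelevant); at each pixel the maximal response over all 36 filters selects
the winning filter, whose orientation becomes the pixel's orientation; exact
ties resolve to the lowest filter index. The σx = 0.1 px scale yields a
near-delta kernel and never wins in practice, but is kept for fidelity to
the published bank. The kernels retain their DC component (a plain
windowed cosine): an exactly uniform image is rejected explicitly as
having no structure, and near-uniform images are a documented limitation
(the response falls off only at the frame border).

The fiber mask is `max_response > t`. The default mode `"otsu2"` (Otsu
applied again above the first Otsu cut) matters: the maximum-response
histogram is trimodal — background noise, a *filter halo* extending ~σy
beyond each object, and on-structure responses — and a single Otsu keeps a
halo ~2× the structure area whose orientations are uninformative and bias
the orientation statistics.

The **fiber main axis** is the principal axis (largest-eigenvalue
eigenvector of the second central moments, folded to [0°, 180°)) of the
*cell* mask. The cell outline is what must be measured — the principal axis
of the raw mitochondrial texture mask is biased by the orientation mixture
itself (errors above 20° in mixed fibers). When no independent cell
segmentation exists, `estimate_cell_mask` approximates the outline as the
convex hull of the fiber mask. Nearly isotropic masks (eigenvalue ratio
< 1.05) trigger a warning; the angle is still returned.

**Relative orientation**: per masked pixel, Δθ = pixel orientation − axis,
folded into [0°, 90°] (orientations are axial). The histogram uses 3 or 8
equal-width bins of [0°, 90°], in percent of masked pixels (pixel weighting,
not object weighting). The longitudinal/transverse split cuts at 30°/60°:
with a 6-orientation bank relative angles quantize near {0, 30, 60, 90}°, so
Δθ < 30° is "same orientation as the cell" and Δθ ≥ 60° "perpendicular";
the split is computed from the exact discrete angle masses, not from the
binned histogram, so it is identical for 3 and 8 bins.

## EM morphometry and SR–mitochondria contacts (`fibermito.em`)

Input is contour-based — closed mitochondrial polygons, open/closed jSR
polylines and a fiber-region polygon in pixel coordinates with an nm/px
calibration — matching what an analyst traces on micrographs; a
labeled-mask importer (`contours_from_labels`) is provided. Geometry is
delegated to shapely:

* counts normalized to a reference fiber area (default 98 µm²);
* per-object cross-section areas (shoelace × nm²/px²) and their mean;
* density = Σ mitochondrial area / fiber area (dimensionless);
* a (mito, jSR) **pair** iff the minimum boundary-to-boundary distance is
  ≤ the gap threshold (default 50 nm, the accepted tether criterion). A jSR
  element may pair with several mitochondria and vice versa; `n_pairs`
  counts distinct pairs, and `percent_paired` — the fraction of mitochondria
  with ≥1 partner — is the primary statistic (the denominator convention is
  a package choice and is stated on the result);
* **interface fraction**: the mitochondrial boundary is resampled at a fixed
  arc-length step (default 5 nm) and the fraction of samples within the gap
  threshold of any jSR polyline is reported as % of perimeter. The sampling
  error is bounded by one step; halving the step changes smooth scenes by
  < 1 percentage point (asserted in tests). Degenerate (zero-area) polygons
  are rejected.
* SSM/IMF classification: a mitochondrion whose boundary lies within 500 nm
  of the fiber-region boundary is sub-sarcolemmal, else intermyofibrillar.
  The numeric rule is a package convention, exposed as a parameter.

Both the pair flags and the interface fractions are verified in the tests
against dense brute-force oracles (1 nm boundary sampling with exact
point-to-segment distances).

## Ratiometric Ca²⁺ traces (`fibermito.calcium`)

Records are two-channel (490 and 420 nm excitation) ROI-mean series at a
2 s default frame interval; the signal is the 490/420 ratio. Cytosolic
single-dye records reuse the machinery via F/F₀ (`dff_trace`), with F₀ the
pre-stimulus mean. Components:

* `baseline_subtract`: per-channel (or per-pixel, in image mode) subtraction
  of the pre-stimulus mean; the window must be nonempty and precede the
  stimulus.
* `roi_means`: per-frame means over 3–6 ROI masks; the cell trace is their
  mean.
* `compute_ratio`: 490/420, gain-invariant by construction; samples with a
  denominator below a floor are masked (NaN) with a warning.
* `transient_metrics`: resting level = mean ratio over the pre-stimulus
  window; the peak is read from a lightly smoothed copy of the trace
  (centered moving average, default 3 frames; window 1 disables) searched
  after the stimulus; amplitude = peak − resting; detected iff amplitude
  > k × raw pre-stimulus SD (k = 3 default).

The 3-frame smoothing is deliberate: the raw maximum of ~270 noisy
post-stimulus frames is an extreme-value statistic, biased upward by
≈ 2.5σ of the noise under the null — enough to break both amplitude
recovery (bias ≫ 2%) and detection calibration (false-positive rate ~30%
at k = 3). With the default transient kinetics (rise 10 s, decay 60 s,
2 s frames) the smoothing attenuates a true peak by ~0.3%, while the null
false-detection rate drops to ~10⁻⁵ (the smoothed max needs a ≈ 5.2σ
noise excursion); the Monte-Carlo null test bounds it at ≤ 1%.

## Synthetic data (`fibermito.synthetic`)

The generators define the package's study conditions; every default below
is a package choice, fixed once, and all outputs are bit-reproducible given
identical parameters and seed.

**Fiber stacks.** 45 z-slices at 1 µm spacing, 320×320 px at 0.2 µm/px
(a 60×-objective-like sampling). The cell is an ellipse along the fiber
axis (semi-axes 0.45 and 0.18 of the frame side, i.e. a ≈ 58 × 23 µm
outline) — elongated and fully in frame so its main axis is well defined.
Mitochondria are triaxial ellipsoids rotated in the imaging plane only
(the orientation analysis is per-pixel and 2D): default 10 objects of mean
volume 600 voxels (≈ 9.6 × 2.4 × 2 µm at default calibration, a fused-like
morphology), lognormal volumes with CV 0.3 truncated at 1.8× the mean
(overlong objects cannot sit transverse inside the cell width, which would
couple size to orientation), in-plane aspect ratio 4, z semi-axis 1 voxel.
The object scale is chosen so the projected stripe widths and lengths sit
inside the operating range of the bank's fixed pixel-unit scales (λ up to
20.4 px); the selection diagnostic was class-conditional per-pixel
assignment accuracy on object pixels (~100% at these defaults), not any
published group value. In-plane long-axis angles are drawn from the
orientation mixture — independently per object by default, or with
randomized-rounding quotas (`mix_assignment="stratified"`, exact expectation,
lower Monte-Carlo variance) in benchmark protocols. Objects are placed
largest-first by rejection sampling, disjoint in z-projection with a 2 px
margin (so the projected texture has one orientation per pixel); pure-3D
disjointness is available (`disjoint_in_projection=False`) for dense
morphometry stacks. Placement failure raises an explicit capacity error.
Rendering: binary ellipsoids at intensity 1, optional Gaussian PSF blur
(0.2/0.6 µm), additive Gaussian noise with SD = (mean foreground
intensity)/SNR (SNR default 10; the acquisition noise level is not published
and is a package choice), clipped at 0.

**EM scenes.** Vector scenes at 2 nm/px; mitochondria are rotated rectangles
with 300–600 nm sides, placed with ≥ 400 nm mutual clearance inside a fiber
region covering 90% of the frame; each jSR cisterna is a straight segment
parallel to one edge of its partner mitochondrion, centered, 60% of the edge
length, at a prescribed minimum boundary gap (drawn uniformly from
10–150 nm when not given). This construction has closed-form truth: pair
flag = (gap ≤ 50 nm); the boundary length within 50 nm of a segment of
length L at gap g is L + 2·√(50² − g²) (never reaching the corners at these
proportions), so the true interface percentage is analytic. The clearance
guarantees a jSR can only tether its constructed partner.

**Traces.** 280 frames × 2 s; stimulus at frame 30; ratio(t) = resting +
A·s(t−t₀) with s the unit-peak kinetic form (1 − e^(−t/τ_rise))·e^(−t/τ_decay),
τ_rise = 10 s, τ_decay = 60 s; A (default 0.5) is therefore the true peak
height, and the peak time has the closed form τ_r·ln(1 + τ_d/τ_r). The
420 nm channel is a constant (100); noise with SD 0.01 enters the 490 nm
channel so the measured ratio is the true ratio plus exactly that noise.

**What the benchmarks show — and don't.** Passing recovery tests shows the
analysis chain is internally consistent: it recovers what the stylized
generator encodes, at realistic noise. The generator does **not** emulate
photobleaching, depth-dependent aberrations, anisotropic or correlated
noise, touching/branching mitochondrial networks, curved fibers,
non-rectangular organelle shapes, SR geometry beyond straight cisternae, or
motion; performance on real micrographs therefore still depends on
acquisition quality and segmentation choices (above all the thresholds,
which the original workflow set manually and blinded).

## Benchmark protocols and problem sizes (`fibermito.protocols`)

* **Orientation recovery**: 96 fibers per setting (each with a uniformly
  random fiber axis, stratified mixture assignment, all other generator
  defaults), full pipeline, mean of the per-fiber recovered transverse
  percentage. At 96 fibers the standard error is ≈ 0.7 points. The same
  routine drives `scripts/acceptance.py`.
* **Morphometry recovery**: 20 stacks of 50 objects (mean 150 voxels,
  32×144×144, unblurred, 3D-disjoint, whole-frame placement), Otsu
  threshold, 26-connectivity, 20-voxel minimum size. Unblurred stacks are
  used so the rendered voxel count is a well-defined target for a global
  threshold; the deconvolution operator is validated separately (monotone
  residual, delta-PSF identity).
* **Ca²⁺ calibration**: 100 traces for estimator bias, 1000 null traces for
  the false-detection rate.

These sizes keep the full suite and the reproduction script to a few
minutes on one CPU core while holding Monte-Carlo error well inside the
stated tolerances.

## Pipeline and reporting (`fibermito.pipeline`)

`run_pipeline` executes the selected stages per simulated fiber per group,
with per-fiber seeds derived from (master seed, group index, fiber index,
stream) via `numpy.random.SeedSequence`, so reruns are byte-identical and
adding a stage does not reshuffle another stage's data. Group summaries
report mean, SD (sample, n−1 denominator; a single-record group reports
SD 0 with a flag) and n per metric — tidy tables meant to feed any stats
package; the pipeline deliberately performs no hypothesis testing. Every
output carries a provenance header (package version, config hash, seed).
Configurations round-trip through YAML/JSON and reject unknown keys.

## Known limitations

* Per-pixel orientation is quantized to the 6 bank angles; mixtures
  containing oblique (30–60°) populations land in the middle of the folded
  histogram and the longitudinal/transverse split does not resolve them.
* The convex-hull cell outline assumes a convex cell footprint; strongly
  curved fibers need an explicit cell mask.
* `"otsu2"` thresholding presumes sparse foreground; use `"otsu"` or a
  numeric threshold for balanced images.
* The EM interface measure is sampling-based (bounded by one boundary
  step), not an exact arc-length computation.
* Gap measurements are boundary-to-boundary in 2D projection, as in
  section-based electron microscopy; no 3D contact-site reconstruction.
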