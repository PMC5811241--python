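"""Per-pixel texture orientation of mitochondria relative to the fiber axis.

A bank of real, even-symmetric Gabor filters (6 orientations × 6 scales by
default, γ = 0.5, λ = 4σx) is applied to a single plane (by default the
maximum-intensity z-projection of the stack). At each pixel the maximal
absolute response over the 36 filters selects both the fiber mask (after
thresholding the maximum-response image) and the pixel's orientation — the
orientation of the winning filter. Orientations are axial (period 180°);
relative orientation folds the difference to the estimated fiber main axis
into [0°, 90°], and the longitudinal/transverse split cuts that range at
30° and 60° (with a 6-orientation bank, relative angles quantize to
{0, 30, 60, 90}°, so bin 0 alone is "same orientation as the cell" and the
folded bins ≥ 60° are "perpendicular").

Angles are measured in the image plane from the +x (column) axis toward the
+y (row) axis, in degrees.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve
from skimage.filters import threshold_otsu

__all__ = [
    "GaborBankConfig",
    "GaborKernel",
    "OrientationMap",
    "OrientationHistogram",
    "EmptySegmentationError",
    "DegenerateAxisWarning",
    "build_gabor_bank",
    "orientation_map",
    "estimate_fiber_axis",
    "relative_orientation_histogram",
    "longitudinal_transverse_fractions",
]

LONGITUDINAL_CUT_DEG = 30.0
TRANSVERSE_CUT_DEG = 60.0


class EmptySegmentationError(RuntimeError):
    """No pixel exceeded the fiber threshold."""


class DegenerateAxisWarning(UserWarning):
    """The mask is nearly isotropic; the main axis is ill-determined."""


@dataclass
class GaborBankConfig:
    """Filter-bank parameters.

    ``orientations`` are stripe directions in degrees; each filter's Gaussian
    envelope has σx along the oscillation axis and σy = σx/γ along the
    stripes, with carrier wavelength λ = ``lambda_factor``·σx.
    """

    orientations: tuple[float, ...] = (0.0, 30.0, 60.0, 90.0, 120.0, 150.0)
    sigmas_x: tuple[float, ...] = (0.1, 1.1, 2.1, 3.1, 4.1, 5.1)
    gamma: float = 0.5
    lambda_factor: float = 4.0
    phase: float = 0.0

    def validate(self) -> None:
        if any(s <= 0 for s in self.sigmas_x):
            raise ValueError("all sigmas_x must be > 0")
        if self.gamma <= 0 or self.lambda_factor <= 0:
            raise ValueError("gamma and lambda_factor must be > 0")

    @property
    def size(self) -> int:
        return len(self.orientations) * len(self.sigmas_x)


@dataclass
class GaborKernel:
    theta_deg: float
    sigma_x: float
    array: np.ndarray


def _gabor_kernel(theta_deg: float, sigma_x: float, cfg: GaborBankConfig) -> np.ndarray:
    sigma_y = sigma_x / cfg.gamma
    lam = cfg.lambda_factor * sigma_x
    half = max(int(math.ceil(3.0 * max(sigma_x, sigma_y))), 1)
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1].astype(float)
    # wave vector perpendicular to the stripe direction theta
    phi = math.radians(theta_deg + 90.0)
    u = xx * math.cos(phi) + yy * math.sin(phi)  # oscillation axis
    v = -xx * math.sin(phi) + yy * math.cos(phi)  # along the stripes
    k = np.exp(-0.5 * ((u / sigma_x) ** 2 + (v / sigma_y) ** 2)) * np.cos(
        2.0 * math.pi * u / lam + cfg.phase
    )
    return k / np.linalg.norm(k)


def build_gabor_bank(config: GaborBankConfig | None = None) -> list[GaborKernel]:
    """Build the |orientations| × |sigmas_x| bank (36 kernels at defaults).

    Kernels are real and even-symmetric (cosine carrier, phase 0), sampled on
    a square support capturing 3σ (minimum 3×3) and normalized to unit L2
    norm so responses are comparable across scales.
    """
    cfg = config or GaborBankConfig()
    cfg.validate()
    return [
        GaborKernel(theta, sx, _gabor_kernel(theta, sx, cfg))
        for theta in cfg.orientations
        for sx in cfg.sigmas_x
    ]


@dataclass
class OrientationMap:
    """Per-pixel maximal Gabor response and winning orientation."""

    max_response: np.ndarray
    orientation_index: np.ndarray
    fiber_mask: np.ndarray
    orientations: tuple[float, ...]
    threshold: float = 0.0

    def masked_angles(self) -> np.ndarray:
        """In-plane orientation (degrees) of every fiber pixel."""
        return np.asarray(self.orientations, dtype=float)[self.orientation_index[self.fiber_mask]]


def orientation_map(
    image: np.ndarray,
    bank: list[GaborKernel] | None = None,
    fiber_threshold: float | str = "otsu",
) -> OrientationMap:
    """Filter with the whole bank and keep the per-pixel maximal response.

    The absolute value of each response is taken before the maximum so stripe
    polarity (bright mitochondria on dark background or the reverse) is
    irrelevant. Ties at the maximum resolve to the lowest filter index. The
    fiber mask is ``max_response > fiber_threshold``; the threshold may be
    numeric, ``"otsu"`` (Otsu's criterion on the maximum-response image) or
    ``"otsu2"`` (Otsu applied again above the first cut — the maximum-response
    histogram is typically trimodal with background, filter halo and true
    structure, and the two-stage cut discards the halo).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("orientation analysis expects a single 2D plane")
    if np.ptp(image) == 0:  # no contrast: nothing can respond above threshold
        raise EmptySegmentationError("uniform image; no fiber structure to segment")
    if bank is None:
        bank = build_gabor_bank()
    orientations = tuple(dict.fromkeys(k.theta_deg for k in bank))
    n_scales = len(bank) // len(orientations)

    responses = np.empty((len(bank),) + image.shape)
    for i, k in enumerate(bank):
        responses[i] = np.abs(fftconvolve(image, k.array, mode="same"))
    max_response = responses.max(axis=0)
    winner = responses.argmax(axis=0)  # first (lowest-index) maximum wins
    orientation_index = winner // n_scales

    if isinstance(fiber_threshold, str):
        if fiber_threshold not in ("otsu", "otsu2"):
            raise ValueError(f"unknown fiber_threshold mode {fiber_threshold!r}")
        if np.ptp(max_response) == 0:  # constant response: nothing to segment
            raise EmptySegmentationError("uniform response image; no fiber structure")
        thr = float(threshold_otsu(max_response))
        if fiber_threshold == "otsu2":
            tail = max_response[max_response > thr]
            if tail.size > 1 and np.ptp(tail) > 0:
                thr = float(threshold_otsu(tail))
    else:
        thr = float(fiber_threshold)
    fiber_mask = max_response > thr
    if not fiber_mask.any():
        raise EmptySegmentationError("no pixel exceeded the fiber threshold")
    return OrientationMap(
        max_response=max_response,
        orientation_index=orientation_index.astype(np.int16),
        fiber_mask=fiber_mask,
        orientations=orientations,
        threshold=thr,
    )


def estimate_fiber_axis(cell_mask: np.ndarray, degenerate_ratio: float = 1.05) -> float:
    """Main axis of a binary cell mask from second central moments.

    Returns the angle (degrees, folded to [0, 180)) of the largest-variance
    eigenvector of the pixel coordinate covariance. A nearly isotropic mask
    (eigenvalue ratio below ``degenerate_ratio``) raises
    :class:`DegenerateAxisWarning` but the angle is still returned.
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    rows, cols = np.nonzero(cell_mask)
    if rows.size == 0:
        raise ValueError("cell mask is empty")
    x = cols - cols.mean()
    y = rows - rows.mean()
    cxx, cyy, cxy = (x * x).mean(), (y * y).mean(), (x * y).mean()
    cov = np.array([[cxx, cxy], [cxy, cyy]])
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] > 0 and evals[1] / max(evals[0], 1e-12) < degenerate_ratio:
        warnings.warn(
            "mask is nearly isotropic; fiber axis is ill-determined",
            DegenerateAxisWarning,
            stacklevel=2,
        )
    vx, vy = evecs[:, 1]  # eigenvector of the largest eigenvalue
    return float(math.degrees(math.atan2(vy, vx)) % 180.0)


def _fold_to_quadrant(delta_deg: np.ndarray) -> np.ndarray:
    d = np.mod(delta_deg, 180.0)
    return np.minimum(d, 180.0 - d)


@dataclass
class OrientationHistogram:
    """Axis-relative orientation distribution of fiber pixels.

    ``percent_per_bin`` are percentages of masked pixels over ``n_bins``
    equal-width bins of the folded relative angle range [0°, 90°]; bin 0
    contains relative angle 0. ``angle_values``/``angle_percents`` keep the
    exact discrete distribution over the (few) distinct relative angles the
    bank can produce, which the longitudinal/transverse split uses directly.
    """

    n_bins: int
    bin_edges: np.ndarray
    percent_per_bin: np.ndarray
    fiber_axis: float
    angle_values: np.ndarray = field(default_factory=lambda: np.array([]))
    angle_percents: np.ndarray = field(default_factory=lambda: np.array([]))


def relative_orientation_histogram(
    omap: OrientationMap, fiber_axis: float, n_bins: int = 3
) -> OrientationHistogram:
    """Histogram of per-pixel orientation relative to the fiber main axis.

    Pixel orientations are axial, so the difference to the fiber axis is
    folded into [0°, 90°] and binned into 3 or 8 equal-width bins expressed
    as percent of masked pixels.
    """
    if n_bins not in (3, 8):
        raise ValueError("n_bins must be 3 or 8")
    angles = omap.masked_angles()
    if angles.size == 0:
        raise EmptySegmentationError("orientation map has an empty fiber mask")
    rel = _fold_to_quadrant(angles - fiber_axis)
    edges = np.linspace(0.0, 90.0, n_bins + 1)
    idx = np.clip(np.digitize(rel, edges[1:-1], right=False), 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    percents = 100.0 * counts / counts.sum()
    vals, vcounts = np.unique(np.round(rel, 9), return_counts=True)
    return OrientationHistogram(
        n_bins=n_bins,
        bin_edges=edges,
        percent_per_bin=percents,
        fiber_axis=float(fiber_axis % 180.0),
        angle_values=vals,
        angle_percents=100.0 * vcounts / vcounts.sum(),
    )


def longitudinal_transverse_fractions(hist: OrientationHistogram) -> tuple[float, float]:
    """Percent of fiber pixels longitudinal (Δθ < 30°) and transverse (Δθ ≥ 60°)."""
    longitudinal = float(hist.angle_percents[hist.angle_values < LONGITUDINAL_CUT_DEG].sum())
    transverse = float(hist.angle_percents[hist.angle_values >= TRANSVERSE_CUT_DEG].sum())
    return longitudinal, transverse


def estimate_cell_mask(fiber_mask: np.ndarray) -> np.ndarray:
    """Approximate the complete-cell outline as the convex hull of the fiber
    mask. The main-axis estimate must see the cell shape, not the mitochondrial
    texture: the principal axis of the raw mask is biased by the orientation
    mixture itself."""
    from skimage.morphology import convex_hull_image

    return convex_hull_image(np.asarray(fiber_mask, dtype=bool))


@dataclass
class FiberOrientationResult:
    """End-to-end per-fiber orientation summary."""

    omap: OrientationMap
    fiber_axis: float
    histogram: OrientationHistogram
    percent_longitudinal: float
    percent_transverse: float


def analyze_fiber_orientation(
    stack_or_image: np.ndarray,
    bank: list[GaborKernel] | None = None,
    n_bins: int = 3,
    fiber_threshold: float | str = "otsu2",
) -> FiberOrientationResult:
    """Full orientation pipeline on a stack (max z-projection) or a 2D plane.

    Runs the filter bank, segments fiber pixels, estimates the cell main axis
    from the convex hull of the fiber mask, builds the axis-relative histogram
    and reports the longitudinal/transverse percentages.
    """
    plane = max_projection(stack_or_image)
    omap = orientation_map(plane, bank=bank, fiber_threshold=fiber_threshold)
    axis = estimate_fiber_axis(estimate_cell_mask(omap.fiber_mask))
    hist = relative_orientation_histogram(omap, axis, n_bins=n_bins)
    lo, tr = longitudinal_transverse_fractions(hist)
    return FiberOrientationResult(
        omap=omap,
        fiber_axis=axis,
        histogram=hist,
        percent_longitudinal=lo,
        percent_transverse=tr,
    )


def max_projection(voxels: np.ndarray) -> np.ndarray:
    """Maximum-intensity z-projection, the default input plane."""
    voxels = np.asarray(voxels)
    if voxels.ndim == 2:
        return voxels
    if voxels.ndim != 3:
        raise ValueError("expected a 2D image or a 3D (z, y, x) stack")
    return voxels.max(axis=0)
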