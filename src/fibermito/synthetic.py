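"""Ground-truthed synthetic data for every analysis stage.

Three generators emulate the study conditions the analyses assume, so the
whole pipeline is testable without microscope data:

* :func:`simulate_fiber_stack` — a confocal-like 3D stack of a muscle fiber
  containing disjoint ellipsoidal mitochondria whose in-plane long axes are
  drawn from a controllable orientation mixture, with optional Gaussian PSF
  blur and Gaussian noise at a stated SNR.
* :func:`simulate_em_scene` — a calibrated 2D vector scene of mitochondrion
  and junctional-SR contours at prescribed boundary gaps, with analytic
  ground truth for pair flags and interface fractions at the 50 nm criterion.
* :func:`simulate_trace` — a two-channel (490/420 nm excitation) ratiometric
  Ca²⁺ record with a resting level and an ATP-evoked transient of unit-peak
  double-exponential kinetics.

All generators are bit-reproducible given identical parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .morphometry3d import ImageStack, LabeledStack

__all__ = [
    "CapacityError",
    "FiberSimParams",
    "EMSimParams",
    "TraceSimParams",
    "simulate_fiber_stack",
    "simulate_em_scene",
    "simulate_trace",
]

#: gap (nm) at or below which a jSR cisterna counts as tethered to a mitochondrion
CONTACT_GAP_NM = 50.0


class CapacityError(RuntimeError):
    """Raised when disjoint object placement fails within the retry budget."""


def _fold_axial(angle_deg: np.ndarray | float) -> np.ndarray | float:
    """Fold an axial (period-180°) angle difference into [0, 90]."""
    d = np.mod(angle_deg, 180.0)
    return np.minimum(d, 180.0 - d)


# ---------------------------------------------------------------------------
# 3D fiber stacks
# ---------------------------------------------------------------------------


@dataclass
class FiberSimParams:
    """Conditions for a simulated muscle-fiber stack.

    Mitochondria are triaxial ellipsoids rotated in the imaging plane only
    (orientation analysis is per-pixel and 2D). ``orientation_mix`` lists
    absolute in-plane angles with weights; ``transverse_fraction`` is a
    convenience override placing that mass at ``fiber_axis_deg + 90°`` and the
    rest along the fiber axis. Objects are placed inside an elongated
    elliptical cell region whose long axis is the fiber axis, and are pairwise
    disjoint in z-projection, so the projected texture has a well-defined
    per-pixel orientation and the cell outline has a well-defined main axis.
    """

    n_mito: int = 10
    mean_volume_vox: float = 600.0
    volume_cv: float = 0.3
    fiber_axis_deg: float = 25.0
    orientation_mix: list[tuple[float, float]] | None = None
    transverse_fraction: float | None = None
    stack_shape: tuple[int, int, int] = (45, 320, 320)
    voxel_size: tuple[float, float, float] = (1.0, 0.2, 0.2)
    snr: float = 10.0
    seed: int = 0
    #: "random" draws each object's mixture component independently;
    #: "stratified" fixes per-component counts at n*weight with randomized
    #: rounding (exact expectation, low Monte-Carlo variance for benchmarks)
    mix_assignment: str = "random"
    # geometry / rendering choices (package defaults, see docs/methods.md)
    aspect_ratio: float = 4.0
    z_semiaxis_vox: float = 1.0
    apply_psf: bool = True
    psf_sigma_xy_um: float = 0.2
    psf_sigma_z_um: float = 0.6
    placement_margin_px: int = 2
    #: if True (default) objects are pairwise disjoint in z-projection — the
    #: regime the per-pixel 2D orientation analysis assumes; if False only 3D
    #: disjointness is enforced (denser stacks for pure 3D morphometry runs)
    disjoint_in_projection: bool = True
    cell_semi_long_frac: float = 0.45
    cell_semi_short_frac: float = 0.18
    max_retries: int = 5000

    def cell_mask(self) -> np.ndarray:
        """Ground-truth 2D cell region: an ellipse along the fiber axis."""
        _, ny, nx = self.stack_shape
        s = min(ny, nx)
        a = self.cell_semi_long_frac * s
        b = self.cell_semi_short_frac * s
        th = math.radians(self.fiber_axis_deg)
        yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
        dx, dy = xx - nx / 2.0, yy - ny / 2.0
        u = dx * math.cos(th) + dy * math.sin(th)
        v = -dx * math.sin(th) + dy * math.cos(th)
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0

    def resolved_mix(self) -> list[tuple[float, float]]:
        if self.transverse_fraction is not None:
            p = float(self.transverse_fraction)
            if not 0.0 <= p <= 1.0:
                raise ValueError("transverse_fraction must be in [0, 1]")
            return [
                (self.fiber_axis_deg % 180.0, 1.0 - p),
                ((self.fiber_axis_deg + 90.0) % 180.0, p),
            ]
        if self.orientation_mix is None:
            return [(self.fiber_axis_deg % 180.0, 1.0)]
        return [(float(a) % 180.0, float(w)) for a, w in self.orientation_mix]

    def validate(self) -> None:
        if self.n_mito < 0:
            raise ValueError("n_mito must be >= 0")
        if self.mean_volume_vox <= 0 or self.volume_cv < 0:
            raise ValueError("mean_volume_vox must be > 0 and volume_cv >= 0")
        if not (0.0 <= self.fiber_axis_deg < 180.0):
            raise ValueError("fiber_axis_deg must be in [0, 180)")
        mix = self.resolved_mix()
        weights = np.array([w for _, w in mix])
        if (weights < 0).any() or abs(weights.sum() - 1.0) > 1e-9:
            raise ValueError("orientation mixture weights must be >= 0 and sum to 1")
        if len(self.stack_shape) != 3 or min(self.stack_shape) < 1:
            raise ValueError("stack_shape must be (z, y, x) with all dims >= 1")
        if self.snr <= 0 and np.isfinite(self.snr):
            raise ValueError("snr must be positive (use inf for noise-free)")


def _ellipsoid_mask(a: float, b: float, c: float, theta_deg: float, ext_xy: int):
    """Boolean 3D mask of an in-plane-rotated triaxial ellipsoid, in a box of
    half-extents (ceil(c), ext_xy, ext_xy)."""
    th = math.radians(theta_deg)
    ez = int(math.ceil(c))
    zz, yy, xx = np.mgrid[-ez : ez + 1, -ext_xy : ext_xy + 1, -ext_xy : ext_xy + 1].astype(float)
    u = xx * math.cos(th) + yy * math.sin(th)
    v = -xx * math.sin(th) + yy * math.cos(th)
    mask = (u / a) ** 2 + (v / b) ** 2 + (zz / c) ** 2 <= 1.0
    return mask, ext_xy, ez


def _ellipse_footprint(a: float, b: float, theta_deg: float, margin: int = 0):
    """Boolean in-plane footprint of an ellipse (semi-axes a >= b, rotated by
    theta) optionally grown by ``margin`` pixels; returned with its half-size."""
    th = math.radians(theta_deg)
    ext = int(math.ceil(max(a, b) + margin)) + 1
    yy, xx = np.mgrid[-ext : ext + 1, -ext : ext + 1].astype(float)
    u = xx * math.cos(th) + yy * math.sin(th)
    v = -xx * math.sin(th) + yy * math.cos(th)
    fp = (u / (a + margin)) ** 2 + (v / (b + margin)) ** 2 <= 1.0
    return fp, ext


def simulate_fiber_stack(
    params: FiberSimParams,
) -> tuple[ImageStack, LabeledStack, pd.DataFrame]:
    """Render a ground-truthed fiber stack.

    Returns
    -------
    intensity : ImageStack
        Blurred (optional) and noisy stack, clipped at zero.
    labels : LabeledStack
        Ground-truth label volume, one label per mitochondrion.
    truth : pandas.DataFrame
        One row per object: label, rendered voxel volume, in-plane angle,
        angle relative to the fiber axis, transverse flag, mixture component.

    Raises
    ------
    CapacityError
        If disjoint placement of ``n_mito`` objects fails within the retry
        budget (``max_retries`` per object).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    nz, ny, nx = params.stack_shape
    labels = np.zeros(params.stack_shape, dtype=np.int32)
    cols = ["label", "volume_vox", "volume_um3", "angle_deg", "rel_angle_deg",
            "is_transverse", "component"]
    voxel_vol = float(np.prod(params.voxel_size))

    if params.n_mito == 0:
        intensity = _finish_intensity(labels, params, rng)
        return intensity, LabeledStack(labels, params.voxel_size), pd.DataFrame(columns=cols)

    mix = params.resolved_mix()
    angles_avail = np.array([a for a, _ in mix])
    weights = np.array([w for _, w in mix])
    weights = weights / weights.sum()
    if params.mix_assignment == "random":
        comp = rng.choice(len(mix), size=params.n_mito, p=weights)
    elif params.mix_assignment == "stratified":
        quota = weights * params.n_mito
        counts = np.floor(quota).astype(int)
        frac = quota - counts
        short = params.n_mito - counts.sum()
        if short > 0:  # randomized rounding keeps the expectation exact
            extra = rng.choice(len(mix), size=short, replace=False,
                               p=frac / frac.sum() if frac.sum() > 0 else None)
            counts[extra] += 1
        comp = rng.permutation(np.repeat(np.arange(len(mix)), counts))
    else:
        raise ValueError("mix_assignment must be 'random' or 'stratified'")

    sigma_ln = math.sqrt(math.log(1.0 + params.volume_cv**2))
    mu_ln = math.log(params.mean_volume_vox) - 0.5 * sigma_ln**2
    if sigma_ln > 0:
        volumes = rng.lognormal(mu_ln, sigma_ln, size=params.n_mito)
        # redraw extreme sizes: very long objects cannot sit transverse in the
        # cell width, which would couple size to orientation
        for _ in range(100):
            big = volumes > 1.8 * params.mean_volume_vox
            if not big.any():
                break
            volumes[big] = rng.lognormal(mu_ln, sigma_ln, size=int(big.sum()))
        volumes = np.minimum(volumes, 1.8 * params.mean_volume_vox)
    else:
        volumes = np.full(params.n_mito, params.mean_volume_vox)

    c = params.z_semiaxis_vox
    r = params.aspect_ratio
    if params.disjoint_in_projection:
        occupancy = np.zeros((ny, nx), dtype=bool)
    else:
        occupancy3d = np.zeros((nz, ny, nx), dtype=bool)
    cell = params.cell_mask()
    axis_th = math.radians(params.fiber_axis_deg)
    tangent = np.array([math.cos(axis_th), math.sin(axis_th)])  # (x, y) unit vectors
    normal = np.array([-math.sin(axis_th), math.cos(axis_th)])
    center = np.array([nx / 2.0, ny / 2.0])
    s = min(ny, nx)
    semi_long = params.cell_semi_long_frac * s
    semi_short = params.cell_semi_short_frac * s

    rows = []
    # place the largest objects first: packing succeeds far more often
    placement_order = np.argsort(-volumes)
    for rank, i in enumerate(placement_order):
        vol = volumes[i]
        b = math.sqrt(3.0 * vol / (4.0 * math.pi * r * c))
        a = r * b
        theta = float(angles_avail[comp[i]])
        m = params.placement_margin_px
        fp_dil, ext_d = _ellipse_footprint(a, b, theta, margin=m)
        fp3_dil = None
        if not params.disjoint_in_projection:
            fp3_dil, _, ez_d = _ellipsoid_mask(a + m, b + m, c + m, theta, ext_d)
        cz_half = int(math.ceil(c + (0 if params.disjoint_in_projection else m))) + 1
        placed = False
        for _ in range(params.max_retries):
            # sample in cell coordinates (axial offset, normal offset)
            s_ax = rng.uniform(-semi_long, semi_long)
            s_no = rng.uniform(-semi_short, semi_short)
            cx, cy = center + s_ax * tangent + s_no * normal
            if not (ext_d + 1 <= cx < nx - ext_d - 2 and ext_d + 1 <= cy < ny - ext_d - 2):
                continue
            cxi, cyi = int(round(cx)), int(round(cy))
            sl = (slice(cyi - ext_d, cyi + ext_d + 1), slice(cxi - ext_d, cxi + ext_d + 1))
            if not cell[sl][fp_dil].all():
                continue
            if nz > 2 * (cz_half + 1):
                cz = int(rng.integers(cz_half + 1, nz - cz_half - 1))
            else:
                cz = nz // 2
            if params.disjoint_in_projection:
                if occupancy[sl][fp_dil].any():
                    continue
                occupancy[sl] |= fp_dil
            else:
                if cz - ez_d < 0 or cz + ez_d + 1 > nz:
                    continue
                sl3 = (slice(cz - ez_d, cz + ez_d + 1),) + sl
                if occupancy3d[sl3][fp3_dil].any():
                    continue
                occupancy3d[sl3][fp3_dil] = True
            lab_id = rank + 1
            _render_ellipsoid(labels, lab_id, (cz, cyi, cxi), (a, b, c), theta)
            vol_vox = int((labels == lab_id).sum())
            rel = float(_fold_axial(theta - params.fiber_axis_deg))
            rows.append(
                {
                    "label": lab_id,
                    "volume_vox": vol_vox,
                    "volume_um3": vol_vox * voxel_vol,
                    "angle_deg": theta,
                    "rel_angle_deg": rel,
                    "is_transverse": rel >= 60.0,
                    "component": int(comp[i]),
                }
            )
            placed = True
            break
        if not placed:
            raise CapacityError(
                f"could not place object {rank + 1}/{params.n_mito} after "
                f"{params.max_retries} retries; reduce n_mito or object size"
            )

    truth = pd.DataFrame(rows, columns=cols)
    intensity = _finish_intensity(labels, params, rng)
    return intensity, LabeledStack(labels, params.voxel_size), truth


def _render_ellipsoid(labels, lab, center, semiaxes, theta_deg) -> None:
    cz, cy, cx = center
    a, b, c = semiaxes
    th = math.radians(theta_deg)
    nz, ny, nx = labels.shape
    ez = int(math.ceil(c))
    exy = int(math.ceil(a)) + 1
    z0, z1 = max(cz - ez, 0), min(cz + ez + 1, nz)
    y0, y1 = max(cy - exy, 0), min(cy + exy + 1, ny)
    x0, x1 = max(cx - exy, 0), min(cx + exy + 1, nx)
    zz, yy, xx = np.mgrid[z0:z1, y0:y1, x0:x1].astype(float)
    dx, dy, dz = xx - cx, yy - cy, zz - cz
    u = dx * math.cos(th) + dy * math.sin(th)
    v = -dx * math.sin(th) + dy * math.cos(th)
    inside = (u / a) ** 2 + (v / b) ** 2 + (dz / c) ** 2 <= 1.0
    region = labels[z0:z1, y0:y1, x0:x1]
    region[inside & (region == 0)] = lab


def _finish_intensity(labels: np.ndarray, params: FiberSimParams, rng) -> ImageStack:
    intensity = (labels > 0).astype(float)
    if params.apply_psf:
        sigma_vox = (
            params.psf_sigma_z_um / params.voxel_size[0],
            params.psf_sigma_xy_um / params.voxel_size[1],
            params.psf_sigma_xy_um / params.voxel_size[2],
        )
        intensity = gaussian_filter(intensity, sigma_vox)
    fg = labels > 0
    mean_fg = float(intensity[fg].mean()) if fg.any() else 1.0
    if np.isfinite(params.snr):
        noise_sd = mean_fg / params.snr
        intensity = intensity + rng.normal(0.0, noise_sd, size=intensity.shape)
    return ImageStack(np.maximum(intensity, 0.0), params.voxel_size)


# ---------------------------------------------------------------------------
# EM-style 2D scenes
# ---------------------------------------------------------------------------


@dataclass
class EMSimParams:
    """Conditions for a simulated EM longitudinal-section scene.

    Mitochondria are rotated rectangles placed with a generous mutual
    clearance inside the fiber region; each jSR cisterna is a straight
    segment parallel to one edge of its partner mitochondrion at a prescribed
    minimum boundary gap, so pair flags and interface fractions have closed
    forms.
    """

    n_mito: int = 12
    n_jsr: int = 8
    gap_distribution: list[float] | None = None
    nm_per_pixel: float = 2.0
    fiber_area_fraction: float = 0.9
    scene_shape: tuple[int, int] = (4096, 4096)
    seed: int = 0
    mito_side_nm: tuple[float, float] = (300.0, 600.0)
    jsr_length_frac: float = 0.6
    min_clearance_nm: float = 400.0
    gap_range_nm: tuple[float, float] = (10.0, 150.0)
    max_retries: int = 1000

    def validate(self) -> None:
        if self.n_mito < 0 or self.n_jsr < 0:
            raise ValueError("counts must be >= 0")
        if self.nm_per_pixel <= 0:
            raise ValueError("nm_per_pixel must be > 0")
        if self.gap_distribution is not None:
            if any(g < 0 for g in self.gap_distribution):
                raise ValueError("all gaps must be >= 0")
        if not (0 < self.fiber_area_fraction <= 1):
            raise ValueError("fiber_area_fraction must be in (0, 1]")


@dataclass
class EMGroundTruth:
    """Analytic per-object truth accompanying a simulated EM scene."""

    mito: pd.DataFrame
    jsr: pd.DataFrame

    @property
    def percent_paired(self) -> float:
        if len(self.mito) == 0:
            return 0.0
        return 100.0 * float(self.mito["paired"].mean())

    @property
    def n_pairs(self) -> int:
        return int(self.jsr["pair_flag"].sum()) if len(self.jsr) else 0


def simulate_em_scene(params: EMSimParams):
    """Build a calibrated vector scene plus analytic ground truth.

    Returns ``(scene, truth)`` where ``scene`` is an
    :class:`~fibermito.em.EMScene` (pixel coordinates) and ``truth`` an
    :class:`EMGroundTruth` with pair flags (gap <= 50 nm) and the true
    interface percentage of each mitochondrion's perimeter.
    """
    from .em import EMScene  # local import to avoid a cycle

    params.validate()
    rng = np.random.default_rng(params.seed)
    npx = params.nm_per_pixel
    H_nm = params.scene_shape[0] * npx
    W_nm = params.scene_shape[1] * npx
    s = math.sqrt(params.fiber_area_fraction)
    fx0, fy0 = W_nm * (1 - s) / 2, H_nm * (1 - s) / 2
    fiber_nm = np.array(
        [[fx0, fy0], [fx0 + s * W_nm, fy0], [fx0 + s * W_nm, fy0 + s * H_nm], [fx0, fy0 + s * H_nm]]
    )

    gaps = (
        np.asarray(params.gap_distribution, dtype=float)
        if params.gap_distribution is not None
        else rng.uniform(*params.gap_range_nm, size=params.n_jsr)
    )
    n_jsr = len(gaps)
    if params.n_mito == 0 and n_jsr > 0:
        raise CapacityError("cannot place jSR contours without mitochondria")

    clear = params.min_clearance_nm
    inset = clear / 2 + max(params.mito_side_nm) + 200.0
    if params.n_mito > 0 and (s * W_nm <= 2 * inset or s * H_nm <= 2 * inset):
        raise CapacityError("scene too small for any mitochondrion: scene overflow")
    mitos = []  # (corners_nm (4,2), w, h, angle)
    for i in range(params.n_mito):
        w = rng.uniform(*params.mito_side_nm)
        h = rng.uniform(*params.mito_side_nm)
        ang = rng.uniform(0.0, 180.0)
        placed = False
        for _ in range(params.max_retries):
            cx = rng.uniform(fx0 + inset, fx0 + s * W_nm - inset)
            cy = rng.uniform(fy0 + inset, fy0 + s * H_nm - inset)
            corners = _rect_corners(cx, cy, w, h, ang)
            if all(
                _min_rect_gap(corners, other[0]) >= clear for other in mitos
            ):
                mitos.append((corners, w, h, ang))
                placed = True
                break
        if not placed:
            raise CapacityError(
                f"could not place mitochondrion {i + 1}/{params.n_mito}: scene overflow"
            )

    jsr_rows, jsr_contours = [], []
    used_edges: dict[int, set[int]] = {}
    for j in range(n_jsr):
        m = j % max(params.n_mito, 1)
        corners, w, h, ang = mitos[m]
        free = [e for e in range(4) if e not in used_edges.setdefault(m, set())]
        if not free:
            raise CapacityError("more jSR contours than free mitochondrial edges")
        e = free[int(rng.integers(len(free)))]
        used_edges[m].add(e)
        p0, p1 = corners[e], corners[(e + 1) % 4]
        edge_vec = p1 - p0
        edge_len = float(np.linalg.norm(edge_vec))
        t = edge_vec / edge_len
        nvec = np.array([t[1], -t[0]])
        centroid = corners.mean(axis=0)
        if (p0 + p1) @ nvec / 2 < centroid @ nvec:  # make the normal point outward
            nvec = -nvec
        g = float(gaps[j])
        L = params.jsr_length_frac * edge_len
        mid = (p0 + p1) / 2 + nvec * g
        seg = np.array([mid - t * L / 2, mid + t * L / 2])
        jsr_contours.append(seg)
        # analytic boundary coverage at the contact criterion
        cov = 0.0
        if g <= CONTACT_GAP_NM:
            cov = min(edge_len, L + 2.0 * math.sqrt(CONTACT_GAP_NM**2 - g**2))
        jsr_rows.append(
            {
                "jsr": j,
                "mito": m,
                "gap_nm": g,
                "pair_flag": g <= CONTACT_GAP_NM,
                "covered_nm": cov,
                "length_nm": L,
            }
        )

    jsr_df = pd.DataFrame(
        jsr_rows, columns=["jsr", "mito", "gap_nm", "pair_flag", "covered_nm", "length_nm"]
    )
    mito_rows = []
    for m, (corners, w, h, ang) in enumerate(mitos):
        per = 2.0 * (w + h)
        sub = jsr_df[jsr_df["mito"] == m] if len(jsr_df) else jsr_df
        cov = float(sub["covered_nm"].sum()) if len(sub) else 0.0
        mito_rows.append(
            {
                "mito": m,
                "area_um2": w * h * 1e-6,
                "perimeter_nm": per,
                "interface_percent_true": 100.0 * cov / per,
                "paired": bool(sub["pair_flag"].any()) if len(sub) else False,
            }
        )
    mito_df = pd.DataFrame(
        mito_rows, columns=["mito", "area_um2", "perimeter_nm", "interface_percent_true", "paired"]
    )

    scene = EMScene(
        mito_contours=[m[0] / npx for m in mitos],
        jsr_contours=[seg / npx for seg in jsr_contours],
        fiber_region=fiber_nm / npx,
        nm_per_pixel=npx,
    )
    return scene, EMGroundTruth(mito=mito_df, jsr=jsr_df)


def _rect_corners(cx, cy, w, h, angle_deg) -> np.ndarray:
    th = math.radians(angle_deg)
    R = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    half = np.array([[-w / 2, -h / 2], [w / 2, -h / 2], [w / 2, h / 2], [-w / 2, h / 2]])
    return half @ R.T + np.array([cx, cy])


def _min_rect_gap(c1: np.ndarray, c2: np.ndarray) -> float:
    """Minimum boundary-to-boundary distance between two convex quads (nm)."""
    from shapely.geometry import Polygon

    return float(Polygon(c1).distance(Polygon(c2)))


# ---------------------------------------------------------------------------
# Ratiometric traces
# ---------------------------------------------------------------------------


@dataclass
class TraceSimParams:
    """Conditions for a simulated two-channel ratiometric Ca²⁺ record.

    The underlying ratio follows a unit-peak double-exponential transient on
    top of a resting level; ``transient_amplitude`` is therefore the true
    peak height above rest. Channels are synthesized so 490/420 reproduces the
    ratio exactly up to the stated noise (noise enters the 490 nm channel).
    """

    n_frames: int = 280
    dt: float = 2.0
    resting_ratio: float = 1.0
    transient_amplitude: float = 0.5
    stimulus_frame: int = 30
    rise_tau: float = 10.0
    decay_tau: float = 60.0
    noise_sd: float = 0.01
    seed: int = 0
    f420_level: float = 100.0

    def validate(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not (0 <= self.stimulus_frame < self.n_frames):
            raise ValueError("stimulus_frame must satisfy 0 <= stimulus_frame < n_frames")
        if self.rise_tau <= 0 or self.decay_tau <= 0:
            raise ValueError("time constants must be > 0")
        if self.dt <= 0 or self.noise_sd < 0 or self.f420_level <= 0:
            raise ValueError("dt and f420_level must be > 0, noise_sd >= 0")


def transient_shape(t_after: np.ndarray, rise_tau: float, decay_tau: float) -> np.ndarray:
    """Unit-peak kinetic shape ``(1 - e^{-t/τr}) e^{-t/τd}`` (0 before onset)."""
    t_after = np.asarray(t_after, dtype=float)
    raw = np.where(
        t_after >= 0,
        (1.0 - np.exp(-np.maximum(t_after, 0) / rise_tau)) * np.exp(-np.maximum(t_after, 0) / decay_tau),
        0.0,
    )
    t_peak = rise_tau * math.log1p(decay_tau / rise_tau)
    peak = (1.0 - math.exp(-t_peak / rise_tau)) * math.exp(-t_peak / decay_tau)
    return raw / peak


def transient_peak_time(rise_tau: float, decay_tau: float) -> float:
    """Time after stimulus at which the kinetic shape peaks (closed form)."""
    return rise_tau * math.log1p(decay_tau / rise_tau)


def simulate_trace(params: TraceSimParams):
    """Synthesize a :class:`~fibermito.calcium.RatiometricTrace` plus truth.

    Returns ``(trace, truth)`` with ``truth`` a dict holding the resting
    ratio, true peak amplitude, and the absolute peak time.
    """
    from .calcium import RatiometricTrace

    params.validate()
    rng = np.random.default_rng(params.seed)
    t = np.arange(params.n_frames) * params.dt
    t0 = params.stimulus_frame * params.dt
    ratio_true = params.resting_ratio + params.transient_amplitude * transient_shape(
        t - t0, params.rise_tau, params.decay_tau
    )
    noise = rng.normal(0.0, params.noise_sd, size=params.n_frames) if params.noise_sd > 0 else 0.0
    f420 = np.full(params.n_frames, params.f420_level)
    f490 = f420 * (ratio_true + noise)
    trace = RatiometricTrace(time=t, f490=f490, f420=f420, stimulus_time=t0)
    truth = {
        "resting": params.resting_ratio,
        "amplitude": params.transient_amplitude,
        "t_peak": t0 + transient_peak_time(params.rise_tau, params.decay_tau),
        "ratio_true": ratio_true,
    }
    return trace, truth
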