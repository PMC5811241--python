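"""End-to-end pipeline driver and per-group summary tables.

``run_pipeline`` executes the selected stages on simulated bundles — one
fiber stack, EM scene and Ca²⁺ trace per simulated fiber per age group — and
writes per-stage CSV tables plus a combined mean ± SD group summary, the
desk-scale analogue of the study's per-group bar data. Every output carries a
provenance header (package version, config hash, seed) and reruns with the
same config and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import calcium, io, morphometry3d, orientation
from .em import em_counts_and_size, sr_mito_pairs
from .synthetic import (
    EMSimParams,
    FiberSimParams,
    TraceSimParams,
    simulate_em_scene,
    simulate_fiber_stack,
    simulate_trace,
)

logger = logging.getLogger("fibermito")

STAGES = ("morphometry", "orientation", "em", "calcium")


def _check_keys(d: dict, allowed, what: str) -> None:
    unknown = set(d) - set(allowed)
    if unknown:
        raise ValueError(f"unknown {what} keys: {sorted(unknown)}")


@dataclass
class GroupConfig:
    """One age group: a label plus generator overrides shared by its fibers."""

    label: str
    n_fibers: int = 4
    fiber: dict = field(default_factory=dict)
    em: dict = field(default_factory=dict)
    trace: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_keys(self.fiber, [f.name for f in dataclasses.fields(FiberSimParams)], "fiber")
        _check_keys(self.em, [f.name for f in dataclasses.fields(EMSimParams)], "em")
        _check_keys(self.trace, [f.name for f in dataclasses.fields(TraceSimParams)], "trace")
        # canonicalize so load(save(cfg)) == cfg holds through YAML/JSON
        for d in (self.fiber, self.em, self.trace):
            for k, v in d.items():
                if isinstance(v, list):
                    d[k] = tuple(v)


@dataclass
class RunConfig:
    """Full pipeline configuration; round-trips through dict/YAML/JSON."""

    out_dir: str = "fibermito_results"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    groups: tuple[GroupConfig, ...] = ()
    threshold: float | str = "otsu2"
    connectivity: int = 26
    min_voxels: int = 20
    deconvolve: bool = False
    iterations: int = 25
    n_bins: int = 3
    fiber_threshold: float | str = "otsu2"
    gap_threshold_nm: float = 50.0
    boundary_step_nm: float = 5.0
    detection_k: float = 3.0

    def __post_init__(self) -> None:
        self.stages = tuple(self.stages)
        bad = set(self.stages) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        self.groups = tuple(
            g if isinstance(g, GroupConfig) else GroupConfig(**g) for g in self.groups
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["groups"] = [dataclasses.asdict(g) for g in self.groups]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        _check_keys(d, [f.name for f in dataclasses.fields(cls)], "config")
        return cls(**d)

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(io.load_config(path))

    def save(self, path) -> None:
        io.save_config(path, self.to_dict())


def _fiber_seed(seed: int, group_idx: int, fiber_idx: int, stream: int) -> int:
    ss = np.random.SeedSequence((int(seed), group_idx, fiber_idx, stream))
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Execute the selected stages on simulated bundles and write results.

    Returns the per-stage record tables (also written as CSV in ``out_dir``
    together with the group summary and a copy of the configuration).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = config.to_dict()
    config.save(out / "config.json")
    logger.info("run: stages=%s seed=%d out=%s", config.stages, config.seed, out)
    logger.info("full configuration: %s", cfg_dict)

    bank = orientation.build_gabor_bank() if "orientation" in config.stages else None
    tables: dict[str, list[dict]] = {s: [] for s in config.stages}
    need_stack = {"morphometry", "orientation"} & set(config.stages)

    for gi, group in enumerate(config.groups):
        for fi in range(group.n_fibers):
            base = {"group": group.label, "fiber": fi}
            if need_stack:
                fp = FiberSimParams(
                    **{**group.fiber, "seed": _fiber_seed(config.seed, gi, fi, 0)}
                )
                stack, labels_true, truth = simulate_fiber_stack(fp)
                if "morphometry" in config.stages:
                    work = stack
                    if config.deconvolve:
                        psf = morphometry3d.gaussian_psf(
                            (fp.psf_sigma_z_um, fp.psf_sigma_xy_um, fp.psf_sigma_xy_um),
                            fp.voxel_size,
                        )
                        work = morphometry3d.landweber_deconvolve(
                            work, psf, iterations=config.iterations
                        )
                    seg = morphometry3d.apply_threshold(work, config.threshold)
                    lab = morphometry3d.label_components(
                        seg.mask, config.connectivity, fp.voxel_size
                    )
                    lab = morphometry3d.remove_small_objects(lab, config.min_voxels)
                    m = morphometry3d.compute_morphometry(lab)
                    tables["morphometry"].append(
                        base
                        | {
                            "n_objects": m.n_objects,
                            "true_n_objects": len(truth),
                            "mean_volume_vox": m.mean_volume_vox,
                            "total_volume_vox": m.total_volume_vox,
                            "mean_volume_um3": m.mean_volume_um3,
                        }
                    )
                if "orientation" in config.stages:
                    r = orientation.analyze_fiber_orientation(
                        stack.voxels,
                        bank=bank,
                        n_bins=config.n_bins,
                        fiber_threshold=config.fiber_threshold,
                    )
                    true_tr = (
                        100.0 * truth["is_transverse"].mean() if len(truth) else np.nan
                    )
                    tables["orientation"].append(
                        base
                        | {
                            "fiber_axis_deg": r.fiber_axis,
                            "percent_longitudinal": r.percent_longitudinal,
                            "percent_transverse": r.percent_transverse,
                            "true_percent_transverse": true_tr,
                        }
                    )
            if "em" in config.stages:
                ep = EMSimParams(**{**group.em, "seed": _fiber_seed(config.seed, gi, fi, 1)})
                scene, em_truth = simulate_em_scene(ep)
                counts = em_counts_and_size(scene)
                contacts = sr_mito_pairs(
                    scene,
                    gap_threshold_nm=config.gap_threshold_nm,
                    boundary_step_nm=config.boundary_step_nm,
                )
                tables["em"].append(
                    base
                    | {
                        "count_per_reference_area": counts.count_per_reference_area,
                        "mean_area_um2": counts.mean_area_um2,
                        "density": counts.density,
                        "n_pairs": contacts.n_pairs,
                        "percent_paired": contacts.percent_paired,
                        "mean_interface_percent": float(
                            np.mean(contacts.per_mito_interface_percent)
                        ),
                        "true_percent_paired": em_truth.percent_paired,
                    }
                )
            if "calcium" in config.stages:
                tp = TraceSimParams(
                    **{**group.trace, "seed": _fiber_seed(config.seed, gi, fi, 2)}
                )
                trace, tr_truth = simulate_trace(tp)
                metrics = calcium.transient_metrics(
                    trace.ratio, trace.time, trace.stimulus_time, k=config.detection_k
                )
                tables["calcium"].append(
                    base
                    | {
                        "resting_level": metrics.resting_level,
                        "peak_amplitude": metrics.peak_amplitude,
                        "time_to_peak": metrics.time_to_peak,
                        "detected": metrics.detected,
                        "true_resting": tr_truth["resting"],
                        "true_amplitude": tr_truth["amplitude"],
                    }
                )

    frames: dict[str, pd.DataFrame] = {}
    for stage in config.stages:
        df = pd.DataFrame(tables[stage])
        frames[stage] = df
        io.write_table(out / f"{stage}.csv", df, cfg_dict, config.seed)
    summary = summarize_groups(pd.concat(frames.values(), axis=0, join="outer"))
    frames["summary"] = summary
    io.write_table(out / "summary.csv", summary, cfg_dict, config.seed)
    io.write_json(
        out / "summary.json",
        {"summary": summary.to_dict(orient="records")},
        cfg_dict,
        config.seed,
    )
    return frames


def summarize_groups(records: pd.DataFrame, group_col: str = "group") -> pd.DataFrame:
    """Mean ± SD and n per metric per group (sample SD, n−1 denominator).

    Empty groups are excluded with a warning; single-record groups report
    SD = 0 with ``single_record=True``. No hypothesis testing is performed —
    the tidy table is meant to feed any stats package.
    """
    if group_col not in records.columns:
        raise ValueError(f"records lack a {group_col!r} column")
    metrics = [
        c
        for c in records.columns
        if c not in (group_col, "fiber") and pd.api.types.is_numeric_dtype(records[c])
    ]
    rows = []
    for label, sub in records.groupby(group_col, sort=True):
        for metric in metrics:
            vals = sub[metric].dropna().to_numpy(dtype=float)
            if vals.size == 0:
                warnings.warn(f"group {label!r} has no data for {metric}", stacklevel=2)
                continue
            rows.append(
                {
                    "group": label,
                    "metric": metric,
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                    "n": int(vals.size),
                    "single_record": vals.size == 1,
                }
            )
    return pd.DataFrame(rows, columns=["group", "metric", "mean", "sd", "n", "single_record"])
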