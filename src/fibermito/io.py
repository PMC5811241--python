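"""Shared I/O: TIFF stacks, CSV/JSON results with provenance headers, configs."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .morphometry3d import ImageStack, LabeledStack


def read_stack(path: str | Path, voxel_size=(1.0, 1.0, 1.0)) -> ImageStack:
    """Read a multi-page TIFF as a 3D intensity stack."""
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    return ImageStack(np.asarray(arr, dtype=float), tuple(voxel_size))


def write_stack(path: str | Path, stack: ImageStack | LabeledStack) -> None:
    """Write a stack (intensity as float32, labels as int32) to multi-page TIFF."""
    if isinstance(stack, LabeledStack):
        data = stack.labels.astype(np.int32)
    else:
        data = stack.voxels.astype(np.float32)
    tifffile.imwrite(str(path), data)


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_header(config: dict | None = None, seed: int | None = None) -> str:
    parts = [f"fibermito v{__version__}"]
    if config is not None:
        parts.append(f"config={config_hash(config)}")
    if seed is not None:
        parts.append(f"seed={seed}")
    return "# " + " ".join(parts)


def write_table(
    path: str | Path, table: pd.DataFrame, config: dict | None = None, seed: int | None = None
) -> None:
    """CSV with a provenance comment header (config hash, package version)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(provenance_header(config, seed) + "\n")
        table.to_csv(fh, index=False, lineterminator="\n", float_format="%.10g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_json(
    path: str | Path, payload: dict, config: dict | None = None, seed: int | None = None
) -> None:
    out = {"_provenance": provenance_header(config, seed).lstrip("# ")}
    out.update(payload)
    Path(path).write_text(json.dumps(out, indent=2, sort_keys=True, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON configuration file as a plain dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text) or {}
    return json.loads(text)


def save_config(path: str | Path, config: dict) -> None:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(config, sort_keys=True))
    else:
        path.write_text(json.dumps(config, indent=2, sort_keys=True) + "\n")


def read_trace_csv(path: str | Path):
    """Read a (time, f490, f420) or (time, f) CSV into arrays."""
    df = pd.read_csv(path, comment="#")
    cols = [c.lower().strip() for c in df.columns]
    df.columns = cols
    if "f490" in cols and "f420" in cols:
        return df["time"].to_numpy(), df["f490"].to_numpy(), df["f420"].to_numpy()
    if len(cols) >= 2:
        return df[cols[0]].to_numpy(), df[cols[1]].to_numpy(), None
    raise ValueError("trace CSV needs (time, f490, f420) or (time, f) columns")
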