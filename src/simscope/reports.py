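"""JSON reports and image I/O.

Reports are deterministic: given the same seed and config they are
byte-identical (no wall-clock timestamps; the simulator's own clock is part
of the deterministic state).  Image rasters are written to TIFF or PNG next
to the report, never embedded in JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
from PIL import Image
import tifffile

from . import __version__


def to_jsonable(obj):
    """Recursively convert results (dataclasses, numpy) to JSON-safe values.

    Large rasters are summarized by shape/dtype rather than embedded.
    """
    if isinstance(obj, np.ndarray):
        if obj.ndim >= 2:
            return {"__array__": True, "shape": list(obj.shape), "dtype": str(obj.dtype)}
        return [to_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: to_jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(v) for v in obj]
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return repr(obj)


def config_hash(config: dict | None) -> str | None:
    if config is None:
        return None
    blob = json.dumps(to_jsonable(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_report(result, path: str | Path, seed: int | None = None, config: dict | None = None) -> Path:
    """Write a result object as a versioned JSON report."""
    path = Path(path)
    doc = {
        "simscope_version": __version__,
        "seed": seed,
        "config_hash": config_hash(config),
        "result": to_jsonable(result),
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def save_image(pixels: np.ndarray, path: str | Path) -> Path:
    """Save a raster as TIFF or PNG based on the file extension."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, np.asarray(pixels))
    else:
        Image.fromarray(np.asarray(pixels)).save(path)
    return path


def load_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(path)
    return np.asarray(Image.open(path))
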