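"""File I/O: TIFF images/stacks, JSON calibration reports, CSV tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .noise_model import CameraParams

__all__ = [
    "read_stack",
    "read_frame",
    "write_tiff",
    "save_calibration_report",
    "load_calibration_report",
]


def read_stack(path) -> np.ndarray:
    """Read a TIFF as an integer array (2-D frame or 3-D stack)."""
    arr = tifffile.imread(path)
    return np.asarray(arr)


def read_frame(path, frame: int = 0) -> np.ndarray:
    """Read one 2-D frame of a (possibly multi-page) TIFF."""
    arr = read_stack(path)
    if arr.ndim == 2:
        return arr
    return arr[frame]


def write_tiff(path, array: np.ndarray, dtype=np.uint16) -> None:
    """Write an array as a TIFF, clipping into the target dtype range."""
    info = np.iinfo(dtype)
    out = np.clip(np.asarray(array), info.min, info.max).astype(dtype)
    tifffile.imwrite(path, out)


def save_calibration_report(path, report: dict) -> None:
    out = {}
    for k, v in report.items():
        if isinstance(v, CameraParams):
            out[k] = v.to_dict()
        elif isinstance(v, (np.floating, np.integer)):
            out[k] = v.item()
        else:
            out[k] = v
    Path(path).write_text(json.dumps(out, indent=2, sort_keys=True) + "\n")


def load_calibration_report(path) -> dict:
    report = json.loads(Path(path).read_text())
    if report.get("params"):
        report["params"] = CameraParams.from_dict(report["params"])
    return report
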