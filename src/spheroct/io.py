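"""Image and sidecar I/O: grayscale TIFF in, TIFF + JSON ground truth out."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile

from .confocal import ZStack


def read_image(path) -> np.ndarray:
    """Read a single-page grayscale raster as a nonnegative float array."""
    arr = tifffile.imread(str(path))
    if arr.ndim == 3 and arr.shape[0] == 1:
        arr = arr[0]
    if arr.ndim != 2:
        raise ValueError(
            f"{path}: expected a single-page grayscale image, got shape {arr.shape} "
            "(RGB or multi-page input)"
        )
    out = arr.astype(float)
    if np.any(out < 0):
        raise ValueError(f"{path}: negative intensities in input")
    return out


def read_stack(path, z_step: float = 7.0, medium: Optional[str] = None,
               channel: Optional[str] = None) -> ZStack:
    """Read a multi-page grayscale TIFF as a ZStack, page order preserved."""
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        raise ValueError(f"{path}: single page, not a stack")
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected grayscale pages, got shape {arr.shape}")
    return ZStack(arr.astype(float), z_step=z_step, medium=medium, channel=channel)


def write_image(path, image: np.ndarray, dtype: str = "uint16") -> tuple[np.ndarray, float]:
    """Write an intensity image (2-D) or stack (3-D) to TIFF.

    Nonnegative float data is scaled to the full 16-bit range (scale factor
    returned and recorded in sidecars); ``dtype="float32"`` stores values
    verbatim. Returns ``(stored_array, scale)``.
    """
    image = np.asarray(image)
    if dtype == "float32":
        stored, scale = image.astype(np.float32), 1.0
    elif dtype == "uint16":
        peak = float(image.max()) if image.size else 0.0
        scale = 65535.0 / peak if peak > 0 else 1.0
        stored = np.round(image * scale).astype(np.uint16)
    else:
        raise ValueError("dtype must be 'uint16' or 'float32'")
    tifffile.imwrite(str(path), stored)
    return stored, scale


def save_simulation(out_dir, name: str, image: np.ndarray, ground_truth,
                    params: dict, seed: int, dtype: str = "uint16") -> dict:
    """Write a simulated raster plus a JSON sidecar with identical basename.

    The sidecar carries the ground truth, the generator parameters, the
    seed, and the intensity scale applied on write.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tif_path = out_dir / f"{name}.tif"
    _, scale = write_image(tif_path, image, dtype=dtype)
    sidecar = {
        "ground_truth": ground_truth.to_dict(),
        "params": params,
        "seed": seed,
        "intensity_scale": scale,
    }
    json_path = out_dir / f"{name}.json"
    json_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return {"tiff": str(tif_path), "sidecar": str(json_path)}
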