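"""Confocal z-stack signal quantification and maximum imaging depth.

For each slice of a fluorescence z-stack the raw integrated density (sum of
pixel values inside a spheroid ROI) is computed; the maximum imaging depth
is the depth of the first slice in which no in-ROI pixel rises above the
measured mean background — the point where signal becomes indistinguishable
from background. Summaries across stacks acquired in different immersion
media quantify how refractive-index matching extends imaging depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from skimage import measure as skmeasure
from skimage.morphology import convex_hull_image

from .morphometry import intermodes_threshold


@dataclass
class ZStack:
    """Ordered grayscale slices with a physical z-step (µm)."""

    slices: np.ndarray
    z_step: float = 7.0
    medium: Optional[str] = None
    channel: Optional[str] = None

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices, dtype=float)
        if self.slices.ndim != 3 or self.slices.shape[0] < 2:
            raise ValueError("ZStack needs >= 2 same-shape slices")
        if self.z_step <= 0:
            raise ValueError("z_step must be > 0")

    @property
    def n_slices(self) -> int:
        return self.slices.shape[0]

    @property
    def depths_um(self) -> np.ndarray:
        return np.arange(self.n_slices) * self.z_step


@dataclass
class DepthProfile:
    """Per-slice signal measures and the maximum-imaging-depth statistic."""

    raw_integrated_density: np.ndarray
    max_in_roi: np.ndarray
    background_mean: float
    max_depth_um: float
    unterminated: bool
    roi_area_px: int
    z_step: float
    medium: Optional[str] = None
    channel: Optional[str] = None


def define_roi(stack: ZStack, mode: str = "auto", mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Region of interest covering the whole spheroid.

    Auto mode thresholds the maximum-intensity projection with the
    Intermodes algorithm (bright-object polarity, since fluorescence signal
    is bright), keeps the largest connected component and returns its convex
    hull. Explicit mode accepts a caller-supplied boolean mask.
    """
    if mode == "explicit":
        if mask is None:
            raise ValueError("explicit mode requires a mask")
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != stack.slices.shape[1:]:
            raise ValueError("mask shape does not match slices")
        if not mask.any():
            raise ValueError("explicit ROI is empty")
        return mask
    if mode != "auto":
        raise ValueError("mode must be 'auto' or 'explicit'")

    mip = stack.slices.max(axis=0)
    lo, hi = float(mip.min()), float(mip.max()) + 1e-9
    hist, _ = np.histogram(mip, bins=256, range=(lo, hi))
    try:
        tbin, _ = intermodes_threshold(hist)
    except ValueError as exc:
        raise ValueError(f"auto ROI found no object: {exc}") from exc
    threshold = lo + (tbin + 0.5) * (hi - lo) / 256.0
    fg = mip > threshold
    if not fg.any():
        raise ValueError("auto ROI found no object above threshold")
    labels = skmeasure.label(fg, connectivity=2)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    return convex_hull_image(labels == largest)


def raw_integrated_density(slice_: np.ndarray, roi: np.ndarray) -> float:
    """Sum of pixel values within the ROI (additive over disjoint ROIs)."""
    slice_ = np.asarray(slice_)
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != slice_.shape:
        raise ValueError("ROI shape does not match slice")
    if not roi.any():
        raise ValueError("empty ROI")
    return float(slice_[roi].sum())


def estimate_background(stack: ZStack, roi: np.ndarray) -> tuple[float, int]:
    """Mean of out-of-ROI pixels on the first slice, and the count used."""
    roi = np.asarray(roi, dtype=bool)
    outside = ~roi
    if not outside.any():
        raise ValueError("no background region: ROI covers the full frame")
    vals = stack.slices[0][outside]
    return float(vals.mean()), int(vals.size)


def max_imaging_depth(
    stack: ZStack,
    roi: np.ndarray,
    background_mean: float,
    *,
    consecutive: int = 1,
) -> tuple[float, bool]:
    """Depth of the first slice with no in-ROI pixel above background.

    Scanning slices in order from depth 0, the stopping index ``k`` is the
    first slice whose in-ROI maximum is <= ``background_mean`` (strictly
    "no pixel above": a literal background criterion). With
    ``consecutive=q > 1``, ``q`` successive stopping slices are required and
    the first of the run is reported, guarding against single-slice noise.

    Returns ``(max_depth_um, unterminated)``; when no slice stops, the depth
    is the full stack extent and the flag is set.
    """
    if consecutive < 1:
        raise ValueError("consecutive must be >= 1")
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("empty ROI")
    stopped = np.array(
        [stack.slices[k][roi].max() <= background_mean for k in range(stack.n_slices)]
    )
    run = 0
    for k, s in enumerate(stopped):
        run = run + 1 if s else 0
        if run >= consecutive:
            return (k - consecutive + 1) * stack.z_step, False
    return (stack.n_slices - 1) * stack.z_step, True


def depth_profile(
    stack: ZStack,
    roi: Optional[np.ndarray] = None,
    *,
    consecutive: int = 1,
) -> DepthProfile:
    """Full per-stack analysis: ROI, background, per-slice RID, max depth."""
    if roi is None:
        roi = define_roi(stack, "auto")
    bg, _ = estimate_background(stack, roi)
    rid = np.array([raw_integrated_density(s, roi) for s in stack.slices])
    mx = np.array([s[roi].max() for s in stack.slices])
    depth, unterminated = max_imaging_depth(stack, roi, bg, consecutive=consecutive)
    return DepthProfile(
        raw_integrated_density=rid,
        max_in_roi=mx,
        background_mean=bg,
        max_depth_um=depth,
        unterminated=unterminated,
        roi_area_px=int(roi.sum()),
        z_step=stack.z_step,
        medium=stack.medium,
        channel=stack.channel,
    )


def compare_media(profiles: Iterable[DepthProfile]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summarise maximum imaging depth per immersion medium.

    Returns ``(summary, curves)``: a per-medium table of mean, sd and N of
    the maximum imaging depth, and the per-slice mean-signal curves
    (raw integrated density normalised by ROI area versus depth).
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles")
    rows, curve_rows = [], []
    for i, p in enumerate(profiles):
        rows.append({"medium": p.medium or "?", "max_depth_um": p.max_depth_um})
        depths = np.arange(len(p.raw_integrated_density)) * p.z_step
        for z, rid in zip(depths, p.raw_integrated_density):
            curve_rows.append(
                {
                    "medium": p.medium or "?",
                    "profile": i,
                    "depth_um": z,
                    "mean_signal": rid / p.roi_area_px,
                }
            )
    df = pd.DataFrame(rows)
    summary = (
        df.groupby("medium")["max_depth_um"]
        .agg(
            mean="mean",
            sd=lambda v: v.std(ddof=1) if len(v) > 1 else np.nan,
            N="count",
        )
        .reset_index()
    )
    return summary, pd.DataFrame(curve_rows)
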