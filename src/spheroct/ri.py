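"""Group refractive-index estimation from OCT B-scans by path-length matching.

A spheroid resting on a flat reflective dish displaces every reflection
beneath its surface deeper in the image, because OCT measures optical rather
than geometrical path. With the top-surface depth ``z1``, the extrapolated
dish depth ``z0`` (a path through air — the geometrical reference) and the
detected spheroid-bottom depth ``z0'`` (a path through tissue — the optical
reference), the group index of the sample is the ratio of optical to
geometrical thickness::

    n_s = d / t = (z0' - z1) / (z0 - z1)

The module provides the individual pipeline stages as functions and a
statsmodels-style :class:`SpheroidRIModel` / :class:`SpheroidRIResults` pair
that orchestrates them: background correction, matched-filter surface peak
detection with sub-pixel refinement, second-order polynomial fits to the
dish and spheroid surfaces, thickness measurement at columns near the apex,
aggregation, one-way ANOVA across groups, and a necrotic-dip detector for
A-scan profiles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter1d, uniform_filter1d
from scipy.signal import find_peaks

from .instrument import InstrumentSpec

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))
# sd of max(N(0, 1), 0): used to recover the raw noise scale from a
# background-subtracted (hence zero-clipped) blank region.
_CLIPPED_SD = math.sqrt(0.5 - 1.0 / math.pi)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class BScan:
    """Calibrated 2-D OCT intensity image (rows = depth, air-equivalent)."""

    intensity: np.ndarray
    instrument: InstrumentSpec
    provenance: Optional[str] = None

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise ValueError("BScan intensity must be 2-D")
        if self.intensity.shape[0] < 32 or self.intensity.shape[1] < 32:
            raise ValueError("BScan must be at least 32 rows x 32 columns")
        if np.any(self.intensity < 0):
            raise ValueError("BScan intensities must be nonnegative")

    @property
    def n_rows(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_cols(self) -> int:
        return self.intensity.shape[1]

    @property
    def depth_um(self) -> np.ndarray:
        """Air-equivalent depth of each row, µm."""
        return np.arange(self.n_rows) * self.instrument.axial_pitch

    @classmethod
    def from_tiff(cls, path, instrument: InstrumentSpec) -> "BScan":
        from .io import read_image

        return cls(read_image(path), instrument, provenance=str(path))


@dataclass
class AScanProfile:
    """Single depth scan: intensity versus calibrated depth at one column."""

    column: int
    depth_um: np.ndarray
    intensity: np.ndarray
    axial_resolution_um: float = 3.1

    def __post_init__(self) -> None:
        if len(self.depth_um) != len(self.intensity):
            raise ValueError("depth and intensity must have equal length")
        if np.any(np.diff(self.depth_um) <= 0):
            raise ValueError("depth axis must be strictly increasing")


@dataclass
class SurfaceTrace:
    """Detected per-column reflection depths plus a degree-2 polynomial fit.

    ``poly_coeffs`` are highest-power-first (numpy convention), mapping
    column index to depth in µm.
    """

    columns: np.ndarray
    z_detected: np.ndarray
    poly_coeffs: np.ndarray
    rms_residual: float
    label: str = ""

    def poly(self, x) -> np.ndarray:
        return np.polyval(self.poly_coeffs, x)


@dataclass
class ThicknessMeasurement:
    """Path-length-matching quantities at one column (all depths in µm)."""

    column: int
    z1: float          # spheroid top
    z0: float          # extrapolated dish (geometrical reference)
    z0_prime: float    # detected spheroid bottom (optical reference)
    t: float           # geometrical thickness, z0 - z1
    d: float           # optical thickness, z0' - z1
    valid: bool = True
    reason: Optional[str] = None


@dataclass
class RIEstimate:
    """Aggregated refractive-index estimate for one spheroid."""

    n_s_mean: float
    n_s_sd: float
    n_measurements: int
    under_replicated: bool
    spheroid_id: Optional[str] = None
    labels: dict = field(default_factory=dict)


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p_value: float
    group_summaries: pd.DataFrame
    significant: bool = False  # at alpha = 0.05


@dataclass
class DipInterval:
    """Interior low-signal interval of an A-scan (candidate necrotic core)."""

    column: int
    dip_start: float
    dip_end: float
    depth_of_minimum: float
    relative_depth_of_signal: float


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------

def subtract_background(bscan: BScan, blank_rows) -> BScan:
    """Subtract the per-column mean of sample-free rows; clip negatives to 0.

    ``blank_rows`` is a row range (slice or (start, stop)) that the caller
    asserts contains no sample or dish reflections — conventionally the rows
    above all structure.
    """
    rows = _as_slice(blank_rows)
    if rows.stop is not None and rows.stop > bscan.n_rows:
        raise ValueError("blank_rows out of image bounds")
    idx = np.arange(bscan.n_rows)[rows]
    if idx.size == 0:
        raise ValueError("blank_rows selects no rows")
    bg = bscan.intensity[rows, :].mean(axis=0, keepdims=True)
    corrected = np.clip(bscan.intensity - bg, 0.0, None)
    return BScan(corrected, bscan.instrument, provenance=bscan.provenance)


def _as_slice(rows) -> slice:
    if isinstance(rows, slice):
        return rows
    if isinstance(rows, (tuple, list)) and len(rows) == 2:
        return slice(int(rows[0]), int(rows[1]))
    if isinstance(rows, range):
        return slice(rows.start, rows.stop, rows.step)
    raise ValueError("blank_rows must be a slice, range or (start, stop) pair")


def _subpixel_refine(window: np.ndarray, k: int) -> float:
    """3-point parabolic sub-pixel peak offset around discrete maximum `k`.

    The parabola is fitted to the logarithm of intensity when all three
    samples are positive (exact for a Gaussian-shaped reflection), falling
    back to linear intensity otherwise. Returns the fractional row offset
    in [-0.5, 0.5].
    """
    if k <= 0 or k >= len(window) - 1:
        return 0.0
    y = window[k - 1 : k + 2].astype(float)
    if np.all(y > 0):
        y = np.log(y)
    denom = y[0] - 2.0 * y[1] + y[2]
    if denom >= 0 or not np.isfinite(denom):
        return 0.0
    off = 0.5 * (y[0] - y[2]) / denom
    return float(np.clip(off, -0.5, 0.5))


def detect_surface_peaks(
    bscan: BScan,
    columns: Sequence[int],
    search_window: tuple[float, float],
    k_sigma: float = 3.0,
    *,
    blank_rows=None,
    mode: str = "shallowest",
    rel_height: float = 0.0,
    per_column_window: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Detect one reflection depth per column within a depth window.

    Each column is matched-filtered with a Gaussian of the instrument's
    axial point-spread width, then local maxima exceeding
    ``k_sigma`` × (robust noise scale of that column's blank region) are
    located. The shallowest qualifying peak wins (first-reflection
    semantics); ``mode="deepest"`` selects the deepest instead, for bottom
    surfaces. Depths are refined to sub-pixel precision by 3-point parabolic
    interpolation and returned in µm; columns with no qualifying peak are
    returned as NaN, never fabricated.

    ``rel_height`` additionally requires peaks to reach that fraction of the
    window maximum, which suppresses diffuse interior backscatter when
    hunting the bright bottom reflection. ``per_column_window`` optionally
    overrides the lower window edge per column (µm).
    """
    ap = bscan.instrument.axial_pitch
    z_lo, z_hi = search_window
    r_lo, r_hi = int(math.floor(z_lo / ap)), int(math.ceil(z_hi / ap))
    if r_lo < 0 or r_hi > bscan.n_rows or r_lo >= r_hi:
        raise ValueError("search window outside image depth range")
    if mode not in ("shallowest", "deepest"):
        raise ValueError("mode must be 'shallowest' or 'deepest'")

    blank = _as_slice(blank_rows) if blank_rows is not None else slice(0, max(4, r_lo // 2) or 4)
    sigma_px = bscan.instrument.axial_resolution_um * _FWHM_TO_SIGMA / ap

    out = np.full(len(columns), np.nan)
    for i, c in enumerate(columns):
        if not 0 <= c < bscan.n_cols:
            raise ValueError(f"column {c} out of range")
        col = bscan.intensity[:, c]
        blank_vals = col[blank]
        # blank region of a corrected image is zero-clipped noise; rescale
        # its sd back to the raw noise scale
        sigma = blank_vals.std() / _CLIPPED_SD if blank_vals.size else 0.0
        threshold = max(k_sigma * sigma, 1e-12)

        lo = r_lo
        if per_column_window is not None and np.isfinite(per_column_window[i]):
            lo = max(r_lo, int(math.ceil(per_column_window[i] / ap)))
        if lo >= r_hi - 1:
            continue
        smoothed = gaussian_filter1d(col.astype(float), sigma_px, mode="nearest")
        seg = smoothed[lo:r_hi]
        peaks, props = find_peaks(seg, height=threshold)
        if rel_height > 0 and peaks.size:
            keep = props["peak_heights"] >= rel_height * props["peak_heights"].max()
            peaks = peaks[keep]
        if peaks.size == 0:
            continue
        k = peaks[0] if mode == "shallowest" else peaks[-1]
        off = _subpixel_refine(seg, int(k))
        out[i] = (lo + k + off) * ap

    if np.all(np.isnan(out)):
        raise ValueError("no surface found in any requested column")
    return out


def fit_surface(columns, depths, label: str = "") -> SurfaceTrace:
    """Least-squares degree-2 polynomial through (column, depth) detections.

    Duplicate columns are averaged first; at least 3 distinct columns are
    required. NaN depths (missing detections) are dropped.
    """
    columns = np.asarray(columns, dtype=float)
    depths = np.asarray(depths, dtype=float)
    ok = np.isfinite(depths)
    columns, depths = columns[ok], depths[ok]
    if columns.size:
        uniq, inv = np.unique(columns, return_inverse=True)
        sums = np.bincount(inv, weights=depths)
        counts = np.bincount(inv)
        columns, depths = uniq, sums / counts
    if columns.size < 3:
        raise ValueError("fit_surface requires at least 3 non-missing points")
    coeffs = np.polyfit(columns, depths, deg=2)
    resid = depths - np.polyval(coeffs, columns)
    rms = float(np.sqrt(np.mean(resid**2)))
    return SurfaceTrace(columns.astype(int), depths, coeffs, rms, label=label)


def locate_footprint(
    dish_trace: SurfaceTrace,
    top_detections: np.ndarray,
    *,
    clearance_um: float = 10.0,
    edge_margin: int = 2,
):
    """Contiguous column interval where a top reflection sits above the dish.

    Returns an inclusive ``(first, last)`` column pair, or ``None`` when no
    column shows a reflection above the extrapolated dish line (an empty
    footprint, signalled distinctly from an error). A footprint touching the
    image edge raises, since the dish cannot then be fitted on both flanks.
    """
    cols = np.arange(len(top_detections))
    dish_line = dish_trace.poly(cols)
    above = np.isfinite(top_detections) & (top_detections < dish_line - clearance_um)
    if not above.any():
        return None
    runs = _contiguous_runs(above)
    first, last = max(runs, key=lambda r: r[1] - r[0])
    if first <= edge_margin or last >= len(top_detections) - 1 - edge_margin:
        raise ValueError("spheroid not fully in field: footprint touches image edge")
    return (int(first), int(last))


def _contiguous_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    splits = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[0], splits + 1])
    ends = np.concatenate([splits, [idx.size - 1]])
    return [(int(idx[s]), int(idx[e])) for s, e in zip(starts, ends)]


def measure_thickness(
    top: SurfaceTrace,
    bottom: SurfaceTrace,
    dish: SurfaceTrace,
    columns: Sequence[int],
) -> list[ThicknessMeasurement]:
    """Evaluate z1, z0, z0' from the fitted traces at the given columns.

    The dish polynomial is extrapolated beneath the spheroid to give the
    geometrical reference z0. Measurements with t <= 0 or d < t are flagged
    invalid with a reason rather than clamped.
    """
    out = []
    for x in columns:
        z1 = float(top.poly(x))
        z0 = float(dish.poly(x))
        z0p = float(bottom.poly(x))
        t = z0 - z1
        d = z0p - z1
        valid, reason = True, None
        if t <= 0:
            valid, reason = False, "t <= 0 (degenerate geometry)"
        elif d < t:
            valid, reason = False, "d < t (non-physical; check surface assignment)"
        out.append(ThicknessMeasurement(int(x), z1, z0, z0p, t, d, valid, reason))
    return out


def compute_ri(m: ThicknessMeasurement) -> float:
    """Refractive index from one thickness measurement: n_s = d / t.

    Magnitudes are used so either depth-axis orientation yields n_s >= 1;
    the result is invariant to a common rescaling of all depths.
    """
    t, d = abs(m.t), abs(m.d)
    if t == 0:
        raise ValueError("degenerate geometry: t = 0")
    if d < t:
        raise ValueError("non-physical measurement (d < t): check surface assignment")
    return d / t


def aggregate_ri(
    values: Sequence[float],
    min_count: int = 15,
    spheroid_id: Optional[str] = None,
    labels: Optional[dict] = None,
) -> RIEstimate:
    """Mean and sample sd of single-measurement RI values.

    Estimates built from fewer than ``min_count`` measurements carry an
    explicit under-replicated flag (not an error).
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("no RI values to aggregate")
    if not np.all(np.isfinite(arr)):
        raise ValueError("RI values must be finite")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return RIEstimate(
        n_s_mean=float(arr.mean()),
        n_s_sd=sd,
        n_measurements=int(arr.size),
        under_replicated=arr.size < min_count,
        spheroid_id=spheroid_id,
        labels=dict(labels or {}),
    )


def one_way_anova(groups: dict) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA over labelled value collections.

    F = (SSB/df_between) / (SSW/df_within); the p-value comes from the F
    distribution. Significance is reported at alpha = 0.05, two-sided
    convention, no multiple-testing correction.
    """
    if len(groups) < 2:
        raise ValueError("one_way_anova requires at least 2 groups")
    arrs = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, a in arrs.items():
        if a.size < 2:
            raise ValueError(f"group {k!r} has fewer than 2 values")
    all_vals = np.concatenate(list(arrs.values()))
    grand = all_vals.mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrs.values())
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrs.values())
    df_b = len(arrs) - 1
    df_w = all_vals.size - len(arrs)
    if df_w < 1:
        raise ValueError("within-group degrees of freedom must be >= 1")
    if ssw == 0:
        if ssb == 0:
            f_stat, p = 0.0, 1.0
        else:
            warnings.warn(
                "zero within-group variance with unequal means; p reported as limit 0"
            )
            f_stat, p = math.inf, 0.0
    else:
        f_stat = (ssb / df_b) / (ssw / df_w)
        p = float(stats.f.sf(f_stat, df_b, df_w))
    summaries = pd.DataFrame(
        {
            "group": list(arrs),
            "mean": [a.mean() for a in arrs.values()],
            "sd": [a.std(ddof=1) for a in arrs.values()],
            "n": [a.size for a in arrs.values()],
        }
    )
    return AnovaResult(float(f_stat), df_b, df_w, p, summaries, significant=p < 0.05)


def extract_ascan(bscan: BScan, column: int) -> AScanProfile:
    """Pure view of one column's intensity versus calibrated depth."""
    if not 0 <= column < bscan.n_cols:
        raise ValueError(f"column {column} out of range [0, {bscan.n_cols})")
    return AScanProfile(
        column=int(column),
        depth_um=bscan.depth_um,
        intensity=bscan.intensity[:, column].copy(),
        axial_resolution_um=bscan.instrument.axial_resolution_um,
    )


def detect_necrotic_dip(
    profile: AScanProfile,
    z1: float,
    z0_prime: float,
    smooth_width: float = 15.0,
    dip_ratio: float = 0.5,
    *,
    rim_fraction: float = 0.2,
) -> Optional[DipInterval]:
    """Find an interior low-signal interval between the boundary reflections.

    After moving-average smoothing (width ``smooth_width`` µm) the interior
    of the profile — strictly between z1 and z0', excluding a guard band of
    one axial-resolution width at each end — is compared against
    ``dip_ratio`` × the median smoothed intensity of the interior rim zones
    (the first and last ``rim_fraction`` of the interior span). The longest
    sub-threshold run bracketed by supra-threshold signal on *both* sides is
    returned; runs touching either guard band are rejected, so a profile
    that merely decays with depth (signal attenuation, not necrosis) never
    fires the detector.
    """
    if not 0 < dip_ratio < 1:
        raise ValueError("dip_ratio must lie in (0, 1)")
    z = profile.depth_um
    if not (z[0] <= z1 < z0_prime <= z[-1]):
        raise ValueError("boundaries outside profile depth range")
    pitch = float(z[1] - z[0])
    width_px = max(1, int(round(smooth_width / pitch)))
    smoothed = uniform_filter1d(profile.intensity.astype(float), width_px, mode="nearest")

    guard = profile.axial_resolution_um
    interior = (z > z1 + guard) & (z < z0_prime - guard)
    idx = np.flatnonzero(interior)
    if idx.size < 5:
        return None
    span = idx.size
    n_rim = max(1, int(round(rim_fraction * span)))
    rim_vals = np.concatenate([smoothed[idx[:n_rim]], smoothed[idx[-n_rim:]]])
    rim_median = float(np.median(rim_vals))
    if rim_median <= 0:
        return None
    threshold = dip_ratio * rim_median

    below = smoothed[idx] < threshold
    runs = _contiguous_runs(below)
    # a dip must recover on both sides; runs touching a guard band are
    # attenuation, not necrosis
    runs = [r for r in runs if r[0] > 0 and r[1] < span - 1]
    if not runs:
        return None
    s, e = max(runs, key=lambda r: r[1] - r[0])
    seg = smoothed[idx[s] : idx[e] + 1]
    kmin = int(np.argmin(seg))
    return DipInterval(
        column=profile.column,
        dip_start=float(z[idx[s]]),
        dip_end=float(z[idx[e]]),
        depth_of_minimum=float(z[idx[s] + kmin]),
        relative_depth_of_signal=float(seg[kmin] / rim_median),
    )


def oct_diameter(top: SurfaceTrace, dish: SurfaceTrace) -> float:
    """Geometrical thickness t at the apex column (µm).

    The apex is the column maximizing dish.poly(x) − top.poly(x) over the
    top trace's support.
    """
    if top.columns.size == 0:
        raise ValueError("empty footprint: no top-surface support")
    x = np.arange(top.columns.min(), top.columns.max() + 1)
    t = dish.poly(x) - top.poly(x)
    return float(t.max())


def compare_diameters(oct_t: float, brightfield_d: float) -> tuple[float, float]:
    """Ratio and percent difference between OCT and brightfield diameters.

    Returns ``(ratio, percent_difference)`` with
    ratio = oct_t / brightfield_d and percent difference = (1 − ratio)·100.
    """
    if oct_t <= 0 or brightfield_d <= 0:
        raise ValueError("diameters must be positive")
    ratio = oct_t / brightfield_d
    return ratio, (1.0 - ratio) * 100.0


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class SpheroidRIModel:
    """Path-length-matching refractive-index model for one B-scan.

    Parameters
    ----------
    bscan : BScan
        Calibrated intensity image (need not be background-corrected; the
        model corrects it using ``blank_rows``).
    k_sigma : float
        Peak-detection threshold in units of the per-column blank-region
        noise scale.
    blank_rows : slice or (start, stop), optional
        Sample-free rows used for background correction and noise
        estimation. Default: the top 10% of rows (at least 8).
    n_measurement_columns : int
        Number of columns, centred on the apex, at which Eq.-style
        thickness measurements are taken.
    column_spacing : int, optional
        Spacing of measurement columns in pixels. Default: one lateral
        resolution width.
    fit_fraction : float
        Central fraction of the footprint half-width over which the top and
        bottom surface polynomials are fitted. A quadratic is only a local
        model of an elliptical arc; restricting the support keeps the apex
        bias negligible.
    dish_margin : int
        Columns adjacent to the footprint excluded from the dish fit.
    footprint_clearance_um : float
        Minimum height above the dish line for a detection to count as
        spheroid top.
    min_count : int
        Replication threshold below which the aggregate is flagged
        under-replicated.
    """

    def __init__(
        self,
        bscan: BScan,
        *,
        k_sigma: float = 3.0,
        blank_rows=None,
        n_measurement_columns: int = 5,
        column_spacing: Optional[int] = None,
        fit_fraction: float = 0.5,
        dish_margin: int = 10,
        footprint_clearance_um: float = 10.0,
        min_count: int = 15,
    ) -> None:
        self.bscan = bscan
        self.k_sigma = k_sigma
        n_rows = bscan.n_rows
        self.blank_rows = _as_slice(blank_rows) if blank_rows is not None else slice(
            0, max(8, n_rows // 10)
        )
        self.n_measurement_columns = n_measurement_columns
        inst = bscan.instrument
        if column_spacing is None:
            # measurement columns span apex ± one lateral-resolution width,
            # where the spheroid-dish air gap and surface obliquity vanish
            column_spacing = max(
                1, int(round(0.5 * inst.lateral_resolution_um / inst.lateral_pitch))
            )
        self.column_spacing = column_spacing
        self.fit_fraction = fit_fraction
        self.dish_margin = dish_margin
        self.footprint_clearance_um = footprint_clearance_um
        self.min_count = min_count

    @classmethod
    def from_tiff(cls, path, instrument: InstrumentSpec, **kwargs) -> "SpheroidRIModel":
        return cls(BScan.from_tiff(path, instrument), **kwargs)

    # -- fitting ------------------------------------------------------------

    def fit(self) -> "SpheroidRIResults":
        bscan = subtract_background(self.bscan, self.blank_rows)
        inst = bscan.instrument
        ap = inst.axial_pitch
        all_cols = list(range(bscan.n_cols))
        z_lo = (self.blank_rows.stop or 0) * ap
        z_hi = (bscan.n_rows - 1) * ap

        # first reflection per column: dish on the flanks, spheroid top inside
        first = detect_surface_peaks(
            bscan, all_cols, (z_lo, z_hi), self.k_sigma, blank_rows=self.blank_rows
        )

        # provisional dish level from the lateral flanks
        n = bscan.n_cols
        flank = np.concatenate([first[: n // 4], first[-(n // 4):]])
        flank = flank[np.isfinite(flank)]
        if flank.size < 3:
            raise ValueError("no dish reflection found on the image flanks")
        dish_level = float(np.median(flank))

        provisional = np.isfinite(first) & (
            first < dish_level - self.footprint_clearance_um
        )
        runs = _contiguous_runs(provisional)
        if runs:
            f0, f1 = max(runs, key=lambda r: r[1] - r[0])
        else:
            f0, f1 = None, None

        # dish fit on columns outside footprint plus a safety margin
        dish_cols = np.arange(n)
        if f0 is not None:
            outside = (dish_cols < f0 - self.dish_margin) | (
                dish_cols > f1 + self.dish_margin
            )
        else:
            outside = np.ones(n, dtype=bool)
        dish_trace = fit_surface(dish_cols[outside], first[outside], label="dish")

        footprint = locate_footprint(
            dish_trace, first, clearance_um=self.footprint_clearance_um
        )
        if footprint is None:
            raise ValueError("no spheroid footprint found in image")
        f0, f1 = footprint

        # restrict surface fits to the central portion of the footprint
        half = (f1 - f0) / 2.0
        c_mid = (f0 + f1) / 2.0
        lo = int(math.ceil(c_mid - self.fit_fraction * half))
        hi = int(math.floor(c_mid + self.fit_fraction * half))
        central = np.arange(lo, hi + 1)
        top_trace = fit_surface(central, first[central], label="spheroid_top")

        # bottom surface: deepest strong peak below the top reflection
        below = first[central] + 3.0 * inst.axial_resolution_um
        bottom_z = detect_surface_peaks(
            bscan,
            list(central),
            (z_lo, z_hi),
            self.k_sigma,
            blank_rows=self.blank_rows,
            mode="deepest",
            rel_height=0.25,
            per_column_window=below,
        )
        bottom_trace = fit_surface(central, bottom_z, label="spheroid_bottom")

        # apex and measurement columns
        t_curve = dish_trace.poly(central) - top_trace.poly(central)
        apex_col = int(central[np.argmax(t_curve)])
        offsets = np.arange(self.n_measurement_columns) - (self.n_measurement_columns - 1) // 2
        meas_cols = apex_col + offsets * self.column_spacing
        meas_cols = meas_cols[(meas_cols >= lo) & (meas_cols <= hi)]

        measurements = measure_thickness(top_trace, bottom_trace, dish_trace, meas_cols)
        ri_values = [compute_ri(m) for m in measurements if m.valid]
        if not ri_values:
            raise ValueError("no valid thickness measurement (all filtered)")
        estimate = aggregate_ri(ri_values, min_count=self.min_count)

        return SpheroidRIResults(
            model=self,
            corrected=bscan,
            dish=dish_trace,
            top=top_trace,
            bottom=bottom_trace,
            footprint=(f0, f1),
            apex_column=apex_col,
            measurements=measurements,
            estimate=estimate,
        )


@dataclass
class SpheroidRIResults:
    """Fitted surfaces, thickness measurements and the aggregated RI."""

    model: SpheroidRIModel
    corrected: BScan
    dish: SurfaceTrace
    top: SurfaceTrace
    bottom: SurfaceTrace
    footprint: tuple[int, int]
    apex_column: int
    measurements: list[ThicknessMeasurement]
    estimate: RIEstimate

    @property
    def n_s(self) -> float:
        return self.estimate.n_s_mean

    @property
    def n_s_sd(self) -> float:
        return self.estimate.n_s_sd

    @property
    def ri_values(self) -> list[float]:
        return [compute_ri(m) for m in self.measurements if m.valid]

    def measurements_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.measurements:
            rows.append(
                {
                    "column": m.column,
                    "z1_um": m.z1,
                    "z0_um": m.z0,
                    "z0_prime_um": m.z0_prime,
                    "t_um": m.t,
                    "d_um": m.d,
                    "n_s": compute_ri(m) if m.valid else np.nan,
                    "valid": m.valid,
                    "reason": m.reason or "",
                }
            )
        return pd.DataFrame(rows)

    def oct_diameter(self) -> float:
        return oct_diameter(self.top, self.dish)

    def summary(self) -> str:
        df = self.measurements_frame()
        lines = [
            "Spheroid refractive index - path-length matching",
            "=" * 56,
            f"footprint columns        : [{self.footprint[0]}, {self.footprint[1]}]",
            f"apex column              : {self.apex_column}",
            f"geometrical thickness t  : {self.oct_diameter():.1f} um (apex)",
            f"dish fit rms residual    : {self.dish.rms_residual:.3f} um",
            f"top fit rms residual     : {self.top.rms_residual:.3f} um",
            f"bottom fit rms residual  : {self.bottom.rms_residual:.3f} um",
            "",
            df.to_string(index=False, float_format=lambda v: f"{v:.3f}"),
            "",
            f"n_s = {self.estimate.n_s_mean:.4f} +/- {self.estimate.n_s_sd:.4f} "
            f"(n = {self.estimate.n_measurements}"
            + (", under-replicated)" if self.estimate.under_replicated else ")"),
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Overlay the fitted dish/top/bottom polynomials on the B-scan."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        inst = self.corrected.instrument
        ax.imshow(
            self.corrected.intensity,
            aspect="auto",
            cmap="gray",
            extent=[0, self.corrected.n_cols, self.corrected.depth_um[-1], 0],
        )
        xs = np.arange(self.corrected.n_cols)
        ax.plot(xs, self.dish.poly(xs), "r-", lw=1, label="dish")
        xc = np.arange(self.footprint[0], self.footprint[1] + 1)
        ax.plot(xc, self.top.poly(xc), "c-", lw=1, label="top")
        ax.plot(xc, self.bottom.poly(xc), "b-", lw=1, label="bottom")
        for m in self.measurements:
            ax.plot([m.column] * 3, [m.z1, m.z0, m.z0_prime], "o", ms=3)
        ax.set_xlabel("column")
        ax.set_ylabel("depth (um, air-equivalent)")
        ax.legend(loc="lower right", fontsize="small")
        return ax
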