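"""Seeded synthetic image generation with analytic ground truth.

Three generators emulate the raw data of a spheroid optical-characterisation
experiment:

* :func:`simulate_bscan` — a cross-sectional OCT intensity image of an
  elliptical spheroid resting tangent on a flat reflective Petri dish. The
  forward model encodes the single physical fact the analysis pipeline
  exploits: depth in an OCT image is *optical* path, so every reflection
  beneath the spheroid surface is displaced deeper by the factor ``n_s``
  (the group refractive index) times the geometrical path travelled in
  tissue. The dish reflection under the spheroid therefore appears displaced
  by ``(n_s − 1) · chord(x)`` relative to the extrapolated dish line.
* :func:`simulate_brightfield` — a dark circular silhouette on a bright
  background with optional debris blobs, for morphometry.
* :func:`simulate_confocal_stack` — a z-stack whose in-ROI fluorescence
  decays exponentially with depth, for penetration-depth analysis.

All generators are deterministic given a seed, and return a
:class:`GroundTruth` sidecar object so every downstream estimate can be
checked against the analytic truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .instrument import InstrumentSpec

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass(frozen=True)
class SpheroidPhantom:
    """Geometric and optical description of a simulated spheroid.

    The spheroid is an ellipse of lateral semi-axis ``a`` and axial semi-axis
    ``b`` (µm), tangent to the dish from above: its bottom apex sits exactly
    at ``dish_z``. ``mu_t_sim`` is the generative attenuation rate applied as
    exp(−2·mu_t_sim·path-in-tissue). A centred low-backscatter core of radius
    fraction ``necrotic_fraction`` emulates necrosis.
    """

    center_x: float = 640.0
    a: float = 250.0
    b: float = 150.0
    n_s: float = 1.38
    backscatter_level: float = 60.0
    surface_reflectivity: float = 800.0
    mu_t_sim: float = 0.0
    necrotic_fraction: float = 0.0
    necrotic_contrast: float = 1.0
    dish_z: float = 500.0
    air_gap: bool = False

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("semi-axes a, b must be > 0")
        if self.n_s < 1.0:
            raise ValueError("n_s must be >= 1 (physical sample)")
        if not 0.0 <= self.necrotic_fraction < 1.0:
            raise ValueError("necrotic_fraction must lie in [0, 1)")
        if not 0.0 <= self.necrotic_contrast <= 1.0:
            raise ValueError("necrotic_contrast must lie in [0, 1]")
        if self.dish_z <= 2 * self.b:
            raise ValueError(
                f"spheroid top (dish_z - 2b = {self.dish_z - 2 * self.b:g} um) "
                "must lie below depth 0"
            )

    @property
    def apex_chord(self) -> float:
        """Axial chord through the centre, 2b (µm)."""
        return 2.0 * self.b


@dataclass
class GroundTruth:
    """Analytic truth accompanying a simulated image (test oracle container)."""

    n_s_true: Optional[float] = None
    dish_z: Optional[float] = None
    columns: Optional[np.ndarray] = None        # footprint column indices
    top_surface: Optional[np.ndarray] = None    # µm per footprint column
    apparent_bottom: Optional[np.ndarray] = None
    chord: Optional[np.ndarray] = None          # geometrical chord, µm
    gap: Optional[np.ndarray] = None            # air gap below spheroid, µm
    apex_column: Optional[int] = None
    necrotic_extent: Optional[tuple] = None     # (z_lo, z_hi) µm, image coords
    seed: Optional[int] = None
    # brightfield
    area_um2: Optional[float] = None
    equivalent_diameter_um: Optional[float] = None
    mask: Optional[np.ndarray] = None
    n_objects: Optional[int] = None
    # confocal
    max_depth_true: Optional[float] = None
    roi_mask: Optional[np.ndarray] = None

    def to_dict(self) -> dict:
        out = {}
        for k, v in asdict(self).items():
            if v is None:
                continue
            if isinstance(v, np.ndarray):
                if k == "mask" or k == "roi_mask":
                    continue  # rasters are not serialized into the sidecar
                v = v.tolist()
            out[k] = v
        return out


def _speckle_field(rng: np.random.Generator, shape: tuple, contrast: float) -> np.ndarray:
    """Multiplicative speckle: unit-mean gamma field with σ/mean = contrast.

    Gamma(k, θ) with k = 1/c², θ = c² has mean 1 and sd c; at c = 1 this is
    the exponential intensity law of fully developed speckle.
    """
    if contrast <= 0:
        return np.ones(shape)
    k = 1.0 / contrast**2
    return rng.gamma(shape=k, scale=contrast**2, size=shape)


def simulate_bscan(
    phantom: SpheroidPhantom,
    instrument: InstrumentSpec,
    seed: int,
    *,
    n_rows: int = 384,
    n_cols: int = 256,
) -> tuple[np.ndarray, GroundTruth]:
    """Render a B-scan of `phantom` and return it with its ground truth.

    Rows are depth (air-equivalent µm = row · ``axial_pitch``), columns are
    lateral position (µm = col · ``lateral_pitch``). Outside the spheroid
    footprint a single bright dish reflection sits at ``dish_z``; inside, the
    top-surface reflection follows the ellipse upper boundary and the bottom
    reflection is displaced deeper by ``(n_s − 1) · chord(x)`` relative to
    the extrapolated dish line. Reflections carry a Gaussian axial
    point-spread of FWHM ``instrument.axial_resolution_um``; multiplicative
    speckle and an additive noise floor are applied last.

    Raises
    ------
    ValueError
        If the phantom geometry extends beyond the image, naming the
        violated bound.
    """
    ap, lp = instrument.axial_pitch, instrument.lateral_pitch
    depth_extent = (n_rows - 1) * ap
    width_extent = (n_cols - 1) * lp

    margin = 3.0 * instrument.axial_resolution_um
    z_top_apex = phantom.dish_z - 2.0 * phantom.b
    if z_top_apex < margin:
        raise ValueError(
            f"spheroid top at {z_top_apex:g} um is above the usable image top "
            f"(needs >= {margin:g} um for the axial PSF)"
        )
    deepest = z_top_apex + phantom.n_s * 2.0 * phantom.b + (
        0.0 if not phantom.air_gap else 0.0
    )
    if deepest + margin > depth_extent:
        raise ValueError(
            f"apparent spheroid bottom at {deepest:g} um exceeds image depth "
            f"extent {depth_extent:g} um"
        )
    if phantom.center_x - phantom.a < 0 or phantom.center_x + phantom.a > width_extent:
        raise ValueError(
            f"lateral extent [{phantom.center_x - phantom.a:g}, "
            f"{phantom.center_x + phantom.a:g}] um exceeds image width "
            f"[0, {width_extent:g}] um"
        )

    z = np.arange(n_rows) * ap  # depth grid, µm
    sigma_um = instrument.axial_resolution_um * _FWHM_TO_SIGMA
    sigma_px = sigma_um / ap

    img = np.zeros((n_rows, n_cols))
    zc = phantom.dish_z - phantom.b  # physical ellipse centre depth

    cols = np.arange(n_cols)
    x_um = cols * lp
    u = (x_um - phantom.center_x) / phantom.a
    inside = np.abs(u) < 1.0

    fp_cols, tops, bottoms, chords, gaps = [], [], [], [], []

    def peak(z0: float, amp: float) -> np.ndarray:
        return amp * np.exp(-0.5 * ((z - z0) / sigma_um) ** 2)

    for j in cols:
        col = np.zeros(n_rows)
        if not inside[j]:
            col += peak(phantom.dish_z, instrument.dish_reflectivity)
        else:
            s = math.sqrt(1.0 - u[j] ** 2)
            chord = 2.0 * phantom.b * s
            z_top = zc - phantom.b * s
            z_bot_img = z_top + phantom.n_s * chord
            gap = phantom.b * (1.0 - s)

            # diffuse interior backscatter with depth attenuation
            interior = (z > z_top) & (z < z_bot_img)
            if interior.any():
                p = (z[interior] - z_top) / phantom.n_s  # physical path in tissue
                level = phantom.backscatter_level * np.exp(-2.0 * phantom.mu_t_sim * p)
                if phantom.necrotic_fraction > 0.0:
                    z_phys = z_top + p
                    f = phantom.necrotic_fraction
                    in_core = (u[j] / f) ** 2 + ((z_phys - zc) / (f * phantom.b)) ** 2 <= 1.0
                    level = np.where(in_core, level * phantom.necrotic_contrast, level)
                smoothed = np.zeros(n_rows)
                smoothed[interior] = level
                col += gaussian_filter1d(smoothed, sigma_px, mode="constant")

            att = math.exp(-2.0 * phantom.mu_t_sim * chord)
            col += peak(z_top, phantom.surface_reflectivity)
            col += peak(z_bot_img, instrument.dish_reflectivity * att)
            if phantom.air_gap and gap > 0.0:
                col += peak(z_bot_img + gap, instrument.dish_reflectivity * att)

            fp_cols.append(j)
            tops.append(z_top)
            bottoms.append(z_bot_img + (gap if phantom.air_gap else 0.0))
            chords.append(chord)
            gaps.append(gap if phantom.air_gap else 0.0)
        img[:, j] = col

    rng = np.random.default_rng(seed)
    img *= _speckle_field(rng, img.shape, instrument.speckle_contrast)
    if instrument.noise_floor > 0:
        img += instrument.noise_floor
        img += rng.normal(0.0, 0.2 * instrument.noise_floor, img.shape)
        np.clip(img, 0.0, None, out=img)

    necrotic_extent = None
    if phantom.necrotic_fraction > 0.0:
        # axial extent of the core at the centre column, in image (optical) depth
        f = phantom.necrotic_fraction
        z_top_c = phantom.dish_z - 2.0 * phantom.b
        lo_phys, hi_phys = zc - f * phantom.b, zc + f * phantom.b
        necrotic_extent = (
            z_top_c + phantom.n_s * (lo_phys - z_top_c),
            z_top_c + phantom.n_s * (hi_phys - z_top_c),
        )

    gt = GroundTruth(
        n_s_true=phantom.n_s,
        dish_z=phantom.dish_z,
        columns=np.asarray(fp_cols, dtype=int),
        top_surface=np.asarray(tops),
        apparent_bottom=np.asarray(bottoms),
        chord=np.asarray(chords),
        gap=np.asarray(gaps),
        apex_column=int(round(phantom.center_x / lp)),
        necrotic_extent=necrotic_extent,
        seed=seed,
    )
    return img, gt


def simulate_brightfield(
    phantom: SpheroidPhantom,
    lateral_pitch: float,
    debris_count: int,
    seed: int,
    *,
    shape: tuple[int, int] = (768, 768),
    background: float = 200.0,
    object_level: float = 50.0,
    noise_sigma: float = 0.0,
    debris_radius_px: tuple[int, int] = (2, 4),
    max_retries: int = 200,
) -> tuple[np.ndarray, GroundTruth]:
    """Render a transmitted-light silhouette image of the spheroid.

    The projected spheroid is a dark disk of radius ``phantom.a`` µm on a
    bright background, plus ``debris_count`` small dark blobs that do not
    touch the main object. Ground truth records the analytic area and
    equivalent diameter and the noiseless object mask.
    """
    if lateral_pitch <= 0:
        raise ValueError("lateral_pitch must be > 0")
    rng = np.random.default_rng(seed)
    n_rows, n_cols = shape
    r_px = phantom.a / lateral_pitch
    cy, cx = n_rows / 2.0, n_cols / 2.0
    if r_px >= min(cy, cx) - 8:
        raise ValueError("spheroid silhouette does not fit in the image")

    yy, xx = np.mgrid[0:n_rows, 0:n_cols]
    main = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_px**2
    mask = main.copy()

    placed = 0
    tries = 0
    clearance = r_px + 3 * max(debris_radius_px) + 4
    while placed < debris_count:
        if tries > max_retries * max(debris_count, 1):
            raise RuntimeError("could not place debris without overlapping the spheroid")
        tries += 1
        r_d = rng.integers(debris_radius_px[0], debris_radius_px[1] + 1)
        dy = rng.uniform(r_d + 2, n_rows - r_d - 3)
        dx = rng.uniform(r_d + 2, n_cols - r_d - 3)
        if math.hypot(dy - cy, dx - cx) < clearance:
            continue
        blob = (yy - dy) ** 2 + (xx - dx) ** 2 <= r_d**2
        if (blob & mask).any():
            continue
        mask |= blob
        placed += 1

    img = np.full(shape, background, dtype=float)
    img[mask] = object_level
    if noise_sigma > 0:
        img += rng.normal(0.0, noise_sigma, shape)
        np.clip(img, 0.0, None, out=img)

    gt = GroundTruth(
        area_um2=math.pi * phantom.a**2,
        equivalent_diameter_um=2.0 * phantom.a,
        mask=mask,
        n_objects=1 + debris_count,
        seed=seed,
    )
    return img, gt


def simulate_confocal_stack(
    n_slices: int,
    step: float,
    roi_radius: float,
    signal0: float,
    decay_length: float,
    background_mean: float,
    seed: int,
    *,
    shape: tuple[int, int] = (128, 128),
    noise: bool = True,
) -> tuple[np.ndarray, GroundTruth]:
    """Simulate a fluorescence z-stack with exponential signal decay.

    Slice ``k`` carries an in-ROI expected signal of
    ``background_mean + signal0 · exp(−k·step/decay_length)``; pixels are
    Poisson counts (or rounded expectations with ``noise=False``), emulating
    the depth-dependent signal loss caused by refractive-index mismatch
    between spheroid and immersion medium.

    Ground truth ``max_depth_true`` is the depth of the first slice whose
    expected excess signal falls below half an intensity count — the first
    slice whose rounded noise-free value is indistinguishable from
    background — or the full stack extent if no slice decays that far.
    """
    if n_slices < 2:
        raise ValueError("n_slices must be >= 2")
    if step <= 0:
        raise ValueError("step must be > 0")
    if decay_length <= 0:
        raise ValueError("decay_length must be > 0")
    rng = np.random.default_rng(seed)
    n_rows, n_cols = shape
    yy, xx = np.mgrid[0:n_rows, 0:n_cols]
    roi = (yy - n_rows / 2.0) ** 2 + (xx - n_cols / 2.0) ** 2 <= roi_radius**2

    stack = np.empty((n_slices, n_rows, n_cols))
    max_depth = None
    for k in range(n_slices):
        excess = signal0 * math.exp(-k * step / decay_length) if signal0 > 0 else 0.0
        expected = np.where(roi, background_mean + excess, background_mean)
        if noise:
            stack[k] = rng.poisson(expected)
        else:
            stack[k] = np.round(expected)
        if max_depth is None and excess < 0.5:
            max_depth = k * step
    if max_depth is None:
        max_depth = (n_slices - 1) * step

    gt = GroundTruth(max_depth_true=max_depth, roi_mask=roi, seed=seed)
    return stack, gt
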