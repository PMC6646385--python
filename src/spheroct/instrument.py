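"""Instrument and calibration descriptions.

Depth conventions used throughout the package: image rows run downward with
physical depth, and all stored depths are *air-equivalent optical distances*
in micrometres (what a time-of-flight instrument actually measures), converted
from pixels via ``axial_pitch``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


def coherence_axial_resolution(lambda0_nm: float, delta_lambda_nm: float) -> float:
    """Theoretical axial resolution (µm, in air) of a Gaussian-spectrum source.

    l_c = (2 ln 2 / π) · λ0² / Δλ, the round-trip coherence length that sets
    the depth-gating width of a low-coherence interferometer.
    """
    if lambda0_nm <= 0 or delta_lambda_nm <= 0:
        raise ValueError("wavelengths must be positive")
    lc_nm = (2.0 * math.log(2.0) / math.pi) * lambda0_nm**2 / delta_lambda_nm
    return lc_nm * 1e-3


@dataclass(frozen=True)
class InstrumentSpec:
    """Optical and sampling parameters of the tomography system.

    Parameters
    ----------
    lambda0 : float
        Central wavelength of the source, nm.
    delta_lambda : float
        Source bandwidth, nm (metadata; the point-spread width used by the
        simulator is `axial_resolution_um`, see below).
    axial_pitch : float
        Air-equivalent µm per pixel along depth.
    lateral_pitch : float
        µm per pixel laterally.
    axial_resolution_um : float
        FWHM of the axial point-spread function, µm in air. Kept as an
        explicit parameter rather than derived from ``delta_lambda`` because
        published system descriptions commonly quote both numbers and they
        need not be mutually consistent; the measured/quoted resolution is
        authoritative here.
    lateral_resolution_um : float
        Lateral (spot) resolution, µm. Metadata; also sets the default
        spacing of measurement columns in the RI pipeline.
    depth_of_focus_um : float
        Confocal parameter / depth of focus, µm. Metadata only.
    noise_floor : float
        Mean additive background intensity level (counts).
    speckle_contrast : float
        σ/mean of the multiplicative speckle field, in [0, 1]. 1 corresponds
        to fully developed speckle; 0 disables it.
    dish_reflectivity : float
        Peak intensity of the dish first reflection (counts).
    """

    lambda0: float = 840.0
    delta_lambda: float = 10.0
    axial_pitch: float = 2.0
    lateral_pitch: float = 5.0
    axial_resolution_um: float = 3.1
    lateral_resolution_um: float = 21.0
    depth_of_focus_um: float = 820.0
    noise_floor: float = 0.0
    speckle_contrast: float = 0.0
    dish_reflectivity: float = 1000.0

    def __post_init__(self) -> None:
        if self.lambda0 <= 0:
            raise ValueError("lambda0 must be > 0")
        if self.delta_lambda <= 0:
            raise ValueError("delta_lambda must be > 0")
        if self.axial_pitch <= 0:
            raise ValueError("axial_pitch must be > 0")
        if self.lateral_pitch <= 0:
            raise ValueError("lateral_pitch must be > 0")
        if self.axial_resolution_um <= 0:
            raise ValueError("axial_resolution_um must be > 0")
        if not 0.0 <= self.speckle_contrast <= 1.0:
            raise ValueError("speckle_contrast must lie in [0, 1]")
        if self.noise_floor < 0:
            raise ValueError("noise_floor must be nonnegative")


@dataclass(frozen=True)
class Calibration:
    """Pixel calibration for brightfield morphometry (µm per pixel)."""

    microns_per_pixel: float = 0.891

    def __post_init__(self) -> None:
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be > 0")
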