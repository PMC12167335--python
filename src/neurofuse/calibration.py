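"""Radiometric calibration of the two optical modalities.

Hyperspectral cubes are converted from raw digital numbers to reflectance
fraction with white/dark reference cubes, and restricted to the bands the
operating light source actually illuminates.  pCLE frames are corrected by
subtracting a fluorescence-free background reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import envi

logger = logging.getLogger(__name__)

#: Denominator guard (digital numbers): pixel-bands where the white-dark
#: difference falls below this are flagged invalid instead of divided.
DENOMINATOR_TOL = 1e-6

#: Default illumination cutoff: the microscope light source emits up to
#: 770 nm, so bands centred at or above it carry no signal.
DEFAULT_CUTOFF_NM = 770.0


class CalibrationError(ValueError):
    """Shape/band mismatch or other calibration precondition failure."""


class EmptyBandSelection(CalibrationError):
    """Band restriction left no band below the cutoff."""


def _check_band_axes(data: np.ndarray, band_centers_nm: np.ndarray) -> None:
    if data.ndim != 3:
        raise CalibrationError("cube data must be rows x cols x bands")
    if data.shape[2] != band_centers_nm.shape[0]:
        raise CalibrationError(
            f"band axis {data.shape[2]} != band centers {band_centers_nm.shape[0]}")
    if band_centers_nm.ndim != 1 or np.any(np.diff(band_centers_nm) <= 0):
        raise CalibrationError("band centers must be strictly increasing")
    if np.any(band_centers_nm <= 0):
        raise CalibrationError("band centers must be positive (nanometres)")
    if not np.all(np.isfinite(data)):
        raise CalibrationError("cube data contains non-finite values")


@dataclass
class RawCube:
    """Uncalibrated cube in digital numbers.

    Also represents the white (``W``) and dark (``D``) reference acquisitions.
    """

    data: np.ndarray                  # rows x cols x bands, digital numbers
    band_centers_nm: np.ndarray       # strictly increasing, nm

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.band_centers_nm = np.asarray(self.band_centers_nm, dtype=np.float64)
        _check_band_axes(self.data, self.band_centers_nm)

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]


@dataclass
class ReflectanceCube:
    """White/dark-calibrated cube in unitless reflectance fraction.

    ``valid_mask`` is False where the white-dark denominator was degenerate;
    downstream classification must exclude those pixels.  ``pixel_size_mm``
    is the on-specimen footprint of one pixel at the working distance
    (0.31 mm for the hyperspectral camera at 30 cm).
    """

    data: np.ndarray
    band_centers_nm: np.ndarray
    pixel_size_mm: float = 0.31
    valid_mask: np.ndarray | None = None   # rows x cols, True where usable

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.band_centers_nm = np.asarray(self.band_centers_nm, dtype=np.float64)
        _check_band_axes(self.data, self.band_centers_nm)
        if self.pixel_size_mm <= 0:
            raise CalibrationError("pixel_size_mm must be positive")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.data.shape[:2], dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.data.shape[:2]:
                raise CalibrationError("valid_mask shape must match spatial dims")

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]


@dataclass
class PCLEFrame:
    """A grayscale confocal endomicroscopy frame."""

    image: np.ndarray
    is_background_corrected: bool = False

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=np.float64)
        if self.image.ndim != 2:
            raise CalibrationError("pCLE frame must be a 2-D grayscale array")
        if self.is_background_corrected and np.any(self.image < 0):
            raise CalibrationError("corrected frame must be non-negative")


def white_dark_calibrate(raw: RawCube, white: RawCube, dark: RawCube,
                         pixel_size_mm: float = 0.31) -> ReflectanceCube:
    """Convert raw digital numbers to reflectance: ``(R - D) / (W - D)``.

    Pixel-bands whose denominator ``W - D`` is at or below
    :data:`DENOMINATOR_TOL` are excluded via the output validity mask
    (a pixel is invalid if any of its bands is degenerate).  Negative
    reflectance (``R < D``) is clipped to zero with a logged count;
    reflectance above 1 (specular highlights) passes through unclipped.
    """
    for other, name in ((white, "white"), (dark, "dark")):
        if other.data.shape != raw.data.shape:
            raise CalibrationError(f"{name} reference shape differs from raw")
        if not np.array_equal(other.band_centers_nm, raw.band_centers_nm):
            raise CalibrationError(f"{name} reference band centers differ from raw")

    denom = white.data - dark.data
    bad = denom <= DENOMINATOR_TOL
    safe_denom = np.where(bad, 1.0, denom)
    refl = (raw.data - dark.data) / safe_denom
    refl[bad] = 0.0

    n_neg = int(np.count_nonzero(refl < 0))
    if n_neg:
        logger.info("clipped %d negative reflectance values to 0", n_neg)
        refl = np.clip(refl, 0.0, None)
    n_over = int(np.count_nonzero(refl > 1))
    if n_over:
        logger.info("%d reflectance values exceed 1 (passed through)", n_over)

    valid = ~np.any(bad, axis=2)
    return ReflectanceCube(data=refl, band_centers_nm=raw.band_centers_nm.copy(),
                           pixel_size_mm=pixel_size_mm, valid_mask=valid)


def restrict_bands(cube: RawCube | ReflectanceCube,
                   cutoff_nm: float = DEFAULT_CUTOFF_NM):
    """Keep only the bands centred strictly below ``cutoff_nm``.

    With the 51 factory bands evenly spaced over 450-850 nm and the default
    770 nm illumination limit this retains 40 bands ending at 762 nm.
    """
    keep = cube.band_centers_nm < cutoff_nm
    if not np.any(keep):
        raise EmptyBandSelection(
            f"no band center below cutoff {cutoff_nm} nm "
            f"(min center {cube.band_centers_nm.min()} nm)")
    data = cube.data[:, :, keep]
    centers = cube.band_centers_nm[keep]
    if isinstance(cube, ReflectanceCube):
        return ReflectanceCube(data=data, band_centers_nm=centers,
                               pixel_size_mm=cube.pixel_size_mm,
                               valid_mask=cube.valid_mask.copy())
    return RawCube(data=data, band_centers_nm=centers)


def pcle_background_subtract(frame: PCLEFrame, background: PCLEFrame) -> PCLEFrame:
    """Subtract the fluorescence-free reference, flooring at zero."""
    if frame.is_background_corrected or background.is_background_corrected:
        raise CalibrationError("background subtraction applied twice")
    if frame.image.shape != background.image.shape:
        raise CalibrationError("frame and background shapes differ")
    corrected = np.clip(frame.image - background.image, 0.0, None)
    return PCLEFrame(image=corrected, is_background_corrected=True)


# --- cube file I/O -------------------------------------------------------

def load_raw_cube(path_hdr: str | Path,
                  default_range_nm: tuple[float, float] = (450.0, 850.0)) -> RawCube:
    """Load a cube from an ENVI pair.

    If the header lacks a wavelength list, band centers default to even
    spacing across ``default_range_nm`` (the sensor's stated range).
    """
    data, wl = envi.read_envi(path_hdr)
    if wl is None:
        wl = np.linspace(default_range_nm[0], default_range_nm[1], data.shape[2])
    return RawCube(data=data, band_centers_nm=wl)


def save_cube(path_hdr: str | Path, cube: RawCube | ReflectanceCube) -> None:
    envi.write_envi(path_hdr, cube.data, cube.band_centers_nm)
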