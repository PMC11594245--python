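"""Hyperspectral cubes, reflectance calibration, band cropping and masking.

A cube is an ``H x W x B`` array of intensities (raw sensor counts) or
reflectance, together with a strictly increasing wavelength vector of length
``B`` (nanometres).  Raw counts are turned into dimensionless reflectance by
min-max calibration against dark-current and white-reference cubes,

    R = (I_raw - I_dark) / (I_white - I_dark),

after which only a contiguous near-infrared band window is retained (the
band edges carry low signal-to-noise) and pixels whose mean reflectance over
the retained bands does not exceed a threshold are discarded as background,
shadow or dead pixels.  The surviving "effective" pixels provide one spectrum
each; every physical sample (instance) therefore contributes a matrix of
pixel spectra rather than a single averaged spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    CalibrationReferenceError,
    ConfigurationError,
    DegenerateInstanceError,
    InputError,
)

__all__ = [
    "RawCube",
    "CalibrationPair",
    "CalibratedCube",
    "InstanceRecord",
    "calibrate",
    "select_bands",
    "effective_mask",
    "cube_to_instance",
]


def _check_wavelengths(wavelengths: np.ndarray, n_bands: int) -> np.ndarray:
    wl = np.asarray(wavelengths, dtype=float).ravel()
    if wl.size != n_bands:
        raise InputError(
            f"wavelength vector has {wl.size} entries but cube has {n_bands} bands"
        )
    if wl.size > 1 and not np.all(np.diff(wl) > 0):
        raise InputError("wavelengths must be strictly increasing")
    return wl


@dataclass
class RawCube:
    """Raw sensor counts ``H x W x B`` plus band-centre wavelengths (nm)."""

    values: np.ndarray
    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise InputError(f"cube must be 3-D (H, W, B); got shape {self.values.shape}")
        self.wavelengths = _check_wavelengths(self.wavelengths, self.values.shape[2])

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class CalibrationPair:
    """Dark-current and white-reference cubes matching a raw cube's shape."""

    dark: np.ndarray
    white: np.ndarray

    def __post_init__(self) -> None:
        self.dark = np.asarray(self.dark, dtype=float)
        self.white = np.asarray(self.white, dtype=float)
        if self.dark.shape != self.white.shape:
            raise InputError(
                f"dark shape {self.dark.shape} != white shape {self.white.shape}"
            )


@dataclass
class CalibratedCube:
    """Dimensionless reflectance cube with optional effective-pixel mask."""

    reflectance: np.ndarray
    wavelengths: np.ndarray
    mask: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.reflectance.ndim != 3:
            raise InputError(
                f"cube must be 3-D (H, W, B); got shape {self.reflectance.shape}"
            )
        self.wavelengths = _check_wavelengths(
            self.wavelengths, self.reflectance.shape[2]
        )
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.reflectance.shape[:2]:
                raise InputError(
                    f"mask shape {self.mask.shape} does not match spatial shape "
                    f"{self.reflectance.shape[:2]}"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.reflectance.shape


@dataclass
class InstanceRecord:
    """Effective-pixel spectra of one physical sample.

    ``spectra`` is ``N x D`` (one row per effective pixel, restricted to the
    retained bands); ``pixel_coords`` is ``N x 2`` of (row, col) positions so
    pixel-level maps can be reconstructed.
    """

    instance_id: str
    label: int
    spectra: np.ndarray
    pixel_coords: np.ndarray

    def __post_init__(self) -> None:
        self.spectra = np.atleast_2d(np.asarray(self.spectra, dtype=float))
        self.pixel_coords = np.atleast_2d(np.asarray(self.pixel_coords, dtype=int))
        if self.spectra.shape[0] < 1:
            raise DegenerateInstanceError(
                f"instance {self.instance_id!r} has no spectra"
            )
        if self.pixel_coords.shape != (self.spectra.shape[0], 2):
            raise InputError(
                f"pixel_coords shape {self.pixel_coords.shape} inconsistent with "
                f"{self.spectra.shape[0]} spectra"
            )
        if not np.all(np.isfinite(self.spectra)):
            raise InputError(f"instance {self.instance_id!r} has non-finite spectra")

    @property
    def n_pixels(self) -> int:
        return self.spectra.shape[0]

    @property
    def n_bands(self) -> int:
        return self.spectra.shape[1]


def calibrate(raw: RawCube, refs: CalibrationPair) -> CalibratedCube:
    """Min-max calibrate raw counts to reflectance.

    ``R = (raw - dark) / (white - dark)`` elementwise.  The returned cube has
    no mask; call :func:`effective_mask` after band selection.

    Raises
    ------
    InputError
        if shapes disagree.
    CalibrationReferenceError
        if any ``white - dark`` element is <= 0, naming an offending position.
    """
    if refs.dark.shape != raw.values.shape:
        raise InputError(
            f"reference shape {refs.dark.shape} != cube shape {raw.values.shape}"
        )
    denom = refs.white - refs.dark
    bad = denom <= 0
    if np.any(bad):
        r, c, b = (int(i[0]) for i in np.nonzero(bad))
        raise CalibrationReferenceError(
            f"white - dark is non-positive at pixel ({r}, {c}), band {b} "
            f"(value {denom[r, c, b]:g}); check reference cubes"
        )
    reflectance = (raw.values - refs.dark) / denom
    return CalibratedCube(reflectance=reflectance, wavelengths=raw.wavelengths)


def select_bands(wavelengths: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Indices of bands whose centre lies in the closed interval [lo, hi] nm.

    The result is a contiguous, sorted integer index array; its length is the
    spectral dimensionality D used downstream.
    """
    if not lo < hi:
        raise ConfigurationError(f"band window requires lo < hi; got [{lo}, {hi}]")
    wl = _check_wavelengths(np.asarray(wavelengths, dtype=float), len(wavelengths))
    idx = np.nonzero((wl >= lo) & (wl <= hi))[0]
    if idx.size == 0:
        raise ConfigurationError(
            f"no bands fall in [{lo}, {hi}] nm "
            f"(wavelengths span [{wl.min():g}, {wl.max():g}] nm)"
        )
    return idx


def effective_mask(
    cube: CalibratedCube, band_idx: np.ndarray, threshold: float = 0.1
) -> np.ndarray:
    """Boolean H x W mask of effective pixels.

    A pixel is effective iff its mean reflectance over the retained bands is
    strictly greater than ``threshold`` (default 0.1); pixels at exactly the
    threshold are excluded.  Raising the threshold can only remove pixels.
    """
    band_idx = np.asarray(band_idx, dtype=int)
    if band_idx.size == 0:
        raise ConfigurationError("band index set is empty")
    means = cube.reflectance[:, :, band_idx].mean(axis=2)
    return means > threshold


def cube_to_instance(
    cube: CalibratedCube,
    band_idx: np.ndarray,
    label: int,
    instance_id: str,
) -> InstanceRecord:
    """Collect the effective-pixel spectra of a masked cube into one record.

    Raises
    ------
    DegenerateInstanceError
        if the cube's mask selects zero pixels.  Degenerate instances must be
        reported by the caller, never silently dropped, so dataset bookkeeping
        stays exact.
    """
    if cube.mask is None:
        raise InputError("cube has no mask; call effective_mask first")
    band_idx = np.asarray(band_idx, dtype=int)
    rows, cols = np.nonzero(cube.mask)
    if rows.size == 0:
        raise DegenerateInstanceError(
            f"instance {instance_id!r}: no effective pixels survive masking"
        )
    spectra = cube.reflectance[rows, cols][:, band_idx]
    coords = np.stack([rows, cols], axis=1)
    return InstanceRecord(
        instance_id=str(instance_id),
        label=int(label),
        spectra=spectra,
        pixel_coords=coords,
    )
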