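"""Spectral image cube container.

A :class:`SpectralCube` holds a pushbroom hyperspectral image as a
``lines x samples x bands`` array together with its wavelength axis,
a units tag tracking the processing stage (``DN`` raw counts,
``radiance`` after radiometric conversion, ``transmittance`` after
normalisation) and a boolean validity mask over the spatial grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: recognised units tags, in pipeline order
UNITS = ("DN", "radiance", "transmittance")


@dataclass
class SpectralCube:
    """A hyperspectral image with wavelength axis, units tag and pixel mask.

    Parameters
    ----------
    data : ndarray, shape (lines, samples, bands)
        Pixel spectra. Invalid pixels may hold any value; the mask governs.
    wavelengths : ndarray, shape (bands,)
        Band-centre wavelengths in nm, strictly increasing.
    units : {"DN", "radiance", "transmittance"}
        Processing-stage tag. Operations check it so the pipeline order
        (convert, mask, PAR subset, normalise, smooth) cannot be violated
        silently.
    mask : ndarray of bool, shape (lines, samples), optional
        True marks valid scene/core pixels. Defaults to all-valid.
    pixel_pitch : float
        Ground sampling distance in mm per pixel.
    meta : dict
        Free-form provenance (scan geometry, section id, light source, ...).
    """

    data: np.ndarray
    wavelengths: np.ndarray
    units: str = "DN"
    mask: np.ndarray | None = None
    pixel_pitch: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube data must be 3-D (lines, samples, bands)")
        if self.wavelengths.ndim != 1 or self.wavelengths.size != self.data.shape[2]:
            raise ValueError(
                f"wavelength count {self.wavelengths.size} does not match "
                f"band count {self.data.shape[2]}"
            )
        if self.wavelengths.size > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.units not in UNITS:
            raise ValueError(f"unknown units tag {self.units!r}; expected one of {UNITS}")
        if self.mask is None:
            self.mask = np.ones(self.data.shape[:2], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape[:2]:
                raise ValueError("mask shape must equal the cube's spatial shape")
        if not self.pixel_pitch > 0:
            raise ValueError("pixel_pitch must be positive")

    # -- geometry -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    # -- wavelength lookup --------------------------------------------------

    def sampling_interval(self) -> float:
        """Median band spacing in nm."""
        if self.n_bands < 2:
            raise ValueError("need at least two bands for a sampling interval")
        return float(np.median(np.diff(self.wavelengths)))

    def band_index(self, wavelength_nm: float) -> int:
        """Index of the band nearest *wavelength_nm*.

        Requests farther than one sampling interval from every band are
        rejected: silently snapping e.g. 677 nm onto a grid that stops at
        650 nm would corrupt every downstream index.
        """
        idx = int(np.argmin(np.abs(self.wavelengths - wavelength_nm)))
        if abs(self.wavelengths[idx] - wavelength_nm) > self.sampling_interval():
            raise ValueError(
                f"{wavelength_nm} nm is farther than one sampling interval "
                f"from any band (nearest: {self.wavelengths[idx]:.2f} nm)"
            )
        return idx

    # -- pixel access -------------------------------------------------------

    def valid_spectra(self) -> np.ndarray:
        """Spectra of valid pixels as an (n_valid, bands) matrix."""
        return self.data[self.mask]

    def mean_spectrum(self) -> np.ndarray:
        """Mean spectrum over valid pixels."""
        if self.n_valid == 0:
            raise ValueError("cube has no valid pixels")
        return self.valid_spectra().mean(axis=0)

    def copy_with(self, **changes) -> "SpectralCube":
        """Shallow dataclass copy with field overrides (meta dict is copied)."""
        if "meta" not in changes:
            changes["meta"] = dict(self.meta)
        return replace(self, **changes)

    def require_units(self, units: str) -> None:
        if self.units != units:
            raise ValueError(
                f"operation requires a cube in {units!r} units, got {self.units!r}"
            )
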