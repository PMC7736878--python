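"""Radiometric conversion, masking, PAR subsetting, binning, smoothing and
transmittance normalisation of hyperspectral cubes.

Operations enforce the workflow order through the cube's units tag:
raw counts are converted to radiance, scenes are masked to the core
surface, restricted to photosynthetically active radiation (400-700 nm),
normalised to (pseudo-)transmittance and spectrally smoothed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .cube import SpectralCube
from .synthetic import IlluminationSpectrum

#: inclusive PAR wavelength bounds, nm
PAR_BOUNDS = (400.0, 700.0)


@dataclass
class RadiometricCalibration:
    """Per-band DN-to-radiance calibration: gain, dark offset, exposure."""

    gain: np.ndarray  # radiance units per DN, per band
    dark: np.ndarray  # DN offset, per band
    integration_time: float = 1.0  # exposure normaliser

    def __post_init__(self) -> None:
        self.gain = np.atleast_1d(np.asarray(self.gain, dtype=float))
        self.dark = np.atleast_1d(np.asarray(self.dark, dtype=float))
        if np.any(self.gain <= 0):
            raise ValueError("calibration gain must be positive")
        if np.any(self.dark < 0):
            raise ValueError("dark offset must be non-negative")
        if self.integration_time <= 0:
            raise ValueError("integration time must be positive")


def _per_band(values: np.ndarray, n_bands: int, name: str) -> np.ndarray:
    if values.size == 1:
        return np.full(n_bands, values[0])
    if values.size != n_bands:
        raise ValueError(f"calibration {name} has {values.size} bands, cube has {n_bands}")
    return values


def dn_to_radiance(raw: SpectralCube, cal: RadiometricCalibration) -> SpectralCube:
    """Convert raw digital numbers to transmitted radiance.

    radiance = (DN - dark) * gain / integration_time per band; negative
    results (noise below the dark frame) clip to zero.
    """
    raw.require_units("DN")
    gain = _per_band(cal.gain, raw.n_bands, "gain")
    dark = _per_band(cal.dark, raw.n_bands, "dark")
    radiance = (raw.data - dark) * gain / cal.integration_time
    return raw.copy_with(data=np.clip(radiance, 0.0, None), units="radiance")


def radiance_to_dn(cube: SpectralCube, cal: RadiometricCalibration) -> SpectralCube:
    """Inverse of :func:`dn_to_radiance`; used to synthesise raw imagery."""
    cube.require_units("radiance")
    gain = _per_band(cal.gain, cube.n_bands, "gain")
    dark = _per_band(cal.dark, cube.n_bands, "dark")
    dn = cube.data * cal.integration_time / gain + dark
    return cube.copy_with(data=dn, units="DN")


def apply_mask(cube: SpectralCube, mask: np.ndarray) -> SpectralCube:
    """Intersect the cube's validity mask with a scene mask.

    Masked-out pixels are excluded from every downstream mean, fit and
    map; their stored values are untouched.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cube.spatial_shape:
        raise ValueError("mask shape must match the cube's spatial shape")
    combined = cube.mask & mask
    if not combined.any():
        raise ValueError("mask removes every pixel; nothing left to analyse")
    return cube.copy_with(mask=combined)


def subset_par(cube: SpectralCube,
               bounds: tuple[float, float] = PAR_BOUNDS) -> SpectralCube:
    """Keep only bands within the PAR window (inclusive on both ends)."""
    lo, hi = bounds
    keep = (cube.wavelengths >= lo) & (cube.wavelengths <= hi)
    if not keep.any():
        raise ValueError(f"no bands inside [{lo}, {hi}] nm")
    return cube.copy_with(data=cube.data[:, :, keep],
                          wavelengths=cube.wavelengths[keep])


def spatial_bin(cube: SpectralCube, factor: int,
                min_valid_fraction: float = 0.5) -> SpectralCube:
    """Average non-overlapping factor x factor pixel blocks.

    Block means are taken over valid member pixels only; a block is valid
    iff at least *min_valid_fraction* of a full block's members are valid.
    The pixel pitch grows by *factor*. Trailing rows/columns that do not
    fill a block are kept as partial blocks.
    """
    if factor < 1:
        raise ValueError("bin factor must be >= 1")
    ny, nx = cube.spatial_shape
    if factor > ny or factor > nx:
        raise ValueError("bin factor exceeds the image size")
    if factor == 1:
        return cube.copy_with()

    nby = -(-ny // factor)
    nbx = -(-nx // factor)
    out = np.zeros((nby, nbx, cube.n_bands))
    out_mask = np.zeros((nby, nbx), dtype=bool)
    for by in range(nby):
        ys = slice(by * factor, min((by + 1) * factor, ny))
        for bx in range(nbx):
            xs = slice(bx * factor, min((bx + 1) * factor, nx))
            block_mask = cube.mask[ys, xs]
            n_valid = int(block_mask.sum())
            if n_valid >= min_valid_fraction * factor * factor and n_valid > 0:
                out[by, bx] = cube.data[ys, xs][block_mask].mean(axis=0)
                out_mask[by, bx] = True
    if not out_mask.any():
        raise ValueError("binning left no valid blocks")
    return cube.copy_with(data=out, mask=out_mask,
                          pixel_pitch=cube.pixel_pitch * factor)


def savgol_smooth(cube: SpectralCube, polyorder: int = 2,
                  window: int = 9) -> SpectralCube:
    """Savitzky-Golay low-pass filter along the spectral axis of each pixel.

    Window length defaults to 9 bands; polynomial order is exposed
    because vertical and horizontal scans tolerate different amounts of
    smoothing (orders 1-3 in practice). Mirror padding at the spectral
    edges. Spatial dimensions are untouched.
    """
    if window % 2 == 0:
        raise ValueError("Savitzky-Golay window length must be odd")
    if not 1 <= polyorder < window:
        raise ValueError("polyorder must satisfy 1 <= polyorder < window")
    if window > cube.n_bands:
        raise ValueError("window longer than the spectral axis")
    smoothed = savgol_filter(cube.data, window_length=window,
                             polyorder=polyorder, axis=2, mode="mirror")
    return cube.copy_with(data=smoothed)


def to_transmittance(cube: SpectralCube,
                     led: IlluminationSpectrum) -> SpectralCube:
    """Normalise transmitted radiance by the lamp radiance: T = L_t / L_LED.

    Values are not clipped above 1; negative radiances were clipped to 0
    at conversion, so T >= 0 for valid pixels.
    """
    cube.require_units("radiance")
    if not np.array_equal(cube.wavelengths, led.wavelengths):
        raise ValueError("cube and LED wavelength grids must agree")
    if np.any(led.mean_radiance <= 0):
        raise ValueError("LED radiance must be positive in every retained band")
    t = cube.data / led.mean_radiance[None, None, :]
    return cube.copy_with(data=t, units="transmittance")


def to_pseudo_transmittance(cube: SpectralCube,
                            cavity_mask: np.ndarray) -> SpectralCube:
    """Normalise an under-ice scene by its algae-poor cavity spectrum.

    T_d = L_d,t / mean-over-cavity L_d,cavity per band. Cavity pixels are
    those flagged in *cavity_mask* and valid in the cube's own mask.
    Values legitimately exceed 1 for pixels brighter than the cavity mean.
    """
    cube.require_units("radiance")
    cavity_mask = np.asarray(cavity_mask, dtype=bool)
    if cavity_mask.shape != cube.spatial_shape:
        raise ValueError("cavity mask shape must match the cube")
    sel = cavity_mask & cube.mask
    if not sel.any():
        raise ValueError("cavity selection contains no valid pixels")
    cavity_spectrum = cube.data[sel].mean(axis=0)
    if np.any(cavity_spectrum <= 0):
        raise ValueError("cavity mean radiance must be positive in every band")
    t = cube.data / cavity_spectrum[None, None, :]
    return cube.copy_with(data=t, units="transmittance")
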