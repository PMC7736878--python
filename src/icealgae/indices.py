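"""Spectral indices for ice-algal biomass from transmittance spectra.

Implements the two-band normalised difference index (NDI) and the
continuum-removal family over the 650-700 nm chlorophyll-a absorption
feature: the trapezoidal area under the feature (AUC), its
normalisations by a constant band depth at 677 nm (ANCB) and by the
per-spectrum maximal band depth (ANMB), and the logarithm of the area
(LAUC), which linearises the exponential attenuation of light passing
through an absorbing medium.

By default the AUC family integrates band depth (1 - continuum-removed
transmittance), so every index grows with absorption; the literal
area-under-transmittance reading is available via ``auc_mode="literal"``.
Undefined values (divisions or logs at or below a numeric floor)
propagate as NaN markers, never exceptions, so per-pixel maps stay
total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cube import SpectralCube

#: numeric floor guarding divisions and logarithms
FLOOR = 1e-6

#: default continuum-removal window, nm
CR_WINDOW = (650.0, 700.0)

#: default constant-band-depth wavelength, nm
CBD_WAVELENGTH = 677.0


def _band_index(wavelengths: np.ndarray, target: float) -> int:
    """Nearest band to *target*, rejecting requests off the grid."""
    idx = int(np.argmin(np.abs(wavelengths - target)))
    interval = float(np.median(np.diff(wavelengths))) if wavelengths.size > 1 else np.inf
    if abs(wavelengths[idx] - target) > interval:
        raise ValueError(
            f"{target} nm is farther than one sampling interval from any band"
        )
    return idx


# ---------------------------------------------------------------------------
# NDI
# ---------------------------------------------------------------------------

def ndi(spectrum: np.ndarray, wavelengths: np.ndarray,
        lambda1: float, lambda2: float, floor: float = FLOOR) -> float:
    """Normalised difference index (T(l1) - T(l2)) / (T(l1) + T(l2)).

    Returns NaN when the denominator is at or below the floor.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    i1 = _band_index(wavelengths, lambda1)
    i2 = _band_index(wavelengths, lambda2)
    denom = spectrum[i1] + spectrum[i2]
    if not denom > floor:
        return float("nan")
    return float((spectrum[i1] - spectrum[i2]) / denom)


# ---------------------------------------------------------------------------
# continuum removal
# ---------------------------------------------------------------------------

@dataclass
class ContinuumSegment:
    """Continuum-removed transmittance over an absorption window.

    ``rho`` is the continuum-removed transmittance T_j / continuum_j;
    ``depth`` is the band depth 1 - rho, clipped to [0, 1] under the
    default policy (noise can push T above the continuum).
    """

    wavelengths: np.ndarray
    raw: np.ndarray
    continuum: np.ndarray
    rho: np.ndarray
    depth: np.ndarray
    window: tuple[float, float]
    clip_depth: bool

    @property
    def n(self) -> int:
        return self.wavelengths.size


def _upper_hull(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Upper convex hull of (x, y), evaluated at every x (monotone chain)."""
    hull: list[int] = []
    for i in range(x.size):
        while len(hull) >= 2:
            i0, i1 = hull[-2], hull[-1]
            cross = (x[i1] - x[i0]) * (y[i] - y[i0]) - (y[i1] - y[i0]) * (x[i] - x[i0])
            if cross >= 0:  # middle point lies on/below the chord: drop it
                hull.pop()
            else:
                break
        hull.append(i)
    return np.interp(x, x[hull], y[hull])


def continuum_remove(
    spectrum: np.ndarray,
    wavelengths: np.ndarray,
    window: tuple[float, float] = CR_WINDOW,
    mode: str = "chord",
    clip_depth: bool = True,
) -> ContinuumSegment:
    """Continuum-removal of one spectrum over an absorption window.

    The default continuum is the straight chord between the transmittance
    at the bands nearest the window endpoints, the convention for
    fixed-window band-depth indices; ``mode="hull"`` substitutes the
    upper convex hull over the window for comparison.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    wavelengths = np.asarray(wavelengths, dtype=float)
    i_lo = _band_index(wavelengths, window[0])
    i_hi = _band_index(wavelengths, window[1])
    if i_hi - i_lo + 1 < 3:
        raise ValueError("continuum window must contain at least 3 bands")
    lam = wavelengths[i_lo:i_hi + 1]
    raw = spectrum[i_lo:i_hi + 1]
    if mode == "chord":
        continuum = np.interp(lam, [lam[0], lam[-1]], [raw[0], raw[-1]])
    elif mode == "hull":
        continuum = _upper_hull(lam, raw)
    else:
        raise ValueError(f"unknown continuum mode {mode!r}")
    if np.any(continuum <= 0):
        raise ValueError("continuum is non-positive inside the window")
    rho = raw / continuum
    depth = 1.0 - rho
    if clip_depth:
        depth = np.clip(depth, 0.0, 1.0)
    return ContinuumSegment(lam, raw, continuum, rho, depth, tuple(window), clip_depth)


def auc(seg: ContinuumSegment, mode: str = "depth") -> float:
    """Trapezoidal area of the continuum-removed feature.

    ``mode="depth"`` (default) integrates band depth, so the area grows
    with absorption; ``mode="literal"`` integrates the continuum-removed
    transmittance itself.
    """
    y = seg.depth if mode == "depth" else seg.rho
    if mode not in ("depth", "literal"):
        raise ValueError(f"unknown AUC mode {mode!r}")
    return float(np.trapezoid(y, seg.wavelengths))


def cbd(seg: ContinuumSegment, wavelength: float = CBD_WAVELENGTH) -> float:
    """Constant band depth: depth at the band nearest *wavelength*."""
    if not seg.wavelengths[0] <= wavelength <= seg.wavelengths[-1]:
        raise ValueError(f"{wavelength} nm lies outside the continuum window")
    return float(seg.depth[np.argmin(np.abs(seg.wavelengths - wavelength))])


def mbd(seg: ContinuumSegment) -> float:
    """Maximal band depth, localised per spectrum."""
    return float(np.max(seg.depth))


def ancb(seg: ContinuumSegment, cbd_wavelength: float = CBD_WAVELENGTH,
         auc_mode: str = "depth", floor: float = FLOOR) -> float:
    """AUC normalised to the constant band depth at *cbd_wavelength*."""
    d = cbd(seg, cbd_wavelength)
    if not d > floor:
        return float("nan")
    return auc(seg, auc_mode) / d


def anmb(seg: ContinuumSegment, auc_mode: str = "depth",
         floor: float = FLOOR) -> float:
    """AUC normalised to the per-spectrum maximal band depth."""
    d = mbd(seg)
    if not d > floor:
        return float("nan")
    return auc(seg, auc_mode) / d


def lauc(seg: ContinuumSegment, auc_mode: str = "depth",
         log_base: float = math.e, floor: float = FLOOR) -> float:
    """Logarithm of the AUC (natural log by default)."""
    a = auc(seg, auc_mode)
    if not a > floor:
        return float("nan")
    return math.log(a) / math.log(log_base)


# ---------------------------------------------------------------------------
# per-pixel and per-section evaluation
# ---------------------------------------------------------------------------

@dataclass
class IndexConfig:
    """Identity and parameters of one spectral index.

    ``name`` is one of NDI, AUC, ANCB, ANMB, LAUC; NDI additionally needs
    its two wavelengths.
    """

    name: str
    lambda1: float | None = None
    lambda2: float | None = None
    window: tuple[float, float] = CR_WINDOW
    cbd_wavelength: float = CBD_WAVELENGTH
    auc_mode: str = "depth"
    clip_depth: bool = True
    log_base: float = math.e
    floor: float = FLOOR

    def __post_init__(self) -> None:
        if self.name not in ("NDI", "AUC", "ANCB", "ANMB", "LAUC"):
            raise ValueError(f"unknown index {self.name!r}")
        if self.name == "NDI" and (self.lambda1 is None or self.lambda2 is None):
            raise ValueError("NDI requires lambda1 and lambda2")

    @property
    def label(self) -> str:
        if self.name == "NDI":
            return f"NDI({self.lambda1:g}:{self.lambda2:g})"
        return self.name

    @classmethod
    def from_label(cls, label: str, **kwargs) -> "IndexConfig":
        """Parse labels like ``"LAUC"`` or ``"NDI(587:621)"``."""
        label = label.strip()
        if label.upper().startswith("NDI"):
            inner = label[label.index("(") + 1:label.rindex(")")]
            l1, l2 = (float(v) for v in inner.split(":"))
            return cls("NDI", lambda1=l1, lambda2=l2, **kwargs)
        return cls(label.upper(), **kwargs)


@dataclass
class IndexValue:
    """A section-level index value with its computation method recorded."""

    name: str
    value: float
    method: int  # 1 = index of mean spectrum, 2 = mean of per-pixel indices
    n_pixels: int


def _evaluate_matrix(matrix: np.ndarray, wavelengths: np.ndarray,
                     cfg: IndexConfig) -> np.ndarray:
    """Vectorised index over an (n, bands) matrix; NaN marks undefined."""
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    if cfg.name == "NDI":
        i1 = _band_index(wavelengths, cfg.lambda1)
        i2 = _band_index(wavelengths, cfg.lambda2)
        t1, t2 = matrix[:, i1], matrix[:, i2]
        denom = t1 + t2
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(denom > cfg.floor, (t1 - t2) / denom, np.nan)
        return out

    i_lo = _band_index(wavelengths, cfg.window[0])
    i_hi = _band_index(wavelengths, cfg.window[1])
    if i_hi - i_lo + 1 < 3:
        raise ValueError("continuum window must contain at least 3 bands")
    lam = wavelengths[i_lo:i_hi + 1]
    raw = matrix[:, i_lo:i_hi + 1]
    continuum = raw[:, :1] + (raw[:, -1:] - raw[:, :1]) * (
        (lam - lam[0]) / (lam[-1] - lam[0]))[None, :]
    bad = np.any(continuum <= 0, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(continuum > 0, raw / continuum, np.nan)
    depth = 1.0 - rho
    if cfg.clip_depth:
        depth = np.clip(depth, 0.0, 1.0)
    y = depth if cfg.auc_mode == "depth" else rho
    area = np.trapezoid(y, lam, axis=1)

    if cfg.name == "AUC":
        out = area
    elif cfg.name == "ANCB":
        j = int(np.argmin(np.abs(lam - cfg.cbd_wavelength)))
        d = depth[:, j]
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(d > cfg.floor, area / d, np.nan)
    elif cfg.name == "ANMB":
        d = np.max(depth, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(d > cfg.floor, area / d, np.nan)
    else:  # LAUC
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(area > cfg.floor,
                           np.log(np.maximum(area, cfg.floor)) / math.log(cfg.log_base),
                           np.nan)
    out = np.asarray(out, dtype=float)
    out[bad] = np.nan
    return out


def index_map(cube: SpectralCube, cfg: IndexConfig) -> np.ndarray:
    """Evaluate an index independently at every valid pixel.

    Returns a (lines, samples) raster; masked-out pixels and per-pixel
    precondition failures are NaN.
    """
    cube.require_units("transmittance")
    flat = cube.data.reshape(-1, cube.n_bands)
    values = _evaluate_matrix(flat, cube.wavelengths, cfg)
    raster = values.reshape(cube.spatial_shape)
    raster = np.where(cube.mask, raster, np.nan)
    return raster


def section_index(cube: SpectralCube, cfg: IndexConfig,
                  method: int = 2) -> IndexValue:
    """Section-level index value.

    Method 1 evaluates the index on the mean transmittance spectrum of
    all valid pixels; method 2 (the default used throughout the
    pipeline, being more representative of noisy per-pixel acquisition)
    evaluates the index per pixel and averages, excluding undefined
    pixels.
    """
    cube.require_units("transmittance")
    if method == 1:
        value = float(_evaluate_matrix(cube.mean_spectrum()[None, :],
                                       cube.wavelengths, cfg)[0])
        n = cube.n_valid
    elif method == 2:
        values = _evaluate_matrix(cube.valid_spectra(), cube.wavelengths, cfg)
        n = int(np.sum(~np.isnan(values)))
        if n == 0:
            raise ValueError(f"{cfg.label} undefined at every valid pixel")
        value = float(np.nanmean(values))
    else:
        raise ValueError("method must be 1 or 2")
    if math.isnan(value):
        raise ValueError(f"{cfg.label} undefined for this section")
    return IndexValue(cfg.label, value, method, n)


# ---------------------------------------------------------------------------
# NDI wavelength-pair optimisation
# ---------------------------------------------------------------------------

@dataclass
class CorrelationSurface:
    """Pearson r between section-level NDI and log Chl a, per band pair.

    Antisymmetric under axis swap; the diagonal is undefined (NaN).
    """

    wavelengths: np.ndarray
    r: np.ndarray  # (bands, bands), r[i, j] for NDI(lambda_i, lambda_j)
    n_sections: int


def _pairwise_ndi_means(matrix: np.ndarray, floor: float,
                        chunk: int = 2048) -> np.ndarray:
    """Mean over pixels of NDI for every ordered band pair, (B, B)."""
    n, b = matrix.shape
    total = np.zeros((b, b))
    count = np.zeros((b, b))
    for start in range(0, n, chunk):
        t = matrix[start:start + chunk]
        diff = t[:, :, None] - t[:, None, :]
        s = t[:, :, None] + t[:, None, :]
        ok = s > floor
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(ok, diff / np.where(ok, s, 1.0), 0.0)
        total += vals.sum(axis=0)
        count += ok.sum(axis=0)
    with np.errstate(invalid="ignore"):
        return np.where(count > 0, total / count, np.nan)


def ndi_correlation_surface(
    sections: list[tuple[SpectralCube, float]],
    floor: float = FLOOR,
) -> CorrelationSurface:
    """Correlate section-level NDIs of every band pair with log Chl a.

    For each ordered wavelength pair, the per-section NDI (method 2:
    mean of per-pixel values) is Pearson-correlated with the natural log
    of extracted Chl a across sections. Cells with zero variance are NaN.
    """
    if len(sections) < 3:
        raise ValueError("need at least 3 sections for a correlation surface")
    wavelengths = sections[0][0].wavelengths
    ndis, log_chla = [], []
    for cube, chla in sections:
        cube.require_units("transmittance")
        if not np.array_equal(cube.wavelengths, wavelengths):
            raise ValueError("all sections must share one wavelength grid")
        if chla <= 0:
            raise ValueError("Chl a must be positive for log transformation")
        ndis.append(_pairwise_ndi_means(cube.valid_spectra(), floor))
        log_chla.append(math.log(chla))
    x = np.stack(ndis)  # (S, B, B)
    y = np.asarray(log_chla)
    xm = x - x.mean(axis=0)
    ym = y - y.mean()
    cov = np.tensordot(ym, xm, axes=([0], [0]))
    sx = np.sqrt((xm**2).sum(axis=0))
    sy = math.sqrt(float((ym**2).sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where((sx > 0) & (sy > 0), cov / (sx * sy), np.nan)
    np.fill_diagonal(r, np.nan)
    return CorrelationSurface(wavelengths, r, len(sections))


def select_ndi_pairs(
    surface: CorrelationSurface,
    min_abs_r: float = 0.7,
    min_separation_nm: float = 12.0,
    required_regions: tuple[tuple[float, float], ...] = ((430.0, 460.0),
                                                        (650.0, 700.0)),
):
    """Rank NDI wavelength pairs by the selection criteria.

    Qualifying pairs have |r| >= *min_abs_r*, wavelength separation
    strictly greater than *min_separation_nm* (avoiding autocorrelated
    neighbours), and at least one wavelength inside a chlorophyll-a
    absorption region. Each unordered pair is reported once, oriented so
    r is positive; ranking is by |r| descending, ties broken by larger
    separation then lower lambda1. Returns a DataFrame with columns
    lambda1, lambda2, r, separation_nm (empty if nothing qualifies).
    """
    import pandas as pd

    lam = surface.wavelengths
    rows = []
    for i in range(lam.size):
        for j in range(i + 1, lam.size):
            r = surface.r[i, j]
            if np.isnan(r) or abs(r) < min_abs_r:
                continue
            sep = abs(lam[j] - lam[i])
            if sep <= min_separation_nm:
                continue
            if not any(lo <= w <= hi for lo, hi in required_regions
                       for w in (lam[i], lam[j])):
                continue
            l1, l2 = (lam[i], lam[j]) if r >= 0 else (lam[j], lam[i])
            rows.append((l1, l2, abs(r), sep))
    rows.sort(key=lambda t: (-t[2], -t[3], t[0]))
    return pd.DataFrame(rows, columns=["lambda1", "lambda2", "r", "separation_nm"])
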