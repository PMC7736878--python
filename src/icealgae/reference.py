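"""Published reference values for the Antarctic land-fast-ice core study
that this package's synthetic scenes emulate (Cape Evans, spring 2018).

These numbers are inputs, not results: the scan geometry fixes the pixel
pitches the simulator uses, the section bookkeeping fixes calibration
sample sizes, and the published log-linear calibration table supplies
index coefficients used as ground truth by the synthetic generators.
"""

from __future__ import annotations

import math

import pandas as pd

# -- scan geometry ----------------------------------------------------------

#: across-track scan-line width of the vertical core scans, mm
VERTICAL_SCAN_LINE_WIDTH_MM = 400.0
#: across-track pixel count after 2x at-sensor spatial binning
VERTICAL_ACROSS_TRACK_PIXELS = 1024
#: horizontal-section scans: native ground sampling distance, mm
HORIZONTAL_PIXEL_PITCH_MM = 0.44
#: under-ice sled imagery: native ground sampling distance, mm
UNDER_ICE_NATIVE_PITCH_MM = 0.624
#: spatial binning factor applied to the under-ice imagery
UNDER_ICE_BIN_FACTOR = 4
#: variogram lag width in (binned) pixels
VARIOGRAM_LAG_PIXELS = 5
#: ice corer internal diameter, cm
CORE_DIAMETER_CM = 14.0

# -- sample bookkeeping -----------------------------------------------------

#: cores extracted; every core's bottom 0-3 cm section was scanned
N_BOTTOM_SECTIONS = 42
#: cores additionally sectioned at 3-6 and 6-9 cm
N_DEEP_SECTIONED_CORES = 6
#: extra horizontal sections per deep-sectioned core (3-6 cm and 6-9 cm)
N_EXTRA_SECTIONS_PER_CORE = 2

# -- field statistics of the bottom (0-3 cm) sections -----------------------

#: extracted chlorophyll a of the 42 bottom sections, mg m^-2
BOTTOM_CHLA_MEAN = 18.74
BOTTOM_CHLA_SD = 18.04
BOTTOM_CHLA_RANGE = (1.1, 117.5)


def vertical_pixel_pitch_mm() -> float:
    """Across-track pixel pitch of the vertical core scans, mm."""
    return VERTICAL_SCAN_LINE_WIDTH_MM / VERTICAL_ACROSS_TRACK_PIXELS


def core_disc_area_m2(diameter_cm: float = CORE_DIAMETER_CM) -> float:
    """Surface area of a core disc of the given diameter, m^2."""
    if diameter_cm <= 0:
        raise ValueError("diameter must be positive")
    r_m = diameter_cm / 100.0 / 2.0
    return math.pi * r_m**2


def variogram_lag_cm(
    native_pitch_mm: float = UNDER_ICE_NATIVE_PITCH_MM,
    bin_factor: int = UNDER_ICE_BIN_FACTOR,
    lag_pixels: int = VARIOGRAM_LAG_PIXELS,
) -> float:
    """Variogram lag width in cm implied by the under-ice pixel grid."""
    return native_pitch_mm * bin_factor * lag_pixels / 10.0


def n_horizontal_sections() -> int:
    """Total horizontal core sections scanned for calibration."""
    return N_BOTTOM_SECTIONS + N_DEEP_SECTIONED_CORES * N_EXTRA_SECTIONS_PER_CORE


def reference_calibration() -> pd.DataFrame:
    """Published log-linear calibration table, one row per spectral index.

    Columns: intercept ``alpha`` and slope ``beta`` of
    log(Chl a) = alpha + beta * index, calibration R^2, RMSE (log units),
    adjusted R^2, AIC, and tenfold cross-validation MSE and RMSE.
    """
    rows = [
        ("NDI(587:621)", 0.269, 119.186, 0.629, 1.005, 0.622, 155.771, 1.173, 1.083),
        ("NDI(517:449)", -0.056, 24.927, 0.617, 1.021, 0.610, 157.484, 1.128, 1.062),
        ("AUC", 0.353, 1.352, 0.530, 1.131, 0.521, 168.465, 1.370, 1.170),
        ("ANCB", -17.718, 0.772, 0.710, 0.889, 0.704, 142.454, 0.871, 0.933),
        ("ANMB", -12.211, 0.571, 0.782, 0.771, 0.777, 127.122, 0.607, 0.779),
        ("LAUC", 0.791, 0.986, 0.840, 0.660, 0.837, 110.327, 0.441, 0.664),
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "index", "alpha", "beta", "r2", "rmse",
            "r2_adj", "aic", "mse_cv", "rmse_cv",
        ],
    ).set_index("index")
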