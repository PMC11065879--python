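"""Spectral vegetation indices and SAR channel parameters.

Nine optical indices (EVI, GCVI, LSWI, REPI, RENDVI, NDPI, SAVI, OSAVI,
TCARI) plus the TCARI/OSAVI chlorophyll-sensitivity ratio, and five SAR
parameters (VH, VV, cross-polarization ratio and sum, RVI).

Notes
-----
* OSAVI is implemented by default with SWIR1 in the denominator,
  ``1.16 (NIR - red) / (NIR + SWIR1 + 0.16)``; set ``osavi_standard=True``
  for the literature-standard red-band denominator.
* SAR channel combinations are formed in linear power units
  (``10**(dB/10)``); a dB-domain variant is available via ``db_domain``.
* Any denominator smaller than 1e-9 in magnitude yields NaN (missing),
  never +/-inf.
"""

from __future__ import annotations

import numpy as np

from .series import IndexSeries, ReflectanceSeries, SARSeries

OPTICAL_INDICES = (
    "EVI",
    "GCVI",
    "LSWI",
    "REPI",
    "RENDVI",
    "NDPI",
    "SAVI",
    "OSAVI",
    "TCARI",
    "TCARI_OSAVI",
)

SAR_PARAMETERS = ("VH", "VV", "cross_ratio", "cross_sum", "RVI")

_DIV_EPS = 1e-9

_REQUIRED_BANDS = {
    "EVI": ("NIR", "red", "blue"),
    "GCVI": ("NIR", "green"),
    "LSWI": ("NIR", "SWIR1"),
    "REPI": ("red", "RE1", "RE2", "RE3"),
    "RENDVI": ("NIR", "RE2"),
    "NDPI": ("NIR", "red", "SWIR1"),
    "SAVI": ("NIR", "red"),
    "OSAVI": ("NIR", "red", "SWIR1"),
    "TCARI": ("red", "green", "RE1"),
    "TCARI_OSAVI": ("NIR", "red", "green", "RE1", "SWIR1"),
}


def _safe_divide(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """Elementwise num/den with |den| < 1e-9 mapped to NaN."""
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    out = np.full(np.broadcast(num, den).shape, np.nan)
    ok = np.abs(den) >= _DIV_EPS
    np.divide(num, den, out=out, where=ok)
    return out


def _evi(b):
    return 2.5 * _safe_divide(
        b["NIR"] - b["red"], b["NIR"] + 6.0 * b["red"] - 7.5 * b["blue"] + 1.0
    )


def _gcvi(b):
    return _safe_divide(b["NIR"], b["green"]) - 1.0


def _lswi(b):
    return _safe_divide(b["NIR"] - b["SWIR1"], b["NIR"] + b["SWIR1"])


def _repi(b):
    return 705.0 + 35.0 * _safe_divide(
        (b["red"] + b["RE3"]) / 2.0 - b["RE1"], b["RE2"] - b["RE1"]
    )


def _rendvi(b):
    return _safe_divide(b["NIR"] - b["RE2"], b["NIR"] + b["RE2"])


def _ndpi(b):
    mix = 0.78 * b["red"] + 0.22 * b["SWIR1"]
    return _safe_divide(b["NIR"] - mix, b["NIR"] + mix)


def _savi(b):
    return 1.5 * _safe_divide(b["NIR"] - b["red"], b["NIR"] + b["red"] + 0.5)


def _osavi(b, standard: bool = False):
    soil_band = b["red"] if standard else b["SWIR1"]
    return 1.16 * _safe_divide(b["NIR"] - b["red"], b["NIR"] + soil_band + 0.16)


def _tcari(b):
    return 3.0 * (
        (b["RE1"] - b["red"])
        - 0.2 * (b["RE1"] - b["green"]) * _safe_divide(b["RE1"], b["red"])
    )


def compute_index(
    refl: ReflectanceSeries, name: str, *, osavi_standard: bool = False
) -> IndexSeries:
    """Compute one spectral index (or the TCARI/OSAVI ratio) per date.

    Parameters
    ----------
    refl
        Source reflectance series; must contain the bands the index needs.
    name
        One of :data:`OPTICAL_INDICES`.
    osavi_standard
        Use the red-band OSAVI denominator instead of SWIR1.

    Returns
    -------
    IndexSeries
        Same time axis as ``refl``; invalid observations are NaN.
    """
    if name not in OPTICAL_INDICES:
        raise ValueError(
            f"unknown index {name!r}; expected one of {OPTICAL_INDICES}"
        )
    for band in _REQUIRED_BANDS[name]:
        if band not in refl.bands:
            raise KeyError(f"index {name} requires missing band {band!r}")
    b = refl.bands
    if name == "EVI":
        values = _evi(b)
    elif name == "GCVI":
        values = _gcvi(b)
    elif name == "LSWI":
        values = _lswi(b)
    elif name == "REPI":
        values = _repi(b)
    elif name == "RENDVI":
        values = _rendvi(b)
    elif name == "NDPI":
        values = _ndpi(b)
    elif name == "SAVI":
        values = _savi(b)
    elif name == "OSAVI":
        values = _osavi(b, standard=osavi_standard)
    elif name == "TCARI":
        values = _tcari(b)
    else:  # TCARI_OSAVI
        values = _safe_divide(_tcari(b), _osavi(b, standard=osavi_standard))
    values = np.where(refl.mask, values, np.nan)
    return IndexSeries(name=name, times=refl.times.copy(), values=values)


def db_to_linear(db: np.ndarray) -> np.ndarray:
    """Convert backscatter from decibels to linear power."""
    return np.power(10.0, np.asarray(db, dtype=float) / 10.0)


def sar_parameter(
    sar: SARSeries, name: str, *, db_domain: bool = False
) -> IndexSeries:
    """Compute one SAR parameter per date.

    VH and VV pass through in dB.  Channel combinations (cross_ratio,
    cross_sum, RVI = 4*VH/(VH+VV)) are formed in linear power by default;
    ``db_domain=True`` combines the raw dB values instead (sensitivity
    variant only -- a dB-domain "sum" has no physical meaning).
    """
    if name not in SAR_PARAMETERS:
        raise ValueError(
            f"unknown SAR parameter {name!r}; expected one of {SAR_PARAMETERS}"
        )
    if name == "VH":
        values = sar.vh.copy()
    elif name == "VV":
        values = sar.vv.copy()
    else:
        vh = sar.vh if db_domain else db_to_linear(sar.vh)
        vv = sar.vv if db_domain else db_to_linear(sar.vv)
        if name == "cross_ratio":
            values = _safe_divide(vh, vv)
        elif name == "cross_sum":
            values = vh + vv
        else:  # RVI
            values = _safe_divide(4.0 * vh, vh + vv)
    values = np.where(sar.mask, values, np.nan)
    return IndexSeries(name=name, times=sar.times.copy(), values=values)
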