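"""Time-series containers for optical reflectance and SAR backscatter.

A sample (field point or pixel) is observed on an irregular set of
day-of-year (DOY) dates.  Optical observations carry nine Sentinel-2-like
surface-reflectance bands; SAR observations carry dual-polarization
backscatter in decibels.  Both containers keep a per-date validity mask so
cloud gaps propagate explicitly instead of as silent NaNs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical band order.  Sentinel-2 naming: B2 blue, B3 green, B4 red,
#: B5-B7 red edge 1-3, B8A narrow NIR, B11/B12 shortwave infrared.
BANDS = ("blue", "green", "red", "RE1", "RE2", "RE3", "NIR", "SWIR1", "SWIR2")

SENTINEL2_COLUMNS = {
    "B2": "blue",
    "B3": "green",
    "B4": "red",
    "B5": "RE1",
    "B6": "RE2",
    "B7": "RE3",
    "B8A": "NIR",
    "B11": "SWIR1",
    "B12": "SWIR2",
}


def _as_float_array(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


@dataclass
class ReflectanceSeries:
    """Multi-band surface-reflectance time series for one sample.

    Parameters
    ----------
    times
        Day-of-year of each observation, integers in [1, 366], strictly
        increasing.
    bands
        Mapping band name -> reflectance array (unitless, ~[0, 1.2]).
        All nine bands of :data:`BANDS` must be present for index
        computation, but a subset is accepted at construction.
    mask
        Boolean validity per observation; ``None`` means all valid.
    """

    times: np.ndarray
    bands: dict[str, np.ndarray]
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = _as_float_array(self.times)
        if self.times.ndim != 1:
            raise ValueError("times must be one-dimensional")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        n = self.times.size
        self.bands = {k: _as_float_array(v) for k, v in self.bands.items()}
        for name, arr in self.bands.items():
            if arr.shape != (n,):
                raise ValueError(
                    f"band {name!r} has length {arr.size}, expected {n}"
                )
        if self.mask is None:
            self.mask = np.ones(n, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (n,):
                raise ValueError("mask length mismatch")
        for name, arr in self.bands.items():
            vals = arr[self.mask]
            if not np.all(np.isfinite(vals)) or np.any(vals < 0):
                raise ValueError(
                    f"band {name!r} has non-finite or negative reflectance "
                    "at valid observations"
                )

    def __len__(self) -> int:
        return self.times.size

    def band(self, name: str) -> np.ndarray:
        try:
            return self.bands[name]
        except KeyError:
            raise KeyError(
                f"band {name!r} not present; available: {sorted(self.bands)}"
            ) from None


@dataclass
class SARSeries:
    """Dual-polarization backscatter time series (decibels)."""

    times: np.ndarray
    vv: np.ndarray
    vh: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = _as_float_array(self.times)
        self.vv = _as_float_array(self.vv)
        self.vh = _as_float_array(self.vh)
        n = self.times.size
        if self.vv.shape != (n,) or self.vh.shape != (n,):
            raise ValueError("vv/vh length mismatch with times")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.mask is None:
            self.mask = np.ones(n, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (n,):
                raise ValueError("mask length mismatch")
        for name, arr in (("vv", self.vv), ("vh", self.vh)):
            if not np.all(np.isfinite(arr[self.mask])):
                raise ValueError(f"{name} non-finite at valid observations")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class IndexSeries:
    """A derived per-date scalar series (vegetation index or SAR parameter).

    Values are unitless except REPI, which is a wavelength in nanometres.
    Invalid source observations appear as NaN with ``mask`` False.
    """

    name: str
    times: np.ndarray
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times = _as_float_array(self.times)
        self.values = _as_float_array(self.values)
        if self.values.shape != self.times.shape:
            raise ValueError("values/times length mismatch")
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)

    def __len__(self) -> int:
        return self.times.size
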