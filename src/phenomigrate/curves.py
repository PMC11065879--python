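"""Per-sample curve workflow: bands -> gridded curves -> phenology -> integrals.

The order of operations follows the package default: composite each
band onto the temporal grid, fill gaps, smooth the *bands*, then compute
indices from the smoothed bands (configurable; index-first is available
by regularizing an IndexSeries directly with :mod:`phenomigrate.prep`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .indices import compute_index
from .phenology import (
    HIGH_GROUP,
    LOW_GROUP,
    PhenologyDates,
    extract_phenology,
    integral_vectors,
)
from .prep import GriddedSeries, TemporalGrid, composite, fill_gaps, sg_smooth
from .series import IndexSeries, ReflectanceSeries

#: Index curves the screening stage needs.
SCREENING_INDICES = ("EVI", "LSWI", "RENDVI", "REPI", "TCARI_OSAVI")


def gridded_band_curves(
    refl: ReflectanceSeries,
    grid: TemporalGrid,
    *,
    window: int = 7,
    order: int = 2,
    smooth: bool = True,
) -> dict[str, GriddedSeries]:
    """Regularize every band of a reflectance series onto the grid."""
    out: dict[str, GriddedSeries] = {}
    for name, arr in refl.bands.items():
        series = IndexSeries(
            name=name,
            times=refl.times,
            values=np.where(refl.mask, arr, np.nan),
        )
        g = fill_gaps(composite(series, grid))
        if smooth:
            g = sg_smooth(g, window=window, order=order)
        out[name] = g
    return out


def index_curves_from_bands(
    gridded: dict[str, GriddedSeries],
    grid: TemporalGrid,
    names: tuple[str, ...] = SCREENING_INDICES,
    *,
    osavi_standard: bool = False,
) -> dict[str, GriddedSeries]:
    """Compute index curves from smoothed gridded bands.

    Smoothing can produce slightly negative reflectance near zero; values
    are clipped at zero before the index formulas are applied.
    """
    bands = {b: np.clip(g.values, 0.0, None) for b, g in gridded.items()}
    rs = ReflectanceSeries(times=grid.centres, bands=bands)
    curves = {}
    for name in names:
        iv = compute_index(rs, name, osavi_standard=osavi_standard)
        g = GriddedSeries(grid=grid, values=iv.values, name=name)
        if not g.is_gap_free():
            # isolated zero-denominator bins: refill from neighbours
            g = fill_gaps(g)
        curves[name] = g
    return curves


@dataclass
class SampleSignature:
    """Everything the screening stage derives from one sample's optics."""

    phen: PhenologyDates
    high: np.ndarray        # seasonal integrals (EVI, RE2, SWIR2)
    low: np.ndarray         # seasonal integrals (LSWI, RENDVI, REPI)
    cci: float
    band_curves: dict[str, GriddedSeries]
    index_curves: dict[str, GriddedSeries]


def compute_signature(
    refl: ReflectanceSeries,
    grid: TemporalGrid | None = None,
    *,
    window: int = 7,
    order: int = 2,
    smooth: bool = True,
    osavi_standard: bool = False,
) -> SampleSignature:
    """Run one sample through compositing, phenology, integrals and CCI."""
    from .migration import compute_cci  # local import to avoid a cycle

    grid = grid or TemporalGrid()
    band_curves = gridded_band_curves(
        refl, grid, window=window, order=order, smooth=smooth
    )
    idx_curves = index_curves_from_bands(
        band_curves, grid, osavi_standard=osavi_standard
    )
    curves = dict(idx_curves)
    curves["RE2"] = band_curves["RE2"]
    curves["SWIR2"] = band_curves["SWIR2"]
    phen = extract_phenology(curves["EVI"])
    high, low = integral_vectors(curves, phen)
    cci = compute_cci(curves["TCARI_OSAVI"], phen)
    return SampleSignature(
        phen=phen, high=high, low=low, cci=cci,
        band_curves=band_curves, index_curves=idx_curves,
    )
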