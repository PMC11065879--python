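"""Growing-season phenology and seasonal curve integrals.

The peak of season (POS) is the date of the EVI maximum.  Start and end
of season (SOS, EOS) come from the amplitude-median rule: the dates at
which the curve crosses the mid-amplitude level, min + 0.5*(max - min),
upward before the peak and downward after it.  Curve integrals over
[SOS, EOS] feed the two 3-D screening spaces: the high-value group
(EVI, RE2, SWIR2), where soybean sits above other crops, and the
low-value group (LSWI, RENDVI, REPI), where it sits below.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .prep import GriddedSeries

#: Fixed component order of the two screening groups.
HIGH_GROUP = ("EVI", "RE2", "SWIR2")
LOW_GROUP = ("LSWI", "RENDVI", "REPI")

_FLAT_EPS = 1e-6


@dataclass(frozen=True)
class PhenologyDates:
    """Season timing in day-of-year; dates may be fractional."""

    sos: float
    pos: float
    eos: float

    def __post_init__(self) -> None:
        if not (self.sos <= self.pos <= self.eos):
            raise ValueError(
                f"require SOS <= POS <= EOS, got {self.sos}, {self.pos}, {self.eos}"
            )

    @property
    def los(self) -> float:
        """Length of season in days."""
        return self.eos - self.sos


def _cross_up(t0, v0, t1, v1, level):
    return t0 + (level - v0) / (v1 - v0) * (t1 - t0)


def extract_phenology(evi: GriddedSeries) -> PhenologyDates:
    """Extract SOS/POS/EOS from a gap-free, smoothed EVI curve.

    POS is the bin centre of the global maximum (earliest bin on ties).
    SOS is the last upward crossing of the mid-amplitude level before
    POS, linearly interpolated between bins; EOS the first downward
    crossing after POS.  A missing crossing clamps to the grid edge.
    """
    if not evi.is_gap_free():
        raise ValueError("phenology requires a gap-free series")
    t = evi.times
    v = evi.values
    vmax = float(v.max())
    vmin = float(v.min())
    if vmax - vmin < _FLAT_EPS:
        raise ValueError("no seasonal signal: EVI amplitude below 1e-6")
    ipos = int(np.argmax(v))
    pos = float(t[ipos])
    level = vmin + 0.5 * (vmax - vmin)

    sos = float(t[0])
    for i in range(ipos - 1, -1, -1):
        if v[i] < level <= v[i + 1]:
            sos = _cross_up(t[i], v[i], t[i + 1], v[i + 1], level)
            break

    eos = float(t[-1])
    for i in range(ipos, len(t) - 1):
        if v[i] >= level > v[i + 1]:
            eos = _cross_up(t[i], v[i], t[i + 1], v[i + 1], level)
            break

    return PhenologyDates(sos=sos, pos=pos, eos=eos)


def seasonal_integral(x: GriddedSeries, phen: PhenologyDates, *,
                      start: float | None = None,
                      end: float | None = None) -> float:
    """Trapezoidal integral of the curve over [SOS, EOS] (units x days).

    The curve is taken piecewise-linear between bin centres, with linear
    interpolation at the fractional endpoints.  ``start``/``end``
    override the phenology limits (used for the phenophase integrals).
    """
    a = phen.sos if start is None else start
    b = phen.eos if end is None else end
    t = x.times
    if a < t[0] - 1e-9 or b > t[-1] + 1e-9:
        raise ValueError(
            f"integration limits [{a}, {b}] outside grid [{t[0]}, {t[-1]}]"
        )
    if b <= a:
        return 0.0
    inner = t[(t > a) & (t < b)]
    knots = np.concatenate(([a], inner, [b]))
    vals = x.interp(knots)
    return float(np.trapezoid(vals, knots))


def integral_vectors(
    curves: dict[str, GriddedSeries], phen: PhenologyDates
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble the high- and low-group seasonal integral vectors.

    Parameters
    ----------
    curves
        Gap-free gridded curves keyed by name; must contain all of
        :data:`HIGH_GROUP` and :data:`LOW_GROUP`.
    phen
        Season limits for this sample.

    Returns
    -------
    (high, low)
        Two length-3 arrays in the fixed orders (EVI, RE2, SWIR2) and
        (LSWI, RENDVI, REPI).
    """
    missing = [k for k in HIGH_GROUP + LOW_GROUP if k not in curves]
    if missing:
        raise KeyError(f"missing curves for integral groups: {missing}")
    high = np.array([seasonal_integral(curves[k], phen) for k in HIGH_GROUP])
    low = np.array([seasonal_integral(curves[k], phen) for k in LOW_GROUP])
    return high, low
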