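"""Synthetic multi-crop scenes for desk-scale testing.

Each crop archetype drives nine reflectance bands with a double-logistic
canopy-development curve between a shared bare-soil state and a
crop-specific peak-canopy state, plus dual-polarization SAR backscatter
correlated with canopy development.  The archetypes are built so the
derived quantities reproduce the qualitative structure the screening
method relies on:

* high-chlorophyll crops (soybean, corn, rice) have a TCARI/OSAVI curve
  that *falls* toward the season peak (concave; negative CCI), while
  low-chlorophyll crops (peanut, cotton, potato) show the opposite
  (convex; positive CCI);
* soybean's seasonal integrals sit above corn/rice in the high-value
  group (EVI, RE2, SWIR2) and below them in the low-value group
  (LSWI, RENDVI, REPI).

Observation dates follow a 5-day revisit thinned by a per-date cloud-gap
probability; bands carry independent Gaussian noise.  Everything is
deterministic under a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .points import SamplePoint
from .raster import Raster
from .series import BANDS, ReflectanceSeries, SARSeries

#: Shared bare-soil reflectance (start/end-of-season state).
SOIL = {
    "blue": 0.060, "green": 0.090, "red": 0.100,
    "RE1": 0.150, "RE2": 0.180, "RE3": 0.200,
    "NIR": 0.210, "SWIR1": 0.280, "SWIR2": 0.220,
}


@dataclass(frozen=True)
class CropArchetype:
    """Parametric seasonal trajectory for one crop.

    ``sos_true``/``eos_true`` are the logistic inflection dates of
    green-up and senescence (DOY); ``rate_growth``/``rate_senesce`` the
    logistic rates (1/day).  ``peak`` is the full-canopy reflectance per
    band; ``gamma`` optional per-band shape exponents (> 1 delays a
    band's development toward the peak).  ``high_chlorophyll`` records
    which CCI sign the archetype is constructed to produce.
    """

    name: str
    sos_true: float
    eos_true: float
    rate_growth: float
    rate_senesce: float
    peak: dict[str, float]
    gamma: dict[str, float] = field(default_factory=dict)
    soil: dict[str, float] = field(default_factory=lambda: dict(SOIL))
    high_chlorophyll: bool = True
    noise_sigma: float = 0.010
    cloud_gap_prob: float = 0.30
    vh_db: tuple[float, float] = (-22.0, 8.0)   # (base, gain) in dB
    vv_db: tuple[float, float] = (-13.0, 4.0)
    sar_sigma: float = 0.4

    def __post_init__(self) -> None:
        if not self.sos_true < self.eos_true:
            raise ValueError("sos_true must precede eos_true")
        missing = [b for b in BANDS if b not in self.peak]
        if missing:
            raise ValueError(f"peak missing bands {missing}")

    def driver(self, t) -> np.ndarray:
        """Normalized double-logistic canopy development in [0, 1]."""
        t = np.asarray(t, dtype=float)
        up = 1.0 / (1.0 + np.exp(-self.rate_growth * (t - self.sos_true)))
        down = 1.0 / (1.0 + np.exp(self.rate_senesce * (t - self.eos_true)))
        g = up * down
        tt = np.linspace(self.sos_true - 30, self.eos_true + 30, 2001)
        gup = 1.0 / (1.0 + np.exp(-self.rate_growth * (tt - self.sos_true)))
        gdn = 1.0 / (1.0 + np.exp(self.rate_senesce * (tt - self.eos_true)))
        return g / np.max(gup * gdn)

    def band_value(self, band: str, t) -> np.ndarray:
        """Noise-free continuous reflectance of one band at DOY t."""
        g = self.driver(t)
        gam = self.gamma.get(band, 1.0)
        return self.soil[band] + (self.peak[band] - self.soil[band]) * g ** gam


def _mk(name, s1, s2, rg, rs, peak, *, gamma=None, chl=True, **kw):
    return CropArchetype(
        name=name, sos_true=s1, eos_true=s2, rate_growth=rg, rate_senesce=rs,
        peak=peak, gamma=gamma or {}, high_chlorophyll=chl, **kw
    )


#: Default archetype set.  Peak-band values are chosen so the derived
#: index curves satisfy the documented contract (CCI sign per
#: chlorophyll class; soybean group-integral orderings vs corn/rice).
ARCHETYPES: dict[str, CropArchetype] = {
    "soybean": _mk(
        "soybean", 160, 270, 0.12, 0.12,
        {"blue": 0.030, "green": 0.055, "red": 0.030, "RE1": 0.055,
         "RE2": 0.380, "RE3": 0.420, "NIR": 0.450, "SWIR1": 0.260,
         "SWIR2": 0.140},
    ),
    "corn": _mk(
        "corn", 140, 265, 0.11, 0.11,
        {"blue": 0.035, "green": 0.060, "red": 0.040, "RE1": 0.070,
         "RE2": 0.280, "RE3": 0.380, "NIR": 0.400, "SWIR1": 0.180,
         "SWIR2": 0.090},
    ),
    "rice": _mk(
        "rice", 150, 275, 0.11, 0.11,
        {"blue": 0.035, "green": 0.060, "red": 0.045, "RE1": 0.075,
         "RE2": 0.260, "RE3": 0.340, "NIR": 0.380, "SWIR1": 0.100,
         "SWIR2": 0.060},
    ),
    "peanut": _mk(
        "peanut", 145, 260, 0.10, 0.10,
        {"blue": 0.045, "green": 0.080, "red": 0.085, "RE1": 0.210,
         "RE2": 0.260, "RE3": 0.300, "NIR": 0.340, "SWIR1": 0.220,
         "SWIR2": 0.160},
        gamma={"RE1": 3.0}, chl=False,
    ),
    "cotton": _mk(
        "cotton", 135, 280, 0.09, 0.10,
        {"blue": 0.040, "green": 0.075, "red": 0.080, "RE1": 0.235,
         "RE2": 0.280, "RE3": 0.320, "NIR": 0.360, "SWIR1": 0.240,
         "SWIR2": 0.170},
        gamma={"RE1": 3.5}, chl=False,
    ),
    "potato": _mk(
        "potato", 130, 240, 0.11, 0.12,
        {"blue": 0.045, "green": 0.085, "red": 0.080, "RE1": 0.200,
         "RE2": 0.250, "RE3": 0.290, "NIR": 0.330, "SWIR1": 0.230,
         "SWIR2": 0.150},
        gamma={"RE1": 3.0}, chl=False,
    ),
    "other": _mk(
        "other", 120, 290, 0.06, 0.06,
        {"blue": 0.050, "green": 0.080, "red": 0.085, "RE1": 0.210,
         "RE2": 0.240, "RE3": 0.270, "NIR": 0.300, "SWIR1": 0.250,
         "SWIR2": 0.180},
        gamma={"RE1": 3.0}, chl=False,
    ),
}

LANDCOVER_CLASSES = {"cropland": 40, "tree": 10, "grass": 30,
                     "water": 80, "built": 50}


def simulate_series(
    archetype: CropArchetype, year: int, seed: int,
    *, doy_start: int = 60, doy_end: int = 330, cadence: int = 5,
) -> tuple[ReflectanceSeries, SARSeries]:
    """Simulate one sample's optical + SAR time series for a year.

    Observation dates run at ``cadence`` days, each dropped with the
    archetype's cloud-gap probability (optical only; SAR is unaffected
    by clouds).  Bands get i.i.d. Gaussian noise, clipped at zero.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, year % 10000]))
    times = np.arange(doy_start, doy_end + 1, cadence, dtype=float)
    keep = rng.random(times.size) >= archetype.cloud_gap_prob
    if keep.sum() < 5:  # guarantee a usable series even at high gap rates
        keep[rng.choice(times.size, size=5, replace=False)] = True
    g = archetype.driver(times)
    bands = {}
    for b in BANDS:
        clean = archetype.band_value(b, times)
        noisy = clean + rng.normal(0.0, archetype.noise_sigma, times.size)
        bands[b] = np.clip(noisy, 0.0, None)
    refl = ReflectanceSeries(times=times, bands=bands, mask=keep)

    vh = archetype.vh_db[0] + archetype.vh_db[1] * g
    vv = archetype.vv_db[0] + archetype.vv_db[1] * g
    vh = vh + rng.normal(0.0, archetype.sar_sigma, times.size)
    vv = vv + rng.normal(0.0, archetype.sar_sigma, times.size)
    sar = SARSeries(times=times.copy(), vv=vv, vh=vh)
    return refl, sar


def simulate_landcover(
    extent_m: tuple[float, float] = (5000.0, 5000.0),
    patch_size_m: float = 300.0,
    class_mix: dict[str, float] | None = None,
    seed: int = 0,
    *, cell_size_m: float = 10.0,
) -> Raster:
    """Patchy categorical land-cover raster (Voronoi patches).

    Patch seeds are scattered at a density of one per ``patch_size_m``
    square and assigned classes by the mix probabilities; each cell
    takes the class of its nearest seed, giving irregular patches of the
    requested typical size.
    """
    if class_mix is None:
        class_mix = {"cropland": 0.6, "tree": 0.15, "grass": 0.15,
                     "water": 0.05, "built": 0.05}
    unknown = set(class_mix) - set(LANDCOVER_CLASSES)
    if unknown:
        raise ValueError(f"unknown land-cover classes {sorted(unknown)}")
    total = sum(class_mix.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"class mix must sum to 1, sums to {total}")
    rng = np.random.default_rng(seed)
    width, height = extent_m
    ncols = int(round(width / cell_size_m))
    nrows = int(round(height / cell_size_m))
    n_seeds = max(1, int(round((width * height) / patch_size_m**2)))
    seeds_xy = rng.random((n_seeds, 2)) * np.array([width, height])
    names = list(class_mix)
    codes = np.array([LANDCOVER_CLASSES[n] for n in names])
    probs = np.array([class_mix[n] for n in names])
    seed_class = rng.choice(codes, size=n_seeds, p=probs)
    xs = (np.arange(ncols) + 0.5) * cell_size_m
    ys = height - (np.arange(nrows) + 0.5) * cell_size_m
    gx, gy = np.meshgrid(xs, ys)
    _, nearest = cKDTree(seeds_xy).query(np.column_stack([gx.ravel(), gy.ravel()]))
    data = seed_class[nearest].reshape(nrows, ncols)
    return Raster(data=data, x_origin=0.0, y_origin=height,
                  cell_size=cell_size_m, nodata=0, crs="local-metres")


@dataclass
class Scene:
    """A complete desk-scale testbed for migration and classification."""

    points: list[SamplePoint]
    optical: dict[str, ReflectanceSeries]
    sar: dict[str, SARSeries]
    truth: dict[str, str]          # id -> crop name
    reference_ids: list[str]       # ground-survey soybean subset
    landcover: Raster | None = None
    year: int = 2019
    region: str = "R1"

    @property
    def candidate_ids(self) -> list[str]:
        ref = set(self.reference_ids)
        return [p.id for p in self.points if p.id not in ref]


def simulate_region(
    n_per_crop: dict[str, int] | None = None,
    seed: int = 0,
    *,
    n_reference: int = 80,
    year: int = 2019,
    region: str = "R1",
    archetypes: dict[str, CropArchetype] | None = None,
    separation: float = 1.0,
    noise_sigma: float | None = None,
    extent_m: tuple[float, float] = (5000.0, 5000.0),
) -> Scene:
    """Generate a labelled scene: points, series, truth, reference subset.

    Default composition is 200 each of soybean, corn, rice and peanut.
    ``n_reference`` soybean points are marked as ground-survey reference
    samples; all remaining points form the candidate pool.

    ``separation`` in [0, 1] shrinks every crop's peak-state contrast
    against the soybean archetype (1 = documented archetypes, 0 = all
    crops share soybean's trajectory), for effect-size sweeps.
    """
    if n_per_crop is None:
        n_per_crop = {"soybean": 200, "corn": 200, "rice": 200, "peanut": 200}
    if "soybean" not in n_per_crop or len(n_per_crop) < 2:
        raise ValueError("scene needs soybean plus at least one other crop")
    if n_per_crop["soybean"] < n_reference:
        raise ValueError("fewer soybean points than requested references")
    archetypes = dict(archetypes or ARCHETYPES)
    if separation != 1.0:
        soy = archetypes["soybean"]
        shrunk = {}
        for name, arch in archetypes.items():
            if name == "soybean":
                shrunk[name] = arch
                continue
            peak = {
                b: soy.peak[b] + separation * (arch.peak[b] - soy.peak[b])
                for b in arch.peak
            }
            gamma = {
                b: 1.0 + separation * (g - 1.0)
                for b, g in arch.gamma.items()
            }
            shrunk[name] = replace(arch, peak=peak, gamma=gamma)
        archetypes = shrunk

    rng = np.random.default_rng(seed)
    width, height = extent_m
    # Nominal geographic placement: local metres mapped onto a small
    # lon/lat window (1 deg ~ 111 km) so points carry valid coordinates.
    lon0, lat0 = 125.0, 45.0
    points: list[SamplePoint] = []
    optical: dict[str, ReflectanceSeries] = {}
    sar: dict[str, SARSeries] = {}
    truth: dict[str, str] = {}
    i = 0
    for crop, n in n_per_crop.items():
        if crop not in archetypes:
            raise KeyError(f"no archetype for crop {crop!r}")
        arch = archetypes[crop]
        if noise_sigma is not None:
            arch = replace(arch, noise_sigma=noise_sigma)
        for _ in range(n):
            pid = f"{region}_{year}_{i:05d}"
            x = float(rng.random() * width)
            y = float(rng.random() * height)
            points.append(
                SamplePoint(
                    id=pid,
                    lon=lon0 + x / 111_000.0,
                    lat=lat0 + y / 111_000.0,
                    year=year,
                    region=region,
                    crop=crop,
                )
            )
            refl, s = simulate_series(
                arch, year, int(rng.integers(0, 2**31 - 1))
            )
            optical[pid] = refl
            sar[pid] = s
            truth[pid] = crop
            i += 1
    soy_ids = [p.id for p in points if truth[p.id] == "soybean"]
    ref_ids = list(rng.choice(soy_ids, size=n_reference, replace=False))
    for p in points:
        if p.id in set(ref_ids):
            p.label = "soybean"
            p.provenance = "ground_survey"
    landcover = simulate_landcover(extent_m=extent_m, seed=seed + 1)
    return Scene(
        points=points, optical=optical, sar=sar, truth=truth,
        reference_ids=ref_ids, landcover=landcover, year=year, region=region,
    )
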