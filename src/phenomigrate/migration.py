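"""Training-sample migration: the core screening algorithm.

Reference soybean points (ground surveys, possibly from another year or
region) define two 3-D multivariate Gaussian models over seasonal curve
integrals: a high-value group (EVI, RE2, SWIR2) and a low-value group
(LSWI, RENDVI, REPI).  Candidate cropland points are screened by

1. the Concave-Convexity Index
   ``CCI = 2*r(POS) - [r(SOS) + r(EOS)]`` of the TCARI/OSAVI curve
   (negative = concave = high-chlorophyll crop candidate), and
2. Mahalanobis distances to both group models against percentile
   thresholds derived from the reference distribution:

   * robust references are those inside the central 50 %-probability
     region (density above ``p50``, estimated by Monte Carlo);
   * the soybean threshold is the 90th percentile of robust references'
     distances, the non-soybean threshold the 95th percentile of *all*
     references' distances.

A candidate is labelled soybean when its CCI is negative and both
distances fall below the soybean thresholds; non-soybean when both
distances exceed the non-soybean thresholds; otherwise it is discarded.

The model/results interface: :class:`SoybeanMigration` holds the data,
``fit()`` runs the algorithm and returns a :class:`MigrationResult` with
the fitted group models, per-candidate audit records and a summary.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .curves import SampleSignature, compute_signature
from .phenology import PhenologyDates
from .points import SamplePoint
from .prep import GriddedSeries, TemporalGrid
from .raster import Raster
from .series import ReflectanceSeries

_LOG2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# CCI

def compute_cci(ratio: GriddedSeries, phen: PhenologyDates) -> float:
    """Concave-Convexity Index of the TCARI/OSAVI curve.

    ``CCI = 2*r(POS) - [r(SOS) + r(EOS)]`` with linear interpolation at
    the fractional phenology dates.  Negative values indicate a concave
    (high-chlorophyll) seasonal trajectory.
    """
    if not ratio.is_gap_free():
        raise ValueError("ratio curve has missing values at required dates")
    vals = ratio.interp([phen.sos, phen.pos, phen.eos])
    if not np.all(np.isfinite(vals)):
        raise ValueError("ratio curve non-finite at SOS/POS/EOS")
    return float(2.0 * vals[1] - (vals[0] + vals[2]))


# ---------------------------------------------------------------------------
# Gaussian group models

@dataclass
class GaussianGroupModel:
    """Fitted 3-D Gaussian for one integral group with its thresholds."""

    group: str                 # "high" | "low"
    mu: np.ndarray
    sigma: np.ndarray
    p50: float
    r50: float
    d_soy_thresh: float
    d_nonsoy_thresh: float
    n_fit: int
    n_mc: int
    seed: int
    _chol: tuple = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self._chol is None:
            self._chol = cho_factor(self.sigma, lower=True)

    @property
    def dim(self) -> int:
        return self.mu.size

    def mahalanobis(self, x) -> np.ndarray | float:
        """Mahalanobis distance(s) via the Cholesky factor of Sigma."""
        x = np.asarray(x, dtype=float)
        scalar = x.ndim == 1
        pts = np.atleast_2d(x)
        if not np.all(np.isfinite(pts)):
            raise ValueError("non-finite input to mahalanobis")
        diff = pts - self.mu
        sol = cho_solve(self._chol, diff.T)
        d = np.sqrt(np.einsum("ij,ji->i", diff, sol))
        return float(d[0]) if scalar else d

    def pdf(self, x) -> np.ndarray | float:
        """Multivariate normal density at x."""
        d = np.asarray(self.mahalanobis(x))
        logdet = 2.0 * np.sum(np.log(np.diag(self._chol[0])))
        logc = -0.5 * (self.dim * _LOG2PI + logdet)
        out = np.exp(logc - 0.5 * d**2)
        return float(out) if out.ndim == 0 else out

    def density_at_radius(self, r: float) -> float:
        """Density on the Mahalanobis shell of radius r."""
        logdet = 2.0 * np.sum(np.log(np.diag(self._chol[0])))
        return float(np.exp(-0.5 * (self.dim * _LOG2PI + logdet) - 0.5 * r**2))

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "mu": self.mu.tolist(),
            "sigma": self.sigma.tolist(),
            "p50": self.p50,
            "r50": self.r50,
            "d_soy_thresh": self.d_soy_thresh,
            "d_nonsoy_thresh": self.d_nonsoy_thresh,
            "n_fit": self.n_fit,
            "n_mc": self.n_mc,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GaussianGroupModel":
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "GaussianGroupModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def mahalanobis(x, model: GaussianGroupModel) -> float:
    """Distance of a single vector to a fitted group model."""
    return model.mahalanobis(np.asarray(x, dtype=float))


def fit_group_model(
    reference_integrals,
    group: str,
    n_mc: int = 100_000,
    seed: int = 0,
    *,
    soy_percentile: float = 90.0,
    nonsoy_percentile: float = 95.0,
    min_reference: int = 30,
    cond_threshold: float = 1e8,
    ridge: float = 1e-6,
) -> GaussianGroupModel:
    """Fit one integral-group Gaussian and derive its thresholds.

    The density level ``p50`` bounding the central 50 %-probability
    region is estimated by Monte Carlo: draw ``n_mc`` points from the
    fitted Gaussian and take the median sampled density -- equivalently
    the density at the median Mahalanobis radius ``r50``.  Reference
    points denser than ``p50`` (distance below ``r50``) are the robust
    set; the soybean threshold is their ``soy_percentile`` distance, the
    non-soybean threshold the ``nonsoy_percentile`` distance of all
    references.
    """
    X = np.asarray(reference_integrals, dtype=float)
    if X.ndim != 2:
        raise ValueError("reference_integrals must be an (n, d) array")
    n, d = X.shape
    if n < min_reference:
        raise ValueError(
            f"need at least {min_reference} reference points to fit a "
            f"{d}-D Gaussian, have {n}; collect more surveys or use "
            "migration from a better-covered region/year"
        )
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite reference integrals")
    mu = X.mean(axis=0)
    sigma = np.cov(X, rowvar=False, ddof=1)
    if np.linalg.cond(sigma) > cond_threshold:
        sigma = sigma + ridge * (np.trace(sigma) / d) * np.eye(d)
    if np.any(np.linalg.eigvalsh(sigma) <= 0):
        raise ValueError("covariance not positive definite after regularization")

    model = GaussianGroupModel(
        group=group, mu=mu, sigma=sigma, p50=np.nan, r50=np.nan,
        d_soy_thresh=np.nan, d_nonsoy_thresh=np.nan,
        n_fit=n, n_mc=n_mc, seed=seed,
    )
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(mu, sigma, size=n_mc, method="cholesky")
    d2 = model.mahalanobis(draws) ** 2
    model.r50 = float(np.sqrt(np.median(d2)))
    model.p50 = model.density_at_radius(model.r50)

    dist_ref = model.mahalanobis(X)
    robust = dist_ref < model.r50
    if not np.any(robust):
        raise ValueError("no reference point inside the 50% density region")
    model.d_soy_thresh = float(np.percentile(dist_ref[robust], soy_percentile))
    model.d_nonsoy_thresh = float(np.percentile(dist_ref, nonsoy_percentile))
    if model.d_soy_thresh > model.r50 + 1e-12:
        raise AssertionError("soybean threshold exceeds r50")
    if model.d_nonsoy_thresh < model.d_soy_thresh:
        warnings.warn(
            "non-soybean threshold below soybean threshold; reference set "
            "is too small or degenerate", stacklevel=2,
        )
    return model


# ---------------------------------------------------------------------------
# Candidate classification

@dataclass
class CandidateRecord:
    """Audit record for one screened candidate point."""

    point: SamplePoint
    cci: float
    d_high: float
    d_low: float
    decision: str = "cropland_unknown"


def classify_candidate(
    rec: CandidateRecord,
    high_model: GaussianGroupModel,
    low_model: GaussianGroupModel,
) -> str:
    """Apply the soybean / non-soybean decision rules to one candidate."""
    if rec.d_high < 0 or rec.d_low < 0:
        raise ValueError("distances must be non-negative")
    soy = (
        rec.cci < 0
        and rec.d_high < high_model.d_soy_thresh
        and rec.d_low < low_model.d_soy_thresh
    )
    non_soy = (
        rec.d_high > high_model.d_nonsoy_thresh
        and rec.d_low > low_model.d_nonsoy_thresh
    )
    if soy:
        return "soybean"
    if non_soy:
        return "non_soybean"
    return "cropland_unknown"


# ---------------------------------------------------------------------------
# Cropland point generation

def _hex_vertices(cx: float, cy: float, radius: float) -> np.ndarray:
    ang = np.pi / 180.0 * (60.0 * np.arange(6) + 30.0)  # pointy-top
    return np.column_stack([cx + radius * np.cos(ang), cy + radius * np.sin(ang)])


def _point_in_hex(px, py, cx, cy, radius) -> np.ndarray:
    """Vectorized pointy-top hexagon containment."""
    dx = np.abs(px - cx) / radius
    dy = np.abs(py - cy) / radius
    w = np.sqrt(3.0) / 2.0
    return (dx <= w) & (dy <= 1.0 - dx / np.sqrt(3.0))


def buffer_purity(landcover: Raster, x: float, y: float,
                  buffer_radius: float, code: int) -> float:
    """Fraction of cells with centres within the buffer matching ``code``."""
    r = buffer_radius
    X, Y = landcover.cell_centres()
    within = (X - x) ** 2 + (Y - y) ** 2 <= r * r
    n = int(within.sum())
    if n == 0:
        return 0.0
    return float(np.mean(landcover.data[within] == code))


def sample_cropland(
    landcover: Raster,
    hex_spacing: float = 500.0,
    points_per_hex: int = 3,
    buffer_radius: float = 50.0,
    purity: float = 0.90,
    seed: int = 0,
    *,
    cropland_code: int = 40,
    year: int = 2019,
    region: str = "R1",
) -> list[SamplePoint]:
    """Hexagonal random sampling of pure cropland points.

    A pointy-top hexagonal tessellation with centre spacing
    ``hex_spacing`` covers the raster; ``points_per_hex`` points are
    scattered uniformly in each hexagon, and a point is retained (label
    ``cropland_unknown``) only when the cropland class covers more than
    ``purity`` of the cells whose centres fall within ``buffer_radius``.
    """
    if not (0.5 < purity <= 1.0):
        raise ValueError("purity must lie in (0.5, 1]")
    if not np.any(landcover.data == cropland_code):
        raise ValueError(f"raster has no cells with cropland code {cropland_code}")
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = landcover.extent
    radius = hex_spacing / np.sqrt(3.0)
    dy = 1.5 * radius
    kept: list[SamplePoint] = []
    i = 0
    row = 0
    cy = ymin
    while cy <= ymax + dy:
        offset = (hex_spacing / 2.0) if row % 2 else 0.0
        cx = xmin + offset
        while cx <= xmax + hex_spacing:
            # rejection-sample uniform points inside the hexagon
            got = 0
            while got < points_per_hex:
                px = cx + (rng.random(8) - 0.5) * 2 * radius
                py = cy + (rng.random(8) - 0.5) * 2 * radius
                ok = _point_in_hex(px, py, cx, cy, radius)
                for x, y in zip(px[ok], py[ok]):
                    if got >= points_per_hex:
                        break
                    got += 1
                    if not (xmin <= x < xmax and ymin <= y < ymax):
                        continue
                    frac = buffer_purity(landcover, x, y, buffer_radius,
                                         cropland_code)
                    if frac > purity:
                        kept.append(
                            SamplePoint(
                                id=f"hex_{i:05d}",
                                lon=max(-180.0, min(180.0, x / 111_000.0)),
                                lat=max(-90.0, min(90.0, y / 111_000.0)),
                                year=year,
                                region=region,
                            )
                        )
                        i += 1
            cx += hex_spacing
        cy += dy
        row += 1
    if not kept:
        warnings.warn("no cropland points retained", stacklevel=2)
    return kept


# ---------------------------------------------------------------------------
# Migration-priority strategy

@dataclass(frozen=True)
class SurveySet:
    """An available ground-survey collection for one region-year."""

    region: str
    year: int
    climate_zone: float = 0.0


def select_reference_set(
    target_region: str,
    target_year: int,
    inventory: list[SurveySet],
    *,
    target_climate_zone: float = 0.0,
) -> tuple[SurveySet, str]:
    """Choose the survey set to migrate from, with its strategy tag.

    Priority: same region (any year; temporal migration) over same year
    from the climatically nearest region (spatial) over different
    region and year (spatiotemporal; nearest year, then nearest climate
    zone).  Ties break on smaller |year difference| then lexicographic
    region id.
    """
    if not inventory:
        raise ValueError("empty survey inventory")
    same_region = [s for s in inventory if s.region == target_region]
    if same_region:
        best = min(same_region, key=lambda s: (abs(s.year - target_year), s.region))
        return best, "temporal"
    same_year = [s for s in inventory if s.year == target_year]
    if same_year:
        best = min(
            same_year,
            key=lambda s: (abs(s.climate_zone - target_climate_zone),
                           abs(s.year - target_year), s.region),
        )
        return best, "spatial"
    best = min(
        inventory,
        key=lambda s: (abs(s.year - target_year),
                       abs(s.climate_zone - target_climate_zone), s.region),
    )
    return best, "spatiotemporal"


# ---------------------------------------------------------------------------
# Orchestration: model / results objects

@dataclass
class MigrationConfig:
    """Knobs of the screening algorithm (defaults follow the protocol)."""

    grid: TemporalGrid = field(default_factory=TemporalGrid)
    sg_window: int = 7
    sg_order: int = 2
    smooth: bool = True
    osavi_standard: bool = False
    soy_percentile: float = 90.0
    nonsoy_percentile: float = 95.0
    n_mc: int = 100_000
    min_reference: int = 30
    seed: int = 0


class SoybeanMigration:
    """Sample-migration model: reference surveys + candidate pool.

    Parameters
    ----------
    reference_series
        id -> ReflectanceSeries for ground-survey soybean points.
    candidate_points, candidate_series
        The cropland-unknown pool to screen.
    config
        Algorithm settings; defaults follow the documented protocol.
    """

    def __init__(
        self,
        reference_series: dict[str, ReflectanceSeries],
        candidate_points: list[SamplePoint],
        candidate_series: dict[str, ReflectanceSeries],
        config: MigrationConfig | None = None,
    ) -> None:
        self.reference_series = reference_series
        self.candidate_points = candidate_points
        self.candidate_series = candidate_series
        self.config = config or MigrationConfig()
        missing = [p.id for p in candidate_points if p.id not in candidate_series]
        if missing:
            raise ValueError(f"candidates without series: {missing[:5]}...")

    @classmethod
    def from_scene(cls, scene, config: MigrationConfig | None = None):
        """Build from a synthetic :class:`~phenomigrate.synthetic.Scene`."""
        ref = {i: scene.optical[i] for i in scene.reference_ids}
        cands = [p for p in scene.points if p.id not in set(scene.reference_ids)]
        cand_series = {p.id: scene.optical[p.id] for p in cands}
        return cls(ref, cands, cand_series, config)

    def _signature(self, refl: ReflectanceSeries) -> SampleSignature:
        c = self.config
        return compute_signature(
            refl, c.grid, window=c.sg_window, order=c.sg_order,
            smooth=c.smooth, osavi_standard=c.osavi_standard,
        )

    def fit(self, seed: int | None = None) -> "MigrationResult":
        """Run the full screening and return the results object."""
        c = self.config
        seed = c.seed if seed is None else seed
        counts = {"reference_total": len(self.reference_series),
                  "candidate_total": len(self.candidate_points)}

        ref_high, ref_low = [], []
        ref_failed = 0
        for rid, refl in self.reference_series.items():
            try:
                sig = self._signature(refl)
            except ValueError:
                ref_failed += 1
                continue
            ref_high.append(sig.high)
            ref_low.append(sig.low)
        counts["reference_usable"] = len(ref_high)
        counts["reference_failed"] = ref_failed

        high_model = fit_group_model(
            np.array(ref_high), "high", n_mc=c.n_mc, seed=seed,
            soy_percentile=c.soy_percentile,
            nonsoy_percentile=c.nonsoy_percentile,
            min_reference=c.min_reference,
        )
        low_model = fit_group_model(
            np.array(ref_low), "low", n_mc=c.n_mc, seed=seed + 1,
            soy_percentile=c.soy_percentile,
            nonsoy_percentile=c.nonsoy_percentile,
            min_reference=c.min_reference,
        )

        records: list[CandidateRecord] = []
        cand_failed = 0
        for p in self.candidate_points:
            try:
                sig = self._signature(self.candidate_series[p.id])
            except ValueError:
                cand_failed += 1
                continue
            rec = CandidateRecord(
                point=p,
                cci=sig.cci,
                d_high=float(high_model.mahalanobis(sig.high)),
                d_low=float(low_model.mahalanobis(sig.low)),
            )
            rec.decision = classify_candidate(rec, high_model, low_model)
            records.append(rec)
        counts["candidate_failed"] = cand_failed
        counts["cci_negative"] = sum(1 for r in records if r.cci < 0)
        counts["labelled_soybean"] = sum(
            1 for r in records if r.decision == "soybean")
        counts["labelled_non_soybean"] = sum(
            1 for r in records if r.decision == "non_soybean")
        counts["discarded"] = sum(
            1 for r in records if r.decision == "cropland_unknown")

        return MigrationResult(
            model=self, high_model=high_model, low_model=low_model,
            records=records, stage_counts=counts, seed=seed,
        )


class MigrationResult:
    """Fitted group models plus per-candidate screening decisions."""

    def __init__(self, model, high_model, low_model, records, stage_counts,
                 seed):
        self.model = model
        self.high_model = high_model
        self.low_model = low_model
        self.records = records
        self.stage_counts = stage_counts
        self.seed = seed

    @property
    def labelled_points(self) -> list[SamplePoint]:
        """Newly labelled soybean / non-soybean points (discards dropped)."""
        out = []
        for r in self.records:
            if r.decision == "cropland_unknown":
                continue
            p = r.point
            out.append(
                SamplePoint(
                    id=p.id, lon=p.lon, lat=p.lat, year=p.year,
                    label=r.decision, provenance="generated",
                    region=p.region, crop=p.crop,
                )
            )
        return out

    @property
    def audit_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.point.id for r in self.records],
                "cci": [r.cci for r in self.records],
                "d_high": [r.d_high for r in self.records],
                "d_low": [r.d_low for r in self.records],
                "decision": [r.decision for r in self.records],
            }
        )

    def precision_against(self, truth: dict[str, str]) -> dict[str, float]:
        """Label precision vs generator truth (crop name per id)."""
        out = {}
        for label, want_soy in (("soybean", True), ("non_soybean", False)):
            sel = [r for r in self.records if r.decision == label]
            if not sel:
                out[label] = float("nan")
                continue
            good = sum(
                1 for r in sel
                if (truth[r.point.id] == "soybean") == want_soy
            )
            out[label] = good / len(sel)
        return out

    def summary(self) -> str:
        c = self.stage_counts
        lines = [
            "Soybean sample-migration results",
            "=" * 44,
            f"{'references (usable/total)':34s}"
            f"{c['reference_usable']}/{c['reference_total']}",
            f"{'candidates screened':34s}{len(self.records)}",
            f"{'candidates with CCI < 0':34s}{c['cci_negative']}",
            f"{'labelled soybean':34s}{c['labelled_soybean']}",
            f"{'labelled non-soybean':34s}{c['labelled_non_soybean']}",
            f"{'discarded (unknown)':34s}{c['discarded']}",
            "-" * 44,
        ]
        for m in (self.high_model, self.low_model):
            lines += [
                f"{m.group}-value group (n_fit={m.n_fit}, n_mc={m.n_mc}, "
                f"seed={m.seed})",
                f"  r50 = {m.r50:.4f}   p50 = {m.p50:.4g}",
                f"  D_soy({int(90)}th pct) = {m.d_soy_thresh:.4f}   "
                f"D_nonsoy({int(95)}th pct) = {m.d_nonsoy_thresh:.4f}",
            ]
        return "\n".join(lines)

    def plot_distances(self, ax=None):
        """Scatter of candidate Mahalanobis distances with thresholds."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        tab = self.audit_table
        colors = {"soybean": "tab:green", "non_soybean": "tab:brown",
                  "cropland_unknown": "0.7"}
        for decision, grp in tab.groupby("decision"):
            ax.scatter(grp["d_high"], grp["d_low"], s=8,
                       c=colors.get(decision, "k"), label=decision)
        ax.axvline(self.high_model.d_soy_thresh, ls="--", c="tab:green", lw=1)
        ax.axhline(self.low_model.d_soy_thresh, ls="--", c="tab:green", lw=1)
        ax.axvline(self.high_model.d_nonsoy_thresh, ls="--", c="tab:brown", lw=1)
        ax.axhline(self.low_model.d_nonsoy_thresh, ls="--", c="tab:brown", lw=1)
        ax.set_xlabel("Mahalanobis distance, high-value group")
        ax.set_ylabel("Mahalanobis distance, low-value group")
        ax.legend(fontsize=8)
        return ax

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.audit_table.to_csv(outdir / "audit.csv", index=False)
        self.high_model.save(outdir / "model_high.json")
        self.low_model.save(outdir / "model_low.json")
        (outdir / "stage_counts.json").write_text(
            json.dumps(self.stage_counts, indent=1))


def migrate_samples(
    reference_series: dict[str, ReflectanceSeries],
    candidate_points: list[SamplePoint],
    candidate_series: dict[str, ReflectanceSeries],
    config: MigrationConfig | None = None,
) -> MigrationResult:
    """Functional wrapper over :class:`SoybeanMigration`."""
    return SoybeanMigration(
        reference_series, candidate_points, candidate_series, config
    ).fit()
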