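"""Classification features: optical statistics, phenology, harmonics,
accumulated biomass, SAR statistics and temporal principal components.

The optical block (69 features) combines six distribution statistics of
five index curves (EVI, GCVI, LSWI, REPI, NDPI) and five bands
(RE1-RE3, SWIR1, SWIR2 = B5-B7, B11, B12), season timing (SOS, EOS,
LOS), amplitude and phase of the first two harmonics of the EVI series,
and the green-up / senescence EVI integrals.  The SAR block (50) takes
seven statistics of the five SAR parameters plus each parameter's first
three temporal principal-component scores.  A seeded random-forest
importance ranking keeps the top fraction (default half) of features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .curves import gridded_band_curves, index_curves_from_bands
from .indices import SAR_PARAMETERS, compute_index, sar_parameter
from .phenology import PhenologyDates, extract_phenology, seasonal_integral
from .prep import GriddedSeries, TemporalGrid, composite, fill_gaps, sg_smooth
from .series import ReflectanceSeries, SARSeries

FEATURE_INDICES = ("EVI", "GCVI", "LSWI", "REPI", "NDPI")
FEATURE_BANDS = ("RE1", "RE2", "RE3", "SWIR1", "SWIR2")
BAND_COLUMN = {"RE1": "b5", "RE2": "b6", "RE3": "b7",
               "SWIR1": "b11", "SWIR2": "b12"}
SAR_COLUMN = {"VH": "sar_vh", "VV": "sar_vv", "cross_ratio": "sar_ratio",
              "cross_sum": "sar_sum", "RVI": "sar_rvi"}

OPTICAL_STATS = ("min", "max", "std", "p15", "p50", "p90")
SAR_STATS = ("max", "min", "mean", "std", "p15", "p50", "p90")


def series_statistics(x: GriddedSeries | np.ndarray) -> dict[str, float]:
    """Six distribution statistics of a gap-free series.

    Percentiles use linear interpolation between order statistics.
    """
    v = x.values if isinstance(x, GriddedSeries) else np.asarray(x, float)
    if v.size == 0:
        raise ValueError("empty series")
    if not np.all(np.isfinite(v)):
        raise ValueError("series statistics require a gap-free series")
    p15, p50, p90 = np.percentile(v, [15, 50, 90])
    return {
        "min": float(v.min()), "max": float(v.max()),
        "std": float(v.std(ddof=0)),
        "p15": float(p15), "p50": float(p50), "p90": float(p90),
    }


def sar_statistics(x: GriddedSeries | np.ndarray) -> dict[str, float]:
    """Seven statistics (adds the mean) used for the SAR parameters."""
    out = series_statistics(x)
    v = x.values if isinstance(x, GriddedSeries) else np.asarray(x, float)
    out["mean"] = float(v.mean())
    return out


@dataclass
class HarmonicFit:
    """Least-squares harmonic decomposition f(t) = a + b t + sum_m
    C_m cos(2 pi m w t) + D_m sin(2 pi m w t), w = 1/365."""

    a: float
    b: float
    cos_coef: np.ndarray   # C_m, m = 1..M
    sin_coef: np.ndarray   # D_m
    residual_rms: float
    omega: float = 1.0 / 365.0

    @property
    def n_harmonics(self) -> int:
        return self.cos_coef.size

    def amplitude(self, m: int) -> float:
        """Magnitude of the (C_m, D_m) vector; m is 1-based."""
        return float(np.hypot(self.cos_coef[m - 1], self.sin_coef[m - 1]))

    def phase(self, m: int) -> float:
        """Angle of the (C_m, D_m) vector in (-pi, pi]."""
        return float(np.arctan2(self.sin_coef[m - 1], self.cos_coef[m - 1]))

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = self.a + self.b * t
        for m in range(1, self.n_harmonics + 1):
            arg = 2.0 * np.pi * m * self.omega * t
            out = out + self.cos_coef[m - 1] * np.cos(arg)
            out = out + self.sin_coef[m - 1] * np.sin(arg)
        return out


def harmonic_fit(times, values, M: int = 2, *,
                 omega: float = 1.0 / 365.0) -> HarmonicFit:
    """Fit the harmonic model by ordinary least squares.

    ``times`` in day-of-year; NaN values are dropped.  Needs at least
    2M + 2 observations (constant, trend, and M cosine/sine pairs).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    ok = np.isfinite(y)
    t, y = t[ok], y[ok]
    if t.size < 2 * M + 2:
        raise ValueError(
            f"harmonic fit with M={M} needs >= {2 * M + 2} observations, "
            f"have {t.size}"
        )
    cols = [np.ones_like(t), t]
    for m in range(1, M + 1):
        arg = 2.0 * np.pi * m * omega * t
        cols += [np.cos(arg), np.sin(arg)]
    A = np.column_stack(cols)
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise ValueError("rank-deficient harmonic design matrix")
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    return HarmonicFit(
        a=float(coef[0]), b=float(coef[1]),
        cos_coef=coef[2::2].copy(), sin_coef=coef[3::2].copy(),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        omega=omega,
    )


def accumulated_evi(
    evi: GriddedSeries, phen: PhenologyDates
) -> tuple[float, float]:
    """Green-up and senescence EVI integrals: [SOS, POS] and [POS, EOS]."""
    green_up = seasonal_integral(evi, phen, start=phen.sos, end=phen.pos)
    senescence = seasonal_integral(evi, phen, start=phen.pos, end=phen.eos)
    return green_up, senescence


def temporal_pca(matrix: np.ndarray, k: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Project samples onto the top-k temporal principal components.

    Columns (time steps) are centred; eigenvectors of the temporal
    covariance define the components.  Deterministic sign rule: the
    largest-magnitude loading of each component is made positive.

    Returns
    -------
    scores : (n_samples, k_eff) array
    explained : fraction of variance per component
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("matrix must be 2-D (samples x time)")
    if not np.all(np.isfinite(X)):
        raise ValueError("PCA requires a gap-free matrix")
    Xc = X - X.mean(axis=0, keepdims=True)
    cov = Xc.T @ Xc / max(1, X.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    rank = int(np.sum(evals > max(1e-12, 1e-10 * evals.max())))
    k_eff = min(k, rank)
    if k_eff < k:
        warnings.warn(
            f"requested {k} components but matrix rank is {rank}; "
            f"returning {k_eff}", stacklevel=2,
        )
    V = evecs[:, :k_eff]
    for j in range(k_eff):
        i = int(np.argmax(np.abs(V[:, j])))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
    total = evals.sum()
    explained = evals[:k_eff] / total if total > 0 else np.zeros(k_eff)
    return Xc @ V, explained


def select_features(
    table: pd.DataFrame,
    labels,
    fraction: float = 0.5,
    seed: int = 999,
    *,
    n_estimators: int = 200,
) -> list[str]:
    """Keep the top fraction of features by random-forest importance."""
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("feature selection needs at least two classes")
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    rf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    rf.fit(table.to_numpy(), y)
    order = np.argsort(rf.feature_importances_)[::-1]
    keep = int(np.ceil(fraction * table.shape[1]))
    return [table.columns[i] for i in order[:keep]]


# ---------------------------------------------------------------------------
# Full feature-table assembly

def _regularize_sar(series, grid, window, order):
    g = fill_gaps(composite(series, grid))
    return sg_smooth(g, window=window, order=order)


def extract_features(
    ids: list[str],
    optical: dict[str, ReflectanceSeries],
    sar: dict[str, SARSeries],
    grid: TemporalGrid | None = None,
    *,
    window: int = 7,
    order: int = 2,
    n_harmonics: int = 2,
    osavi_standard: bool = False,
) -> pd.DataFrame:
    """Build the full optical + SAR feature table for a set of samples.

    Returns a DataFrame indexed by sample id with 119 columns: the
    69-feature optical block and the 50-feature SAR block.  Samples
    whose phenology cannot be extracted are dropped with a warning.
    """
    grid = grid or TemporalGrid()
    rows: dict[str, dict[str, float]] = {}
    sar_curves: dict[str, dict[str, np.ndarray]] = {p: {} for p in SAR_PARAMETERS}
    dropped = []
    for sid in ids:
        refl = optical[sid]
        try:
            bands = gridded_band_curves(refl, grid, window=window, order=order)
            idx = index_curves_from_bands(
                bands, grid, FEATURE_INDICES, osavi_standard=osavi_standard
            )
            phen = extract_phenology(idx["EVI"])
        except ValueError:
            dropped.append(sid)
            continue
        row: dict[str, float] = {}
        for name in FEATURE_INDICES:
            for stat, val in series_statistics(idx[name]).items():
                row[f"{name.lower()}_{stat}"] = val
        for band in FEATURE_BANDS:
            col = BAND_COLUMN[band]
            for stat, val in series_statistics(bands[band]).items():
                row[f"{col}_{stat}"] = val
        row["sos"] = phen.sos
        row["eos"] = phen.eos
        row["los"] = phen.los
        evi_raw = compute_index(refl, "EVI")
        fit = harmonic_fit(evi_raw.times, evi_raw.values, M=n_harmonics)
        for m in range(1, n_harmonics + 1):
            row[f"evi_amp{m}"] = fit.amplitude(m)
            row[f"evi_phase{m}"] = fit.phase(m)
        green_up, senescence = accumulated_evi(idx["EVI"], phen)
        row["evi_accum_greenup"] = green_up
        row["evi_accum_senescence"] = senescence

        s = sar[sid]
        for pname in SAR_PARAMETERS:
            g = _regularize_sar(
                sar_parameter(s, pname), grid, window, order
            )
            col = SAR_COLUMN[pname]
            for stat, val in sar_statistics(g).items():
                row[f"{col}_{stat}"] = val
            sar_curves[pname][sid] = g.values
        rows[sid] = row
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} samples without extractable phenology",
            stacklevel=2,
        )
    if not rows:
        raise ValueError("no samples yielded features")
    table = pd.DataFrame.from_dict(rows, orient="index")

    # cross-sample temporal PCA per SAR parameter
    kept_ids = list(table.index)
    for pname in SAR_PARAMETERS:
        mat = np.vstack([sar_curves[pname][sid] for sid in kept_ids])
        scores, _ = temporal_pca(mat, k=3)
        col = SAR_COLUMN[pname]
        for j in range(scores.shape[1]):
            table[f"{col}_pc{j + 1}"] = scores[:, j]
    return table


def feature_manifest(table: pd.DataFrame) -> dict:
    """Machine-readable inventory of the feature table."""
    cols = list(table.columns)
    n_optical = sum(
        1 for c in cols if not c.startswith("sar_")
    )
    return {
        "n_features": len(cols),
        "n_optical": n_optical,
        "n_sar": len(cols) - n_optical,
        "columns": cols,
    }
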