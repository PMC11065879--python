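"""Tabular I/O for time series (CSV / Parquet, Sentinel column naming)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .series import SENTINEL2_COLUMNS, ReflectanceSeries, SARSeries

_BAND_TO_COLUMN = {v: k for k, v in SENTINEL2_COLUMNS.items()}


def optical_to_frame(series: dict[str, ReflectanceSeries]) -> pd.DataFrame:
    """Long-form table: sample_id, doy, valid, B2..B12."""
    frames = []
    for sid, s in series.items():
        row = {"sample_id": sid, "doy": s.times.astype(int),
               "valid": s.mask.astype(int)}
        for band, arr in s.bands.items():
            row[_BAND_TO_COLUMN.get(band, band)] = arr
        frames.append(pd.DataFrame(row))
    return pd.concat(frames, ignore_index=True)


def frame_to_optical(df: pd.DataFrame) -> dict[str, ReflectanceSeries]:
    out = {}
    band_cols = [c for c in df.columns if c in SENTINEL2_COLUMNS]
    if not band_cols:
        raise ValueError("no Sentinel-2 band columns (B2..B12) found")
    for sid, grp in df.groupby("sample_id", sort=False):
        grp = grp.sort_values("doy")
        bands = {
            SENTINEL2_COLUMNS[c]: grp[c].to_numpy(dtype=float)
            for c in band_cols
        }
        mask = (
            grp["valid"].to_numpy(dtype=bool)
            if "valid" in grp.columns else None
        )
        out[str(sid)] = ReflectanceSeries(
            times=grp["doy"].to_numpy(dtype=float), bands=bands, mask=mask
        )
    return out


def sar_to_frame(series: dict[str, SARSeries]) -> pd.DataFrame:
    frames = []
    for sid, s in series.items():
        frames.append(
            pd.DataFrame(
                {"sample_id": sid, "doy": s.times.astype(int),
                 "valid": s.mask.astype(int), "VV": s.vv, "VH": s.vh}
            )
        )
    return pd.concat(frames, ignore_index=True)


def frame_to_sar(df: pd.DataFrame) -> dict[str, SARSeries]:
    out = {}
    for sid, grp in df.groupby("sample_id", sort=False):
        grp = grp.sort_values("doy")
        mask = (
            grp["valid"].to_numpy(dtype=bool)
            if "valid" in grp.columns else None
        )
        out[str(sid)] = SARSeries(
            times=grp["doy"].to_numpy(dtype=float),
            vv=grp["VV"].to_numpy(dtype=float),
            vh=grp["VH"].to_numpy(dtype=float),
            mask=mask,
        )
    return out


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write CSV or Parquet by extension."""
    path = Path(path)
    if path.suffix == ".parquet":
        df.to_parquet(path, index=False)
    else:
        df.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".parquet":
        return pd.read_parquet(path)
    return pd.read_csv(path)
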