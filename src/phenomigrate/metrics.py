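"""Validation metrics: confusion-matrix accuracies and area agreement.

Soybean is the positive class.  By the standard remote-sensing
convention the producer's accuracy is recall (TP / (TP + FN)) and the
user's accuracy is precision (TP / (TP + FP)); ``paper_convention=True``
swaps the two error terms, reproducing an alternative printed form of
the same pair.  Undefined ratios (zero denominators) are reported as
``None``, never as silent NaNs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import Point

from .raster import Raster


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts with soybean as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_labels(cls, truth, predicted, positive="soybean"):
        t = np.asarray(truth)
        p = np.asarray(predicted)
        if t.shape != p.shape:
            raise ValueError("truth/prediction length mismatch")
        return cls(
            tp=int(np.sum((t == positive) & (p == positive))),
            fp=int(np.sum((t != positive) & (p == positive))),
            fn=int(np.sum((t == positive) & (p != positive))),
            tn=int(np.sum((t != positive) & (p != positive))),
        )


def _ratio(num: float, den: float) -> float | None:
    return num / den if den > 0 else None


def accuracy_metrics(
    cm: ConfusionMatrix, *, paper_convention: bool = False
) -> dict[str, float | None]:
    """Producer's/user's accuracy, F1, overall accuracy and Kappa.

    Returns a dict with keys ``recall`` (PA), ``precision`` (UA),
    ``f1``, ``oa``, ``kappa`` and a ``convention`` tag recording which
    PA/UA definition was used.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    if paper_convention:
        pa = _ratio(cm.tp, cm.tp + cm.fp)
        ua = _ratio(cm.tp, cm.tp + cm.fn)
    else:
        pa = _ratio(cm.tp, cm.tp + cm.fn)
        ua = _ratio(cm.tp, cm.tp + cm.fp)
    if pa is None or ua is None or pa + ua == 0:
        f1 = None
    else:
        f1 = 2.0 * pa * ua / (pa + ua)
    n = cm.total
    po = (cm.tp + cm.tn) / n
    pe = (
        (cm.tp + cm.fp) * (cm.tp + cm.fn)
        + (cm.fn + cm.tn) * (cm.fp + cm.tn)
    ) / (n * n)
    kappa = (po - pe) / (1.0 - pe) if pe < 1.0 else None
    return {
        "recall": pa,
        "precision": ua,
        "f1": f1,
        "oa": po,
        "kappa": kappa,
        "convention": "printed" if paper_convention else "standard",
    }


def area_agreement(
    mapped: dict[str, float], reported: dict[str, float]
) -> dict[str, float | None]:
    """R^2 (squared Pearson correlation), RMSE and MAE between mapped
    and reported areas over matched administrative units."""
    if set(mapped) != set(reported):
        raise ValueError(
            f"unit keys differ: {sorted(set(mapped) ^ set(reported))}"
        )
    keys = sorted(mapped)
    if len(keys) < 2:
        raise ValueError("need at least two units")
    m = np.array([mapped[k] for k in keys], dtype=float)
    r = np.array([reported[k] for k in keys], dtype=float)
    diff = m - r
    rmse = float(np.sqrt(np.mean(diff**2)))
    mae = float(np.mean(np.abs(diff)))
    if np.std(r) == 0 or np.std(m) == 0:
        r2 = None  # degenerate: correlation undefined
    else:
        r2 = float(np.corrcoef(m, r)[0, 1] ** 2)
    return {"r2": r2, "rmse": rmse, "mae": mae}


def pixel_area(
    r: Raster, units: dict[str, object], *, soybean_value: float = 1.0
) -> dict[str, float]:
    """Soybean area per administrative unit (same units as cell_size^2).

    ``units`` maps unit name -> shapely polygon in the raster's
    coordinate frame; a pixel counts toward the unit containing its
    centre.
    """
    X, Y = r.cell_centres()
    soy = r.data == soybean_value
    cell_area = r.cell_size**2
    out = {}
    for name, poly in units.items():
        total = 0
        for x, y in zip(X[soy], Y[soy]):
            if poly.contains(Point(float(x), float(y))):
                total += 1
        out[name] = total * cell_area
    return out
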