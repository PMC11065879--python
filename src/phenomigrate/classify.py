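"""Random-forest classification and map post-processing.

Protocol: a stratified 50/50 per-region train/test split; forests fitted
at tree counts 50..500 in steps of 50 with random seed 999; the chosen
count is the first local maximum of held-out accuracy above 100 trees;
all other hyperparameters stay at library defaults.  The classified map
is cleaned with a single pass of an eight-neighbourhood majority filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .raster import Raster

TREE_GRID = tuple(range(50, 501, 50))
DEFAULT_RF_SEED = 999


def split_train_test(
    index,
    labels,
    regions=None,
    seed: int = 0,
) -> tuple[list, list]:
    """Stratified 50/50 split per region and class.

    Returns (train_ids, test_ids).  Within each (region, class) cell the
    ids are shuffled and split in half (odd cells give the extra sample
    to the training side).
    """
    index = list(index)
    labels = np.asarray(labels)
    regions = (
        np.asarray(regions) if regions is not None
        else np.array(["all"] * len(index))
    )
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("split needs at least two classes")
    rng = np.random.default_rng(seed)
    train, test = [], []
    for region in np.unique(regions):
        for cls in classes:
            sel = [
                i for i in range(len(index))
                if regions[i] == region and labels[i] == cls
            ]
            if not sel:
                continue
            if len(sel) < 2:
                raise ValueError(
                    f"class {cls!r} has a single sample in region {region!r}"
                )
            sel = list(rng.permutation(sel))
            half = (len(sel) + 1) // 2
            train += [index[i] for i in sel[:half]]
            test += [index[i] for i in sel[half:]]
    return train, test


def choose_tree_count(accuracy_by_trees: dict[int, float]) -> int:
    """First local accuracy maximum above 100 trees.

    The smallest count t > 100 with accuracy(t) >= accuracy(t-50) and
    accuracy(t) >= accuracy(t+50) (the right comparison is skipped at
    500).  Falls back to 500 with a warning when the curve keeps rising.
    """
    missing = [t for t in TREE_GRID if t not in accuracy_by_trees]
    if missing:
        raise ValueError(f"incomplete accuracy curve; missing {missing}")
    rising = all(
        accuracy_by_trees[t] > accuracy_by_trees[t - 50]
        for t in TREE_GRID[1:]
    )
    for t in TREE_GRID:
        if t <= 100:
            continue
        left_ok = accuracy_by_trees[t] >= accuracy_by_trees[t - 50]
        right_ok = t == 500 or accuracy_by_trees[t] >= accuracy_by_trees[t + 50]
        if left_ok and right_ok:
            if t == 500 and rising:
                warnings.warn(
                    "accuracy still rising at 500 trees; using 500",
                    stacklevel=2,
                )
            return t
    warnings.warn(
        "no local maximum above 100 trees; using 500", stacklevel=2
    )
    return 500


@dataclass
class ClassifierConfig:
    seed: int = DEFAULT_RF_SEED
    split_seed: int = 0
    tree_grid: tuple[int, ...] = TREE_GRID
    feature_fraction: float = 0.5


class SoybeanClassifier:
    """Random-forest soybean/non-soybean model over a feature table.

    Parameters
    ----------
    features
        DataFrame indexed by sample id (feature columns only).
    labels
        Mapping or Series id -> {"soybean", "non_soybean"}.
    regions
        Optional id -> region for the per-region split.
    """

    def __init__(self, features: pd.DataFrame, labels, regions=None,
                 config: ClassifierConfig | None = None) -> None:
        self.features = features
        self.labels = pd.Series(labels).reindex(features.index)
        if self.labels.isna().any():
            raise ValueError("every sample needs a label")
        self.regions = (
            pd.Series(regions).reindex(features.index)
            if regions is not None else None
        )
        self.config = config or ClassifierConfig()

    def fit(self, selected_features: list[str] | None = None
            ) -> "ClassifierResult":
        """Run the split, the tree-count sweep and the final refit."""
        cfg = self.config
        cols = selected_features or list(self.features.columns)
        X = self.features[cols]
        train_ids, test_ids = split_train_test(
            X.index, self.labels.to_numpy(),
            self.regions.to_numpy() if self.regions is not None else None,
            seed=cfg.split_seed,
        )
        Xtr = X.loc[train_ids].to_numpy()
        ytr = self.labels.loc[train_ids].to_numpy()
        Xte = X.loc[test_ids].to_numpy()
        yte = self.labels.loc[test_ids].to_numpy()
        curve: dict[int, float] = {}
        for t in cfg.tree_grid:
            rf = RandomForestClassifier(n_estimators=t, random_state=cfg.seed)
            rf.fit(Xtr, ytr)
            curve[t] = float(np.mean(rf.predict(Xte) == yte))
        chosen = choose_tree_count(curve)
        final = RandomForestClassifier(
            n_estimators=chosen, random_state=cfg.seed
        )
        final.fit(Xtr, ytr)
        return ClassifierResult(
            model=self, forest=final, tree_count=chosen,
            accuracy_curve=curve, feature_names=cols,
            train_ids=list(train_ids), test_ids=list(test_ids),
        )


@dataclass
class ClassifierResult:
    """Fitted forest with its protocol record."""

    model: SoybeanClassifier
    forest: RandomForestClassifier
    tree_count: int
    accuracy_curve: dict[int, float]
    feature_names: list[str]
    train_ids: list
    test_ids: list

    @property
    def test_accuracy(self) -> float:
        return self.accuracy_curve[self.tree_count]

    def predict(self, features: pd.DataFrame) -> pd.Series:
        """Predict labels for a feature table (columns must match)."""
        missing = [c for c in self.feature_names if c not in features.columns]
        extra = [c for c in features.columns if c not in self.feature_names]
        if missing:
            raise ValueError(
                f"feature columns mismatch; missing {missing}, "
                f"unexpected {extra}"
            )
        X = features[self.feature_names].to_numpy()
        return pd.Series(self.forest.predict(X), index=features.index)

    def predict_raster(
        self, stack: dict[str, np.ndarray], template: Raster
    ) -> Raster:
        """Per-pixel prediction over a feature stack.

        ``stack`` maps feature name -> 2-D array on the template grid.
        Pixels with any non-finite feature become nodata.  Output codes:
        1 = soybean, 0 = non-soybean, template nodata elsewhere.
        """
        missing = [c for c in self.feature_names if c not in stack]
        if missing:
            raise ValueError(f"feature stack missing {missing}")
        shape = template.data.shape
        flat = np.column_stack(
            [np.asarray(stack[c], dtype=float).reshape(-1)
             for c in self.feature_names]
        )
        ok = np.all(np.isfinite(flat), axis=1)
        out = np.full(flat.shape[0], template.nodata, dtype=float)
        if ok.any():
            pred = self.forest.predict(flat[ok])
            out[ok] = (pred == "soybean").astype(float)
        return template.copy_with(out.reshape(shape))

    def plot_accuracy_curve(self, ax=None):
        """Held-out accuracy versus tree count, with the chosen count."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 3))
        ts = sorted(self.accuracy_curve)
        ax.plot(ts, [self.accuracy_curve[t] for t in ts], marker="o", ms=3)
        ax.axvline(self.tree_count, ls="--", c="tab:red", lw=1)
        ax.set_xlabel("trees")
        ax.set_ylabel("held-out accuracy")
        return ax

    def summary(self) -> str:
        lines = [
            "Random-forest classification results",
            "=" * 44,
            f"{'features used':26s}{len(self.feature_names)}",
            f"{'train / test samples':26s}"
            f"{len(self.train_ids)} / {len(self.test_ids)}",
            f"{'chosen tree count':26s}{self.tree_count}",
            f"{'held-out accuracy':26s}{self.test_accuracy:.4f}",
            "-" * 44,
            "accuracy by tree count:",
        ]
        lines += [
            f"  {t:4d}: {a:.4f}" for t, a in sorted(self.accuracy_curve.items())
        ]
        return "\n".join(lines)


def majority_filter(r: Raster) -> Raster:
    """Eight-neighbourhood majority vote on a binary {1, 0, nodata} map.

    Each pixel takes the majority class over its 3x3 neighbourhood
    (centre included); ties keep the centre value; nodata cells do not
    vote and nodata centres stay nodata.  Single application.
    """
    data = np.asarray(r.data, dtype=float)
    nodata = r.nodata
    valid = data != nodata
    is_soy = (data == 1) & valid
    is_non = valid & ~is_soy

    def _neighbour_sum(mask: np.ndarray) -> np.ndarray:
        padded = np.pad(mask.astype(int), 1)
        out = np.zeros_like(mask, dtype=int)
        for di in (0, 1, 2):
            for dj in (0, 1, 2):
                out += padded[di:di + mask.shape[0], dj:dj + mask.shape[1]]
        return out

    soy_votes = _neighbour_sum(is_soy)
    non_votes = _neighbour_sum(is_non)
    out = data.copy()
    flip_soy = valid & (soy_votes > non_votes)
    flip_non = valid & (non_votes > soy_votes)
    out[flip_soy] = 1
    out[flip_non] = 0
    return r.copy_with(out)


def export_soybean_map(r: Raster) -> Raster:
    """Encode the final product: value 1 for soybean, nodata elsewhere."""
    out = np.where(r.data == 1, 1.0, r.nodata)
    return r.copy_with(out)
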