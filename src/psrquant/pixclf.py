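"""Trainable four-class pixel segmentation — the WEKA analogue.

Per-pixel features are the raw value plus five local window statistics
(mean, minimum, maximum, median, variance) of each RGB channel over square
windows at several radii.  A class-balanced random forest is trained from
sparse labelled regions and extrapolated across whole tiles.  Three training
regimes mirror the study: ``per_set`` (one classifier per stain set, trained
only on that set), ``combined`` (one classifier trained on all sets), and
``combined_retrained`` (the combined classifier further trained on cases
whose inter-laboratory scores diverged by more than a factor threshold).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import rank
from skimage.morphology import footprint_rectangle
from sklearn.ensemble import RandomForestClassifier

from psrquant.hsb import ClassCounts, NoTissueError
from psrquant.synth import PixelClass
from psrquant.tiles import TileImage

DEFAULT_RADII: tuple[int, ...] = (1, 2, 4, 8)
_STATS = ("mean", "min", "max", "median", "variance")


@dataclass(frozen=True)
class FeatureStack:
    """Per-pixel feature tensor (H, W, F) with recorded feature order."""

    data: np.ndarray
    feature_names: tuple[str, ...]
    radii: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.data.shape[-1] != len(self.feature_names):
            raise ValueError("feature name count disagrees with tensor depth")
        if not np.isfinite(self.data).all():
            raise ValueError("features must be finite")


@dataclass(frozen=True)
class LabelledRegion:
    """A sparse user annotation: a set of pixels of one class on one tile."""

    tile_id: str
    coords: np.ndarray  # (N, 2) row, col
    pixel_class: PixelClass
    stain_set: str = ""
    case_id: str = ""
    annotator: str = ""

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError("coords must be (N, 2)")
        if int(self.pixel_class) not in [int(c) for c in PixelClass]:
            raise ValueError("invalid class")


@dataclass
class TrainedClassifier:
    """A fitted tree ensemble plus everything needed to reapply it."""

    model: RandomForestClassifier
    radii: tuple[int, ...]
    feature_names: tuple[str, ...]
    classes: tuple[int, ...]
    regime: str  # per_set | combined | combined_retrained
    seed: int
    holdout_accuracy: float
    provenance: dict = field(default_factory=dict)
    training_table: pd.DataFrame | None = None


def compute_features(
    tile: TileImage | np.ndarray,
    radii: Sequence[int] = DEFAULT_RADII,
    dtype: np.dtype = np.float32,
) -> FeatureStack:
    """Raw value + windowed mean/min/max/median/variance per RGB channel.

    Windows are squares of side ``2r + 1`` with edge-replicated borders;
    variance is the population variance.  Statistics are computed in
    float64 and stored as ``dtype`` (float32 by default — a study's
    feature cache is large); pass float64 to keep full computation
    precision.  Deterministic.
    """
    if len(radii) == 0 or any(r < 1 for r in radii):
        raise ValueError("radii must be non-empty, each >= 1")
    img = tile.pixel_raster if isinstance(tile, TileImage) else np.asarray(tile)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected H x W x 3 raster")
    planes: list[np.ndarray] = []
    names: list[str] = []
    for ch, ch_name in enumerate("RGB"):
        chan8 = img[..., ch]
        chan = chan8.astype(np.float64)
        planes.append(chan)
        names.append(f"{ch_name}_raw")
        for r in radii:
            size = 2 * r + 1
            mean = ndimage.uniform_filter(chan, size=size, mode="nearest")
            sq_mean = ndimage.uniform_filter(chan**2, size=size, mode="nearest")
            var = np.maximum(sq_mean - mean**2, 0.0)
            mn = ndimage.minimum_filter(chan, size=size, mode="nearest")
            mx = ndimage.maximum_filter(chan, size=size, mode="nearest")
            # rank.median over the padded tile matches a replicate-border
            # sliding-window median exactly while staying O(1) per pixel
            padded = np.pad(chan8, r, mode="edge")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                med = rank.median(padded, footprint_rectangle((size, size)))
            med = med[r:-r, r:-r].astype(np.float64)
            for stat, plane in zip(_STATS, (mean, mn, mx, med, var)):
                planes.append(plane)
                names.append(f"{ch_name}_{stat}_r{r}")
    data = np.stack(planes, axis=-1).astype(dtype)
    return FeatureStack(data=data, feature_names=tuple(names), radii=tuple(radii))


def collect_training(
    regions: Iterable[LabelledRegion],
    features: Mapping[str, FeatureStack],
) -> pd.DataFrame:
    """One row per labelled pixel: feature vector, class, provenance.

    Raises on a region referencing a missing tile and on overlapping
    regions that assign conflicting classes to the same pixel.
    """
    regions = list(regions)
    seen: dict[tuple[str, int, int], int] = {}
    rows = []
    feature_names: tuple[str, ...] | None = None
    for region in regions:
        if region.tile_id not in features:
            raise KeyError(f"region references missing tile {region.tile_id!r}")
        stack = features[region.tile_id]
        if feature_names is None:
            feature_names = stack.feature_names
        elif stack.feature_names != feature_names:
            raise ValueError("inconsistent feature configuration across tiles")
        h, w = stack.data.shape[:2]
        coords = np.asarray(region.coords, dtype=int)
        if coords.size and (
            coords.min() < 0 or coords[:, 0].max() >= h or coords[:, 1].max() >= w
        ):
            raise ValueError(f"region coordinates outside tile {region.tile_id!r}")
        conflicts = []
        for r, c in coords:
            key = (region.tile_id, int(r), int(c))
            prev = seen.get(key)
            if prev is not None and prev != int(region.pixel_class):
                conflicts.append(key)
            seen[key] = int(region.pixel_class)
        if conflicts:
            raise ValueError(f"conflicting labels at pixels: {conflicts[:10]}")
        vec = stack.data[coords[:, 0], coords[:, 1]]
        frame = pd.DataFrame(vec, columns=list(feature_names))
        frame["pixel_class"] = int(region.pixel_class)
        frame["tile_id"] = region.tile_id
        frame["stain_set"] = region.stain_set
        frame["case_id"] = region.case_id
        rows.append(frame)
    if not rows:
        return pd.DataFrame()
    return pd.concat(rows, ignore_index=True)


def balance_classes(table: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Upsample minority classes with replacement to the majority count.

    An already balanced table is returned unchanged (same row multiset).
    Deterministic given ``seed``.
    """
    counts = table["pixel_class"].value_counts()
    if len(counts) < 2:
        raise ValueError("balancing requires at least two classes")
    majority = int(counts.max())
    if (counts == majority).all():
        return table
    rng = np.random.default_rng(seed)
    parts = []
    for cls in sorted(counts.index):
        sub = table[table["pixel_class"] == cls]
        parts.append(sub)
        deficit = majority - len(sub)
        if deficit > 0:
            picks = rng.choice(sub.index.to_numpy(), size=deficit, replace=True)
            parts.append(table.loc[picks])
    return pd.concat(parts, ignore_index=True)


def _feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in ("pixel_class", "tile_id", "stain_set", "case_id")]


def train(
    table: pd.DataFrame,
    n_trees: int = 100,
    seed: int = 0,
    regime: str = "combined",
    radii: Sequence[int] = DEFAULT_RADII,
    provenance: dict | None = None,
) -> TrainedClassifier:
    """Fit the class-balanced tree ensemble on a training table.

    Out-of-bag accuracy is reported as the held-out estimate.  Requires all
    four classes; deterministic given ``seed``.
    """
    present = set(table["pixel_class"].unique())
    missing = [c.name for c in PixelClass if int(c) not in present]
    if missing:
        raise ValueError(f"training table missing classes: {missing}")
    cols = _feature_columns(table)
    X = table[cols].to_numpy(dtype=np.float32)
    y = table["pixel_class"].to_numpy(dtype=int)
    # half the features per split: with strongly correlated window
    # statistics, sqrt-subsampling too often hides the raw colour channels
    # from a split and costs exactness in the separable limit
    model = RandomForestClassifier(
        n_estimators=n_trees,
        random_state=int(seed) % (2**31),
        max_features=0.5,
        oob_score=True,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, y)
    prov = dict(provenance or {})
    prov.setdefault("stain_sets", sorted(map(str, table["stain_set"].unique())))
    prov.setdefault("tiles", sorted(map(str, table["tile_id"].unique())))
    return TrainedClassifier(
        model=model,
        radii=tuple(radii),
        feature_names=tuple(cols),
        classes=tuple(int(c) for c in model.classes_),
        regime=regime,
        seed=int(seed),
        holdout_accuracy=float(model.oob_score_),
        provenance=prov,
        training_table=table,
    )


def segment_tile(
    clf: TrainedClassifier,
    tile: TileImage | np.ndarray,
    features: FeatureStack | None = None,
) -> tuple[np.ndarray, ClassCounts]:
    """Assign every pixel of a tile one of the four classes.

    Returns the class raster and per-class counts (which always sum to the
    pixel count).  A precomputed FeatureStack may be passed; its
    configuration must match the model's.
    """
    if features is None:
        features = compute_features(tile, clf.radii)
    if features.feature_names != clf.feature_names:
        raise ValueError("feature configuration does not match the trained model")
    h, w = features.data.shape[:2]
    X = features.data.reshape(-1, features.data.shape[-1])
    pred = clf.model.predict(X).astype(np.uint8).reshape(h, w)
    counts = ClassCounts(
        {int(c): int(np.count_nonzero(pred == int(c))) for c in PixelClass}
    )
    return pred, counts


def psr_positivity(counts: ClassCounts) -> float:
    """100 x PSR / (PSR + TISSUE + LUMEN); SPACE is excluded."""
    psr = counts.get(PixelClass.PSR)
    denom = psr + counts.get(PixelClass.TISSUE) + counts.get(PixelClass.LUMEN)
    if denom == 0:
        raise NoTissueError("no PSR, tissue or lumen pixels: positivity undefined")
    return 100.0 * psr / denom


def select_divergent_cases(
    scores: pd.DataFrame,
    inter_pairs: Sequence[tuple[str, str]],
    factor: float = 2.0,
) -> list[str]:
    """Cases whose score ratio across any inter-laboratory pair exceeds ``factor``.

    ``scores`` has columns case_id, stain_set, psr_percent (a single method).
    The rule is strict (> factor); a zero score paired with a non-zero one is
    divergent; pairs with a missing member are skipped with a warning.
    """
    if factor <= 1:
        raise ValueError("factor must be > 1")
    divergent = []
    for case_id, sub in scores.groupby("case_id"):
        by_set = sub.set_index("stain_set")["psr_percent"]
        for a, b in inter_pairs:
            if a not in by_set.index or b not in by_set.index:
                warnings.warn(f"case {case_id}: pair ({a}, {b}) incomplete, skipped")
                continue
            lo, hi = sorted([float(by_set[a]), float(by_set[b])])
            if lo == 0.0:
                if hi > 0.0:
                    divergent.append(str(case_id))
                    break
                continue
            if hi / lo > factor:
                divergent.append(str(case_id))
                break
    return divergent


def retrain_with_divergent(
    base: TrainedClassifier,
    extra_regions: Iterable[LabelledRegion],
    features: Mapping[str, FeatureStack],
    seed: int,
    n_trees: int | None = None,
) -> TrainedClassifier:
    """Further train the combined classifier on divergence-flagged cases.

    The new model is fitted on the base training rows plus the new rows,
    re-balanced; provenance records the added case ids.
    """
    if base.regime != "combined":
        raise ValueError("retraining starts from the combined regime")
    extra_regions = list(extra_regions)
    if not extra_regions:
        raise ValueError("no extra regions supplied: retraining would be a no-op")
    if base.training_table is None:
        raise ValueError("base classifier carries no training table")
    new_rows = collect_training(extra_regions, features)
    merged = pd.concat([base.training_table, new_rows], ignore_index=True)
    merged = balance_classes(merged, seed=seed)
    added_cases = sorted({r.case_id for r in extra_regions})
    clf = train(
        merged,
        n_trees=n_trees or base.model.n_estimators,
        seed=seed,
        regime="combined_retrained",
        radii=base.radii,
        provenance={**base.provenance, "added_cases": added_cases},
    )
    return clf


# ---------------------------------------------------------------------------
# persistence

def save_model(clf: TrainedClassifier, path: str | Path) -> None:
    """Persist a model with a JSON sidecar of its configuration."""
    path = Path(path)
    joblib.dump({"model": clf.model, "training_table": clf.training_table}, path)
    meta = {
        "radii": list(clf.radii),
        "feature_names": list(clf.feature_names),
        "classes": list(clf.classes),
        "regime": clf.regime,
        "seed": clf.seed,
        "holdout_accuracy": clf.holdout_accuracy,
        "provenance": clf.provenance,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def load_model(path: str | Path) -> TrainedClassifier:
    path = Path(path)
    payload = joblib.load(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return TrainedClassifier(
        model=payload["model"],
        radii=tuple(meta["radii"]),
        feature_names=tuple(meta["feature_names"]),
        classes=tuple(meta["classes"]),
        regime=meta["regime"],
        seed=meta["seed"],
        holdout_accuracy=meta["holdout_accuracy"],
        provenance=meta["provenance"],
        training_table=payload["training_table"],
    )
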