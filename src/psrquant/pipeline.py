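"""End-to-end study orchestration: simulate, score, analyse.

A study bundle on disk (manifest + tiles + label rasters + ground truth) is
scored slide by slide: pixel counts are summed over all retained tiles of a
slide *before* the percentage formula is applied, so low-tissue tiles are
weighted by their pixel content rather than equally.  Methods:

* ``HSB`` — fixed HSB threshold calibrated once on the calibration set and
  applied unchanged to every stain set (the single-threshold protocol).
* ``PIXCLF_i`` / ``PIXCLF_c1`` / ``PIXCLF_c2`` — the trainable pixel
  classifier in per-set, combined, and divergence-retrained regimes.
* ``GROUND_TRUTH`` — per-section scar percentage read off the label raster.
* ``REF_SHG`` — the per-case stain-free reference (SHG analogue).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from psrquant import hsb as hsbmod
from psrquant import pixclf as pcmod
from psrquant import stats as statsmod
from psrquant.synth import (
    DEFAULT_LABORATORY_OF,
    PixelClass,
    StudyDesign,
    make_study,
    _spawn_seed,
)
from psrquant.tiles import TileImage, compute_tissue_mask

logger = logging.getLogger(__name__)

REFERENCE_SET_LABEL = "SHG"


def _read_image(path: Path) -> np.ndarray:
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        return tifffile.imread(path)
    import imageio.v3 as iio

    return iio.imread(path)


@dataclass
class StudyData:
    """A study bundle loaded into memory."""

    root: Path
    manifest: pd.DataFrame
    ground_truth: pd.DataFrame
    images: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    labels: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    @property
    def stain_sets(self) -> list[str]:
        return list(pd.unique(self.manifest["stain_set"]))

    @property
    def cases(self) -> list[str]:
        return list(pd.unique(self.manifest["case_id"]))

    def tile_id(self, case_id: str, stain_set: str) -> str:
        return f"{case_id}_{stain_set}"


def simulate_study(design: StudyDesign, out_dir: str | Path) -> StudyData:
    """Generate a study bundle on disk and load it back (cmd_simulate)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for label, t in design.stain_sets.items():
        logger.info(
            "stain set %s: hue %+.1f deg, sat x%.2f, bri x%.2f, fade %.2f, noise %.1f",
            label, t.hue_shift_deg, t.saturation_scale, t.brightness_scale,
            t.fade_factor, t.noise_sd,
        )
    make_study(design, out)
    return load_study(out)


def load_study(study_dir: str | Path) -> StudyData:
    root = Path(study_dir)
    manifest = pd.read_csv(root / "manifest.csv")
    ground_truth = pd.read_csv(root / "ground_truth.csv")
    study = StudyData(root=root, manifest=manifest, ground_truth=ground_truth)
    for _, row in manifest.iterrows():
        key = (row["case_id"], row["stain_set"])
        study.images[key] = _read_image(root / row["tile_path"])
        study.labels[key] = _read_image(root / row["label_path"])
    return study


# ---------------------------------------------------------------------------
# HSB scoring

def calibration_pixels(
    study: StudyData,
    set_label: str,
    n_per_class: int,
    seed: int,
    core_margin_px: int = 2,
) -> list[tuple[tuple[float, float, float], int]]:
    """Labelled HSB pixels sampled from one set, for threshold calibration.

    Pixels come from class cores (eroded masks), the way representative
    positive pixels are picked by eye away from blurred boundaries.
    """
    from scipy.ndimage import binary_erosion

    rng = np.random.default_rng(seed)
    out = []
    for case_id in study.cases:
        img = study.images[(case_id, set_label)]
        lab = study.labels[(case_id, set_label)]
        hsv = hsbmod.rgb_to_hsv_raster(img)
        for cls in (PixelClass.PSR, PixelClass.TISSUE):
            mask = lab == int(cls)
            if core_margin_px > 0:
                core = binary_erosion(mask, iterations=core_margin_px)
                if core.any():
                    mask = core
            idx = np.flatnonzero(mask)
            if idx.size == 0:
                continue
            picks = rng.choice(idx, size=min(n_per_class, idx.size), replace=False)
            ys, xs = np.unravel_index(picks, lab.shape)
            for yy, xx in zip(ys, xs):
                h, s, v = hsv[yy, xx]
                out.append(((float(h) * 360.0, float(s), float(v)), int(cls)))
    return out


def score_hsb(
    study: StudyData,
    threshold: hsbmod.HSBThreshold,
    brightness_cutoff: float = 0.92,
    min_object_px: int = 64,
    method_label: str = "HSB",
) -> pd.DataFrame:
    """Fixed-threshold HSB score per slide, one threshold for all sets.

    Per slide, tile counts are summed before the percentage is taken.
    """
    rows = []
    for (case_id, set_label), group in study.manifest.groupby(
        ["case_id", "stain_set"], sort=False
    ):
        img = study.images[(case_id, set_label)]
        tile = TileImage(pixel_raster=img, case_id=case_id, stain_set=set_label)
        mask = compute_tissue_mask(tile, brightness_cutoff, min_object_px)
        total = hsbmod.classify_hsb(tile, mask, threshold)
        rows.append(
            {
                "case_id": case_id,
                "stain_set": set_label,
                "method": method_label,
                "psr_percent": hsbmod.hsb_scar_percent(total),
            }
        )
    return pd.DataFrame(rows)


def aggregate_slide_score(
    tile_counts: Sequence[hsbmod.ClassCounts], formula: str = "hsb"
) -> float:
    """Slide percentage from per-tile counts: sum counts, then divide.

    Summing before the ratio weights tiles by their pixel content; the mean
    of per-tile percentages would overweight low-tissue tiles.
    """
    total = hsbmod.ClassCounts({})
    for counts in tile_counts:
        total = total + counts
    if formula == "hsb":
        return hsbmod.hsb_scar_percent(total)
    if formula == "pixclf":
        return pcmod.psr_positivity(total)
    raise ValueError(f"unknown formula {formula!r}")


# ---------------------------------------------------------------------------
# ground truth / reference scoring

def score_ground_truth(study: StudyData) -> pd.DataFrame:
    """Per-section scar percentage from the label rasters (stain-free scorer)."""
    rows = []
    for (case_id, set_label) in study.images:
        lab = study.labels[(case_id, set_label)]
        counts = hsbmod.ClassCounts(
            {int(c): int(np.count_nonzero(lab == int(c))) for c in PixelClass}
        )
        rows.append(
            {
                "case_id": case_id,
                "stain_set": set_label,
                "method": "GROUND_TRUTH",
                "psr_percent": pcmod.psr_positivity(counts),
            }
        )
    return pd.DataFrame(rows)


def reference_scores(study: StudyData) -> pd.DataFrame:
    """Per-case stain-free reference values (SHG analogue)."""
    return pd.DataFrame(
        {
            "case_id": study.ground_truth["case_id"].astype(str),
            "stain_set": REFERENCE_SET_LABEL,
            "method": "REF_SHG",
            "psr_percent": study.ground_truth["psr_percent"].astype(float),
        }
    )


# ---------------------------------------------------------------------------
# pixel-classifier scoring

def compute_study_features(
    study: StudyData, radii: Sequence[int] = pcmod.DEFAULT_RADII
) -> dict[str, pcmod.FeatureStack]:
    """FeatureStack per tile, computed once and shared by every regime."""
    return {
        study.tile_id(case_id, set_label): pcmod.compute_features(img, radii)
        for (case_id, set_label), img in study.images.items()
    }


def sample_annotations(
    study: StudyData,
    set_labels: Sequence[str],
    n_per_class: int,
    seed: int,
    cases: Sequence[str] | None = None,
    core_margin_px: int = 2,
    n_patches: int = 1,
    patch_radius: int = 10,
    miss_faint_psr: bool = True,
) -> list[pcmod.LabelledRegion]:
    """Sparse class annotations sampled from the label rasters.

    At least one annotated tile per case per listed stain set, mirroring
    the training protocol of annotating every slide in the study.  By
    default pixels are drawn from class *cores* (the class mask eroded by
    ``core_margin_px``), the way an annotator outlines unambiguous regions
    and avoids blurred boundaries, and are confined to ``n_patches`` small
    patches per class — annotations are contiguous strokes, not pixels
    scattered over the whole tile, so each annotated slide contributes only
    a narrow slice of its appearance.

    ``miss_faint_psr`` models annotation-by-eye on poorly stained slides:
    the fainter a slide's PSR signal (saturation relative to unfaded
    scar), the likelier a PSR stroke is labelled TISSUE instead — faint
    septa simply are not seen.  ``core_margin_px=0`` with more patches and
    ``miss_faint_psr=False`` emulates the closer scrutiny of problem
    slides during targeted retraining.
    """
    from scipy.ndimage import binary_erosion

    regions = []
    for set_label in set_labels:
        for case_id in cases if cases is not None else study.cases:
            lab = study.labels[(case_id, set_label)]
            rng = np.random.default_rng(
                _spawn_seed(seed, "annot", case_id, set_label, n_per_class)
            )
            p_miss = 0.0
            if miss_faint_psr:
                p_miss = _psr_miss_probability(
                    study.images[(case_id, set_label)], lab
                )
            for cls in PixelClass:
                mask = lab == int(cls)
                if core_margin_px > 0:
                    core = binary_erosion(mask, iterations=core_margin_px)
                    if core.any():
                        mask = core
                idx = np.flatnonzero(mask)
                if idx.size == 0:
                    continue
                if n_patches > 0:
                    centers = rng.choice(idx, size=min(n_patches, idx.size), replace=False)
                    cy, cx = np.unravel_index(centers, lab.shape)
                    yy, xx = np.unravel_index(idx, lab.shape)
                    near = np.zeros(idx.shape, dtype=bool)
                    for py, px in zip(cy, cx):
                        near |= (np.abs(yy - py) <= patch_radius) & (
                            np.abs(xx - px) <= patch_radius
                        )
                    idx = idx[near]
                picks = rng.choice(idx, size=min(n_per_class, idx.size), replace=False)
                coords = np.column_stack(np.unravel_index(picks, lab.shape))
                label_as = cls
                if cls == PixelClass.PSR and rng.random() < p_miss:
                    label_as = PixelClass.TISSUE  # faint scar read as tissue
                regions.append(
                    pcmod.LabelledRegion(
                        tile_id=study.tile_id(case_id, set_label),
                        coords=coords,
                        pixel_class=label_as,
                        stain_set=set_label,
                        case_id=case_id,
                        annotator="synthetic",
                    )
                )
    return regions


def _psr_miss_probability(img: np.ndarray, lab: np.ndarray) -> float:
    """How likely a by-eye annotator is to overlook a slide's PSR signal.

    Visibility is the mean saturation of the slide's PSR pixels relative to
    a well-stained scar (the default palette's 0.85); the miss probability
    rises linearly as visibility falls, capped at about a third of strokes
    — even on a badly faded slide a trained observer still finds most of
    the scar.
    """
    from scipy.ndimage import binary_erosion

    psr = lab == int(PixelClass.PSR)
    if not psr.any():
        return 0.0
    # judge visibility on the septal cores: boundary pixels are blur-mixed
    # and would understate the scar signal the annotator actually sees
    core = binary_erosion(psr, iterations=2)
    if core.any():
        psr = core
    sat = hsbmod.rgb_to_hsv_raster(img)[..., 1]
    visibility = float(sat[psr].mean()) / 0.85
    return float(np.clip(1.0 - visibility, 0.0, 0.35))


def _score_with_model(
    study: StudyData,
    clf: pcmod.TrainedClassifier,
    features: Mapping[str, pcmod.FeatureStack],
    method_label: str,
    set_labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    rows = []
    for (case_id, set_label), group in study.manifest.groupby(
        ["case_id", "stain_set"], sort=False
    ):
        if set_labels is not None and set_label not in set_labels:
            continue
        _, total = pcmod.segment_tile(
            clf,
            study.images[(case_id, set_label)],
            features[study.tile_id(case_id, set_label)],
        )
        rows.append(
            {
                "case_id": case_id,
                "stain_set": set_label,
                "method": method_label,
                "psr_percent": pcmod.psr_positivity(total),
            }
        )
    return pd.DataFrame(rows)


def score_pixel_classifiers(
    study: StudyData,
    seed: int,
    n_per_class: int = 60,
    n_trees: int = 100,
    radii: Sequence[int] = pcmod.DEFAULT_RADII,
    divergence_factor: float = 2.0,
    retrain_n_per_class: int = 120,
    laboratory_of: Mapping[str, str] | None = None,
    features: dict[str, pcmod.FeatureStack] | None = None,
) -> pd.DataFrame:
    """Score the study under all three classifier regimes.

    ``PIXCLF_i``: one classifier per stain set, trained and applied within
    that set.  ``PIXCLF_c1``: one classifier trained on annotations from all
    sets.  ``PIXCLF_c2``: the combined classifier further trained on cases
    flagged by the strict >``divergence_factor`` inter-laboratory rule
    applied to the combined classifier's own scores.
    """
    laboratory_of = dict(laboratory_of or DEFAULT_LABORATORY_OF)
    if features is None:
        features = compute_study_features(study, radii)
    set_labels = study.stain_sets

    frames = []
    # per-set regime
    for set_label in set_labels:
        regions = sample_annotations(study, [set_label], n_per_class, seed)
        table = pcmod.balance_classes(
            pcmod.collect_training(regions, features),
            seed=_spawn_seed(seed, "balance", set_label),
        )
        clf = pcmod.train(
            table,
            n_trees=n_trees,
            seed=_spawn_seed(seed, "train_i", set_label),
            regime="per_set",
            radii=radii,
        )
        frames.append(
            _score_with_model(study, clf, features, "PIXCLF_i", set_labels=[set_label])
        )

    # combined regime
    regions_c = sample_annotations(study, set_labels, n_per_class, seed)
    table_c = pcmod.balance_classes(
        pcmod.collect_training(regions_c, features), seed=_spawn_seed(seed, "balance_c")
    )
    clf_c = pcmod.train(
        table_c,
        n_trees=n_trees,
        seed=_spawn_seed(seed, "train_c"),
        regime="combined",
        radii=radii,
    )
    scores_c = _score_with_model(study, clf_c, features, "PIXCLF_c1")
    frames.append(scores_c)

    # divergence-targeted retraining
    pairs = statsmod.build_stain_pairs(set_labels, laboratory_of)
    inter_pairs = [p for p, kind in pairs if kind == "inter"]
    divergent = pcmod.select_divergent_cases(scores_c, inter_pairs, divergence_factor)
    if divergent:
        extra = sample_annotations(
            study, set_labels, retrain_n_per_class,
            _spawn_seed(seed, "annot_extra"), cases=divergent,
            core_margin_px=0, n_patches=6, miss_faint_psr=False,
        )
        clf_c2 = pcmod.retrain_with_divergent(
            clf_c, extra, features, seed=_spawn_seed(seed, "train_c2")
        )
    else:  # nothing flagged: the combined classifier stands
        logger.info("no divergent cases flagged; PIXCLF_c2 equals PIXCLF_c1")
        clf_c2 = clf_c
    frames.append(
        _score_with_model(study, clf_c2, features, "PIXCLF_c2")
    )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# full study + analysis

def run_full_study(
    design: StudyDesign,
    out_dir: str | Path,
    hsb_calibration_set: str = "E1",
    hsb_calibration_pixels: int = 200,
    n_per_class: int = 60,
    n_trees: int = 100,
) -> pd.DataFrame:
    """Simulate, calibrate, and score a study with every method (cmd_score).

    Returns the complete slide-score table; also writes ``scores.csv`` in
    the study directory.
    """
    study = simulate_study(design, out_dir)
    seed = design.master_seed
    pix = calibration_pixels(
        study, hsb_calibration_set, hsb_calibration_pixels, _spawn_seed(seed, "calib")
    )
    # representative calibration tiles: the iterate-by-eye loop checks the
    # thresholded scores against the calibrator's perceived scar fractions
    score_tiles = [
        (
            study.images[(case_id, hsb_calibration_set)],
            study.labels[(case_id, hsb_calibration_set)] != int(PixelClass.SPACE),
            100.0
            * np.count_nonzero(
                study.labels[(case_id, hsb_calibration_set)] == int(PixelClass.PSR)
            )
            / max(
                np.count_nonzero(
                    study.labels[(case_id, hsb_calibration_set)] != int(PixelClass.SPACE)
                ),
                1,
            ),
        )
        for case_id in study.cases[:8]
    ]
    threshold, acc = hsbmod.calibrate_thresholds(pix, score_tiles=score_tiles)
    logger.info("HSB calibration balanced accuracy on %s: %.3f", hsb_calibration_set, acc)
    scores = pd.concat(
        [
            score_hsb(study, threshold),
            score_pixel_classifiers(study, seed=seed, n_per_class=n_per_class, n_trees=n_trees),
            score_ground_truth(study),
            reference_scores(study),
        ],
        ignore_index=True,
    )
    statsmod.write_score_table(scores, Path(out_dir) / "scores.csv")
    return scores


def analyze_scores(
    scores: pd.DataFrame,
    laboratory_of: Mapping[str, str] | None = None,
    reference_method: str = "REF_SHG",
    reference_stain_set: str = "E1",
    methods: Sequence[str] | None = None,
) -> statsmod.ConsistencyReport:
    """Consistency report across stain-set pairs for each method (cmd_analyze)."""
    laboratory_of = dict(laboratory_of or DEFAULT_LABORATORY_OF)
    stained = scores[scores["method"] != reference_method]
    set_labels = [s for s in pd.unique(stained["stain_set"]) if s in laboratory_of]
    pairs = statsmod.build_stain_pairs(set_labels, laboratory_of)
    if methods is None:
        methods = [m for m in pd.unique(stained["method"])]
    report = statsmod.ConsistencyReport(
        reference_method=reference_method, reference_stain_set=reference_stain_set
    )
    for method in methods:
        report.methods[method] = statsmod.method_consistency(scores, method, pairs)
        if reference_method in scores["method"].values:
            try:
                report.reference_correlations[method] = statsmod.reference_correlation(
                    scores, method, reference_method, reference_stain_set
                )
            except statsmod.UndefinedCorrelationError:
                report.reference_correlations[method] = None
    return report
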