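"""Fixed HSB colour-space thresholding — the simple computational comparator.

Two threshold rules, one for PSR-positive pixels and one for total tissue,
are applied in HSB (hue-saturation-brightness) space.  The PSR hue interval
is circular because picrosirius red sits astride 0 deg.  A single threshold
set is applied to every stain set of a study; its sensitivity to staining
drift is exactly the failure mode under study.  Threshold calibration, done
by eye in practice, is recast here as a deterministic grid search maximising
balanced PSR/TISSUE pixel accuracy on labelled calibration pixels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np
from matplotlib.colors import rgb_to_hsv

from psrquant.synth import PixelClass
from psrquant.tiles import TileImage, TissueMask


class NoTissueError(ValueError):
    """Scar percentage requested on a slide with no countable tissue."""


def rgb_to_hsb(pixel: Sequence[float]) -> tuple[float, float, float]:
    """Standard hexcone RGB -> (hue deg in [0, 360), saturation, brightness).

    Brightness is max-channel / 255; achromatic pixels get hue 0.
    """
    arr = np.asarray(pixel, dtype=float)
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("channel values must be in [0, 255]")
    h, s, v = rgb_to_hsv(arr / 255.0)
    return float(h) * 360.0, float(s), float(v)


def rgb_to_hsv_raster(img: np.ndarray) -> np.ndarray:
    """Vectorised hexcone conversion of an 8-bit H x W x 3 raster (hue in [0, 1))."""
    return rgb_to_hsv(np.asarray(img, dtype=float) / 255.0)


def _hue_in(hue: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Circular hue interval membership; lo > hi means the interval wraps 360 -> 0."""
    if lo <= hi:
        return (hue >= lo) & (hue <= hi)
    return (hue >= lo) | (hue <= hi)


@dataclass(frozen=True)
class HSBThreshold:
    """PSR and TISSUE box rules in HSB space, PSR tested first.

    Each rule is (hue_lo, hue_hi) in degrees (wrapping allowed for PSR),
    (sat_lo, sat_hi) and (bri_lo, bri_hi) in [0, 1].
    """

    psr_hue: tuple[float, float] = (330.0, 25.0)
    psr_sat: tuple[float, float] = (0.25, 1.0)
    psr_bri: tuple[float, float] = (0.15, 1.0)
    tissue_hue: tuple[float, float] = (0.0, 360.0)
    tissue_sat: tuple[float, float] = (0.05, 1.0)
    tissue_bri: tuple[float, float] = (0.05, 0.98)

    def classify(self, hsv: np.ndarray) -> np.ndarray:
        """Class codes (PSR / TISSUE / -1 for OTHER) for an H x W x 3 HSB array."""
        hue = hsv[..., 0] * 360.0
        sat = hsv[..., 1]
        bri = hsv[..., 2]
        is_psr = (
            _hue_in(hue, *self.psr_hue)
            & (sat >= self.psr_sat[0])
            & (sat <= self.psr_sat[1])
            & (bri >= self.psr_bri[0])
            & (bri <= self.psr_bri[1])
        )
        is_tissue = (
            _hue_in(hue, *self.tissue_hue)
            & (sat >= self.tissue_sat[0])
            & (sat <= self.tissue_sat[1])
            & (bri >= self.tissue_bri[0])
            & (bri <= self.tissue_bri[1])
        )
        out = np.full(hue.shape, -1, dtype=np.int8)
        out[is_tissue] = int(PixelClass.TISSUE)
        out[is_psr] = int(PixelClass.PSR)  # PSR precedence
        return out


@dataclass(frozen=True)
class ClassCounts:
    """Pixel tallies within the tissue mask, the input of every scar formula."""

    counts: Mapping[int, int]
    total_masked: int = field(default=-1)

    def __post_init__(self) -> None:
        total = int(sum(self.counts.values()))
        if self.total_masked < 0:
            object.__setattr__(self, "total_masked", total)
        elif total != self.total_masked:
            raise ValueError("counts must sum to total_masked")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("counts must be >= 0")

    def get(self, cls: int) -> int:
        return int(self.counts.get(int(cls), 0))

    def __add__(self, other: "ClassCounts") -> "ClassCounts":
        keys = set(self.counts) | set(other.counts)
        return ClassCounts({k: self.get(k) + other.get(k) for k in keys})


def classify_hsb(tile: TileImage, mask: TissueMask, thr: HSBThreshold) -> ClassCounts:
    """Count PSR / TISSUE / OTHER pixels of a tile within its tissue mask."""
    if mask.mask_raster.shape != tile.pixel_raster.shape[:2]:
        raise ValueError("mask dimensions do not match tile")
    hsv = rgb_to_hsv(tile.pixel_raster.astype(float) / 255.0)
    classes = thr.classify(hsv)
    m = mask.mask_raster
    return ClassCounts(
        {
            int(PixelClass.PSR): int(np.count_nonzero((classes == PixelClass.PSR) & m)),
            int(PixelClass.TISSUE): int(
                np.count_nonzero((classes == PixelClass.TISSUE) & m)
            ),
            -1: int(np.count_nonzero((classes == -1) & m)),
        }
    )


def hsb_scar_percent(counts: ClassCounts) -> float:
    """100 x PSR / (PSR + TISSUE).

    The denominator is the two HSB classes only; pixels matching neither
    rule (OTHER) are excluded as unmasked artefacts.
    """
    psr = counts.get(PixelClass.PSR)
    tissue = counts.get(PixelClass.TISSUE)
    if psr + tissue == 0:
        raise NoTissueError("no PSR or tissue pixels: scar percentage undefined")
    return 100.0 * psr / (psr + tissue)


def calibrate_thresholds(
    labelled_pixels: Iterable[tuple[tuple[float, float, float], int]],
    hue_step: float = 5.0,
    sat_step: float = 0.05,
    score_tiles: Sequence[tuple[np.ndarray, np.ndarray, float]] | None = None,
) -> tuple[HSBThreshold, float]:
    """Grid-search an HSBThreshold on labelled (HSB triplet, class) pixels.

    Searches PSR hue-interval centre/half-width on a ``hue_step`` grid over
    the red band and the PSR saturation floor on a ``sat_step`` grid,
    maximising balanced PSR/TISSUE accuracy under the PSR-first precedence
    rule; ties break toward the wider PSR hue interval, then toward the
    interval centred on the labelled PSR hues.  Returns the best threshold
    and its achieved balanced accuracy.

    ``score_tiles`` — optional (rgb_image, tissue_mask, true_percent)
    triplets of representative calibration tiles.  When given, a second
    stage emulates the iterate-on-representative-tiles loop: among the
    candidates within 0.02 balanced accuracy of the best, the threshold
    whose slide scores deviate least (median absolute error) from the
    calibration tiles' scar percentages is selected.
    """
    data = list(labelled_pixels)
    classes = {c for _, c in data}
    if not {int(PixelClass.PSR), int(PixelClass.TISSUE)} <= classes:
        raise ValueError("calibration needs both PSR and TISSUE labelled pixels")

    hsb = np.array([p for p, _ in data], dtype=float)
    y = np.array([c for _, c in data], dtype=int)
    hue, sat, bri = hsb[:, 0], hsb[:, 1], hsb[:, 2]
    is_psr = y == int(PixelClass.PSR)
    is_tis = y == int(PixelClass.TISSUE)

    if np.ptp(hsb[is_psr | is_tis], axis=0).max() == 0:
        warnings.warn("PSR and TISSUE pixels are indistinguishable; accuracy 0.5")
        return HSBThreshold(), 0.5

    # candidate intervals stay within a plausible red band: picrosirius red
    # hues straddle 0 deg, so centres span +-40 deg and half-widths are
    # capped at 20 deg (PSR red spans roughly 345-15 deg; a wider "red"
    # interval would take in pink-orange hues no calibrator would accept
    # by eye)
    centres = np.arange(-40.0, 40.0 + 1e-9, hue_step)
    widths = np.arange(hue_step, 20.0 + 1e-9, hue_step)
    sat_floors = np.arange(0.0, 0.85 + 1e-9, sat_step)

    # circular mean of the labelled PSR hues: remaining ties resolve toward
    # the interval centred on the positive pixels, as a by-eye calibrator
    # would place it
    psr_rad = np.deg2rad(hue[is_psr])
    psr_centre = float(np.rad2deg(np.arctan2(np.sin(psr_rad).mean(), np.cos(psr_rad).mean())))

    def centre_distance(c: float) -> float:
        d = abs(c - psr_centre) % 360.0
        return min(d, 360.0 - d)

    candidates = []
    for centre, width, sfloor in product(centres, widths, sat_floors):
        lo = (centre - width) % 360.0
        hi = (centre + width) % 360.0
        pred_psr = _hue_in(hue, lo, hi) & (sat >= sfloor)
        recall_psr = float(np.mean(pred_psr[is_psr])) if is_psr.any() else 0.0
        recall_tis = float(np.mean(~pred_psr[is_tis])) if is_tis.any() else 0.0
        acc = 0.5 * (recall_psr + recall_tis)
        # wider hue interval wins ties, then proximity to the PSR hue centre
        key = (acc, width, -centre_distance(centre))
        candidates.append((key, (lo, hi, sfloor)))
    candidates.sort(key=lambda c: c[0], reverse=True)

    def build(lo: float, hi: float, sfloor: float) -> HSBThreshold:
        return HSBThreshold(
            psr_hue=(lo, hi),
            psr_sat=(float(sfloor), 1.0),
            psr_bri=(0.05, 1.0),
            tissue_sat=(0.0, 1.0),
            tissue_bri=(0.0, 0.995),
        )

    (best_acc, _, _), params = candidates[0]
    if score_tiles:
        tier = [c for c in candidates if c[0][0] >= best_acc - 0.02][:200]
        hsvs = [rgb_to_hsv_raster(img) for img, _, _ in score_tiles]
        best_err = None
        for (acc_c, _, _), (lo, hi, sfloor) in tier:
            thr_c = build(lo, hi, sfloor)
            errs = []
            for hsv_img, (_, mask, true_pct) in zip(hsvs, score_tiles):
                classes = thr_c.classify(hsv_img)
                psr = int(np.count_nonzero((classes == PixelClass.PSR) & mask))
                tis = int(np.count_nonzero((classes == PixelClass.TISSUE) & mask))
                if psr + tis == 0:
                    errs.append(100.0)
                    continue
                errs.append(abs(100.0 * psr / (psr + tis) - true_pct))
            err = float(np.median(errs))
            if best_err is None or err < best_err:
                best_err, best_acc, params = err, acc_c, (lo, hi, sfloor)
    return build(*params), float(best_acc)
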