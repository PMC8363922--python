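"""Synthetic cirrhotic-section generator with an explicit staining-variation model.

Ground truth is a four-class label raster (SPACE / LUMEN / PSR / TISSUE):
a roughly elliptical tissue profile surrounded by empty SPACE, partitioned
into regenerative nodules by Voronoi tessellation, with PSR-positive fibrous
septa laid along nodule boundaries (plus a thin capsule at the tissue edge)
and vessel lumina carved into the septa as small ellipses.  Septum width is
found by bisection so the realized scar fraction of non-SPACE pixels hits a
requested target.

Staining is modelled as a per-class base palette pushed through an HSB-space
transform: hue rotation, saturation and brightness scaling, a PSR-specific
fade factor standing in for the section-age effect, and additive per-channel
Gaussian noise.  A study bundle renders serial sections of each case under
four stain-set transforms (two "laboratories" x two "batches", E1/E2/N1/N2;
optionally a fresh-section rN3 repeat) with small per-slide jitter around
each batch transform, emulating within-batch operator and reagent variation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from enum import IntEnum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from matplotlib.colors import hsv_to_rgb, rgb_to_hsv
from scipy import ndimage


class PixelClass(IntEnum):
    """The four annotation classes of the segmentation problem."""

    SPACE = 0
    LUMEN = 1
    PSR = 2
    TISSUE = 3


class TargetUnreachableError(RuntimeError):
    """A requested class-fraction target could not be realised."""


def _fractions(labels: np.ndarray) -> dict[PixelClass, float]:
    total = labels.size
    return {c: float(np.count_nonzero(labels == c)) / total for c in PixelClass}


@dataclass(frozen=True)
class GroundTruthTile:
    """Per-pixel class labels for one synthetic section.

    ``realized_fractions`` are fractions of *all* pixels and always agree
    with the raster; scar/lumen targets during generation are expressed as
    fractions of non-SPACE pixels (the analysable tissue footprint).
    """

    label_raster: np.ndarray  # uint8, values in PixelClass
    case_id: str
    section_index: int = 0
    realized_fractions: Mapping[PixelClass, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = np.asarray(self.label_raster)
        if labels.ndim != 2:
            raise ValueError("label raster must be 2-D")
        if not np.isin(labels, [int(c) for c in PixelClass]).all():
            raise ValueError("label raster contains codes outside the four classes")
        if not self.realized_fractions:
            object.__setattr__(self, "realized_fractions", _fractions(labels))
        else:
            expect = _fractions(labels)
            for c in PixelClass:
                if abs(self.realized_fractions.get(c, 0.0) - expect[c]) > 1e-9:
                    raise ValueError("realized_fractions disagree with label raster")

    @property
    def width(self) -> int:
        return self.label_raster.shape[1]

    @property
    def height(self) -> int:
        return self.label_raster.shape[0]

    def scar_fraction_of_tissue(self) -> float:
        """PSR fraction of non-SPACE pixels — the stain-free reference value."""
        labels = self.label_raster
        non_space = np.count_nonzero(labels != PixelClass.SPACE)
        if non_space == 0:
            raise ValueError("tile contains no tissue")
        return float(np.count_nonzero(labels == PixelClass.PSR)) / non_space

    def psr_positivity_percent(self) -> float:
        """100 x PSR / (PSR + TISSUE + LUMEN), the scar-percentage readout."""
        return 100.0 * self.scar_fraction_of_tissue()


@dataclass(frozen=True)
class StainPalette:
    """Base 8-bit RGB appearance of each class under PSR staining."""

    colors: Mapping[PixelClass, tuple[int, int, int]]

    def __post_init__(self) -> None:
        missing = [c for c in PixelClass if c not in self.colors]
        if missing:
            raise ValueError(f"palette missing classes: {missing}")
        h, s, v = _rgb8_to_hsb(self.colors[PixelClass.PSR])
        if not (h <= 30.0 or h >= 330.0):
            raise ValueError("PSR base colour must have hue in the red band")
        _, _, v_space = _rgb8_to_hsb(self.colors[PixelClass.SPACE])
        if v_space < 0.95:
            raise ValueError("SPACE base colour must be near-white (brightness >= 0.95)")

    @classmethod
    def default(cls) -> "StainPalette":
        return cls(
            {
                PixelClass.PSR: (200, 30, 60),
                PixelClass.TISSUE: (230, 190, 120),
                # pale tan, distinct from the white SPACE background so the
                # brightness/saturation tissue mask keeps lumen pixels
                PixelClass.LUMEN: (235, 225, 200),
                PixelClass.SPACE: (255, 255, 255),
            }
        )


@dataclass(frozen=True)
class StainTransform:
    """One laboratory x batch staining condition in HSB space.

    ``fade_factor`` multiplies the saturation of PSR-class pixels only,
    modelling loss of stainability with section age.  The identity
    transform is ``(0, 1, 1, 1, 0)``.
    """

    hue_shift_deg: float = 0.0
    saturation_scale: float = 1.0
    brightness_scale: float = 1.0
    fade_factor: float = 1.0
    noise_sd: float = 0.0
    texture_sd: float = 0.0
    blur_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.saturation_scale < 0 or self.brightness_scale < 0:
            raise ValueError("scales must be >= 0")
        if not 0.0 <= self.fade_factor <= 1.0:
            raise ValueError("fade_factor must be in [0, 1]")
        if self.noise_sd < 0 or self.texture_sd < 0 or self.blur_sigma < 0:
            raise ValueError("noise_sd, texture_sd and blur_sigma must be >= 0")

    @classmethod
    def identity(cls) -> "StainTransform":
        return cls()

    def compose(self, other: "StainTransform") -> "StainTransform":
        """Apply ``other`` on top of this transform.

        Hue shifts add (mod 360), scales and fade multiply, noise standard
        deviations add in quadrature; composing with the identity leaves a
        transform unchanged.
        """
        return StainTransform(
            hue_shift_deg=(self.hue_shift_deg + other.hue_shift_deg) % 360.0,
            saturation_scale=self.saturation_scale * other.saturation_scale,
            brightness_scale=self.brightness_scale * other.brightness_scale,
            fade_factor=self.fade_factor * other.fade_factor,
            noise_sd=float(np.hypot(self.noise_sd, other.noise_sd)),
            texture_sd=float(np.hypot(self.texture_sd, other.texture_sd)),
            blur_sigma=float(np.hypot(self.blur_sigma, other.blur_sigma)),
        )


#: Default batch transforms for the four-set study analogue.  E1 is the
#: calibration set (no batch shift beyond sensor noise and the shared
#: within-section stain texture / optical blur); the others differ by hue
#: rotation, saturation/brightness scaling and section-age fade.
#: The laboratory effect lives mainly in hue (different reagent lots and
#: protocols: Edinburgh near 0 deg, Nottingham rotated ~-15 deg); the batch
#: effect within a laboratory is a smaller hue drift plus saturation loss
#: and section-age fade (second batches stained 6 months later on sections
#: cut at study start).  Same-laboratory sets are therefore more alike than
#: cross-laboratory sets.
#: All first-round sections were cut at study start, so even first-batch
#: sections carry some age-related fade by staining time (N1 slightly more
#: than E1); second batches, stained six months later on sections from the
#: same cutting, fade further.
DEFAULT_STAIN_SETS: dict[str, StainTransform] = {
    "E1": StainTransform(0.0, 1.0, 1.0, 1.0, noise_sd=4.0, texture_sd=0.35, blur_sigma=1.0),
    "E2": StainTransform(4.0, 0.9, 1.05, 0.85, noise_sd=4.0, texture_sd=0.35, blur_sigma=1.0),
    "N1": StainTransform(-15.0 % 360, 1.1, 0.95, 0.95, noise_sd=4.0, texture_sd=0.35, blur_sigma=1.0),
    "N2": StainTransform(-19.0 % 360, 0.8, 1.05, 0.75, noise_sd=4.0, texture_sd=0.35, blur_sigma=1.0),
}

#: Fresh-section repeat in the Nottingham laboratory: N1's protocol without
#: any section-age fade.
RN3_TRANSFORM = StainTransform(
    -15.0 % 360, 1.1, 0.95, 1.0, noise_sd=4.0, texture_sd=0.35, blur_sigma=1.0
)

#: Which laboratory produced each stain set (prefix letter).
DEFAULT_LABORATORY_OF: dict[str, str] = {
    "E1": "Edinburgh",
    "E2": "Edinburgh",
    "N1": "Nottingham",
    "N2": "Nottingham",
    "rN3": "Nottingham",
}


@dataclass(frozen=True)
class StudyDesign:
    """Layout of a synthetic multi-laboratory staining study.

    Per-slide staining jitter around each set's batch transform has two
    components.  The case x laboratory component (``case_lab_*_sd``) is
    shared by both batches of a laboratory for a given case: the same block
    stains similarly under the same protocol (tissue chemistry differs by
    case and aetiology, and each laboratory's protocol interacts with it
    consistently).  The independent per-slide component (``slide_*_sd``) is
    day-to-day staining variation.  Without slide-level jitter a batch
    shift distorts every case identically and rank correlations cannot
    degrade at all.
    """

    n_cases: int = 20
    sections_per_case: int = 4
    tile_size: int = 512
    scar_fraction_range: tuple[float, float] = (0.08, 0.40)
    lumen_fraction: float = 0.02
    stain_sets: Mapping[str, StainTransform] = field(
        default_factory=lambda: dict(DEFAULT_STAIN_SETS)
    )
    master_seed: int = 0
    jitter_px: float = 2.0
    slide_hue_jitter_sd: float = 2.5
    slide_saturation_jitter_sd: float = 0.05
    slide_brightness_jitter_sd: float = 0.03
    case_lab_hue_sd: float = 4.0
    case_lab_saturation_sd: float = 0.08
    case_lab_brightness_sd: float = 0.03
    laboratory_of: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_LABORATORY_OF)
    )
    n_nodules_range: tuple[int, int] = (8, 16)
    image_format: str = "tiff"

    def __post_init__(self) -> None:
        labels = list(self.stain_sets)
        if len(labels) != len(set(labels)):
            raise ValueError("stain set labels must be unique")
        if self.sections_per_case < len(labels):
            raise ValueError("sections_per_case must be >= number of stain sets")
        lo, hi = self.scar_fraction_range
        if not (0.0 < lo <= hi < 0.8):
            raise ValueError("scar_fraction_range must lie inside (0, 0.8)")


# ---------------------------------------------------------------------------
# colour helpers

def _rgb8_to_hsb(rgb: Sequence[float]) -> tuple[float, float, float]:
    h, s, v = rgb_to_hsv(np.asarray(rgb, dtype=float) / 255.0)
    return float(h) * 360.0, float(s), float(v)


def transformed_palette(
    palette: StainPalette, transform: StainTransform
) -> dict[PixelClass, np.ndarray]:
    """The noise-free 8-bit colour each class takes under a transform."""
    out: dict[PixelClass, np.ndarray] = {}
    for c in PixelClass:
        h, s, v = _rgb8_to_hsb(palette.colors[c])
        h = (h + transform.hue_shift_deg) % 360.0
        s = s * transform.saturation_scale
        if c == PixelClass.PSR:
            s = s * transform.fade_factor
        v = v * transform.brightness_scale
        s = min(max(s, 0.0), 1.0)
        v = min(max(v, 0.0), 1.0)
        rgb = hsv_to_rgb([h / 360.0, s, v]) * 255.0
        out[c] = np.round(rgb).astype(np.uint8)
    return out


# ---------------------------------------------------------------------------
# ground-truth generation

def _tissue_profile(rng: np.random.Generator, width: int, height: int) -> np.ndarray:
    """Irregular elliptical tissue footprint; outside is SPACE."""
    yy, xx = np.mgrid[0:height, 0:width]
    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
    theta = np.arctan2(yy - cy, xx - cx)
    # low-order harmonic modulation of the tissue boundary radius
    amp = 1.0
    for k in range(2, 6):
        a = rng.normal(0.0, 0.035)
        b = rng.normal(0.0, 0.035)
        amp = amp + a * np.cos(k * theta) + b * np.sin(k * theta)
    r = np.hypot((yy - cy) / (0.46 * height), (xx - cx) / (0.46 * width))
    return r <= amp


def generate_ground_truth(
    seed: int,
    width: int,
    height: int,
    scar_fraction_target: float,
    lumen_fraction_target: float,
    n_nodules: int,
    case_id: str = "case",
    tolerance: float = 0.02,
) -> GroundTruthTile:
    """Generate one cirrhosis-like labelled section.

    ``scar_fraction_target`` and ``lumen_fraction_target`` are fractions of
    non-SPACE pixels.  Septum width is bisected until the PSR fraction is
    within ``tolerance`` of target; vessel lumina are carved into septa as
    small ellipses until the lumen target is met.  Deterministic in all
    arguments.

    Raises
    ------
    TargetUnreachableError
        if a fraction target cannot be realised within the iteration cap.
    """
    if not (0.0 < scar_fraction_target < 0.8):
        raise ValueError("scar_fraction_target must be in (0, 0.8)")
    if n_nodules < 1:
        raise ValueError("n_nodules must be >= 1")
    if width < 64 or height < 64:
        raise ValueError("dimensions must be >= 64")

    rng = np.random.default_rng(seed)
    tissue = _tissue_profile(rng, width, height)
    n_tissue = int(tissue.sum())
    if n_tissue == 0:
        raise TargetUnreachableError("tissue footprint empty")

    yy, xx = np.mgrid[0:height, 0:width]
    pts = np.flatnonzero(tissue)
    centers = rng.choice(pts, size=min(n_nodules, pts.size), replace=False)
    cy, cx = np.unravel_index(centers, tissue.shape)
    # distances of every pixel to each nodule centre
    d = np.sqrt(
        (yy[..., None] - cy[None, None, :]) ** 2
        + (xx[..., None] - cx[None, None, :]) ** 2
    )
    if d.shape[-1] >= 2:
        part = np.partition(d, 1, axis=-1)
        boundary_gap = part[..., 1] - part[..., 0]  # small near Voronoi boundaries
    else:
        boundary_gap = np.full((height, width), np.inf)
    edge_dist = ndimage.distance_transform_edt(tissue)

    band_target = min(scar_fraction_target + lumen_fraction_target, 0.95)

    # a pixel joins the septal band when it is close to a Voronoi boundary
    # or to the tissue edge (capsule, half the septal width); one distance
    # key expresses both so band membership is monotone in the width t
    band_key = np.minimum(boundary_gap, 2.0 * edge_dist)
    band_key[~tissue] = np.inf
    goal = int(round(band_target * n_tissue))
    if np.isfinite(band_key).sum() < goal - tolerance * n_tissue:
        raise TargetUnreachableError(
            f"scar fraction target {scar_fraction_target} unreachable "
            f"(septal band cannot cover it)"
        )
    # the goal-th smallest key gives the exact band width; trimming to the
    # goal count breaks ties deterministically at pixel precision
    order = np.argsort(band_key, axis=None, kind="stable")
    band = np.zeros(tissue.shape, dtype=bool)
    band.ravel()[order[:goal]] = True
    band &= tissue

    labels = np.full((height, width), int(PixelClass.SPACE), dtype=np.uint8)
    labels[tissue] = int(PixelClass.TISSUE)
    labels[band] = int(PixelClass.PSR)

    # carve vessel lumina into the septal band
    lumen_goal = int(round(lumen_fraction_target * n_tissue))
    if lumen_goal > 0:
        band_idx = np.flatnonzero(band)
        lumen = np.zeros_like(band)
        for _ in range(2000):
            if int(lumen.sum()) >= lumen_goal:
                break
            if band_idx.size == 0:
                break
            c = rng.choice(band_idx)
            py, px = np.unravel_index(c, band.shape)
            ry = rng.uniform(1.5, 4.5)
            rx = rng.uniform(1.5, 4.5)
            ang = rng.uniform(0, np.pi)
            y0, y1 = max(0, int(py - 6)), min(height, int(py + 7))
            x0, x1 = max(0, int(px - 6)), min(width, int(px + 7))
            sy, sx = np.mgrid[y0:y1, x0:x1]
            dy, dx = sy - py, sx - px
            u = dy * np.cos(ang) + dx * np.sin(ang)
            v = -dy * np.sin(ang) + dx * np.cos(ang)
            ell = (u / ry) ** 2 + (v / rx) ** 2 <= 1.0
            patch = lumen[y0:y1, x0:x1]
            patch |= ell & band[y0:y1, x0:x1]
            lumen[y0:y1, x0:x1] = patch
        realized_lumen = int(lumen.sum()) / n_tissue
        if abs(realized_lumen - lumen_fraction_target) > tolerance:
            raise TargetUnreachableError(
                f"lumen fraction target {lumen_fraction_target} not met "
                f"(reached {realized_lumen:.4f})"
            )
        labels[lumen] = int(PixelClass.LUMEN)

    tile = GroundTruthTile(label_raster=labels, case_id=case_id, section_index=0)
    if abs(tile.scar_fraction_of_tissue() - scar_fraction_target) > tolerance:
        raise TargetUnreachableError(
            f"scar fraction target {scar_fraction_target} not met "
            f"(realized {tile.scar_fraction_of_tissue():.4f})"
        )
    return tile


def simulate_serial_sections(
    gt: GroundTruthTile,
    n_sections: int,
    seed: int,
    jitter_px: float = 2.0,
) -> list[GroundTruthTile]:
    """Serial sections of one block: near-identical copies of the parent.

    Each section is the parent raster warped by a smooth random displacement
    field of magnitude at most ``jitter_px`` plus sparse re-labelling noise
    on class boundaries.  Scar fractions stay within 0.01 of the parent.
    """
    if n_sections < 1:
        raise ValueError("n_sections must be >= 1")
    if jitter_px < 0:
        raise ValueError("jitter_px must be >= 0")

    parent = gt.label_raster
    h, w = parent.shape
    rng = np.random.default_rng(seed)
    out: list[GroundTruthTile] = []
    parent_frac = np.count_nonzero(parent == PixelClass.PSR) / parent.size
    for idx in range(n_sections):
        labels = parent
        if jitter_px > 0:
            for attempt in range(5):
                amp = jitter_px / (2**attempt)
                sigma = max(min(h, w) / 8.0, 4.0)
                dy = ndimage.gaussian_filter(rng.normal(size=(h, w)), sigma)
                dx = ndimage.gaussian_filter(rng.normal(size=(h, w)), sigma)
                mag = max(np.abs(dy).max(), np.abs(dx).max(), 1e-12)
                dy *= amp / mag
                dx *= amp / mag
                yy, xx = np.mgrid[0:h, 0:w]
                warped = ndimage.map_coordinates(
                    parent, [yy + dy, xx + dx], order=0, mode="nearest"
                )
                # boundary re-labelling noise: rarely copy a 4-neighbour's class
                shifted = np.roll(warped, 1, axis=rng.integers(0, 2))
                edge = warped != shifted
                flip = edge & (rng.random((h, w)) < 0.02)
                labels = np.where(flip, shifted, warped).astype(np.uint8)
                frac = np.count_nonzero(labels == PixelClass.PSR) / labels.size
                if abs(frac - parent_frac) < 0.01:
                    break
            else:  # pragma: no cover - amplitude halving always converges
                labels = parent
        out.append(
            GroundTruthTile(
                label_raster=np.ascontiguousarray(labels),
                case_id=gt.case_id,
                section_index=idx,
            )
        )
    return out


# ---------------------------------------------------------------------------
# rendering

def render(
    gt: GroundTruthTile,
    palette: StainPalette,
    transform: StainTransform,
    seed: int,
) -> np.ndarray:
    """Render a labelled section as an 8-bit RGB image under one stain condition.

    Per-class palette colours are moved through HSB space (hue rotation,
    saturation/brightness scaling, PSR fade).  ``texture_sd`` modulates the
    saturation (and, attenuated, the brightness) of tissue-bearing pixels by
    smooth log-normal random fields — uneven stain uptake within a section;
    ``blur_sigma`` applies optical blur, mixing colours along class
    boundaries.  Per-pixel Gaussian noise of ``noise_sd`` 8-bit units is
    added last.  With the identity transform and zero noise/texture/blur the
    palette colours are reproduced bit-exactly.  Deterministic given seed.
    """
    colors = transformed_palette(palette, transform)
    labels = gt.label_raster
    lut = np.zeros((len(PixelClass), 3), dtype=np.uint8)
    for c in PixelClass:
        lut[int(c)] = colors[c]
    img = lut[labels]
    rng = np.random.default_rng(seed)
    needs_float = transform.texture_sd > 0 or transform.blur_sigma > 0 or transform.noise_sd > 0
    if not needs_float:
        return img
    out = img.astype(np.float64)
    if transform.texture_sd > 0:
        hsv = rgb_to_hsv(out / 255.0)
        on_tissue = labels != int(PixelClass.SPACE)
        for plane, amp in ((1, transform.texture_sd), (2, 0.3 * transform.texture_sd)):
            field = ndimage.gaussian_filter(rng.normal(size=labels.shape), 12.0)
            sd = field.std()
            if sd > 0:
                field /= sd
            channel = hsv[..., plane]
            channel[on_tissue] = channel[on_tissue] * np.exp(amp * field[on_tissue])
            np.clip(channel, 0.0, 1.0, out=channel)
        out = hsv_to_rgb(hsv) * 255.0
    if transform.blur_sigma > 0:
        for ch in range(3):
            out[..., ch] = ndimage.gaussian_filter(out[..., ch], transform.blur_sigma)
    if transform.noise_sd > 0:
        out = out + rng.normal(0.0, transform.noise_sd, out.shape)
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# study bundle

def _spawn_seed(master_seed: int, *key: object) -> int:
    """Counter-free deterministic per-entity seed below 2**31."""
    digest = hashlib.sha256(
        json.dumps([master_seed, *map(str, key)]).encode()
    ).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _write_image(path: Path, img: np.ndarray, fmt: str) -> None:
    if fmt == "tiff":
        import tifffile

        tifffile.imwrite(path, img)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, img)


def make_study(
    design: StudyDesign,
    out_dir: str | Path,
    palette: StainPalette | None = None,
) -> pd.DataFrame:
    """Generate, render and write a full synthetic staining study.

    For each case one ground truth is generated, serial sections are cut,
    and one section per stain set is rendered under that set's batch
    transform composed with per-slide jitter.  Written artefacts:

    * ``tiles/<case>_<set>.{tif,png}`` — rendered sections
    * ``labels/<case>_<set>.png`` — class-coded label rasters
    * ``manifest.csv`` — case_id, stain_set, section_index, tile_path,
      label_path, scar_fraction
    * ``ground_truth.csv`` — case_id, scar_fraction, psr_percent (the
      stain-free SHG-analogue reference per case)

    Fully reproducible from ``design.master_seed``.  Returns the manifest.
    """
    palette = palette or StainPalette.default()
    out = Path(out_dir)
    (out / "tiles").mkdir(parents=True, exist_ok=True)
    (out / "labels").mkdir(parents=True, exist_ok=True)
    ext = "tif" if design.image_format == "tiff" else "png"

    records = []
    gt_records = []
    set_labels = list(design.stain_sets)
    for i in range(design.n_cases):
        case_id = f"case{i + 1:02d}"
        case_rng = np.random.default_rng(_spawn_seed(design.master_seed, "case", case_id))
        scar = float(case_rng.uniform(*design.scar_fraction_range))
        n_nod = int(case_rng.integers(design.n_nodules_range[0], design.n_nodules_range[1] + 1))
        gt = generate_ground_truth(
            seed=_spawn_seed(design.master_seed, "gt", case_id),
            width=design.tile_size,
            height=design.tile_size,
            scar_fraction_target=scar,
            lumen_fraction_target=design.lumen_fraction,
            n_nodules=n_nod,
            case_id=case_id,
        )
        sections = simulate_serial_sections(
            gt,
            n_sections=design.sections_per_case,
            seed=_spawn_seed(design.master_seed, "sections", case_id),
            jitter_px=design.jitter_px,
        )
        gt_records.append(
            {
                "case_id": case_id,
                "scar_fraction": gt.scar_fraction_of_tissue(),
                "psr_percent": gt.psr_positivity_percent(),
            }
        )
        for j, set_label in enumerate(set_labels):
            section = sections[j]
            # case x laboratory interaction: this block's tissue reacts to a
            # laboratory's protocol the same way in both of its batches
            lab = design.laboratory_of.get(set_label, set_label)
            lab_rng = np.random.default_rng(
                _spawn_seed(design.master_seed, "case_lab", case_id, lab)
            )
            lab_jitter = StainTransform(
                hue_shift_deg=float(lab_rng.normal(0.0, design.case_lab_hue_sd)) % 360.0,
                saturation_scale=float(
                    np.exp(lab_rng.normal(0.0, design.case_lab_saturation_sd))
                ),
                brightness_scale=float(
                    np.exp(lab_rng.normal(0.0, design.case_lab_brightness_sd))
                ),
            )
            slide_rng = np.random.default_rng(
                _spawn_seed(design.master_seed, "slide", case_id, set_label)
            )
            slide_jitter = StainTransform(
                hue_shift_deg=float(slide_rng.normal(0.0, design.slide_hue_jitter_sd)) % 360.0,
                saturation_scale=float(
                    np.exp(slide_rng.normal(0.0, design.slide_saturation_jitter_sd))
                ),
                brightness_scale=float(
                    np.exp(slide_rng.normal(0.0, design.slide_brightness_jitter_sd))
                ),
            )
            slide_transform = (
                design.stain_sets[set_label].compose(lab_jitter).compose(slide_jitter)
            )
            img = render(
                section,
                palette,
                slide_transform,
                seed=_spawn_seed(design.master_seed, "render", case_id, set_label),
            )
            tile_path = out / "tiles" / f"{case_id}_{set_label}.{ext}"
            label_path = out / "labels" / f"{case_id}_{set_label}.png"
            _write_image(tile_path, img, design.image_format)
            _write_image(label_path, section.label_raster, "png")
            records.append(
                {
                    "case_id": case_id,
                    "stain_set": set_label,
                    "section_index": section.section_index,
                    "tile_path": str(tile_path.relative_to(out)),
                    "label_path": str(label_path.relative_to(out)),
                    "scar_fraction": section.scar_fraction_of_tissue(),
                }
            )

    manifest = pd.DataFrame.from_records(records)
    manifest.to_csv(out / "manifest.csv", index=False)
    pd.DataFrame.from_records(gt_records).to_csv(out / "ground_truth.csv", index=False)
    return manifest
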