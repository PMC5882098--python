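"""Tissue masking and ROI sampling from slide images.

A slide enters as an 8-bit RGB raster with microns-per-pixel (mpp) metadata,
is optionally down-sampled to the analysis magnification (5x, i.e. 2 um/px
here), converted to a binary tissue mask by Otsu thresholding on luma, and
square regions of interest (ROIs) are then drawn at random from within the
mask, pairwise non-overlapping.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from PIL import Image
from skimage import morphology
from skimage.transform import resize

from .errors import CapacityError, DegenerateInputError, InvalidArgumentError

__all__ = [
    "SlideImage",
    "TissueMask",
    "RegionOfInterest",
    "downsample_to_target",
    "otsu_threshold",
    "compute_tissue_mask",
    "refine_mask",
    "sample_rois",
    "write_mask_png",
    "read_mask_png",
    "write_roi_manifest",
]

#: analysis magnification: 5x objective equivalent, 2.0 microns per pixel
ANALYSIS_MPP = 2.0

#: objects / holes smaller than this physical area are removed from the mask
MIN_OBJECT_MM2 = 0.1


@dataclass
class SlideImage:
    """8-bit RGB slide (or region) raster with physical pixel size."""

    pixels: np.ndarray
    mpp: float
    slide_id: str = "slide"

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise InvalidArgumentError("slide pixels must be an (H, W, 3) raster")
        if self.pixels.size == 0:
            raise InvalidArgumentError("slide raster is empty")
        if not self.mpp > 0:
            raise InvalidArgumentError(f"mpp must be positive, got {self.mpp}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class TissueMask:
    """Binary tissue mask congruent with its slide."""

    mask: np.ndarray
    threshold_used: int
    provenance: str = "otsu"  # "otsu" or "otsu+manual"

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


@dataclass
class RegionOfInterest:
    """Square tissue sub-image with provenance back to its slide."""

    patient_id: str
    roi_id: str
    row: int
    col: int
    side_px: int
    pixels: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.shape[:2] != (self.side_px, self.side_px):
            raise InvalidArgumentError("ROI raster does not match side_px")


def downsample_to_target(slide: SlideImage, target_mpp: float) -> SlideImage:
    """Down-sample a slide to a coarser microns-per-pixel by area averaging.

    Linear dimensions scale by ``slide.mpp / target_mpp``.  Integer factors
    use exact block averaging; non-integer factors fall back to an
    anti-aliased linear resampler.  Requesting the source resolution is a
    no-op; requesting a finer one (upsampling) is an error.
    """
    if target_mpp < slide.mpp:
        raise InvalidArgumentError(
            f"target mpp {target_mpp} finer than source {slide.mpp} (upsampling)"
        )
    if target_mpp == slide.mpp:
        return replace(slide, pixels=slide.pixels.copy())
    factor = target_mpp / slide.mpp
    h, w = slide.shape
    if abs(factor - round(factor)) < 1e-9:
        f = int(round(factor))
        ht, wt = (h // f) * f, (w // f) * f
        blocks = slide.pixels[:ht, :wt].astype(np.float64)
        blocks = blocks.reshape(ht // f, f, wt // f, f, 3).mean(axis=(1, 3))
        out = np.clip(np.rint(blocks), 0, 255).astype(np.uint8)
    else:
        ho, wo = max(1, int(round(h / factor))), max(1, int(round(w / factor)))
        out = resize(
            slide.pixels.astype(np.float64),
            (ho, wo, 3),
            order=1,
            anti_aliasing=True,
            preserve_range=True,
        )
        out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return SlideImage(out, target_mpp, slide.slide_id)


def _luma(rgb: np.ndarray) -> np.ndarray:
    r, g, b = rgb[..., 0].astype(np.float64), rgb[..., 1].astype(np.float64), rgb[..., 2].astype(np.float64)
    return np.clip(np.rint(0.299 * r + 0.587 * g + 0.114 * b), 0, 255).astype(np.uint8)


def otsu_threshold(gray: np.ndarray) -> int:
    """Otsu's threshold on an 8-bit image: the gray level t maximizing the
    between-class variance of {0..t} vs {t+1..255}; lowest level on ties.

    Foreground is then the darker side, ``gray <= t``.
    """
    hist = np.bincount(np.asarray(gray, dtype=np.uint8).ravel(), minlength=256).astype(np.float64)
    n = hist.sum()
    if n == 0:
        raise DegenerateInputError("empty image")
    p = hist / n
    omega = np.cumsum(p)  # omega[t] = P(class0) for threshold t
    mu = np.cumsum(p * np.arange(256))
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b = np.nan_to_num(sigma_b[:255], nan=-1.0, posinf=-1.0)
    if np.all(sigma_b <= 0):
        raise DegenerateInputError("no valid Otsu threshold (constant-intensity image)")
    return int(np.argmax(sigma_b))  # argmax returns the lowest maximizer


def compute_tissue_mask(slide: SlideImage) -> TissueMask:
    """Otsu-threshold the slide's luma and clean the resulting tissue mask.

    Tissue is the darker class (H&E tissue against a bright background).
    Objects and holes smaller than ``MIN_OBJECT_MM2`` at the slide's mpp are
    removed.  A constant-intensity slide has no valid threshold and raises
    :class:`DegenerateInputError`.
    """
    gray = _luma(slide.pixels)
    t = otsu_threshold(gray)
    mask = gray <= t
    min_px = max(1, int(round(MIN_OBJECT_MM2 * 1e6 / slide.mpp**2)))
    mask = morphology.remove_small_objects(mask, max_size=min_px - 1)
    mask = morphology.remove_small_holes(mask, max_size=min_px - 1)
    if not mask.any():
        raise DegenerateInputError("tissue mask empty after cleaning")
    return TissueMask(mask, threshold_used=t, provenance="otsu")


def refine_mask(
    mask: TissueMask,
    additions: np.ndarray | None = None,
    removals: np.ndarray | None = None,
) -> TissueMask:
    """Apply manual edit strokes: foreground = (mask OR additions) AND NOT removals.

    The original study refined the Otsu border by hand; here the manual step
    is an explicit edit layer so it is scriptable and reproducible.
    """
    out = mask.mask.copy()
    for layer, name in ((additions, "additions"), (removals, "removals")):
        if layer is not None and np.asarray(layer).shape != out.shape:
            raise InvalidArgumentError(f"{name} shape does not match mask")
    if additions is not None:
        out |= np.asarray(additions, dtype=bool)
    if removals is not None:
        out &= ~np.asarray(removals, dtype=bool)
    if not out.any():
        raise DegenerateInputError("refinement removed all foreground")
    return TissueMask(out, threshold_used=mask.threshold_used, provenance="otsu+manual")


def sample_rois(
    slide: SlideImage,
    mask: TissueMask,
    n: int = 11,
    side_px: int = 1250,
    min_tissue_fraction: float = 0.9,
    rng_seed: int = 0,
    max_attempts: int = 10_000,
    patient_id: str | None = None,
) -> list[RegionOfInterest]:
    """Draw ``n`` non-overlapping square ROIs from within the tissue mask.

    Positions are drawn by seeded rejection sampling: a candidate top-left
    corner is accepted if its square holds at least ``min_tissue_fraction``
    tissue pixels and does not intersect any previously accepted ROI.
    Raises :class:`CapacityError` (naming how many were placed) if ``n``
    ROIs cannot be placed within ``max_attempts`` draws.
    """
    if n < 1:
        raise InvalidArgumentError("n must be >= 1")
    h, w = slide.shape
    if side_px > min(h, w):
        raise InvalidArgumentError("side_px exceeds slide dimensions")
    if mask.mask.shape != (h, w):
        raise InvalidArgumentError("mask shape does not match slide")
    rng = np.random.default_rng(rng_seed)
    # summed-area table for O(1) tissue-fraction queries
    sat = np.zeros((h + 1, w + 1), dtype=np.int64)
    sat[1:, 1:] = np.cumsum(np.cumsum(mask.mask, axis=0), axis=1)
    pid = patient_id if patient_id is not None else slide.slide_id
    placed: list[tuple[int, int]] = []
    rois: list[RegionOfInterest] = []
    area = side_px * side_px
    for _ in range(max_attempts):
        if len(rois) == n:
            break
        r = int(rng.integers(0, h - side_px + 1))
        c = int(rng.integers(0, w - side_px + 1))
        tissue = sat[r + side_px, c + side_px] - sat[r, c + side_px] - sat[r + side_px, c] + sat[r, c]
        if tissue < min_tissue_fraction * area:
            continue
        if any(abs(r - r0) < side_px and abs(c - c0) < side_px for r0, c0 in placed):
            continue
        placed.append((r, c))
        rois.append(
            RegionOfInterest(
                patient_id=pid,
                roi_id=f"{slide.slide_id}_roi{len(rois):03d}",
                row=r,
                col=c,
                side_px=side_px,
                pixels=slide.pixels[r : r + side_px, c : c + side_px].copy(),
            )
        )
    if len(rois) < n:
        raise CapacityError(
            f"placed only {len(rois)} of {n} requested ROIs after {max_attempts} attempts",
            n_placed=len(rois),
        )
    return rois


def write_mask_png(mask: TissueMask, path: str | os.PathLike) -> None:
    Image.fromarray((mask.mask.astype(np.uint8)) * 255).save(path)


def read_mask_png(path: str | os.PathLike, threshold_used: int = 0, provenance: str = "otsu") -> TissueMask:
    arr = np.asarray(Image.open(path).convert("L"))
    return TissueMask(arr >= 128, threshold_used=threshold_used, provenance=provenance)


def write_roi_manifest(rois: list[RegionOfInterest], path: str | os.PathLike, slide_id: str, seed: int) -> None:
    pd.DataFrame(
        {
            "slide_id": slide_id,
            "roi_id": [r.roi_id for r in rois],
            "row": [r.row for r in rois],
            "col": [r.col for r in rois],
            "side_px": [r.side_px for r in rois],
            "seed": seed,
        }
    ).to_csv(path, index=False)
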