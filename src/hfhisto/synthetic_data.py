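"""Seeded synthetic H&E-like myocardium cohorts.

The generator renders the two tissue appearances the classification task
rests on, at 5x-equivalent resolution (2 um/px):

* **non-failing** — dense, regular arrays of cardiomyocyte fibers (eosin
  pink, oriented sinusoidal banding) with small, slender hematoxylin nuclei
  and stroma confined to perivascular cuffs;
* **failing** — expansion of pale collagen-rich stroma (fibrosis), loss of
  fiber-orientation coherence, and enlarged, darker ("boxcar") myocyte
  nuclei.

Failing tissue is drawn from two severity tiers (moderate / severe),
reflecting the spectrum of pathology seen across ischemic and non-ischemic
cardiomyopathy; "occult pathology" patients carry the non-failing clinical
label but severe-tier tissue.  Every generator is a pure function of its
arguments including the seed, so all fixtures are reproducible without any
stored image data.

This is a statistical texture model, not photorealistic H&E: it reproduces
the class-separating structure (stroma area fraction, nuclear size/darkness,
fiber coherence) and nothing else.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image
from scipy.ndimage import gaussian_filter, zoom

from .errors import InvalidArgumentError
from .slide_prep import RegionOfInterest, SlideImage

__all__ = [
    "TissueParams",
    "CohortSpec",
    "PatientRecord",
    "SyntheticCohort",
    "generate_tissue_image",
    "generate_slide",
    "generate_cohort",
    "generate_feature_clusters",
    "class_presets",
    "stroma_pixel_fraction",
    "background_pixel_fraction",
    "is_failing_label",
    "LABELS_V1",
    "LABELS_V2",
]

# ---------------------------------------------------------------------------
# palette (8-bit RGB); chosen so a brute-force brightness classifier separates
# the three tissue compartments: nuclei (dark) < myocyte (mid) < stroma (pale)
# < background (near-white)
MYOCYTE_BASE = np.array([198.0, 112.0, 148.0])
FIBER_AMP = np.array([26.0, 20.0, 16.0])
STROMA_BASE = np.array([242.0, 212.0, 226.0])
NUCLEUS_COLOR = np.array([76.0, 48.0, 118.0])
LUMEN_COLOR = np.array([247.0, 244.0, 248.0])
BACKGROUND_LEVEL = 246.0

#: mean-channel level above which a (tissue) pixel is counted as stroma
STROMA_MEAN_LEVEL = 200.0
#: luma level above which a slide pixel is counted as glass background
BACKGROUND_LUMA_LEVEL = 236.0

MYOCYTE_PERIOD_UM = 16.0  # cardiomyocyte fiber banding period

LABELS_V1 = {"failing": "failing", "non_failing": "non-failing"}
LABELS_V2 = {"failing": "abnormal or heart failure", "non_failing": "within normal limits"}

_FAILING_LABELS = {"failing", "abnormal or heart failure"}


def is_failing_label(label: str) -> bool:
    """True for the failing-class label under either label schema."""
    return label in _FAILING_LABELS


@dataclass(frozen=True)
class TissueParams:
    """Parameters of the tissue texture model.

    fibrosis_fraction : proportion of tissue area rendered as pale stroma
    nucleus_density   : nuclei per mm^2
    nucleus_scale     : >= 1; multiplies nuclear size and darkness
    fiber_disruption  : proportion of fiber-orientation coherence lost
    rng_seed          : rendering seed
    """

    fibrosis_fraction: float = 0.05
    nucleus_density: float = 600.0
    nucleus_scale: float = 1.0
    fiber_disruption: float = 0.10
    rng_seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.fibrosis_fraction <= 1.0:
            raise InvalidArgumentError("fibrosis_fraction must be in [0, 1]")
        if not 0.0 <= self.fiber_disruption <= 1.0:
            raise InvalidArgumentError("fiber_disruption must be in [0, 1]")
        if self.nucleus_scale < 1.0:
            raise InvalidArgumentError("nucleus_scale must be >= 1")
        if self.nucleus_density < 0:
            raise InvalidArgumentError("nucleus_density must be >= 0")


# class presets: non-failing anchor and the two failing severity tiers at
# full (strong) effect; weaker effect sizes shrink the failing deltas
_NONFAILING = dict(fibrosis_fraction=0.05, nucleus_density=600.0, nucleus_scale=1.0, fiber_disruption=0.10)
_SEVERE_FULL = dict(fibrosis_fraction=0.40, nucleus_density=520.0, nucleus_scale=1.90, fiber_disruption=0.60)
_MODERATE_FULL = dict(fibrosis_fraction=0.22, nucleus_density=560.0, nucleus_scale=1.45, fiber_disruption=0.35)
_EFFECT_SCALE = {"strong": 1.0, "moderate": 0.45, "weak": 0.18}


def class_presets(effect_size: str = "strong") -> dict[str, TissueParams]:
    """Tissue presets for the two classes at a given class separation.

    Returns ``{"non_failing": ..., "failing_moderate": ..., "failing_severe": ...}``.
    ``effect_size`` scales the failing tiers' parameter deltas from the
    non-failing anchor by 1.0 / 0.45 / 0.18 (strong / moderate / weak).
    """
    if effect_size not in _EFFECT_SCALE:
        raise InvalidArgumentError(f"effect_size must be one of {sorted(_EFFECT_SCALE)}")
    s = _EFFECT_SCALE[effect_size]

    def _blend(target: dict) -> TissueParams:
        kw = {k: _NONFAILING[k] + s * (target[k] - _NONFAILING[k]) for k in _NONFAILING}
        kw["nucleus_scale"] = max(1.0, kw["nucleus_scale"])
        return TissueParams(**kw)

    return {
        "non_failing": TissueParams(**_NONFAILING),
        "failing_moderate": _blend(_MODERATE_FULL),
        "failing_severe": _blend(_SEVERE_FULL),
    }


def stroma_pixel_fraction(pixels: np.ndarray) -> float:
    """Fraction of pixels matching the pale-stroma palette (mean channel
    above ``STROMA_MEAN_LEVEL``).  A brute-force color rule, usable as an
    independent check on the renderer's stroma calibration."""
    return float((np.asarray(pixels, dtype=np.float64).mean(axis=-1) > STROMA_MEAN_LEVEL).mean())


def background_pixel_fraction(pixels: np.ndarray) -> float:
    """Fraction of near-white (glass background) pixels by luma."""
    p = np.asarray(pixels, dtype=np.float64)
    luma = 0.299 * p[..., 0] + 0.587 * p[..., 1] + 0.114 * p[..., 2]
    return float((luma >= BACKGROUND_LUMA_LEVEL).mean())


def _smooth_field(rng: np.random.Generator, side: int, sigma_px: float) -> np.ndarray:
    # render at quarter resolution and bilinearly upsample: the field is
    # band-limited far below the Nyquist of the full grid, and this keeps
    # large-tile generation fast
    sub = 4 if side >= 512 else 1
    s = -(-side // sub)
    f = gaussian_filter(
        rng.standard_normal((s + 1, s + 1), dtype=np.float32), sigma=sigma_px / sub, mode="reflect"
    )
    sd = f.std()
    if sd > 0:
        f /= sd
    if sub == 1:
        return f[:side, :side]
    return zoom(f, sub, order=1, grid_mode=False)[:side, :side]


def _stamp_nuclei(
    img: np.ndarray,
    rng: np.random.Generator,
    params: TissueParams,
    mpp: float,
    theta0: float,
    orient_noise: np.ndarray,
) -> None:
    side = img.shape[0]
    area_mm2 = (side * mpp / 1000.0) ** 2
    n = int(rng.poisson(params.nucleus_density * area_mm2))
    if n == 0:
        return
    rows = rng.uniform(0, side, n)
    cols = rng.uniform(0, side, n)
    lengths = np.clip(rng.normal(9.0, 1.2, n), 5.0, 30.0) * params.nucleus_scale
    widths = np.clip(rng.normal(3.2, 0.5, n), 1.8, 10.0) * np.sqrt(params.nucleus_scale)
    jitter = rng.normal(0.0, 0.15, n)
    color = NUCLEUS_COLOR / params.nucleus_scale**0.35
    for i in range(n):
        r0, c0 = rows[i], cols[i]
        a = 0.5 * lengths[i] / mpp  # semi-major axis, px
        b = 0.5 * widths[i] / mpp
        th = theta0 + 1.2 * params.fiber_disruption * orient_noise[int(r0), int(c0)] + jitter[i]
        w = int(np.ceil(a)) + 1
        rlo, rhi = max(0, int(r0) - w), min(side, int(r0) + w + 1)
        clo, chi = max(0, int(c0) - w), min(side, int(c0) + w + 1)
        if rlo >= rhi or clo >= chi:
            continue
        dr = np.arange(rlo, rhi)[:, None] - r0
        dc = np.arange(clo, chi)[None, :] - c0
        u = (dc * np.cos(th) + dr * np.sin(th)) / a
        v = (-dc * np.sin(th) + dr * np.cos(th)) / max(b, 0.6)
        inside = u * u + v * v <= 1.0
        patch = img[rlo:rhi, clo:chi]
        patch[inside] = 0.12 * patch[inside] + 0.88 * color


def generate_tissue_image(params: TissueParams, side_px: int, mpp: float) -> np.ndarray:
    """Render a square tissue tile; pure function of (params, side_px, mpp).

    The stroma-class pixel fraction of the output approximates
    ``params.fibrosis_fraction`` (calibrated by adjusting the blob-noise
    threshold; a small deficit remains where nuclei overprint stroma).
    """
    if side_px < 128:
        raise InvalidArgumentError("side_px must be >= 128")
    if not mpp > 0:
        raise InvalidArgumentError("mpp must be positive")
    rng = np.random.default_rng([int(params.rng_seed) & 0x7FFFFFFF, side_px, int(round(mpp * 1000))])
    side = int(side_px)
    area_mm2 = (side * mpp / 1000.0) ** 2

    # oriented fiber banding with disruption-controlled phase warp
    theta0 = rng.uniform(0, np.pi)
    orient_noise = _smooth_field(rng, side, sigma_px=max(2.0, 30.0 / mpp))
    ax = np.arange(side, dtype=np.float32)
    period_px = MYOCYTE_PERIOD_UM / mpp
    phase = (2 * np.pi / period_px) * (
        ax[None, :] * np.float32(np.cos(theta0)) + ax[:, None] * np.float32(np.sin(theta0))
    )
    phase += np.float32(0.8 + 10.0 * params.fiber_disruption) * orient_noise
    fiber = np.sin(phase, out=phase)

    img = (
        MYOCYTE_BASE.astype(np.float32)[None, None, :]
        + fiber[:, :, None] * FIBER_AMP.astype(np.float32)[None, None, :]
    )
    img += 4.0 * rng.standard_normal(img.shape, dtype=np.float32)

    # perivascular stroma cuffs (always present) around small vessels
    peri = np.zeros((side, side), dtype=bool)
    lumen = np.zeros((side, side), dtype=bool)
    n_vessels = max(1, int(rng.poisson(1.2 * area_mm2)))
    for _ in range(n_vessels):
        r0, c0 = rng.uniform(0, side, 2)
        lumen_r = rng.uniform(8.0, 15.0) / mpp
        cuff_r = 2.2 * lumen_r
        w = int(np.ceil(cuff_r)) + 1
        rlo, rhi = max(0, int(r0) - w), min(side, int(r0) + w + 1)
        clo, chi = max(0, int(c0) - w), min(side, int(c0) + w + 1)
        dr = np.arange(rlo, rhi)[:, None] - r0
        dc = np.arange(clo, chi)[None, :] - c0
        d2 = dr * dr + dc * dc
        peri[rlo:rhi, clo:chi] |= d2 <= cuff_r**2
        lumen[rlo:rhi, clo:chi] |= d2 <= lumen_r**2

    # fibrosis blobs: threshold a smooth noise field, iteratively calibrated
    # so the stroma union hits fibrosis_fraction
    blob = _smooth_field(rng, side, sigma_px=max(2.0, 25.0 / mpp))
    stroma = peri.copy()
    target = params.fibrosis_fraction
    extra = target - stroma.mean()
    if extra > 0:
        for _ in range(6):
            tau = np.quantile(blob, max(0.0, 1.0 - extra))
            stroma = peri | (blob >= tau)
            err = target - stroma.mean()
            if abs(err) <= 0.01:
                break
            extra = float(np.clip(extra + err, 1e-4, 1.0))

    n_stroma = int(stroma.sum())
    if n_stroma:
        img[stroma] = STROMA_BASE.astype(np.float32)[None, :] + 5.0 * rng.standard_normal(
            (n_stroma, 3), dtype=np.float32
        )
    n_lumen = int(lumen.sum())
    if n_lumen:
        img[lumen] = LUMEN_COLOR.astype(np.float32)[None, :] + 2.0 * rng.standard_normal(
            (n_lumen, 3), dtype=np.float32
        )

    _stamp_nuclei(img, rng, params, mpp, theta0, orient_noise)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def generate_slide(
    params: TissueParams,
    canvas_px: int,
    tissue_extent_px: int,
    rng_seed: int,
    mpp: float = 2.0,
) -> SlideImage:
    """A near-white slide canvas bearing one connected tissue region of the
    requested extent, so Otsu masking and ROI sampling are exercisable."""
    if tissue_extent_px >= canvas_px:
        raise InvalidArgumentError("tissue_extent_px must be smaller than canvas_px")
    if tissue_extent_px < 128:
        raise InvalidArgumentError("tissue_extent_px must be >= 128")
    rng = np.random.default_rng([int(rng_seed) & 0x7FFFFFFF, canvas_px, tissue_extent_px])
    canvas = rng.normal(BACKGROUND_LEVEL, 2.5, (canvas_px, canvas_px, 3))

    # connected tissue blob: a circle of diameter tissue_extent_px with a
    # low-order Fourier wobble on its boundary (area-preserving on average)
    radius = tissue_extent_px / 2.0
    cr = cc = canvas_px / 2.0
    yy, xx = np.mgrid[0:canvas_px, 0:canvas_px].astype(np.float64)
    dr, dc = yy - cr, xx - cc
    ang = np.arctan2(dr, dc)
    wobble = np.zeros_like(ang)
    for k in range(2, 7):
        wobble += rng.normal(0.0, 0.03) * np.cos(k * ang + rng.uniform(0, 2 * np.pi))
    mask = np.hypot(dr, dc) <= radius * (1.0 + wobble)

    tex_params = replace(params, rng_seed=int(rng.integers(0, 2**31 - 1)))
    tex = generate_tissue_image(tex_params, canvas_px, mpp).astype(np.float64)
    canvas[mask] = tex[mask]
    pixels = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    return SlideImage(pixels, mpp=mpp, slide_id=f"synslide_{rng_seed}")


@dataclass(frozen=True)
class CohortSpec:
    """Study design of a synthetic cohort."""

    n_patients: int
    prop_failing: float = 0.5
    occult_fraction: float = 0.0
    rois_per_patient: int = 11
    roi_side_px: int = 1250
    mpp: float = 2.0
    effect_size: str = "strong"
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise InvalidArgumentError("n_patients must be >= 1")
        if not 0.0 <= self.prop_failing <= 1.0:
            raise InvalidArgumentError("prop_failing must be in [0, 1]")
        if not 0.0 <= self.occult_fraction <= 1.0:
            raise InvalidArgumentError("occult_fraction must be in [0, 1]")
        if self.rois_per_patient < 1:
            raise InvalidArgumentError("rois_per_patient must be >= 1")
        if self.effect_size not in _EFFECT_SCALE:
            raise InvalidArgumentError(f"effect_size must be one of {sorted(_EFFECT_SCALE)}")
        if not self.mpp > 0 or self.roi_side_px < 128:
            raise InvalidArgumentError("roi_side_px must be >= 128 and mpp positive")


@dataclass
class PatientRecord:
    """One synthetic patient: labels under both schemas plus render recipes."""

    patient_id: str
    label_v1: str
    label_v2: str
    occult: bool
    tier: str  # "non_failing" | "failing_moderate" | "failing_severe"
    params: TissueParams
    roi_params: tuple[TissueParams, ...] = field(repr=False, default=())

    def label(self, schema: str = "v1") -> str:
        if schema == "v1":
            return self.label_v1
        if schema == "v2":
            return self.label_v2
        raise InvalidArgumentError("schema must be 'v1' or 'v2'")


class SyntheticCohort:
    """A generated cohort; ROI rasters are rendered lazily and deterministically."""

    def __init__(self, spec: CohortSpec, patients: list[PatientRecord]):
        self.spec = spec
        self.patients = patients

    def __len__(self) -> int:
        return len(self.patients)

    def roi_image(self, patient: PatientRecord, k: int) -> np.ndarray:
        return generate_tissue_image(patient.roi_params[k], self.spec.roi_side_px, self.spec.mpp)

    def iter_rois(self, patient: PatientRecord):
        """Yield :class:`RegionOfInterest` objects for one patient (rendered)."""
        for k in range(self.spec.rois_per_patient):
            yield RegionOfInterest(
                patient_id=patient.patient_id,
                roi_id=f"{patient.patient_id}_roi{k:03d}",
                row=0,
                col=0,
                side_px=self.spec.roi_side_px,
                pixels=self.roi_image(patient, k),
            )

    def patient_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": [p.patient_id for p in self.patients],
                "label_v1": [p.label_v1 for p in self.patients],
                "label_v2": [p.label_v2 for p in self.patients],
                "occult": [p.occult for p in self.patients],
                "tier": [p.tier for p in self.patients],
            }
        )

    def write(self, outdir: str | os.PathLike, include_slides: bool = False) -> Path:
        """Write per-ROI PNGs, a cohort manifest CSV, and (optionally) a
        slide-level TIFF per patient with mpp metadata."""
        outdir = Path(outdir)
        (outdir / "rois").mkdir(parents=True, exist_ok=True)
        rows = []
        for p in self.patients:
            paths = []
            for k in range(self.spec.rois_per_patient):
                rel = f"rois/{p.patient_id}_roi{k:03d}.png"
                Image.fromarray(self.roi_image(p, k)).save(outdir / rel)
                paths.append(rel)
            if include_slides:
                slide = generate_slide(
                    p.params,
                    canvas_px=2 * self.spec.roi_side_px,
                    tissue_extent_px=int(1.5 * self.spec.roi_side_px),
                    rng_seed=p.params.rng_seed,
                    mpp=self.spec.mpp,
                )
                tifffile.imwrite(
                    outdir / f"{p.patient_id}_slide.tif",
                    slide.pixels,
                    resolution=(1e4 / self.spec.mpp, 1e4 / self.spec.mpp),
                    resolutionunit="CENTIMETER",
                )
            rows.append(
                {
                    "patient_id": p.patient_id,
                    "label_v1": p.label_v1,
                    "label_v2": p.label_v2,
                    "occult": p.occult,
                    "tier": p.tier,
                    "roi_paths": ";".join(paths),
                    "seed": self.spec.rng_seed,
                }
            )
        pd.DataFrame(rows).to_csv(outdir / "cohort_manifest.csv", index=False)
        return outdir


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a cohort with exact class counts and planted occult patients.

    ``round(n_patients * prop_failing)`` patients are failing (schema v1
    label "failing"); of the non-failing-labeled pool,
    ``round(occult_fraction * n_nonfailing)`` are occult: severe-tier tissue
    under a "non-failing" v1 label, relabeled to the failing class under
    schema v2.  Failing patients split evenly between the severe and
    moderate tiers.  Per-patient and per-ROI severity jitter (sd 0.03 on the
    stroma fraction) emulates biological and sampling variability.
    """
    rng = np.random.default_rng(spec.rng_seed)
    ss = np.random.SeedSequence(spec.rng_seed)
    n = spec.n_patients
    n_fail = int(np.floor(n * spec.prop_failing + 0.5))
    order = rng.permutation(n)
    fail_idx = set(order[:n_fail].tolist())
    nonfail_list = [i for i in range(n) if i not in fail_idx]
    n_occ = int(np.floor(len(nonfail_list) * spec.occult_fraction + 0.5))
    occ_idx = set(rng.choice(nonfail_list, size=n_occ, replace=False).tolist()) if n_occ else set()

    presets = class_presets(spec.effect_size)
    fail_list = sorted(fail_idx)
    tier_order = rng.permutation(len(fail_list))
    tier_of = {}
    for rank, j in enumerate(tier_order):
        tier_of[fail_list[j]] = "failing_severe" if rank < (len(fail_list) + 1) // 2 else "failing_moderate"

    patient_seeds = ss.spawn(n)
    patients: list[PatientRecord] = []
    for i in range(n):
        pid = f"P{i:03d}"
        failing = i in fail_idx
        occult = i in occ_idx
        if failing:
            tier = tier_of[i]
        elif occult:
            tier = "failing_severe"
        else:
            tier = "non_failing"
        base = presets[tier]
        prng = np.random.default_rng(patient_seeds[i])
        fib = float(np.clip(base.fibrosis_fraction + prng.normal(0.0, 0.03), 0.005, 0.9))
        nsc = float(max(1.0, base.nucleus_scale + prng.normal(0.0, 0.05)))
        dis = float(np.clip(base.fiber_disruption + prng.normal(0.0, 0.03), 0.0, 1.0))
        pat_params = replace(base, fibrosis_fraction=fib, nucleus_scale=nsc, fiber_disruption=dis,
                             rng_seed=int(prng.integers(0, 2**31 - 1)))
        roi_params = []
        for _ in range(spec.rois_per_patient):
            rfib = float(np.clip(fib + prng.normal(0.0, 0.03), 0.005, 0.9))
            roi_params.append(
                replace(pat_params, fibrosis_fraction=rfib, rng_seed=int(prng.integers(0, 2**31 - 1)))
            )
        label_key = "failing" if failing else "non_failing"
        v2_key = "failing" if (failing or occult) else "non_failing"
        patients.append(
            PatientRecord(
                patient_id=pid,
                label_v1=LABELS_V1[label_key],
                label_v2=LABELS_V2[v2_key],
                occult=occult,
                tier=tier,
                params=pat_params,
                roi_params=tuple(roi_params),
            )
        )
    return SyntheticCohort(spec, patients)


def generate_feature_clusters(
    n_components: int,
    n_items_per_component: int,
    separation: float,
    n_features: int,
    rng_seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Spherical unit-variance Gaussian components with mutually equidistant
    centers (pairwise distance = ``separation``); a fixture for the
    consensus-clustering stage.  Returns (X, true component labels)."""
    if n_components < 1:
        raise InvalidArgumentError("n_components must be >= 1")
    if n_features < 2:
        raise InvalidArgumentError("n_features must be >= 2")
    if n_components > n_features:
        raise InvalidArgumentError("need n_components <= n_features for equidistant centers")
    if separation < 0:
        raise InvalidArgumentError("separation must be non-negative")
    rng = np.random.default_rng(rng_seed)
    centers = np.zeros((n_components, n_features))
    for i in range(n_components):
        centers[i, i] = separation / np.sqrt(2.0)  # |e_i - e_j| * sep/sqrt(2) = sep
    X = np.concatenate(
        [c + rng.standard_normal((n_items_per_component, n_features)) for c in centers]
    )
    labels = np.repeat(np.arange(n_components), n_items_per_component)
    return X, labels
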