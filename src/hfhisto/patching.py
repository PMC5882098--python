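"""Labeled 64x64 patch sampling from ROIs, with right-angle rotation augmentation.

Supervision is weak: every patch inherits the cohort label of the patient
its ROI came from.  Patch offsets are drawn uniformly with replacement, so
patches may overlap; augmentation is for training only.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from PIL import Image

from .errors import InvalidArgumentError, MissingLabelError
from .slide_prep import RegionOfInterest

__all__ = ["Patch", "PatchSet", "sample_patches", "augment_rotations", "assign_labels"]

PATCH_PX = 64  # 128x128 um at 2 um/px


@dataclass
class Patch:
    pixels: np.ndarray = field(repr=False)
    label: str
    patient_id: str
    roi_id: str
    offset: tuple[int, int]  # (row, col) within the source ROI
    orientation: int = 0  # degrees, one of {0, 90, 180, 270}

    def __post_init__(self):
        if self.pixels.shape[0] != self.pixels.shape[1]:
            raise InvalidArgumentError("patch raster must be square")
        if self.orientation not in (0, 90, 180, 270):
            raise InvalidArgumentError("orientation must be one of 0/90/180/270")


@dataclass
class PatchSet:
    patches: list[Patch]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.patches)

    def __iter__(self):
        return iter(self.patches)

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Stack to (N, S, S, 3) uint8 pixels and an (N,) label array."""
        if not self.patches:
            s = self.provenance.get("patch_px", PATCH_PX)
            return np.zeros((0, s, s, 3), dtype=np.uint8), np.zeros((0,), dtype=object)
        x = np.stack([p.pixels for p in self.patches])
        y = np.array([p.label for p in self.patches], dtype=object)
        return x, y

    def label_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for p in self.patches:
            counts[p.label] = counts.get(p.label, 0) + 1
        return counts


def sample_patches(
    roi: RegionOfInterest,
    label: str,
    n: int = 100,
    patch_px: int = PATCH_PX,
    rng_seed: int = 0,
) -> PatchSet:
    """Sample ``n`` patches at uniformly random offsets within one ROI.

    Offsets are independent draws (overlap allowed); all patches carry the
    given label and orientation 0.
    """
    if patch_px > roi.side_px:
        raise InvalidArgumentError("patch_px exceeds ROI side")
    if n < 0:
        raise InvalidArgumentError("n must be >= 0")
    rng = np.random.default_rng(rng_seed)
    hi = roi.side_px - patch_px + 1
    offs = rng.integers(0, hi, size=(n, 2))
    patches = [
        Patch(
            pixels=roi.pixels[r : r + patch_px, c : c + patch_px].copy(),
            label=label,
            patient_id=roi.patient_id,
            roi_id=roi.roi_id,
            offset=(int(r), int(c)),
        )
        for r, c in offs
    ]
    return PatchSet(
        patches,
        provenance={"roi_id": roi.roi_id, "n": n, "patch_px": patch_px, "rng_seed": rng_seed},
    )


def augment_rotations(patches: PatchSet) -> PatchSet:
    """Expand each patch into its four right-angle orientations (x4).

    Labels, provenance fields and per-label class balance are preserved
    exactly; the 0-degree copy is the original raster.
    """
    out: list[Patch] = []
    for p in patches:
        for k, deg in enumerate((0, 90, 180, 270)):
            out.append(
                Patch(
                    pixels=np.rot90(p.pixels, k=k).copy() if k else p.pixels,
                    label=p.label,
                    patient_id=p.patient_id,
                    roi_id=p.roi_id,
                    offset=p.offset,
                    orientation=deg,
                )
            )
    prov = dict(patches.provenance)
    prov["augmented"] = "rot90"
    return PatchSet(out, provenance=prov)


def assign_labels(patches: PatchSet, patient_table: pd.DataFrame, schema: str = "v1") -> PatchSet:
    """Relabel every patch with its patient's label under the given schema.

    ``patient_table`` must carry ``patient_id`` plus ``label_v1``/``label_v2``
    columns (a plain ``label`` column serves either schema).  Unknown
    patient ids raise :class:`MissingLabelError`.
    """
    col = f"label_{schema}"
    if col not in patient_table.columns:
        if "label" in patient_table.columns:
            col = "label"
        else:
            raise InvalidArgumentError(f"patient table lacks a {col!r} (or 'label') column")
    lut = dict(zip(patient_table["patient_id"], patient_table[col]))
    out: list[Patch] = []
    for p in patches:
        if p.patient_id not in lut:
            raise MissingLabelError(f"patient id {p.patient_id!r} not in patient table")
        out.append(
            Patch(
                pixels=p.pixels,
                label=str(lut[p.patient_id]),
                patient_id=p.patient_id,
                roi_id=p.roi_id,
                offset=p.offset,
                orientation=p.orientation,
            )
        )
    prov = dict(patches.provenance)
    prov["label_schema"] = schema
    return PatchSet(out, provenance=prov)


def write_patch_tiles(patches: PatchSet, outdir: str | os.PathLike) -> None:
    """Optional export: PNG tiles plus a sidecar CSV manifest."""
    os.makedirs(outdir, exist_ok=True)
    rows = []
    for i, p in enumerate(patches):
        name = f"patch{i:06d}.png"
        Image.fromarray(p.pixels).save(os.path.join(outdir, name))
        rows.append(
            {
                "file": name,
                "patient_id": p.patient_id,
                "roi_id": p.roi_id,
                "row": p.offset[0],
                "col": p.offset[1],
                "orientation": p.orientation,
                "label": p.label,
            }
        )
    pd.DataFrame(rows).to_csv(os.path.join(outdir, "patches.csv"), index=False)
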