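"""Patch extraction, per-channel normalization and 8-fold augmentation.

Large histology images are cut into square windows (default 512x512) on a
grid with 50% overlap; every window inherits the label of its source image.
Each patch is expanded into eight symmetry variants (the four rotations,
each with and without a vertical mirror) and normalized to zero mean per
color channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage.transform import resize

from .exceptions import DimensionError, InputError

#: Augmentation order: rotations are counter-clockwise; ``vmir`` flips
#: across the horizontal axis (top row <-> bottom row) after rotating.
TRANSFORM_TAGS = (
    "rot0", "rot90", "rot180", "rot270",
    "rot0_vmir", "rot90_vmir", "rot180_vmir", "rot270_vmir",
)


@dataclass(frozen=True)
class Patch:
    pixels: np.ndarray
    label: object = None
    origin: tuple = (None, 0, 0)  # (source image id, row offset, col offset)
    transform_tag: str = "rot0"


@dataclass(frozen=True)
class PatchSet:
    patches: tuple[Patch, ...]
    provenance: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.patches)

    def __iter__(self):
        return iter(self.patches)

    def __getitem__(self, i):
        return self.patches[i]

    def to_manifest(self) -> pd.DataFrame:
        rows = [
            {
                "image_id": p.origin[0],
                "row": p.origin[1],
                "col": p.origin[2],
                "transform_tag": p.transform_tag,
                "label": p.label,
            }
            for p in self.patches
        ]
        return pd.DataFrame(rows, columns=["image_id", "row", "col", "transform_tag", "label"])


def _axis_anchors(dim: int, side: int, stride: int) -> list[tuple[int, int]]:
    """(offset, extent) windows along one axis; whole-axis fallback if short."""
    if dim < side:
        return [(0, dim)]
    return [(a, side) for a in range(0, dim - side + 1, stride)]


def extract_patches(
    image,
    side: int = 512,
    overlap: float = 0.5,
    label=None,
    image_id=None,
) -> PatchSet:
    """Anchored sliding-window extraction with fractional overlap.

    The stride is ``side * (1 - overlap)``; only full windows on the anchored
    grid are emitted (partial border windows are discarded).  If an image
    dimension is smaller than ``side`` the whole extent of that axis is taken
    and the window is rescaled to ``side`` x ``side`` (bilinear).
    """
    if not 0 <= overlap < 1:
        raise InputError(f"overlap must be in [0, 1), got {overlap}")
    if side < 2:
        raise InputError(f"side must be >= 2, got {side}")
    arr = np.asarray(image, dtype=float)
    if arr.size == 0:
        raise InputError("empty input image")
    if arr.ndim == 2:
        arr = arr[:, :, None]
    h, w = arr.shape[:2]
    stride = max(int(round(side * (1.0 - overlap))), 1)
    patches = []
    for r, hext in _axis_anchors(h, side, stride):
        for c, wext in _axis_anchors(w, side, stride):
            window = arr[r : r + hext, c : c + wext, :]
            if window.shape[:2] != (side, side):
                window = resize(window, (side, side), order=1, anti_aliasing=False)
            patches.append(Patch(pixels=window, label=label, origin=(image_id, r, c)))
    return PatchSet(
        patches=tuple(patches),
        provenance={"image_id": image_id, "shape": (h, w), "side": side,
                    "overlap": overlap, "stride": stride, "label": label},
    )


def normalize_patch(patch: Patch) -> Patch:
    """Subtract each color channel's mean (zero-mean channels, shape kept)."""
    return replace(patch, pixels=normalize_array(patch.pixels))


def normalize_array(pixels: np.ndarray) -> np.ndarray:
    arr = np.asarray(pixels, dtype=float)
    return arr - arr.mean(axis=(0, 1), keepdims=True)


def _apply_transform(pixels: np.ndarray, tag: str) -> np.ndarray:
    rot = {"rot0": 0, "rot90": 1, "rot180": 2, "rot270": 3}[tag.split("_")[0]]
    out = np.rot90(pixels, k=rot, axes=(0, 1))
    if tag.endswith("_vmir"):
        out = out[::-1, ...]
    return out


def augment_patch(patch: Patch) -> list[Patch]:
    """The eight dihedral variants of a square patch, labels inherited.

    Output order follows :data:`TRANSFORM_TAGS`; the first element is the
    untouched patch.
    """
    if patch.pixels.shape[0] != patch.pixels.shape[1]:
        raise DimensionError(
            f"augmentation requires a square patch, got {patch.pixels.shape[:2]}"
        )
    return [
        replace(patch, pixels=np.ascontiguousarray(_apply_transform(patch.pixels, tag)),
                transform_tag=tag)
        for tag in TRANSFORM_TAGS
    ]


def patch_pipeline(
    image,
    side: int = 512,
    overlap: float = 0.5,
    augment: bool = True,
    normalize: bool = True,
    label=None,
    image_id=None,
) -> PatchSet:
    """extract -> (augment) -> (normalize), the training-time preprocessing.

    Normalization runs last so every emitted patch has exactly zero-mean
    channels regardless of the geometric transform applied.
    """
    base = extract_patches(image, side=side, overlap=overlap, label=label, image_id=image_id)
    patches: list[Patch] = []
    for p in base:
        variants = augment_patch(p) if augment else [p]
        if normalize:
            variants = [normalize_patch(v) for v in variants]
        patches.extend(variants)
    return PatchSet(patches=tuple(patches), provenance=dict(base.provenance, augment=augment))
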