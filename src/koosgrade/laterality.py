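"""Tumor-side detection and left/right → ipsilateral/contralateral relabelling.

The side of the vestibular schwannoma is found by comparing the mean of
the tumor mask's projection onto the sagittal (left-right) axis with the
mean of the MR image's projection onto the same axis.  Under RAS the
sagittal coordinate increases toward subject right, so a tumor centroid
to the right of the image centroid means a right-sided tumor.
"""

from __future__ import annotations

import enum

import numpy as np

from .errors import DegenerateInputError, GeometryError, StateError
from .schemes import (
    CONTRA_CEREBELLUM,
    IPSI_CEREBELLUM,
    IPSI_CONTRA,
    LEFT_CEREBELLUM,
    LEFT_RIGHT,
    RIGHT_CEREBELLUM,
)
from .volumes import ImageVolume, LabelVolume, require_ras

SAGITTAL, CORONAL, AXIAL = 0, 1, 2  # anatomical axes under RAS: x, y, z


class Side(enum.Enum):
    LEFT = "left"
    RIGHT = "right"

    @property
    def opposite(self) -> "Side":
        return Side.LEFT if self is Side.RIGHT else Side.RIGHT


def projection_mean(vol: ImageVolume, axis: int = SAGITTAL) -> float:
    """Weight-averaged physical coordinate (mm) along an anatomical axis.

    Weights are the mask indicator for label volumes and the intensity
    clamped at zero for images (so signed intensity conventions cannot
    flip side comparisons).  The volume must be in RAS.
    """
    require_ras(vol)
    if isinstance(vol, LabelVolume):
        w = (vol.voxels != 0).astype(float)
    else:
        w = np.clip(np.asarray(vol.voxels, dtype=float), 0.0, None)
    total = w.sum()
    if total <= 0:
        raise DegenerateInputError("empty mask / all-nonpositive image")
    # weighted mean of indices per grid axis, then through the affine:
    # E[coord_a] = sum_i A[a,i] E[idx_i] + A[a,3]
    mean_idx = np.empty(3)
    for g in range(3):
        idx = np.arange(vol.shape[g], dtype=float)
        w_axis = w.sum(axis=tuple(a for a in range(3) if a != g))
        mean_idx[g] = (idx * w_axis).sum() / total
    return float(vol.affine[axis, :3] @ mean_idx + vol.affine[axis, 3])


def detect_side(image: ImageVolume, vs_mask: LabelVolume) -> Side:
    """Classify the tumor as left- or right-sided.

    Right if the tumor-mask sagittal projection mean exceeds the image's,
    else left (exact equality, a measure-zero event, resolves to left).
    Invariant to uniform intensity rescaling of the image.
    """
    require_ras(image)
    require_ras(vs_mask)
    if not image.same_grid(vs_mask):
        raise GeometryError("image and tumor mask must share a grid")
    tumor_x = projection_mean(vs_mask, SAGITTAL)
    image_x = projection_mean(image, SAGITTAL)
    return Side.RIGHT if tumor_x > image_x else Side.LEFT


def to_ipsi_contra(vol: LabelVolume, side: Side) -> LabelVolume:
    """Rename hemisphere labels relative to the tumor side.

    The cerebellar hemisphere on the tumor side becomes "ipsilateral
    cerebellum", the other "contralateral cerebellum".  Voxel geometry
    and all voxel counts are untouched; only the scheme changes.
    """
    if vol.scheme.sidedness != LEFT_RIGHT:
        raise StateError("scheme is already in ipsi-contra mode")
    if side is Side.LEFT:
        mapping = {LEFT_CEREBELLUM: IPSI_CEREBELLUM, RIGHT_CEREBELLUM: CONTRA_CEREBELLUM}
    else:
        mapping = {RIGHT_CEREBELLUM: IPSI_CEREBELLUM, LEFT_CEREBELLUM: CONTRA_CEREBELLUM}
    scheme = vol.scheme.renamed(mapping, sidedness=IPSI_CONTRA)
    return LabelVolume(vol.voxels, vol.affine, scheme=scheme)


def to_left_right(vol: LabelVolume, side: Side) -> LabelVolume:
    """Inverse of :func:`to_ipsi_contra` for a known tumor side."""
    if vol.scheme.sidedness != IPSI_CONTRA:
        raise StateError("scheme is not in ipsi-contra mode")
    if side is Side.LEFT:
        mapping = {IPSI_CEREBELLUM: LEFT_CEREBELLUM, CONTRA_CEREBELLUM: RIGHT_CEREBELLUM}
    else:
        mapping = {IPSI_CEREBELLUM: RIGHT_CEREBELLUM, CONTRA_CEREBELLUM: LEFT_CEREBELLUM}
    scheme = vol.scheme.renamed(mapping, sidedness=LEFT_RIGHT)
    return LabelVolume(vol.voxels, vol.affine, scheme=scheme)
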