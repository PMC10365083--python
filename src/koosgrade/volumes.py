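"""Volumetric image / label-map containers and canonical-grid preprocessing.

All downstream geometry assumes the canonical grid established here:
RAS orientation (grid axis 0 → subject Right, 1 → Anterior, 2 →
Superior) and isotropic voxels, by default 0.8 mm, obtained with
nearest-neighbour resampling.  NIfTI-1 is the on-disk dialect; the
orientation is decoded from the file affine (nibabel prefers the s-form
when both s- and q-forms are present).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from nibabel import orientations as nio

from .errors import (
    GeometryError,
    LabelDecodingError,
    OrientationError,
    ParameterError,
    SchemeError,
)
from .schemes import LabelScheme, canonical_scheme

RAS = ("R", "A", "S")
TARGET_SPACING_MM = 0.8  # canonical isotropic grid


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4) or not np.isfinite(affine).all():
        raise OrientationError("affine must be a finite 4x4 matrix")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise OrientationError("affine rotation block is singular")
    return affine


@dataclass
class ImageVolume:
    """A 3D scalar image with physical geometry.

    ``affine`` maps voxel indices (i, j, k, 1) to physical RAS+
    millimetre coordinates; spacing, orientation codes and origin are
    derived views of it.
    """

    voxels: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ParameterError("voxel grid must be 3D with each axis length >= 1")
        self.affine = _check_affine(self.affine)

    @property
    def spacing(self) -> tuple[float, float, float]:
        """Per-axis voxel edge length in mm (always positive)."""
        return tuple(np.linalg.norm(self.affine[:3, i]) for i in range(3))

    @property
    def orientation(self) -> tuple[str, str, str]:
        """Anatomical axis codes of the grid axes, e.g. ('R','A','S')."""
        return nio.aff2axcodes(self.affine)

    @property
    def origin(self) -> tuple[float, float, float]:
        """Physical position (mm) of voxel (0, 0, 0)."""
        return tuple(self.affine[:3, 3])

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def same_grid(self, other: "ImageVolume") -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=1e-6
        )

    def voxel_coords(self, mask: np.ndarray) -> np.ndarray:
        """Physical coordinates (n, 3) of the voxel centers selected by *mask*."""
        idx = np.argwhere(mask)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]


@dataclass
class LabelVolume(ImageVolume):
    """A 3D integer label map with a :class:`LabelScheme`."""

    scheme: LabelScheme = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.scheme is None:
            self.scheme = canonical_scheme()
        if not np.issubdtype(self.voxels.dtype, np.integer):
            self.voxels = self.voxels.astype(np.int32)
        present = np.unique(self.voxels)
        unknown = [int(v) for v in present if int(v) not in self.scheme]
        if unknown:
            raise SchemeError(f"voxel labels {unknown} not in scheme")

    def mask(self, structure: str) -> np.ndarray:
        """Binary mask of *structure* (raises SchemeError if unknown)."""
        return self.voxels == self.scheme.label_of(structure)

    def voxel_volume(self) -> float:
        """Volume per voxel V_v in mm^3 (product of spacings)."""
        return float(np.prod(self.spacing))


@dataclass
class OneHotVolume:
    """One-hot encoding of a label map: channel k indicates label k."""

    channels: np.ndarray  # (n_labels, x, y, z), uint8
    scheme: LabelScheme
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.affine = _check_affine(self.affine)
        if self.channels.ndim != 4:
            raise ParameterError("one-hot grid must be 4D (channel first)")

    @property
    def n_channels(self) -> int:
        return self.channels.shape[0]


# ---------------------------------------------------------------------------
# I/O


def load_volume(
    path: str | Path,
    as_labels: bool = False,
    scheme: LabelScheme | None = None,
) -> ImageVolume | LabelVolume:
    """Load a NIfTI-1 volume.

    With ``as_labels`` the stored values must be integral to within
    1e-3 after rounding; they are decoded against *scheme* (canonical
    scheme by default).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    affine = img.affine
    if not as_labels:
        return ImageVolume(np.asarray(data, dtype=float), affine)
    rounded = np.rint(data)
    err = np.abs(np.asarray(data, dtype=float) - rounded)
    if err.max(initial=0.0) > 1e-3:
        bad = float(np.asarray(data).flat[int(np.argmax(err))])
        raise LabelDecodingError(
            f"value {bad} is not integral within 1e-3; not a label map"
        )
    return LabelVolume(rounded.astype(np.int32), affine, scheme=scheme)


def save_volume(vol: ImageVolume, path: str | Path) -> None:
    """Write a volume as NIfTI-1 (labels as int16, images as float32)."""
    if isinstance(vol, LabelVolume):
        data = vol.voxels.astype(np.int16)
    else:
        data = vol.voxels.astype(np.float32)
    nib.save(nib.Nifti1Image(data, vol.affine), str(path))


# ---------------------------------------------------------------------------
# Canonical-grid preprocessing


def reorient_ras(vol: ImageVolume) -> ImageVolume:
    """Permute/flip grid axes so they map to (+Right, +Anterior, +Superior).

    Pure relabelling of the grid: every voxel keeps its physical
    position, so the operation is idempotent and preserves all pairwise
    physical distances.
    """
    ornt = nio.io_orientation(vol.affine)
    if np.any(np.isnan(ornt)):
        raise OrientationError("cannot decode orientation from affine")
    data = nio.apply_orientation(vol.voxels, ornt)
    affine = vol.affine @ nio.inv_ornt_aff(ornt, vol.voxels.shape)
    if isinstance(vol, LabelVolume):
        return LabelVolume(data, affine, scheme=vol.scheme)
    return ImageVolume(data, affine)


def resample_iso(
    vol: ImageVolume,
    target_spacing: float | tuple[float, float, float] = TARGET_SPACING_MM,
) -> ImageVolume:
    """Nearest-neighbour resample onto an isotropic grid.

    The output grid is anchored at the input origin (voxel (0,0,0)
    centers coincide) and extends over ``ceil(extent / target)`` voxels
    per axis so the input physical extent is covered.  Each output voxel
    takes the label/intensity of the nearest input voxel center;
    exact-midpoint ties resolve toward the lower input index.
    """
    target = np.broadcast_to(np.asarray(target_spacing, dtype=float), (3,)).copy()
    if np.any(target <= 0) or not np.isfinite(target).all():
        raise ParameterError("target spacing must be strictly positive")
    spacing = np.array(vol.spacing)
    shape = np.array(vol.shape)
    n_out = np.maximum(1, np.ceil(shape * spacing / target - 1e-9).astype(int))
    index_maps = []
    for ax in range(3):
        # position of output center j along the axis, in input index units
        q = np.arange(n_out[ax]) * target[ax] / spacing[ax]
        src = np.ceil(q - 0.5).astype(int)  # ties toward lower index
        index_maps.append(np.clip(src, 0, shape[ax] - 1))
    data = vol.voxels[np.ix_(*index_maps)]
    direction = vol.affine[:3, :3] / spacing  # unit columns
    affine = np.eye(4)
    affine[:3, :3] = direction * target
    affine[:3, 3] = vol.affine[:3, 3]
    if isinstance(vol, LabelVolume):
        return LabelVolume(data, affine, scheme=vol.scheme)
    return ImageVolume(data, affine)


def one_hot(vol: LabelVolume) -> OneHotVolume:
    """One-hot encode a label map: one binary channel per scheme label.

    The canonical scheme (8 foreground structures + background) yields
    9 channels; channel-wise argmax inverts the encoding exactly.
    """
    labels = vol.scheme.labels
    channels = np.stack([(vol.voxels == k) for k in labels]).astype(np.uint8)
    return OneHotVolume(channels, vol.scheme, vol.affine)


def decode_one_hot(oh: OneHotVolume) -> LabelVolume:
    """Inverse of :func:`one_hot` (argmax over channels)."""
    labels = np.array(oh.scheme.labels)
    data = labels[np.argmax(oh.channels, axis=0)]
    return LabelVolume(data, oh.affine, scheme=oh.scheme)


def require_ras(vol: ImageVolume) -> None:
    if vol.orientation != RAS:
        raise GeometryError(
            f"volume must be in RAS orientation, got {vol.orientation}"
        )
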