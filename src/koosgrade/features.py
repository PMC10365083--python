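"""Handcrafted geometric predictors of Koos grade.

For each brain structure c adjacent to the vestibular schwannoma (VS)
three quantities can be computed from the label map:

* volume            V_c = N_c * V_v  (voxel count times voxel volume),
* shortest distance D_c = min over voxel pairs (i_VS, i_c) of the
  Euclidean distance between voxel centers (mm), and
* contact area      S_c: the VS voxels with a face neighbour labelled c
  are meshed with marching cubes (iso-level 0.5, physical spacing) and
  the triangle areas are summed (mm^2).

The canonical predictor set is 9-dimensional: the VS volume, the
distances from the VS to pons, brainstem, the three vermal lobule
groups and both cerebellar hemispheres (ipsi/contra), and the contact
area with the ipsilateral cerebellum.

Distances are between voxel *centers*, so physically touching
structures measure one voxel spacing rather than zero; classifier
thresholds learned on this scale are self-consistent.  A closed
marching-cubes mesh around a one-voxel contact shell measures roughly
twice the geometric interface area plus rim terms; the factor is
constant and harmless to tree-based classifiers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage.measure import marching_cubes, mesh_surface_area

from .errors import DegenerateInputError, SchemeError, StateError
from .schemes import (
    BRAINSTEM,
    CONTRA_CEREBELLUM,
    IPSI_CEREBELLUM,
    IPSI_CONTRA,
    PONS,
    VERMIS_I_V,
    VERMIS_VI_VII,
    VERMIS_VIII_X,
    VS,
)
from .volumes import LabelVolume

log = logging.getLogger(__name__)

#: default distance (mm) reported for structures absent from the field of view
SENTINEL_DISTANCE_MM = 100.0

#: structures whose shortest distance to the VS is a canonical predictor
DISTANCE_STRUCTURES = (
    PONS,
    BRAINSTEM,
    VERMIS_I_V,
    VERMIS_VI_VII,
    VERMIS_VIII_X,
    IPSI_CEREBELLUM,
    CONTRA_CEREBELLUM,
)


def feature_name(kind: str, structure: str) -> str:
    return f"{kind}[{structure}]"


#: canonical predictor column order (1 volume + 7 distances + 1 contact)
FEATURE_COLUMNS = (
    feature_name("volume", VS),
    *(feature_name("distance_to_vs", s) for s in DISTANCE_STRUCTURES),
    feature_name("contact_area_with_vs", IPSI_CEREBELLUM),
)

FEATURE_UNITS = {
    "volume": "mm^3",
    "distance_to_vs": "mm",
    "contact_area_with_vs": "mm^2",
}


def structure_volume(vol: LabelVolume, structure: str) -> float:
    """Volume of *structure* in mm^3: voxel count times voxel volume."""
    n = int(vol.mask(structure).sum())
    return n * vol.voxel_volume()


def shortest_distance(
    vol: LabelVolume,
    a: str,
    b: str,
    sentinel: float | None = None,
) -> float:
    """Smallest center-to-center distance (mm) between voxels of a and b.

    Computed exactly (k-d tree over physical voxel centers); symmetric in
    its two structures.  If either structure has no voxels, *sentinel* is
    returned when given, otherwise :class:`DegenerateInputError` is raised.
    """
    mask_a = vol.mask(a)
    mask_b = vol.mask(b)
    if not mask_a.any() or not mask_b.any():
        if sentinel is not None:
            return float(sentinel)
        raise DegenerateInputError(f"structure {a if not mask_a.any() else b!r} is empty")
    pa = vol.voxel_coords(mask_a)
    pb = vol.voxel_coords(mask_b)
    if len(pb) < len(pa):  # query the smaller set against the larger tree
        pa, pb = pb, pa
    tree = cKDTree(pb)
    d, _ = tree.query(pa, k=1)
    return float(np.min(d))


def contact_shell(vol: LabelVolume, vs: str, c: str) -> np.ndarray:
    """Binary mask of VS voxels with a face (6-connected) neighbour of c."""
    vs_mask = vol.mask(vs)
    c_mask = vol.mask(c)
    shell = np.zeros_like(vs_mask)
    for ax in range(3):
        for shift in (1, -1):
            shell |= vs_mask & np.roll(c_mask, shift, axis=ax) & _roll_valid(
                c_mask.shape, ax, shift
            )
    return shell


def _roll_valid(shape, ax: int, shift: int) -> np.ndarray:
    """Mask excluding voxels whose rolled neighbour wrapped around the grid."""
    valid = np.ones(shape, dtype=bool)
    sl = [slice(None)] * 3
    sl[ax] = slice(0, 1) if shift == 1 else slice(-1, None)
    valid[tuple(sl)] = False
    return valid


def contact_area(vol: LabelVolume, vs: str, c: str) -> float:
    """Contact surface area S_c (mm^2) between the VS and structure c.

    Three steps: (1) collect the VS voxels with a face neighbour
    labelled c; (2) run marching cubes at iso-level 0.5 on that binary
    shell with the volume's physical spacing; (3) sum the mesh triangle
    areas.  No contact yields 0.
    """
    shell = contact_shell(vol, vs, c)
    if not shell.any():
        return 0.0
    padded = np.pad(shell, 1).astype(np.float32)
    verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=vol.spacing)
    return float(mesh_surface_area(verts, faces))


@dataclass
class FeatureVector:
    """The canonical 9 predictors for one case (tumor-relative labels)."""

    case_id: str
    vs_volume: float
    distances: dict[str, float]
    ipsi_cerebellum_contact: float
    warnings: list[str] = field(default_factory=list)

    def to_series(self) -> pd.Series:
        values = {
            feature_name("volume", VS): self.vs_volume,
            **{
                feature_name("distance_to_vs", s): self.distances[s]
                for s in DISTANCE_STRUCTURES
            },
            feature_name("contact_area_with_vs", IPSI_CEREBELLUM): (
                self.ipsi_cerebellum_contact
            ),
        }
        return pd.Series(values, name=self.case_id)[list(FEATURE_COLUMNS)]


def extract_features(
    vol: LabelVolume,
    case_id: str,
    sentinel_distance: float = SENTINEL_DISTANCE_MM,
) -> FeatureVector:
    """Compute the canonical predictor set from an ipsi/contra label map.

    The tumor must be present; a missing adjacent structure yields the
    sentinel distance plus a warning rather than a failure (restricted
    fields of view routinely truncate contralateral structures).
    """
    if vol.scheme.sidedness != IPSI_CONTRA:
        raise StateError("extract_features expects an ipsi-contra scheme")
    if not vol.mask(VS).any():
        raise DegenerateInputError(f"case {case_id}: tumor mask is empty")
    warnings: list[str] = []
    distances: dict[str, float] = {}
    for s in DISTANCE_STRUCTURES:
        if not vol.mask(s).any():
            distances[s] = sentinel_distance
            msg = f"case {case_id}: structure {s!r} absent; sentinel distance used"
            warnings.append(msg)
            log.warning(msg)
        else:
            distances[s] = shortest_distance(vol, VS, s)
    return FeatureVector(
        case_id=case_id,
        vs_volume=structure_volume(vol, VS),
        distances=distances,
        ipsi_cerebellum_contact=contact_area(vol, VS, IPSI_CEREBELLUM),
        warnings=warnings,
    )


def extract_full_features(
    vol: LabelVolume,
    case_id: str,
    vs: str = VS,
    sentinel_distance: float = SENTINEL_DISTANCE_MM,
) -> pd.Series:
    """Volume, distance and contact area for *every* foreground structure.

    Used by the importance-driven structure selection: with m foreground
    structures the result has 3*(m-1) + 1 predictors (each non-tumor
    structure contributes volume, distance to the VS and contact area;
    the tumor contributes its volume only).
    """
    if vs not in vol.scheme.foreground_names:
        raise SchemeError(f"tumor structure {vs!r} not in scheme")
    if not vol.mask(vs).any():
        raise DegenerateInputError(f"case {case_id}: tumor mask is empty")
    values: dict[str, float] = {feature_name("volume", vs): structure_volume(vol, vs)}
    for s in vol.scheme.foreground_names:
        if s == vs:
            continue
        values[feature_name("volume", s)] = structure_volume(vol, s)
        values[feature_name("distance_to_vs", s)] = shortest_distance(
            vol, vs, s, sentinel=sentinel_distance
        )
        values[feature_name("contact_area_with_vs", s)] = contact_area(vol, vs, s)
    return pd.Series(values, name=case_id)


@dataclass
class FeatureTable:
    """Per-case predictors plus optional ordinal Koos grades (1-4)."""

    features: pd.DataFrame  # rows indexed by unique case_id
    grades: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.features.index.has_duplicates:
            raise DegenerateInputError("case_ids must be unique")
        if self.grades is not None:
            self.grades = self.grades.reindex(self.features.index)
            bad = set(self.grades.dropna().unique()) - {1, 2, 3, 4}
            if bad:
                raise DegenerateInputError(f"grades outside 1..4: {sorted(bad)}")

    @classmethod
    def from_vectors(
        cls, vectors: list[FeatureVector], grades: dict[str, int] | None = None
    ) -> "FeatureTable":
        df = pd.DataFrame([v.to_series() for v in vectors])
        df.index.name = "case_id"
        g = None
        if grades is not None:
            g = pd.Series(grades, name="koos_grade").astype(int)
        return cls(df, g)

    def to_csv(self, path) -> None:
        out = self.features.copy()
        if self.grades is not None:
            out["koos_grade"] = self.grades
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        df = pd.read_csv(path, index_col=0)
        g = None
        if "koos_grade" in df.columns:
            g = df.pop("koos_grade").astype(int)
        return cls(df, g)
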