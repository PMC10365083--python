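"""Synthetic 3D phantoms with analytically known geometry.

Each phantom is a desk-scale stand-in for a segmented head: geometric
primitives (spheres/ellipsoids, boxes, slabs) are digitized onto a
regular grid — a voxel takes a structure's label iff its center lies
inside the primitive, and the tumor wins overlaps.  Because every
primitive has closed-form volume and nearest-point distances, every
feature the classifiers consume has an analytic oracle.

The planted feature→grade rule mirrors the clinical Koos logic at desk
scale:

* grade IV — tumor indenting the brainstem (primitive overlap of at
  least the compression depth) and volume above the compression cutoff,
* grade III — tumor touching the brainstem (cerebellopontine-angle
  occupation) without compression-scale volume,
* grade II — tumor protruding medially past the "meatus" plane and
  contacting the ipsilateral cerebellum,
* grade I — small tumor confined lateral to the meatus plane, away
  from everything.

Geometry per grade is sampled with margins such that the rule applied
to the *extracted* features reproduces the planted grade at zero label
noise.  Per-pseudo-modality label degradation (boundary jitter +
dropout) emulates the lower segmentation quality of hrT2-derived masks
relative to ceT1; it is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import PhantomSpecError
from .laterality import Side
from .schemes import (
    BRAINSTEM,
    IPSI_CEREBELLUM,
    LEFT_CEREBELLUM,
    PONS,
    RIGHT_CEREBELLUM,
    VERMIS_I_V,
    VERMIS_VI_VII,
    VERMIS_VIII_X,
    VS,
    canonical_scheme,
)
from .volumes import ImageVolume, LabelVolume

MODALITIES = ("ceT1", "hrT2", "ceT1+hrT2")

GRID_SHAPE = (80, 80, 80)
SPACING_MM = 0.8  # canonical isotropic grid; physical extent 63.2 mm cube
MIDLINE_X = 31.6
MEATUS_OFFSET_MM = 16.0  # meatus plane at |x - midline| = 16


# ---------------------------------------------------------------------------
# Primitives


@dataclass(frozen=True)
class Ellipsoid:
    center: tuple[float, float, float]
    radii: tuple[float, float, float]

    def contains(self, xs, ys, zs):
        c, r = np.asarray(self.center), np.asarray(self.radii)
        return (
            ((xs - c[0]) / r[0]) ** 2
            + ((ys - c[1]) / r[1]) ** 2
            + ((zs - c[2]) / r[2]) ** 2
        ) <= 1.0

    def volume(self) -> float:
        return 4.0 / 3.0 * np.pi * float(np.prod(self.radii))

    def bounds(self):
        c, r = np.asarray(self.center), np.asarray(self.radii)
        return c - r, c + r


@dataclass(frozen=True)
class Box:
    """Axis-aligned box, half-open: lo <= p < hi per axis."""

    lo: tuple[float, float, float]
    hi: tuple[float, float, float]

    def contains(self, xs, ys, zs):
        lo, hi = np.asarray(self.lo), np.asarray(self.hi)
        return (
            (xs >= lo[0]) & (xs < hi[0])
            & (ys >= lo[1]) & (ys < hi[1])
            & (zs >= lo[2]) & (zs < hi[2])
        )

    def bounds(self):
        return np.asarray(self.lo), np.asarray(self.hi)


@dataclass(frozen=True)
class Slab:
    """Half-space slab: lo <= p . normal <= hi."""

    normal: tuple[float, float, float]
    lo: float
    hi: float

    def contains(self, xs, ys, zs):
        n = np.asarray(self.normal, dtype=float)
        n = n / np.linalg.norm(n)
        proj = xs * n[0] + ys * n[1] + zs * n[2]
        return (proj >= self.lo) & (proj <= self.hi)

    def bounds(self):  # unbounded in-plane; callers clip to the grid
        return None


def sphere_box_gap(sphere: Ellipsoid, box: Box) -> float:
    """Closed-form surface gap between a sphere and a box (negative when
    overlapping).  Requires equal sphere radii."""
    r = sphere.radii
    if not np.allclose(r, r[0]):
        raise PhantomSpecError("analytic gap requires a sphere")
    c = np.asarray(sphere.center)
    nearest = np.clip(c, box.lo, box.hi)
    return float(np.linalg.norm(c - nearest) - r[0])


# ---------------------------------------------------------------------------
# Planted rule


@dataclass(frozen=True)
class PlantedRule:
    """Feature→grade rule planted in every synthetic cohort.

    ``touch_mm`` is the voxel-center distance under which two structures
    are considered in contact (digitized touching surfaces measure one
    voxel spacing, 0.8 mm, never zero); ``volume_iv_mm3`` separates
    compressing (IV) from merely abutting (III) tumors; it sits in the
    gap between the largest grade-III and smallest grade-IV spheres.
    ``compression_mm`` is the geometric overlap depth planted for
    grade-IV tumors.
    """

    touch_mm: float = 2.0
    volume_iv_mm3: float = 2500.0
    compression_mm: float = 2.0

    def classify(
        self,
        vs_volume: float,
        brainstem_distance: float,
        cerebellum_distance: float,
        cerebellum_contact: float,
    ) -> int:
        if brainstem_distance <= self.touch_mm:
            return 4 if vs_volume >= self.volume_iv_mm3 else 3
        if cerebellum_contact > 0 or cerebellum_distance <= self.touch_mm:
            return 2
        return 1

    def classify_features(self, fv) -> int:
        """Apply the rule to an extracted :class:`FeatureVector`."""
        return self.classify(
            fv.vs_volume,
            fv.distances[BRAINSTEM],
            fv.distances[IPSI_CEREBELLUM],
            fv.ipsi_cerebellum_contact,
        )


@dataclass(frozen=True)
class NoiseProfile:
    """Per-pseudo-modality label degradation (jitter voxels, dropout prob)."""

    jitter: dict[str, float] = field(
        default_factory=lambda: {m: 0.0 for m in MODALITIES}
    )
    dropout: dict[str, float] = field(
        default_factory=lambda: {m: 0.0 for m in MODALITIES}
    )

    @classmethod
    def zero(cls) -> "NoiseProfile":
        return cls()

    @classmethod
    def modality_realistic(cls) -> "NoiseProfile":
        """hrT2-tagged masks degrade more than ceT1, the combination least."""
        return cls(
            jitter={"ceT1": 1.0, "hrT2": 2.0, "ceT1+hrT2": 0.0},
            dropout={"ceT1": 0.02, "hrT2": 0.08, "ceT1+hrT2": 0.01},
        )


# ---------------------------------------------------------------------------
# Spec / case


@dataclass(frozen=True)
class PhantomSpec:
    tumor: Ellipsoid
    side: Side
    grade: int
    structures: dict[str, object] = None  # name -> primitive
    shape: tuple[int, int, int] = GRID_SHAPE
    spacing: float = SPACING_MM
    rule: PlantedRule = PlantedRule()
    noise: NoiseProfile = NoiseProfile()
    seed: int = 0


@dataclass
class PhantomCase:
    case_id: str
    volumes: dict[str, LabelVolume]  # per pseudo-modality tag
    image: ImageVolume
    grade: int  # planted Koos grade
    side: Side  # planted tumor side
    truth: dict[str, float]  # analytic quantities
    spec: PhantomSpec


def default_anatomy(side: Side) -> dict[str, object]:
    """Primitive placements for the eight canonical structures.

    The layout is mirror-symmetric about the mid-sagittal plane
    (x = 31.6 mm): brainstem and pons at the midline, three vermal
    lobule boxes stacked posteriorly, a cerebellar hemisphere box on
    each side.  ``side`` is unused (anatomy is bilateral) but kept for
    signature symmetry with tumor placement.
    """
    return {
        BRAINSTEM: Box((26.0, 24.0, 8.0), (37.2, 34.0, 56.0)),
        PONS: Box((26.0, 34.0, 24.0), (37.2, 42.0, 40.0)),
        VERMIS_I_V: Box((28.0, 8.0, 36.0), (35.2, 16.0, 52.0)),
        VERMIS_VI_VII: Box((28.0, 8.0, 24.0), (35.2, 16.0, 36.0)),
        VERMIS_VIII_X: Box((28.0, 8.0, 8.0), (35.2, 16.0, 24.0)),
        LEFT_CEREBELLUM: Box((4.0, 4.0, 8.0), (24.0, 28.0, 48.0)),
        RIGHT_CEREBELLUM: Box((39.2, 4.0, 8.0), (59.2, 28.0, 48.0)),
    }


def _mirror_x(x: float) -> float:
    return 2 * MIDLINE_X - x


def sample_tumor(grade: int, side: Side, rng: np.random.Generator) -> Ellipsoid:
    """Sample a grade-consistent spherical tumor on the requested side.

    Works in right-side coordinates and mirrors for left.  Margins keep
    the planted rule unambiguous: grade I stays > touch_mm clear of the
    cerebellum, grade II stays >= 3 mm clear of the brainstem, grade III
    touches the brainstem face (gap 0), grade IV indents it by at least
    the compression depth.
    """
    meatus_x = MIDLINE_X + MEATUS_OFFSET_MM  # 47.6, right side
    brainstem_face = 37.2
    z = 32.0 + rng.uniform(-3.0, 3.0)
    if grade == 1:
        r = rng.uniform(2.0, 3.5)
        x = meatus_x + r + rng.uniform(0.5, 3.0)
        y = 34.0
    elif grade == 2:
        r = rng.uniform(4.0, 7.0)
        x_lo = max(brainstem_face + 3.0 + r, meatus_x - 2.0)
        x = rng.uniform(x_lo, meatus_x + 2.0)
        y = 30.0
    elif grade == 3:
        r = rng.uniform(6.0, 8.0)
        x = brainstem_face + r  # surface gap 0: touching
        y = 30.0
    elif grade == 4:
        r = rng.uniform(9.0, 11.0)
        depth = rng.uniform(2.0, 4.0)
        x = brainstem_face + r - depth
        y = 30.0
    else:
        raise PhantomSpecError(f"grade must be 1..4, got {grade}")
    if side is Side.LEFT:
        x = _mirror_x(x)
    return Ellipsoid((x, y, z), (r, r, r))


def _coord_grids(shape, spacing):
    ax = [np.arange(n) * spacing for n in shape]
    return np.meshgrid(*ax, indexing="ij", sparse=True)


def make_image(shape=GRID_SHAPE, spacing: float = SPACING_MM) -> ImageVolume:
    """Smooth synthetic head intensity, mirror-symmetric about the
    mid-sagittal plane (its sagittal projection mean sits on the midline)."""
    xs, ys, zs = _coord_grids(shape, spacing)
    head = Ellipsoid((MIDLINE_X, 30.0, 32.0), (28.0, 26.0, 28.0))
    data = head.contains(xs, ys, zs).astype(float) * 100.0
    data = ndimage.gaussian_filter(data, sigma=2.0)
    affine = np.diag([spacing, spacing, spacing, 1.0])
    return ImageVolume(data, affine)


def make_phantom(spec: PhantomSpec, case_id: str = "phantom") -> PhantomCase:
    """Digitize a phantom spec into per-modality label volumes + image.

    A voxel takes a structure's label iff its center lies inside the
    primitive; the tumor overwrites any structure it overlaps.
    Overlapping *non-tumor* primitives or a tumor extending outside the
    grid raise :class:`PhantomSpecError`.  Analytic truths (tumor
    volume, surface gaps to brainstem and ipsilateral cerebellum) are
    recorded alongside.
    """
    structures = spec.structures or default_anatomy(spec.side)
    scheme = canonical_scheme()
    shape, spacing = spec.shape, spec.spacing
    extent = np.asarray(shape) * spacing
    t_lo, t_hi = spec.tumor.bounds()
    if (t_lo < 0).any() or (t_hi > extent).any():
        raise PhantomSpecError("tumor extends outside the grid")
    xs, ys, zs = _coord_grids(shape, spacing)
    labels = np.zeros(shape, dtype=np.int32)
    claimed = np.zeros(shape, dtype=bool)
    for name, prim in structures.items():
        mask = prim.contains(xs, ys, zs)
        if (mask & claimed).any():
            raise PhantomSpecError(f"structure {name!r} overlaps another primitive")
        labels[mask] = scheme.label_of(name)
        claimed |= mask
    tumor_mask = spec.tumor.contains(xs, ys, zs)
    labels[tumor_mask] = scheme.label_of(VS)  # tumor wins overlaps
    affine = np.diag([spacing, spacing, spacing, 1.0])
    clean = LabelVolume(labels, affine, scheme=scheme)

    volumes: dict[str, LabelVolume] = {}
    for i, modality in enumerate(MODALITIES):
        j = spec.noise.jitter.get(modality, 0.0)
        p = spec.noise.dropout.get(modality, 0.0)
        if j == 0 and p == 0:
            volumes[modality] = clean
        else:
            volumes[modality] = degrade_segmentation(
                clean, jitter=j, dropout=p, seed=spec.seed * 7919 + i
            )

    ipsi_name = RIGHT_CEREBELLUM if spec.side is Side.RIGHT else LEFT_CEREBELLUM
    truth = {
        "tumor_volume_mm3": spec.tumor.volume(),
        "brainstem_gap_mm": sphere_box_gap(spec.tumor, structures[BRAINSTEM]),
        "ipsi_cerebellum_gap_mm": sphere_box_gap(spec.tumor, structures[ipsi_name]),
    }
    return PhantomCase(
        case_id=case_id,
        volumes=volumes,
        image=make_image(shape, spacing),
        grade=spec.grade,
        side=spec.side,
        truth=truth,
        spec=spec,
    )


def generate_cohort(
    n: int,
    grade_mix: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
    rule: PlantedRule = PlantedRule(),
    noise: NoiseProfile = NoiseProfile(),
    seed: int = 0,
) -> list[PhantomCase]:
    """Generate a cohort of phantoms with planted grades and sides.

    Grade counts follow ``grade_mix`` by largest remainder (every grade
    must receive at least one case); tumor sides alternate
    pseudo-randomly.  Deterministic under ``seed``.
    """
    if n < 4:
        raise PhantomSpecError("need n >= 4 (at least one case per grade)")
    mix = np.asarray(grade_mix, dtype=float)
    if mix.shape != (4,) or not np.isclose(mix.sum(), 1.0):
        raise PhantomSpecError("grade_mix must be 4 proportions summing to 1")
    raw = mix * n
    counts = np.floor(raw).astype(int)
    for i in np.argsort(raw - counts)[::-1][: n - counts.sum()]:
        counts[i] += 1
    if (counts == 0).any():
        raise PhantomSpecError(f"grade_mix {grade_mix} infeasible for n={n}")
    rng = np.random.default_rng(seed)
    cases = []
    idx = 0
    for grade, count in zip((1, 2, 3, 4), counts):
        for _ in range(count):
            side = Side.RIGHT if rng.random() < 0.5 else Side.LEFT
            tumor = sample_tumor(grade, side, rng)
            spec = PhantomSpec(
                tumor=tumor,
                side=side,
                grade=grade,
                rule=rule,
                noise=noise,
                seed=int(rng.integers(0, 2**20)),
            )
            cases.append(make_phantom(spec, case_id=f"case{idx:04d}"))
            idx += 1
    return cases


def degrade_segmentation(
    vol: LabelVolume, jitter: float, dropout: float, seed: int = 0
) -> LabelVolume:
    """Emulate segmentation noise: boundary jitter + boundary dropout.

    Each foreground structure is randomly eroded or dilated by up to
    ``jitter`` voxels (dilation only into background, so no voxel gains
    a label farther than the jitter from its structure), then boundary
    voxels fall to background with probability ``dropout``.
    """
    if jitter < 0 or not 0 <= dropout < 1:
        raise PhantomSpecError("jitter must be >= 0 and dropout in [0, 1)")
    if jitter == 0 and dropout == 0:
        return vol
    rng = np.random.default_rng(seed)
    labels = vol.voxels.copy()
    for lab in vol.scheme.foreground_labels:
        mask = labels == lab
        if not mask.any():
            continue
        amount = int(rng.integers(0, int(np.floor(jitter)) + 1))
        if amount > 0:
            if rng.random() < 0.5:
                new = ndimage.binary_erosion(mask, iterations=amount)
            else:
                grown = ndimage.binary_dilation(mask, iterations=amount)
                new = mask | (grown & (labels == 0))
            labels[mask & ~new] = 0
            labels[new & ~mask] = lab
    if dropout > 0:
        fg = labels != 0
        boundary = fg & ~ndimage.binary_erosion(fg)
        drop = boundary & (rng.random(labels.shape) < dropout)
        labels[drop] = 0
    return LabelVolume(labels, vol.affine, scheme=vol.scheme)
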