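"""Label schemes: the mapping from integer voxel labels to brain structures.

The canonical scheme covers the eight structures that matter for Koos
grading of a vestibular schwannoma (VS) — the tumor itself, pons,
brainstem, the three cerebellar vermal lobule groups, and the two
cerebellar hemispheres — plus background.  Hemisphere naming exists in
two modes: anatomical ``left-right`` and tumor-relative ``ipsi-contra``
(ipsilateral = same side as the tumor).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .errors import SchemeError

BACKGROUND = "background"
VS = "vestibular schwannoma"
PONS = "pons"
BRAINSTEM = "brainstem"
VERMIS_I_V = "cerebellar vermal lobules I-V"
VERMIS_VI_VII = "cerebellar vermal lobules VI-VII"
VERMIS_VIII_X = "cerebellar vermal lobules VIII-X"
LEFT_CEREBELLUM = "left cerebellum"
RIGHT_CEREBELLUM = "right cerebellum"
IPSI_CEREBELLUM = "ipsilateral cerebellum"
CONTRA_CEREBELLUM = "contralateral cerebellum"

LEFT_RIGHT = "left-right"
IPSI_CONTRA = "ipsi-contra"


@dataclass(frozen=True)
class LabelScheme:
    """Ordered mapping of integer labels to structure names.

    Parameters
    ----------
    entries
        Mapping label integer -> structure name.  Label 0 must map to
        ``"background"`` and names must be unique.
    sidedness
        ``"left-right"`` (anatomical hemispheres) or ``"ipsi-contra"``
        (hemispheres named relative to the tumor side).
    """

    entries: dict[int, str]
    sidedness: str = LEFT_RIGHT
    # normalized copy with int keys, fixed insertion order
    _order: tuple[int, ...] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        entries = {int(k): str(v) for k, v in self.entries.items()}
        if entries.get(0) != BACKGROUND:
            raise SchemeError("label 0 must map to 'background'")
        names = list(entries.values())
        if len(set(names)) != len(names):
            raise SchemeError("structure names must be unique")
        if self.sidedness not in (LEFT_RIGHT, IPSI_CONTRA):
            raise SchemeError(f"unknown sidedness {self.sidedness!r}")
        if self.sidedness == LEFT_RIGHT:
            required = {LEFT_CEREBELLUM, RIGHT_CEREBELLUM}
        else:
            required = {IPSI_CEREBELLUM, CONTRA_CEREBELLUM}
        if not required <= set(names):
            raise SchemeError(
                f"{self.sidedness} scheme must contain {sorted(required)}"
            )
        object.__setattr__(self, "entries", entries)
        object.__setattr__(self, "_order", tuple(sorted(entries)))

    @property
    def labels(self) -> tuple[int, ...]:
        """All labels in ascending order (background first)."""
        return self._order

    @property
    def foreground_labels(self) -> tuple[int, ...]:
        return tuple(k for k in self._order if k != 0)

    @property
    def foreground_names(self) -> tuple[str, ...]:
        return tuple(self.entries[k] for k in self.foreground_labels)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, label: int) -> bool:
        return int(label) in self.entries

    def label_of(self, name: str) -> int:
        for k, v in self.entries.items():
            if v == name:
                return k
        raise SchemeError(f"structure {name!r} not in scheme")

    def name_of(self, label: int) -> str:
        try:
            return self.entries[int(label)]
        except KeyError:
            raise SchemeError(f"label {label} not in scheme") from None

    def renamed(self, mapping: dict[str, str], sidedness: str | None = None) -> "LabelScheme":
        """Return a scheme with structure names replaced via *mapping*."""
        entries = {k: mapping.get(v, v) for k, v in self.entries.items()}
        return LabelScheme(entries, sidedness or self.sidedness)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"sidedness": self.sidedness, "entries": dict(self.entries)}, fh
            )

    @classmethod
    def from_yaml(cls, path) -> "LabelScheme":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(raw["entries"], raw.get("sidedness", LEFT_RIGHT))


def canonical_scheme(sidedness: str = LEFT_RIGHT) -> LabelScheme:
    """The canonical 8-foreground-structure scheme (9 labels with background)."""
    if sidedness == LEFT_RIGHT:
        cere = (LEFT_CEREBELLUM, RIGHT_CEREBELLUM)
    else:
        cere = (IPSI_CEREBELLUM, CONTRA_CEREBELLUM)
    return LabelScheme(
        {
            0: BACKGROUND,
            1: VS,
            2: PONS,
            3: BRAINSTEM,
            4: VERMIS_I_V,
            5: VERMIS_VI_VII,
            6: VERMIS_VIII_X,
            7: cere[0],
            8: cere[1],
        },
        sidedness,
    )
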