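"""Named collections of cardiac structure masks on a shared grid.

The structure vocabulary is the closed 18-name cardiac model plus the
whole heart: four chambers, three great-vessel bases, four valves, four
coronary arteries and the two conduction nodes.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from .core import BinaryMask, VolumeGrid, read_mask, write_volume

logger = logging.getLogger(__name__)

__all__ = [
    "StructureSet",
    "CHAMBERS",
    "GREAT_VESSELS",
    "MULTI_ATLAS_STRUCTURES",
    "VALVES",
    "CORONARY_ARTERIES",
    "CONDUCTION_NODES",
    "ALL_STRUCTURES",
    "canonical_name",
    "read_structure_set",
    "write_structure_set",
]

CHAMBERS = ("LA", "LV", "RA", "RV")
GREAT_VESSELS = ("AA", "PA", "SVC")
#: The seven structures delineated by whole-heart-guided multi-atlas mapping.
MULTI_ATLAS_STRUCTURES = CHAMBERS + GREAT_VESSELS
VALVES = ("AV", "PV", "MV", "TV")
CORONARY_ARTERIES = ("LAD", "LCX", "LMCA", "RCA")
CONDUCTION_NODES = ("AVN", "SAN")
#: The full 18-structure cardiac model (WH is carried alongside, not counted).
ALL_STRUCTURES = MULTI_ATLAS_STRUCTURES + VALVES + CORONARY_ARTERIES + CONDUCTION_NODES

_KNOWN = ("WH",) + ALL_STRUCTURES

# Case-insensitive alias table for names seen in clinical exports; keys are
# normalised by stripping non-alphanumerics.
_ALIASES = {
    "WHOLEHEART": "WH",
    "HEART": "WH",
    "H": "WH",
    "LEFTATRIUM": "LA",
    "LEFTVENTRICLE": "LV",
    "RIGHTATRIUM": "RA",
    "RIGHTVENTRICLE": "RV",
    "ASCENDINGAORTA": "AA",
    "AORTAASC": "AA",
    "PULMONARYARTERY": "PA",
    "SUPERIORVENACAVA": "SVC",
    "VENACAVASUPERIOR": "SVC",
    "AORTICVALVE": "AV",
    "PULMONICVALVE": "PV",
    "PULMONARYVALVE": "PV",
    "MITRALVALVE": "MV",
    "TRICUSPIDVALVE": "TV",
    "LEFTANTERIORDESCENDING": "LAD",
    "LEFTCIRCUMFLEX": "LCX",
    "LEFTMAINCORONARYARTERY": "LMCA",
    "LEFTMAIN": "LMCA",
    "RIGHTCORONARYARTERY": "RCA",
    "ATRIOVENTRICULARNODE": "AVN",
    "SINOATRIALNODE": "SAN",
}


def canonical_name(name: str) -> str | None:
    """Map a free-form structure name to a canonical one, or None."""
    key = re.sub(r"[^A-Za-z0-9]", "", name).upper()
    if key in _KNOWN:
        return key
    return _ALIASES.get(key)


class StructureSet:
    """A mapping from structure names to binary masks on one shared grid."""

    def __init__(self, structures: Mapping[str, BinaryMask] | None = None):
        self._structures: dict[str, BinaryMask] = {}
        if structures:
            for name, mask in structures.items():
                self[name] = mask

    # mapping protocol ----------------------------------------------------
    def __getitem__(self, name: str) -> BinaryMask:
        return self._structures[name]

    def __setitem__(self, name: str, mask: BinaryMask) -> None:
        if not isinstance(mask, BinaryMask):
            raise TypeError("StructureSet holds BinaryMask values")
        if self._structures:
            if not mask.grid.same_geometry(self.grid):
                raise ValueError(f"mask {name!r} is not on the shared grid")
        self._structures[name] = mask

    def __contains__(self, name: str) -> bool:
        return name in self._structures

    def __iter__(self) -> Iterator[str]:
        return iter(self._structures)

    def __len__(self) -> int:
        return len(self._structures)

    def names(self) -> list[str]:
        return list(self._structures)

    def items(self):
        return self._structures.items()

    def get(self, name: str, default=None):
        return self._structures.get(name, default)

    @property
    def grid(self) -> VolumeGrid:
        if not self._structures:
            raise ValueError("empty structure set has no grid")
        return next(iter(self._structures.values())).grid

    def copy(self) -> "StructureSet":
        return StructureSet(dict(self._structures))

    def subset(self, names: Iterable[str]) -> "StructureSet":
        return StructureSet({n: self._structures[n] for n in names if n in self._structures})

    # bookkeeping ---------------------------------------------------------
    def overlapping_pairs(self, names: Iterable[str] | None = None) -> list[tuple[str, str]]:
        """Pairs among ``names`` (default: all) with non-empty intersection."""
        sel = [n for n in (names if names is not None else self.names()) if n in self]
        pairs = []
        for i, a in enumerate(sel):
            for b in sel[i + 1:]:
                if (self[a].values & self[b].values).any():
                    pairs.append((a, b))
        return pairs

    def assert_disjoint(self, names: Iterable[str]) -> None:
        pairs = self.overlapping_pairs(names)
        if pairs:
            raise ValueError(f"structures overlap: {pairs}")


def read_structure_set(directory) -> StructureSet:
    """Read per-structure NIfTI masks from a directory.

    File stems are mapped through the alias table; unrecognised names are
    kept under their raw stem with a warning.
    """
    directory = Path(directory)
    paths = sorted(directory.glob("*.nii.gz")) + sorted(directory.glob("*.nii"))
    if not paths:
        raise ValueError(f"no NIfTI structure files in {directory}")
    out = StructureSet()
    for p in paths:
        stem = p.name.removesuffix(".nii.gz").removesuffix(".nii")
        name = canonical_name(stem)
        if name is None:
            logger.warning("unknown structure name %r; keeping raw name", stem)
            name = stem
        out[name] = read_mask(p)
    return out


def write_structure_set(structures: StructureSet, directory) -> list[Path]:
    """Write one uint8 NIfTI per structure; returns the written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name, mask in structures.items():
        path = directory / f"{name}.nii.gz"
        write_volume(mask.grid, path, dtype="uint8")
        written.append(path)
    return written
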