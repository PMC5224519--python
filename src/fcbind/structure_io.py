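"""Fixed-column PDB reading/writing and atom selection.

Structures and molecular-dynamics trajectory frames are handled through one
container: a :class:`Trajectory` of :class:`StructureModel` frames, each an
ordered list of :class:`AtomRecord`.  Multi-model PDB files (``MODEL`` /
``ENDMDL`` blocks) map one model per frame; a file without ``MODEL`` records
yields a single-frame trajectory.  ``HETATM`` records are retained because
glycan residues (NAG/BMA/MAN) are deposited as heteroatoms.

Residue numbering is the author (``auth``) numbering exactly as printed in
the file, since receptor residues are conventionally cited by their
crystal-structure numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

__all__ = [
    "AtomRecord",
    "StructureModel",
    "Trajectory",
    "Selection",
    "PDBFormatError",
    "EmptySelectionError",
    "read_pdb",
    "write_pdb",
    "resolve_selection",
]

#: residue names treated as glycan residues throughout the toolkit
GLYCAN_RESIDUE_NAMES = frozenset({"NAG", "BMA", "MAN", "FUC", "GAL", "SIA"})

_HYDROGEN_ELEMENTS = frozenset({"H", "D"})


class PDBFormatError(ValueError):
    """Raised for malformed PDB records or unwritable field values."""


class EmptySelectionError(ValueError):
    """Raised when a selection that must match atoms resolves to none."""


@dataclass(frozen=True)
class AtomRecord:
    """One ATOM/HETATM record.

    Coordinates are in Å.  ``residue_seq`` keeps the author numbering from
    the input file; ``insertion_code`` is ``""`` when absent.
    """

    serial: int
    atom_name: str
    residue_name: str
    chain_id: str
    residue_seq: int
    x: float
    y: float
    z: float
    insertion_code: str = ""
    element: str = ""
    altloc: str = ""
    occupancy: float = 1.0
    b_factor: float = 0.0
    is_hetatm: bool = False

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.x, self.y, self.z)):
            raise PDBFormatError(f"non-finite coordinates for atom serial {self.serial}")

    @property
    def residue_key(self) -> tuple[str, int, str]:
        """(chain_id, residue_seq, insertion_code) identifying the residue."""
        return (self.chain_id, self.residue_seq, self.insertion_code)

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in _HYDROGEN_ELEMENTS

    @property
    def coords(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


def _infer_element(atom_name: str, residue_name: str) -> str:
    """Infer the element symbol from the atom name when columns 77-78 are blank.

    PDB atom names right-pad one-letter elements into column 14 (" CA " is a
    carbon, "CA  " starting in column 13 would be calcium); for the protein /
    glycan atoms handled here the first alphabetic character after stripping
    digits is the element, except explicit two-letter ions.
    """
    name = atom_name.strip()
    if not name:
        return ""
    stripped = name.lstrip("0123456789")
    if not stripped:
        return ""
    first = stripped[0].upper()
    if first in _HYDROGEN_ELEMENTS:
        return "H" if first == "H" else "D"
    return first


class StructureModel:
    """A single structural model (one trajectory frame): ordered atoms plus indices."""

    def __init__(self, model_id: int, atoms: Sequence[AtomRecord]):
        self.model_id = int(model_id)
        self.atoms: list[AtomRecord] = list(atoms)
        self._atom_index: dict[tuple[str, int, str, str], int] = {}
        self._chain_index: dict[str, list[int]] = {}
        for i, a in enumerate(self.atoms):
            key = (a.chain_id, a.residue_seq, a.insertion_code, a.atom_name)
            if key in self._atom_index:
                raise PDBFormatError(
                    f"duplicate atom {a.atom_name!r} in residue "
                    f"{a.chain_id}:{a.residue_seq}{a.insertion_code} of model {model_id}"
                )
            self._atom_index[key] = i
            self._chain_index.setdefault(a.chain_id, []).append(i)

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self) -> Iterator[AtomRecord]:
        return iter(self.atoms)

    @property
    def chain_ids(self) -> list[str]:
        return list(self._chain_index)

    def find_atom(
        self,
        chain_id: str,
        residue_seq: int,
        atom_name: str,
        insertion_code: str = "",
    ) -> AtomRecord | None:
        i = self._atom_index.get((chain_id, residue_seq, insertion_code, atom_name))
        return None if i is None else self.atoms[i]

    def atom_identity(self) -> tuple[tuple[str, str, int, str, str], ...]:
        """Topology fingerprint used to check frame compatibility."""
        return tuple(
            (a.chain_id, a.residue_seq, a.insertion_code, a.residue_name, a.atom_name)
            for a in self.atoms
        )

    def transformed(self, rotation, translation) -> "StructureModel":
        """Return a copy with ``x' = R x + t`` applied to every atom."""
        import numpy as np

        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        coords = np.array([a.coords for a in self.atoms])
        moved = coords @ R.T + t
        atoms = [
            replace(a, x=float(p[0]), y=float(p[1]), z=float(p[2]))
            for a, p in zip(self.atoms, moved)
        ]
        return StructureModel(self.model_id, atoms)


class Trajectory:
    """Ordered frames sharing one atom topology.

    ``frame_spacing`` (ns between frames) is optional metadata; analyses index
    frames by position.
    """

    def __init__(self, frames: Sequence[StructureModel], frame_spacing: float | None = None):
        frames = list(frames)
        if not frames:
            raise PDBFormatError("trajectory must contain at least one frame")
        ident = frames[0].atom_identity()
        for k, f in enumerate(frames[1:], start=1):
            if f.atom_identity() != ident:
                raise PDBFormatError(
                    f"frame {k} atom topology differs from frame 0 "
                    f"({len(f)} vs {len(frames[0])} atoms or different identities)"
                )
        self.frames: list[StructureModel] = frames
        self.frame_spacing = frame_spacing

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[StructureModel]:
        return iter(self.frames)

    def __getitem__(self, i):
        return self.frames[i]


@dataclass(frozen=True)
class Selection:
    """Declarative atom subset: chain, residue ranges, residue/atom name, heavy-only.

    ``chain_id=None`` is a wildcard.  ``residue_ranges`` are inclusive author-numbered
    intervals; ``None`` selects all residues.  Resolution order follows file order,
    so repeated resolution is deterministic and idempotent.
    """

    chain_id: str | None = None
    residue_ranges: tuple[tuple[int, int], ...] | None = None
    residue_names: frozenset[str] | None = None
    atom_names: frozenset[str] | None = None
    heavy_atoms_only: bool = False

    @staticmethod
    def of(
        chain_id: str | None = None,
        residues: Iterable[int] | tuple[int, int] | None = None,
        residue_names: Iterable[str] | None = None,
        atom_names: Iterable[str] | None = None,
        heavy_atoms_only: bool = False,
    ) -> "Selection":
        """Convenience constructor; ``residues`` is a (lo, hi) pair or iterable of seqs."""
        ranges: tuple[tuple[int, int], ...] | None
        if residues is None:
            ranges = None
        elif (
            isinstance(residues, tuple)
            and len(residues) == 2
            and all(isinstance(v, int) for v in residues)
        ):
            ranges = ((residues[0], residues[1]),)
        else:
            ranges = tuple((int(r), int(r)) for r in residues)
        return Selection(
            chain_id=chain_id,
            residue_ranges=ranges,
            residue_names=frozenset(residue_names) if residue_names is not None else None,
            atom_names=frozenset(atom_names) if atom_names is not None else None,
            heavy_atoms_only=heavy_atoms_only,
        )

    def matches(self, atom: AtomRecord) -> bool:
        if self.chain_id is not None and atom.chain_id != self.chain_id:
            return False
        if self.residue_ranges is not None and not any(
            lo <= atom.residue_seq <= hi for lo, hi in self.residue_ranges
        ):
            return False
        if self.residue_names is not None and atom.residue_name not in self.residue_names:
            return False
        if self.atom_names is not None and atom.atom_name not in self.atom_names:
            return False
        if self.heavy_atoms_only and atom.is_hydrogen:
            return False
        return True


def resolve_selection(
    model: StructureModel, selection: Selection, require_nonempty: bool = False
) -> list[AtomRecord]:
    """Resolve a :class:`Selection` to the ordered atom subset of ``model``."""
    atoms = [a for a in model.atoms if selection.matches(a)]
    if require_nonempty and not atoms:
        raise EmptySelectionError(f"selection {selection} matched no atoms")
    return atoms


# ---------------------------------------------------------------------------
# parsing


def _parse_atom_line(line: str, lineno: int) -> AtomRecord:
    try:
        serial = int(line[6:11])
    except ValueError:
        serial = 0  # some generators overflow this field; not needed for identity
    try:
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise PDBFormatError(f"line {lineno}: malformed coordinate field: {line.rstrip()!r}") from exc
    occ_field = line[54:60].strip()
    b_field = line[60:66].strip()
    atom_name = line[12:16].strip()
    residue_name = line[17:20].strip()
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = _infer_element(line[12:16], residue_name)
    return AtomRecord(
        serial=serial,
        atom_name=atom_name,
        residue_name=residue_name,
        chain_id=line[21:22].strip(),
        residue_seq=int(line[22:26]),
        insertion_code=line[26:27].strip(),
        x=x,
        y=y,
        z=z,
        element=element,
        altloc=line[16:17].strip(),
        occupancy=float(occ_field) if occ_field else 1.0,
        b_factor=float(b_field) if b_field else 0.0,
        is_hetatm=line.startswith("HETATM"),
    )


def _resolve_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep one location per atom: highest occupancy, ties broken by file order."""
    if not any(a.altloc for a in atoms):
        return atoms
    best: dict[tuple[str, int, str, str], tuple[int, AtomRecord]] = {}
    order: list[tuple[str, int, str, str]] = []
    for i, a in enumerate(atoms):
        key = (a.chain_id, a.residue_seq, a.insertion_code, a.atom_name)
        if key not in best:
            best[key] = (i, a)
            order.append(key)
        elif a.occupancy > best[key][1].occupancy:
            best[key] = (best[key][0], a)  # keep original position in atom order
    resolved = sorted(best.values(), key=lambda pair: pair[0])
    return [replace(a, altloc="") for _, a in resolved]


def read_pdb(path, multi_model: bool = True) -> Trajectory:
    """Read a PDB file into a :class:`Trajectory`.

    One frame per ``MODEL`` block; a file without ``MODEL`` records gives a
    single frame.  With ``multi_model=False`` only the first model is kept.
    Alternate locations are resolved to the highest-occupancy conformer
    (first listed on ties).
    """
    frames: list[StructureModel] = []
    current: list[AtomRecord] = []
    model_id = 0
    in_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                if in_model and current:
                    frames.append(StructureModel(model_id, _resolve_altlocs(current)))
                    current = []
                in_model = True
                try:
                    model_id = int(line[10:14])
                except ValueError:
                    model_id = len(frames) + 1
            elif rec == "ENDMDL":
                frames.append(StructureModel(model_id, _resolve_altlocs(current)))
                current = []
                in_model = False
                if not multi_model:
                    break
            elif rec in ("ATOM  ", "HETATM"):
                current.append(_parse_atom_line(line, lineno))
    if current:
        frames.append(StructureModel(model_id if in_model else 1, _resolve_altlocs(current)))
    if not frames or all(len(f) == 0 for f in frames):
        raise PDBFormatError(f"{path}: no atoms found")
    frames = [f for f in frames if len(f)]
    if not multi_model:
        frames = frames[:1]
    return Trajectory(frames)


# ---------------------------------------------------------------------------
# writing


def _format_atom_name(name: str, element: str) -> str:
    # one-letter elements start in column 14 unless the name is 4 chars wide
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def _format_atom_line(a: AtomRecord, serial: int) -> str:
    if len(a.chain_id) > 1:
        raise PDBFormatError(f"chain_id {a.chain_id!r} longer than 1 character")
    record = "HETATM" if a.is_hetatm else "ATOM  "
    name = _format_atom_name(a.atom_name, a.element)
    return (
        f"{record}{min(serial, 99999):5d} {name}{a.altloc or ' ':1s}"
        f"{a.residue_name:>3s} {a.chain_id or ' ':1s}{a.residue_seq:4d}{a.insertion_code or ' ':1s}   "
        f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{a.occupancy:6.2f}{a.b_factor:6.2f}"
        f"          {a.element:>2s}"
    )


def write_pdb(trajectory: Trajectory | StructureModel, path) -> None:
    """Write a trajectory (MODEL/ENDMDL per frame) or a single model as fixed-column PDB."""
    if isinstance(trajectory, StructureModel):
        trajectory = Trajectory([trajectory])
    lines: list[str] = []
    multi = len(trajectory) > 1
    for k, frame in enumerate(trajectory, start=1):
        if multi:
            lines.append(f"MODEL     {k:4d}")
        for i, atom in enumerate(frame, start=1):
            lines.append(_format_atom_line(atom, i))
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
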