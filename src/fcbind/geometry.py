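"""Interdomain hinge angles and distance-cutoff contact counting.

The hinge angle between two immunoglobulin-like domains (D1/D2 of an Fcγ-type
receptor) is measured as the angle subtended at a vertex residue by two outer
anchor residues, using their Cα atoms by default.  Contacts between two atom
selections are counted at a fixed heavy-atom distance cutoff, 3.0 Å by default
(roughly a hydrogen-bonding donor–acceptor distance), either as the number of
distinct contacting residues of the second selection or as qualifying atom
pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import (
    AtomRecord,
    EmptySelectionError,
    Selection,
    StructureModel,
    Trajectory,
    resolve_selection,
)

__all__ = [
    "HingeAnchor",
    "HingeDefinition",
    "ContactSpec",
    "AngleSeries",
    "ContactSeries",
    "AnchorNotFoundError",
    "hinge_angle",
    "hinge_angle_series",
    "contact_count",
    "contact_series",
    "contact_frequency_table",
]


class AnchorNotFoundError(KeyError):
    """A hinge anchor atom could not be resolved in a model."""


@dataclass(frozen=True)
class HingeAnchor:
    chain_id: str
    residue_seq: int
    atom_name: str = "CA"

    def resolve(self, model: StructureModel) -> AtomRecord:
        atom = model.find_atom(self.chain_id, self.residue_seq, self.atom_name)
        if atom is None:
            raise AnchorNotFoundError(
                f"anchor {self.chain_id}:{self.residue_seq}:{self.atom_name} not found"
            )
        return atom


@dataclass(frozen=True)
class HingeDefinition:
    """Three anchors ordered (outer-D1, vertex, outer-D2); the angle sits at the vertex."""

    outer_a: HingeAnchor
    vertex: HingeAnchor
    outer_b: HingeAnchor

    def __post_init__(self) -> None:
        if len({self.outer_a, self.vertex, self.outer_b}) != 3:
            raise ValueError("hinge anchors must be three distinct atoms")

    @staticmethod
    def from_residues(
        chain_id: str, residues: tuple[int, int, int], atom_name: str = "CA"
    ) -> "HingeDefinition":
        a, v, b = residues
        return HingeDefinition(
            HingeAnchor(chain_id, a, atom_name),
            HingeAnchor(chain_id, v, atom_name),
            HingeAnchor(chain_id, b, atom_name),
        )


@dataclass(frozen=True)
class ContactSpec:
    """Two selections, a distance cutoff (Å, inclusive), and the counting unit."""

    selection_a: Selection
    selection_b: Selection
    cutoff: float = 3.0
    count_unit: str = "residues-of-b"

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.count_unit not in ("residues-of-b", "atom-pairs"):
            raise ValueError("count_unit must be 'residues-of-b' or 'atom-pairs'")


@dataclass
class AngleSeries:
    frame_indices: list[int]
    values_deg: list[float]

    def __len__(self) -> int:
        return len(self.values_deg)

    def summary(self) -> dict[str, float]:
        v = np.asarray(self.values_deg)
        return {
            "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)) if len(v) > 1 else 0.0,
            "min": float(v.min()),
            "max": float(v.max()),
            "n_frames": len(v),
        }


@dataclass
class ContactSeries:
    frame_indices: list[int]
    counts: list[int]

    def __len__(self) -> int:
        return len(self.counts)

    def summary(self) -> dict[str, float]:
        c = np.asarray(self.counts)
        return {
            "mean": float(c.mean()),
            "min": int(c.min()),
            "max": int(c.max()),
            "n_frames": len(c),
        }


def _angle_deg(p_a: np.ndarray, p_v: np.ndarray, p_b: np.ndarray) -> float:
    u = p_a - p_v
    w = p_b - p_v
    nu = np.linalg.norm(u)
    nw = np.linalg.norm(w)
    if nu == 0.0 or nw == 0.0:
        raise ValueError("degenerate hinge: coincident anchor atoms")
    cosang = float(np.clip(np.dot(u, w) / (nu * nw), -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))


def hinge_angle(model: StructureModel, hinge: HingeDefinition) -> float:
    """Angle (degrees, in [0, 180]) at the vertex anchor between the two outer anchors."""
    pa = np.array(hinge.outer_a.resolve(model).coords)
    pv = np.array(hinge.vertex.resolve(model).coords)
    pb = np.array(hinge.outer_b.resolve(model).coords)
    return _angle_deg(pa, pv, pb)


def _window_indices(n_frames: int, frame_window: tuple[int, int | None] | None) -> range:
    if frame_window is None:
        return range(n_frames)
    start, stop = frame_window
    stop = n_frames if stop is None else min(stop, n_frames)
    return range(max(start, 0), stop)


def hinge_angle_series(
    trajectory: Trajectory,
    hinge: HingeDefinition,
    frame_window: tuple[int, int | None] | None = None,
) -> AngleSeries:
    """Per-frame hinge angle over ``frame_window`` (half-open [start, stop))."""
    idx = _window_indices(len(trajectory), frame_window)
    values = []
    for i in idx:
        try:
            values.append(hinge_angle(trajectory[i], hinge))
        except AnchorNotFoundError as exc:
            raise AnchorNotFoundError(f"frame {i}: {exc.args[0]}") from exc
    return AngleSeries(list(idx), values)


def _heavy_coords(atoms: list[AtomRecord]) -> tuple[np.ndarray, list[AtomRecord]]:
    heavy = [a for a in atoms if not a.is_hydrogen]
    if not heavy:
        return np.empty((0, 3)), []
    return np.array([a.coords for a in heavy]), heavy


_FAR_APART_WARN = 500.0  # Å; likely an un-imaged periodic system


def _contact_pairs(
    model: StructureModel, spec: ContactSpec
) -> tuple[list[tuple[int, int]], list[AtomRecord], list[AtomRecord]]:
    atoms_a = resolve_selection(model, spec.selection_a, require_nonempty=True)
    atoms_b = resolve_selection(model, spec.selection_b, require_nonempty=True)
    xyz_a, heavy_a = _heavy_coords(atoms_a)
    xyz_b, heavy_b = _heavy_coords(atoms_b)
    if not len(heavy_a) or not len(heavy_b):
        raise EmptySelectionError("selection contains no heavy atoms")
    span = np.linalg.norm(xyz_a.mean(axis=0) - xyz_b.mean(axis=0))
    if span > _FAR_APART_WARN:
        warnings.warn(
            f"selections are {span:.0f} Å apart; coordinates may not be imaged/whole",
            stacklevel=3,
        )
    tree = cKDTree(xyz_b)
    pairs: list[tuple[int, int]] = []
    for i, neighbours in enumerate(tree.query_ball_point(xyz_a, r=spec.cutoff)):
        pairs.extend((i, j) for j in neighbours)
    return pairs, heavy_a, heavy_b


def contact_count(model: StructureModel, spec: ContactSpec) -> int:
    """Contacts between two selections at the cutoff (d ≤ cutoff, heavy atoms only).

    ``residues-of-b``: distinct residues of selection_b with at least one heavy
    atom within the cutoff of any heavy atom of selection_a.  ``atom-pairs``:
    number of qualifying (a, b) heavy-atom pairs.
    """
    pairs, _, heavy_b = _contact_pairs(model, spec)
    if spec.count_unit == "atom-pairs":
        return len(pairs)
    return len({heavy_b[j].residue_key for _, j in pairs})


def contact_series(
    trajectory: Trajectory,
    spec: ContactSpec,
    frame_window: tuple[int, int | None] | None = None,
) -> ContactSeries:
    """Per-frame contact count over the window."""
    idx = _window_indices(len(trajectory), frame_window)
    return ContactSeries(list(idx), [contact_count(trajectory[i], spec) for i in idx])


def contact_frequency_table(
    trajectory: Trajectory,
    spec: ContactSpec,
    frame_window: tuple[int, int | None] | None = None,
) -> dict[tuple[str, int, str], int]:
    """Frames in which each residue of selection_b contacts selection_a.

    Returns ``{(chain_id, residue_seq, insertion_code): n_frames_in_contact}``;
    residues never in contact are reported with 0.
    """
    idx = _window_indices(len(trajectory), frame_window)
    table: dict[tuple[str, int, str], int] = {}
    for i in idx:
        pairs, _, heavy_b = _contact_pairs(trajectory[i], spec)
        for a in heavy_b:
            table.setdefault(a.residue_key, 0)
        for key in {heavy_b[j].residue_key for _, j in pairs}:
            table[key] += 1
    return table
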