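"""Synthetic fixtures with ground truth for every analysis in the toolkit.

The generators emulate the *statistical and geometric structure* of the
systems the analyses target — a two-domain receptor with a designed hinge
angle, a trajectory whose glycan chain switches between tightly- and
loosely-bound configurations at designed frame fractions with designed
contact counts, 1:1 Langmuir sensorgrams over a doubling-dilution series,
and permethylated-glycan peak lists — at toy scale.  They are Cα-only
pseudo-structures, not physical models: the target of validation is the
analysis operators, not structural realism.

All randomness flows through one ``numpy.random.default_rng(seed)`` per
call; a fixed seed reproduces output bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .glycan_dynamics import GlycanTopology, StateSpec
from .geometry import HingeAnchor, HingeDefinition
from .glycomass import GlycanComposition, permethylated_mz
from .spr_kinetics import (
    InjectionSchedule,
    LangmuirModel,
    Sensorgram,
    doubling_dilutions,
    simulate_sensorgram,
)
from .structure_io import AtomRecord, Selection, StructureModel, Trajectory

__all__ = [
    "StructureRecipe",
    "TrajectoryRecipe",
    "HingeFixture",
    "GlycanStateFixture",
    "make_hinge_structure",
    "make_glycan_state_trajectory",
    "make_sensorgrams",
    "make_peak_list",
]

_CA_SPACING = 3.8  # Å, consecutive Cα distance in an extended chain


@dataclass(frozen=True)
class StructureRecipe:
    """Two rigid pseudo-domains joined at a vertex with a designed hinge angle."""

    hinge_angle_deg: float = 50.0
    atoms_per_domain: int = 8
    noise_sd: float = 0.0
    seed: int = 0
    random_orientation: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.hinge_angle_deg <= 180.0:
            raise ValueError("hinge angle must be in (0, 180] degrees")
        if self.atoms_per_domain < 2:
            raise ValueError("need at least 2 atoms per domain")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")


@dataclass
class HingeFixture:
    model: StructureModel
    hinge: HingeDefinition
    true_angle_deg: float


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, det +1)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def make_hinge_structure(recipe: StructureRecipe) -> HingeFixture:
    """Cα-only two-domain structure whose hinge angle equals the recipe's exactly.

    Domain axes meet at a vertex residue; the hinge anchors are the outermost
    Cα of each domain and the vertex Cα, so the subtended angle equals the
    designed angle before noise.  A seeded random rigid transform is applied
    so the designed angle is not axis-aligned.
    """
    rng = np.random.default_rng(recipe.seed)
    theta = np.radians(recipe.hinge_angle_deg)
    u = np.array([1.0, 0.0, 0.0])
    v = np.array([np.cos(theta), np.sin(theta), 0.0])
    n = recipe.atoms_per_domain
    coords = [np.zeros(3)]  # vertex first, then domain A outward, then domain B
    coords += [u * _CA_SPACING * k for k in range(1, n + 1)]
    coords += [v * _CA_SPACING * k for k in range(1, n + 1)]
    coords = np.array(coords)
    if recipe.random_orientation:
        coords = coords @ _random_rotation(rng).T + rng.normal(scale=20.0, size=3)
    if recipe.noise_sd > 0:
        coords = coords + rng.normal(scale=recipe.noise_sd, size=coords.shape)
    atoms = [
        AtomRecord(
            serial=i + 1,
            atom_name="CA",
            residue_name="ALA",
            chain_id="A",
            residue_seq=i + 1,
            x=float(p[0]),
            y=float(p[1]),
            z=float(p[2]),
            element="C",
        )
        for i, p in enumerate(coords)
    ]
    model = StructureModel(1, atoms)
    hinge = HingeDefinition(
        outer_a=HingeAnchor("A", 1 + n, "CA"),  # tip of domain A
        vertex=HingeAnchor("A", 1, "CA"),
        outer_b=HingeAnchor("A", 1 + 2 * n, "CA"),  # tip of domain B
    )
    return HingeFixture(model=model, hinge=hinge, true_angle_deg=recipe.hinge_angle_deg)


@dataclass(frozen=True)
class TrajectoryRecipe:
    """Designed bound/loose frame labels with exact per-state contact counts.

    ``n_loose`` pins the loose-frame count exactly (design mode); ``p_loose``
    draws labels i.i.d. (sampling mode).  Contact counts realised per state
    must straddle the loose threshold: ``loose_contacts <= loose_threshold <
    bound_contacts``.
    """

    n_frames: int = 100
    n_loose: int | None = None
    p_loose: float | None = None
    bound_contacts: int = 5
    loose_contacts: int = 1
    loose_threshold: int = 2
    jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("need at least one frame")
        if (self.n_loose is None) == (self.p_loose is None):
            raise ValueError("specify exactly one of n_loose (design) or p_loose (sampling)")
        if self.n_loose is not None and not 0 <= self.n_loose <= self.n_frames:
            raise ValueError("n_loose outside [0, n_frames]")
        if self.p_loose is not None and not 0.0 <= self.p_loose <= 1.0:
            raise ValueError("p_loose outside [0, 1]")
        if not self.loose_contacts <= self.loose_threshold < self.bound_contacts:
            raise ValueError(
                "need loose_contacts <= loose_threshold < bound_contacts "
                "for labels to be realizable"
            )
        if self.loose_contacts < 0 or self.bound_contacts > 5:
            raise ValueError("contact counts must be within 0..5 (5 probe residues)")


@dataclass
class GlycanStateFixture:
    trajectory: Trajectory
    topology: GlycanTopology
    state_spec: StateSpec
    true_labels: list[str]
    true_counts: list[int]

    @property
    def true_loose_fraction(self) -> float:
        return self.true_labels.count("loose") / len(self.true_labels)


_N_GRID = 12  # pseudo-Cγ2 residues
_GRID_SPACING = 20.0  # Å between grid residues; >> cutoff, no accidental contacts
_CONTACT_OFFSET = 2.0  # Å, inside the 3.0 Å cutoff
_FAR = 120.0  # Å, parked glycan residues

_GLYCAN_RESNAMES = ("NAG", "NAG", "BMA", "MAN", "MAN", "MAN", "MAN")


def _glycan_frame(count: int, jitter: np.ndarray) -> list[AtomRecord]:
    """One frame: grid protein residues plus a 7-residue pseudo-glycan.

    Probe residues 2..6 are placed so exactly ``count`` distinct grid
    residues have an atom within the cutoff; everything else is parked far
    from the grid.
    """
    atoms = []
    for i in range(_N_GRID):
        atoms.append(
            AtomRecord(
                serial=i + 1,
                atom_name="CA",
                residue_name="ALA",
                chain_id="A",
                residue_seq=i + 1,
                x=_GRID_SPACING * i,
                y=0.0,
                z=0.0,
                element="C",
            )
        )
    probe_indices = (2, 3, 4, 5, 6)
    for k, (idx, resname) in enumerate(zip(range(1, 8), _GLYCAN_RESNAMES)):
        if idx in probe_indices and probe_indices.index(idx) < count:
            j = probe_indices.index(idx)
            pos = np.array([_GRID_SPACING * j, _CONTACT_OFFSET, 0.0]) + jitter[k]
        else:
            pos = np.array([_GRID_SPACING * k, _FAR + 10.0 * k, 0.0]) + jitter[k]
        atoms.append(
            AtomRecord(
                serial=_N_GRID + k + 1,
                atom_name="C1",
                residue_name=resname,
                chain_id="A",
                residue_seq=500 + idx,
                x=round(float(pos[0]), 3),
                y=round(float(pos[1]), 3),
                z=round(float(pos[2]), 3),
                element="C",
            )
        )
    return atoms


def make_glycan_state_trajectory(recipe: TrajectoryRecipe) -> GlycanStateFixture:
    """Trajectory whose per-frame glycan contact counts realise designed labels.

    Design mode places exactly ``n_loose`` loose frames (seeded random
    positions among frames); sampling mode draws each frame's label with
    probability ``p_loose``.  Ground-truth labels and counts are returned
    with the fixture.
    """
    rng = np.random.default_rng(recipe.seed)
    if recipe.n_loose is not None:
        labels = np.array(["bound"] * recipe.n_frames, dtype=object)
        loose_at = rng.choice(recipe.n_frames, size=recipe.n_loose, replace=False)
        labels[loose_at] = "loose"
        labels = list(labels)
    else:
        labels = ["loose" if u < recipe.p_loose else "bound" for u in rng.random(recipe.n_frames)]
    counts = [
        recipe.loose_contacts if lab == "loose" else recipe.bound_contacts for lab in labels
    ]
    frames = []
    for f, count in enumerate(counts):
        jitter = (
            rng.normal(scale=recipe.jitter_sd, size=(7, 3))
            if recipe.jitter_sd > 0
            else np.zeros((7, 3))
        )
        frames.append(StructureModel(f + 1, _glycan_frame(count, jitter)))
    topology = GlycanTopology(
        attachment=("A", 1),
        residues=tuple(
            ("A", 500 + i, name) for i, name in zip(range(1, 8), _GLYCAN_RESNAMES)
        ),
        label="glycan-1",
    )
    spec = StateSpec(
        reference=Selection.of(chain_id="A", residues=(1, _N_GRID), heavy_atoms_only=True),
        probe_indices=(2, 3, 4, 5, 6),
        cutoff=3.0,
        loose_threshold=recipe.loose_threshold,
    )
    return GlycanStateFixture(
        trajectory=Trajectory(frames),
        topology=topology,
        state_spec=spec,
        true_labels=labels,
        true_counts=counts,
    )


def make_sensorgrams(
    kon: float = 6.68e2,
    koff: float = 8.39e-4,
    rmax: float = 100.0,
    top_concentration: float | None = None,
    n_dilutions: int = 6,
    t_switch: float = 300.0,
    t_end: float = 600.0,
    dt: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[list[Sensorgram], LangmuirModel, InjectionSchedule]:
    """Doubling-dilution sensorgram fixture; defaults follow a micromolar-KD
    lectin/Fc-type interaction with a 300 s association phase.

    The default top concentration is 16×KD, covering 16×KD down to 0.5×KD
    over six doubling dilutions.
    """
    model = LangmuirModel(kon=kon, koff=koff, rmax=rmax)
    if top_concentration is None:
        top_concentration = 16.0 * model.kd
    schedule = InjectionSchedule(
        concentrations=doubling_dilutions(top_concentration, n_dilutions),
        t_switch=t_switch,
        t_end=t_end,
        dt=dt,
    )
    curves = simulate_sensorgram(model, schedule, noise_sd=noise_sd, seed=seed)
    return curves, model, schedule


def make_peak_list(
    compositions,
    jitter_sd: float = 0.0,
    base_intensity: float = 100.0,
    seed: int = 0,
) -> list[tuple[float, float]]:
    """Peak list from known compositions, with optional Gaussian m/z jitter."""
    if jitter_sd < 0:
        raise ValueError("jitter SD must be non-negative")
    rng = np.random.default_rng(seed)
    peaks = []
    for comp in compositions:
        if isinstance(comp, str):
            comp = GlycanComposition.parse(comp)
        mz = permethylated_mz(comp)
        if jitter_sd > 0:
            mz += float(rng.normal(scale=jitter_sd))
        intensity = base_intensity * float(rng.uniform(0.5, 1.5))
        peaks.append((mz, intensity))
    return sorted(peaks)
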