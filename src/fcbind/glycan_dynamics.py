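"""Glycan configuration classification and lectin-accessibility geometry.

An Fc N-glycan (Man5GlcNAc2 at the canonical Asn297 site) spends a
molecular-dynamics trajectory switching between two configurations: one in
which the chitobiose core, β-mannose and α1–6 arm are all closely associated
with the Cγ2 domain ("bound"), and one in which only the chitobiose core
remains close ("loose").  A frame is labelled by counting the Cγ2 residues
with any heavy atom within a cutoff (3.0 Å default) of glycan residues 2–6;
frames with at most ``loose_threshold`` (default 2) such residues are loose.

The accessibility test asks whether a lectin carbohydrate-recognition domain,
idealised as a rigid probe sphere (3 nm diameter for a DC-SIGN CRD), can
reach a target mannose through the elliptical entrance of the Fc interdomain
cavity (2 nm × 3.5 nm opening).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import geometry
from .structure_io import Selection, StructureModel, Trajectory

__all__ = [
    "GlycanTopology",
    "StateSpec",
    "ConfigurationState",
    "StateSummary",
    "AccessibilityGeometry",
    "GlycanTopologyError",
    "classify_frame",
    "classify_trajectory",
    "state_fractions",
    "accessibility_check",
]

#: canonical Man5GlcNAc2 residue roles by topology index
MAN5_RESIDUE_ROLES = {
    1: "core GlcNAc (Asn-linked)",
    2: "core GlcNAc (chitobiose)",
    3: "beta-mannose",
    4: "alpha1-3 branch mannose",
    5: "alpha1-6 branch mannose",
    6: "alpha1-6 arm terminal mannose",
    7: "alpha1-6 arm terminal mannose",
}


class GlycanTopologyError(ValueError):
    """Raised when a glycan topology cannot be resolved against a model."""


@dataclass(frozen=True)
class GlycanTopology:
    """Maps Man5GlcNAc2 residue indices 1..7 to residues of one glycan chain.

    Indices: 1–2 chitobiose-core GlcNAcs (NAG), 3 β-mannose (BMA), 4 α1–3
    branch mannose, 5 α1–6 branch mannose, 6–7 terminal mannoses of the α1–6
    arm (MAN).  ``attachment`` is the (chain_id, residue_seq) of the Asn the
    glycan is linked to.
    """

    attachment: tuple[str, int]
    residues: tuple[tuple[str, int, str], ...]  # index i-1 -> (chain, seq, resname)
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.residues) != 7:
            raise GlycanTopologyError("topology must map exactly residues 1..7")
        if len(set(self.residues)) != 7:
            raise GlycanTopologyError("topology residues must be distinct")
        bad = [r for r in self.residues if r[2] not in {"NAG", "BMA", "MAN"}]
        if bad:
            raise GlycanTopologyError(f"unexpected glycan residue names: {bad}")
        chains = {r[0] for r in self.residues}
        if len(chains) != 1:
            raise GlycanTopologyError("glycan residues must share one chain_id")

    @property
    def chain_id(self) -> str:
        return self.residues[0][0]

    def selection(self, indices: tuple[int, ...]) -> Selection:
        """Heavy-atom selection covering the given topology indices."""
        seqs = []
        for i in indices:
            if not 1 <= i <= 7:
                raise GlycanTopologyError(f"topology index {i} outside 1..7")
            seqs.append(self.residues[i - 1][1])
        return Selection.of(chain_id=self.chain_id, residues=seqs, heavy_atoms_only=True)

    def check_resolvable(self, model: StructureModel) -> None:
        for i, (chain, seq, name) in enumerate(self.residues, start=1):
            sel = Selection.of(chain_id=chain, residues=[seq], heavy_atoms_only=True)
            if not any(sel.matches(a) for a in model.atoms):
                raise GlycanTopologyError(
                    f"glycan residue {i} ({chain}:{seq} {name}) not found in model"
                )

    @staticmethod
    def from_dict(d: dict) -> "GlycanTopology":
        residues = tuple(
            (d["residues"][str(i)][0], int(d["residues"][str(i)][1]), d["residues"][str(i)][2])
            for i in range(1, 8)
        )
        return GlycanTopology(
            attachment=(d["attachment"][0], int(d["attachment"][1])),
            residues=residues,
            label=d.get("label", ""),
        )

    def to_dict(self) -> dict:
        return {
            "attachment": list(self.attachment),
            "residues": {str(i): list(r) for i, r in enumerate(self.residues, start=1)},
            "label": self.label,
        }


@dataclass(frozen=True)
class StateSpec:
    """Classification parameters: probe indices, reference selection, cutoff, threshold.

    ``reference`` is the Cγ2-domain selection of the glycan-bearing heavy
    chain; contacts are counted as distinct reference residues within
    ``cutoff`` Å (heavy atoms) of the probe glycan residues.  A frame with
    ``count <= loose_threshold`` is loose.
    """

    reference: Selection
    probe_indices: tuple[int, ...] = (2, 3, 4, 5, 6)
    cutoff: float = 3.0
    loose_threshold: int = 2

    def __post_init__(self) -> None:
        if not set(self.probe_indices) <= set(range(1, 8)):
            raise ValueError("probe indices must be a subset of 1..7")
        if self.loose_threshold < 0:
            raise ValueError("loose_threshold must be non-negative")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


@dataclass(frozen=True)
class ConfigurationState:
    frame_index: int
    chain_label: str
    label: str  # "bound" | "loose"
    contact_count: int


@dataclass
class StateSummary:
    """Per-glycan-chain state fractions over the analyzed window."""

    fractions: dict[str, dict[str, float]]  # chain label -> {"bound": f, "loose": f}
    n_frames: int
    frame_window: tuple[int, int | None] | None

    def loose_fraction(self, chain_label: str) -> float:
        return self.fractions[chain_label]["loose"]

    def bound_fraction(self, chain_label: str) -> float:
        return self.fractions[chain_label]["bound"]


def classify_frame(
    model: StructureModel,
    topology: GlycanTopology,
    spec: StateSpec,
    frame_index: int = 0,
) -> ConfigurationState:
    """Label one frame's glycan chain as bound or loose by the contact-count rule."""
    topology.check_resolvable(model)
    contact_spec = geometry.ContactSpec(
        selection_a=topology.selection(spec.probe_indices),
        selection_b=spec.reference,
        cutoff=spec.cutoff,
        count_unit="residues-of-b",
    )
    count = geometry.contact_count(model, contact_spec)
    label = "loose" if count <= spec.loose_threshold else "bound"
    return ConfigurationState(
        frame_index=frame_index,
        chain_label=topology.label or topology.chain_id,
        label=label,
        contact_count=count,
    )


def classify_trajectory(
    trajectory: Trajectory,
    topologies: list[GlycanTopology],
    spec: StateSpec,
    frame_window: tuple[int, int | None] | None = None,
) -> list[ConfigurationState]:
    """Per-frame, per-chain classification over the window (audit record)."""
    idx = geometry._window_indices(len(trajectory), frame_window)
    states: list[ConfigurationState] = []
    for i in idx:
        for topo in topologies:
            states.append(classify_frame(trajectory[i], topo, spec, frame_index=i))
    return states


def state_fractions(
    trajectory: Trajectory,
    topologies: list[GlycanTopology],
    spec: StateSpec,
    frame_window: tuple[int, int | None] | None = None,
) -> StateSummary:
    """Fraction of analyzed frames each glycan chain spends bound vs loose."""
    idx = geometry._window_indices(len(trajectory), frame_window)
    if len(idx) == 0:
        raise ValueError("empty frame window")
    states = classify_trajectory(trajectory, topologies, spec, frame_window)
    fractions: dict[str, dict[str, float]] = {}
    for topo in topologies:
        label = topo.label or topo.chain_id
        chain_states = [s for s in states if s.chain_label == label]
        n = len(chain_states)
        loose = sum(1 for s in chain_states if s.label == "loose")
        fractions[label] = {"loose": loose / n, "bound": (n - loose) / n}
    return StateSummary(fractions=fractions, n_frames=len(idx), frame_window=frame_window)


# ---------------------------------------------------------------------------
# lectin accessibility


@dataclass(frozen=True)
class AccessibilityGeometry:
    """Entrance-plane frame and probe for the cavity-accessibility test.

    All lengths are nm.  The entrance is an ellipse in the plane through
    ``origin`` with unit ``normal`` pointing out of the cavity;
    ``major_axis`` is the in-plane direction of the semi-major axis.
    Defaults model the Fc cavity opening (semi-axes 1.75 × 1.0 nm, i.e. a
    3.5 × 2 nm opening) and a DC-SIGN CRD probe of 1.5 nm radius; contact
    distance is given in Å (3.0 Å default).
    """

    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    normal: tuple[float, float, float] = (0.0, 0.0, 1.0)
    major_axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    semi_major_nm: float = 1.75
    semi_minor_nm: float = 1.0
    probe_radius_nm: float = 1.5
    contact_distance_angstrom: float = 3.0

    def __post_init__(self) -> None:
        if self.semi_major_nm <= 0 or self.semi_minor_nm <= 0:
            raise ValueError("semi-axes must be positive")
        if self.probe_radius_nm <= 0:
            raise ValueError("probe radius must be positive")
        n = np.asarray(self.normal, float)
        m = np.asarray(self.major_axis, float)
        if np.linalg.norm(n) == 0 or np.linalg.norm(m) == 0:
            raise ValueError("normal and major_axis must be non-zero")
        if abs(np.dot(n / np.linalg.norm(n), m / np.linalg.norm(m))) > 1e-6:
            raise ValueError("major_axis must lie in the entrance plane")

    @property
    def contact_distance_nm(self) -> float:
        return self.contact_distance_angstrom / 10.0


def _ellipse_distance_2d(point: np.ndarray, a: float, b: float) -> float:
    """Distance from a 2D point to the solid ellipse (0 inside), robust bisection."""
    px, py = abs(point[0]), abs(point[1])
    if (px / a) ** 2 + (py / b) ** 2 <= 1.0:
        return 0.0
    # nearest boundary point solves px*a/(t+a^2) , py*b/(t+b^2) on the ellipse
    f = lambda t: (px * a / (t + a * a)) ** 2 + (py * b / (t + b * b)) ** 2 - 1.0
    lo = -min(a, b) ** 2 + 1e-15
    hi = max(px * a, py * b) + max(a, b) ** 2
    while f(hi) > 0:
        hi *= 2
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            lo = mid
        else:
            hi = mid
    t = 0.5 * (lo + hi)
    qx = px * a * a / (t + a * a)
    qy = py * b * b / (t + b * b)
    return float(np.hypot(px - qx, py - qy))


def accessibility_check(
    mannose_coordinates_nm, geometry_spec: AccessibilityGeometry
) -> dict:
    """Can the probe sphere reach the target mannose atom(s)?

    The probe centre may sit anywhere fully outside the entrance plane
    (signed height ≥ probe radius) or, if the ellipse shrunk by the probe
    radius along each semi-axis is still non-degenerate, anywhere in the
    elliptical channel through that shrunk opening.  ``clearance_nm`` is the
    minimal probe-surface-to-atom distance achievable over targets and
    allowed centres; the target is accessible when that clearance is within
    the contact distance (boundary inclusive).  A probe wider than the
    opening is reported as blocked, not an error.
    """
    pts = np.atleast_2d(np.asarray(mannose_coordinates_nm, dtype=float))
    if pts.shape[1] != 3:
        raise ValueError("coordinates must be (n, 3)")
    g = geometry_spec
    o = np.asarray(g.origin, float)
    n = np.asarray(g.normal, float)
    n = n / np.linalg.norm(n)
    e1 = np.asarray(g.major_axis, float)
    e1 = e1 / np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    r = g.probe_radius_nm
    a_shrunk = g.semi_major_nm - r
    b_shrunk = g.semi_minor_nm - r
    channel_open = a_shrunk > 0 and b_shrunk > 0

    clearances = []
    for t in pts:
        rel = t - o
        h = float(np.dot(rel, n))  # signed height; >0 outside the cavity
        d_halfspace = max(0.0, r - h)  # to centres with height >= r
        d_centre = d_halfspace
        if channel_open:
            uv = np.array([np.dot(rel, e1), np.dot(rel, e2)])
            d_channel = _ellipse_distance_2d(uv, a_shrunk, b_shrunk)
            d_centre = min(d_centre, d_channel)
        clearances.append(max(0.0, d_centre - r))
    clearance = float(min(clearances))
    # boundary inclusive, robust to float rounding of the Å->nm conversion
    return {
        "accessible": clearance <= g.contact_distance_nm + 1e-9,
        "clearance_nm": clearance,
        "channel_open": channel_open,
        "n_targets": int(pts.shape[0]),
    }
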