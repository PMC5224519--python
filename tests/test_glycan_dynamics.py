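"""Glycan state classification, trajectory fractions, and probe accessibility."""

import numpy as np
import pytest

from fcbind.glycan_dynamics import (
    AccessibilityGeometry,
    GlycanTopology,
    GlycanTopologyError,
    StateSpec,
    accessibility_check,
    classify_frame,
    state_fractions,
)
from fcbind.structure_io import Selection, Trajectory
from fcbind.synthetic_data import TrajectoryRecipe, make_glycan_state_trajectory

from conftest import random_rotation


def _fixture(**kw):
    return make_glycan_state_trajectory(TrajectoryRecipe(**kw))


def test_threshold_rule_two_or_fewer_contacts_is_loose():
    """Counts at/below the threshold are loose; above it, bound."""
    for count, expected in [(0, "loose"), (2, "loose"), (3, "bound"), (5, "bound")]:
        n_loose = 1 if count <= 2 else 0
        fx = _fixture(
            n_frames=1,
            n_loose=n_loose,
            loose_contacts=count if n_loose else 1,
            bound_contacts=count if not n_loose else 5,
        )
        state = classify_frame(fx.trajectory[0], fx.topology, fx.state_spec)
        assert state.contact_count == count
        assert state.label == expected


def test_translated_glycan_has_zero_contacts_and_is_loose():
    fx = _fixture(n_frames=1, n_loose=0)
    frame = fx.trajectory[0]
    moved_atoms = []
    for a in frame.atoms:
        if a.residue_name in ("NAG", "BMA", "MAN"):
            a = type(a)(**{**a.__dict__, "z": a.z + 50.0})
        moved_atoms.append(a)
    moved = type(frame)(1, moved_atoms)
    state = classify_frame(moved, fx.topology, fx.state_spec)
    assert state.contact_count == 0
    assert state.label == "loose"


def test_classification_is_rigid_motion_invariant():
    fx = _fixture(n_frames=4, n_loose=2, seed=9)
    rng = np.random.default_rng(0)
    for i, frame in enumerate(fx.trajectory):
        ref = classify_frame(frame, fx.topology, fx.state_spec)
        moved = frame.transformed(random_rotation(rng), rng.normal(scale=30, size=3))
        got = classify_frame(moved, fx.topology, fx.state_spec)
        assert (got.label, got.contact_count) == (ref.label, ref.contact_count)


def test_unresolvable_glycan_residue_names_its_index():
    fx = _fixture(n_frames=1, n_loose=0)
    bad = GlycanTopology(
        attachment=("A", 1),
        residues=tuple(("A", 900 + i, n) for i, n in enumerate(
            ("NAG", "NAG", "BMA", "MAN", "MAN", "MAN", "MAN"), start=1)),
    )
    with pytest.raises(GlycanTopologyError, match="residue 1"):
        classify_frame(fx.trajectory[0], bad, fx.state_spec)


def test_designed_fractions_are_reproduced_exactly():
    fx = _fixture(n_frames=100, n_loose=34, seed=2)
    summary = state_fractions(fx.trajectory, [fx.topology], fx.state_spec)
    assert summary.loose_fraction("glycan-1") == pytest.approx(0.34)
    assert summary.bound_fraction("glycan-1") == pytest.approx(0.66)
    assert summary.fractions["glycan-1"]["loose"] + summary.fractions["glycan-1"]["bound"] == pytest.approx(1.0, abs=1e-12)


def test_all_bound_trajectory_has_zero_loose_fraction():
    fx = _fixture(n_frames=20, n_loose=0)
    summary = state_fractions(fx.trajectory, [fx.topology], fx.state_spec)
    assert summary.loose_fraction("glycan-1") == 0.0


def test_sampled_fractions_recovered_within_three_standard_errors():
    p = 0.345
    n = 2000
    fx = _fixture(n_frames=n, p_loose=p, seed=123)
    summary = state_fractions(fx.trajectory, [fx.topology], fx.state_spec)
    se = np.sqrt(p * (1 - p) / n)
    assert abs(summary.loose_fraction("glycan-1") - p) <= 3 * se
    # classification must also agree frame-by-frame with the generated truth
    assert summary.loose_fraction("glycan-1") == pytest.approx(fx.true_loose_fraction)


def test_raising_loose_threshold_never_converts_loose_to_bound():
    fx = _fixture(n_frames=30, n_loose=10, seed=4)
    base = fx.state_spec
    loose_at = {
        s.frame_index
        for s in (classify_frame(fx.trajectory[i], fx.topology, base, i) for i in range(30))
        if s.label == "loose"
    }
    higher = StateSpec(
        reference=base.reference,
        probe_indices=base.probe_indices,
        cutoff=base.cutoff,
        loose_threshold=base.loose_threshold + 2,
    )
    loose_higher = {
        s.frame_index
        for s in (classify_frame(fx.trajectory[i], fx.topology, higher, i) for i in range(30))
        if s.label == "loose"
    }
    assert loose_at <= loose_higher


def test_concatenated_trajectories_average_frame_weighted():
    fx1 = _fixture(n_frames=40, n_loose=10, seed=5)
    fx2 = _fixture(n_frames=60, n_loose=30, seed=6)
    merged = Trajectory(fx1.trajectory.frames + fx2.trajectory.frames)
    s1 = state_fractions(fx1.trajectory, [fx1.topology], fx1.state_spec)
    s2 = state_fractions(fx2.trajectory, [fx2.topology], fx2.state_spec)
    sm = state_fractions(merged, [fx1.topology], fx1.state_spec)
    expected = (40 * s1.loose_fraction("glycan-1") + 60 * s2.loose_fraction("glycan-1")) / 100
    assert sm.loose_fraction("glycan-1") == pytest.approx(expected, abs=1e-12)


def test_empty_frame_window_is_an_error():
    fx = _fixture(n_frames=5, n_loose=0)
    with pytest.raises(ValueError, match="empty"):
        state_fractions(fx.trajectory, [fx.topology], fx.state_spec, frame_window=(5, None))


# ---------------------------------------------------------------------------
# accessibility


def test_target_at_entrance_centre_is_accessible():
    result = accessibility_check([(0.0, 0.0, 0.0)], AccessibilityGeometry())
    assert result["accessible"]
    assert result["clearance_nm"] == pytest.approx(0.0, abs=1e-9)


def test_probe_wider_than_opening_blocks_buried_target():
    """A 1.5 nm probe cannot pass a 1.0 nm semi-minor opening to a target 1 nm deep."""
    geo = AccessibilityGeometry(semi_minor_nm=1.0, probe_radius_nm=1.5)
    result = accessibility_check([(0.0, 0.0, -1.0)], geo)
    assert not result["channel_open"]
    assert not result["accessible"]
    assert result["clearance_nm"] == pytest.approx(1.0, abs=1e-9)


def test_small_probe_reaches_deep_target_through_open_channel():
    geo = AccessibilityGeometry(probe_radius_nm=0.5)
    result = accessibility_check([(0.0, 0.0, -3.0)], geo)
    assert result["channel_open"]
    assert result["accessible"]
    assert result["clearance_nm"] == pytest.approx(0.0, abs=1e-9)


def test_contact_distance_boundary_is_accessible_with_clearance_equal_contact():
    """Target exactly one contact distance beyond the deepest probe surface point."""
    geo = AccessibilityGeometry(semi_minor_nm=1.0, probe_radius_nm=1.5, contact_distance_angstrom=3.0)
    # blocked probe: deepest surface point below the entrance-plane origin is the
    # tangent point at depth 0; a target 0.3 nm inside sits exactly at contact range
    result = accessibility_check([(0.0, 0.0, -0.3)], geo)
    assert result["clearance_nm"] == pytest.approx(geo.contact_distance_nm, abs=1e-9)
    assert result["accessible"]
    just_beyond = accessibility_check([(0.0, 0.0, -0.3 - 1e-6)], geo)
    assert not just_beyond["accessible"]


def test_off_axis_target_outside_shrunk_ellipse_uses_lateral_clearance():
    geo = AccessibilityGeometry(
        semi_major_nm=2.0, semi_minor_nm=2.0, probe_radius_nm=1.0, contact_distance_angstrom=3.0
    )
    # circular opening, shrunk radius 1.0; target 2 nm deep at lateral offset 2.0
    result = accessibility_check([(2.0, 0.0, -2.0)], geo)
    # nearest channel centre is at lateral distance 1.0 -> clearance 1.0 - r = 0
    assert result["clearance_nm"] == pytest.approx(0.0, abs=1e-9)


def test_degenerate_geometry_is_rejected():
    with pytest.raises(ValueError):
        AccessibilityGeometry(semi_major_nm=0.0)
    with pytest.raises(ValueError):
        AccessibilityGeometry(normal=(0, 0, 1), major_axis=(0, 0, 1))
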