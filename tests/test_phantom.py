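"""Gesture templates, transition dynamics, confounders, session streams."""

import numpy as np
import pytest

from eitgest.phantom import (
    ConfounderModel,
    GestureTemplate,
    Inclusion,
    SessionSimulator,
    SessionSpec,
    TransitionProfile,
    apply_confounder,
    default_templates,
    make_gesture_field,
    make_participant,
    relabel_channels_for_rotation,
    simulate_session,
    Participant,
)
from eitgest.protocol import GESTURES


def test_nine_templates_with_rest_empty():
    t = default_templates()
    assert set(t) == set(GESTURES)
    assert t["rest"].inclusions == ()
    for tpl in t.values():
        for inc in tpl.inclusions:
            assert np.hypot(*inc.center) + inc.radius <= 1.0


def test_power_and_thumb_share_three_inclusions_but_differ_in_order():
    t = default_templates()
    power = {tuple(np.round(i.center, 6)) for i in t["power"].inclusions}
    thumb = {tuple(np.round(i.center, 6)) for i in t["thumb"].inclusions}
    assert len(power & thumb) == 3
    shared = sorted(power & thumb)
    lag_p = [i.onset_lag for i in t["power"].inclusions if tuple(np.round(i.center, 6)) in shared]
    lag_t = [i.onset_lag for i in t["thumb"].inclusions if tuple(np.round(i.center, 6)) in shared]
    assert lag_p != lag_t  # finger order differs


def test_inclusion_outside_disk_rejected():
    with pytest.raises(ValueError):
        Inclusion((0.95, 0.0), 0.2, 0.3)


def test_rest_and_zero_activation_leave_base_unchanged(mesh_small):
    base = np.full(mesh_small.n_elements, 0.3)
    t = default_templates()
    out = make_gesture_field(t["rest"], 1.0, base, mesh_small)
    assert np.array_equal(out, base)
    out = make_gesture_field(t["pointer"], 0.0, base, mesh_small)
    assert np.array_equal(out, base)


def test_modified_element_count_matches_point_in_circle_oracle(mesh_small):
    base = np.ones(mesh_small.n_elements)
    t = default_templates()["pointer"]
    out = make_gesture_field(t, 1.0, base, mesh_small)
    changed = np.flatnonzero(out != base)
    # brute-force geometric oracle over element centroids
    cent = mesh_small.node_coords[mesh_small.elements].mean(axis=1)
    inside = np.zeros(mesh_small.n_elements, dtype=bool)
    for inc in t.inclusions:
        inside |= (cent[:, 0] - inc.center[0]) ** 2 + (
            cent[:, 1] - inc.center[1]
        ) ** 2 <= inc.radius**2
    assert np.array_equal(changed, np.flatnonzero(inside))


def test_transition_profile_contract():
    for dur in (0.4, 0.8, 1.2):
        p = TransitionProfile(dur)
        ts = np.linspace(0.0, dur, 101)
        vals = p(ts)
        assert vals[0] == 0.0
        assert vals[-1] >= 0.99
        assert np.all(np.diff(vals) >= -1e-12)
        assert p(-0.1) == 0.0 and p(dur + 1.0) == 1.0


def test_confounder_none_is_identity(mesh_small):
    p = make_participant(seed=0)
    assert apply_confounder(p, ConfounderModel("none")) is p


def test_unknown_confounder_kind_rejected():
    with pytest.raises(ValueError):
        ConfounderModel("gravity")


def test_whole_pitch_rotation_with_relabel_is_identity(mesh_small, protocol):
    """Rotating a homogeneous phantom by one full pitch and cyclically
    relabelling the channels reproduces the frame (16-fold symmetry)."""
    sim = SessionSimulator(mesh_small, protocol)
    sigma = np.full(mesh_small.n_elements, 0.3)
    v = sim.solver.solve(sigma)
    v_rot = relabel_channels_for_rotation(v, 1)
    assert np.abs(v_rot - v).max() / np.abs(v).max() < 1e-9


def test_limb_position_shifts_rest_baseline(mesh_small, protocol):
    """A limb-position change alone (no gesture) moves the boundary
    voltages away from the unperturbed rest reference."""
    p = make_participant(seed=1)
    sim = SessionSimulator(mesh_small, protocol)
    v0 = sim.solver.solve(p.base_field(mesh_small))
    p_limb = apply_confounder(p, ConfounderModel("limb_L", seed=3))
    v1 = sim.solver.solve(p_limb.base_field(mesh_small))
    assert np.abs(v1 - v0).max() / np.abs(v0).max() > 1e-3


def test_contact_rotation_moves_inclusions_clockwise():
    p = make_participant(seed=2)
    rot = apply_confounder(p, ConfounderModel("contact", rotation_frac=0.5))
    a0 = np.arctan2(*p.anatomy[0].center[::-1])
    a1 = np.arctan2(*rot.anatomy[0].center[::-1])
    d = (a1 - a0 + np.pi) % (2 * np.pi) - np.pi
    assert np.isclose(d, -0.5 * 2 * np.pi / 16)


def test_labeled_frame_counts_follow_protocol_arithmetic():
    # printed protocol: 10 reps -> 6210 labelled frames, 5 reps -> 3105
    assert SessionSpec(reps_per_gesture=10).n_labeled_frames == 6210
    assert SessionSpec(reps_per_gesture=5).n_labeled_frames == 3105


def test_session_streams_are_deterministic_and_fully_labelled(mesh_small, protocol):
    sim = SessionSimulator(mesh_small, protocol)
    p = make_participant(seed=0)
    spec = SessionSpec(reps_per_gesture=1, seed=42)
    f1 = simulate_session(spec, p, simulator=sim)
    f2 = simulate_session(spec, p, simulator=sim)
    assert len(f1) == len(GESTURES) * 1 * int(8.0 * 23)
    assert sum(f.gesture_label is not None for f in f1) == spec.n_labeled_frames
    assert all(np.array_equal(a.voltages, b.voltages) for a, b in zip(f1, f2))
    # every frame inside the instructed 3 s carries the instructed label
    for i, f in enumerate(f1):
        within = (i % 184) < 69
        assert (f.gesture_label is not None) == within


def test_noiseless_steady_state_frames_are_identical(mesh_small, protocol):
    sim = SessionSimulator(mesh_small, protocol)
    p = make_participant(seed=0)
    spec = SessionSpec(
        reps_per_gesture=1, noise_snr_db=np.inf, transition_range=(0.4, 0.4), seed=7
    )
    frames = simulate_session(spec, p, simulator=sim)
    # late instructed-period frames of one repetition share the plateau field
    rep = frames[40:68]
    assert all(np.array_equal(f.voltages, rep[0].voltages) for f in rep)


def test_gesture_separation_exceeds_noise_spread(mesh_small, protocol):
    """Steady-state frames of distinct gestures are farther apart than the
    within-gesture measurement-noise spread (fixed seed)."""
    sim = SessionSimulator(mesh_small, protocol)
    p = make_participant(seed=0)
    frames = simulate_session(
        SessionSpec(reps_per_gesture=2, activation_jitter=0.0, seed=11),
        p,
        simulator=sim,
    )
    steady = {}
    for i, f in enumerate(frames):
        if f.gesture_label is not None and 45 <= (i % 184) < 69:
            steady.setdefault(f.gesture_label, []).append(f.voltages)
    # statistical separation: the distance between steady-state mean
    # patterns must exceed several standard errors of those means even for
    # the deliberately similar power/thumb pair
    gestures = list(steady)
    n_frames = min(len(v) for v in steady.values())
    sem = max(
        np.linalg.norm(np.std(np.stack(v), axis=0)) for v in steady.values()
    ) / np.sqrt(n_frames)
    between = min(
        np.linalg.norm(np.mean(steady[a], axis=0) - np.mean(steady[b], axis=0))
        for i, a in enumerate(gestures)
        for b in gestures[i + 1 :]
    )
    assert between > 3.0 * sem


def test_time_drift_grows_and_relabels_condition(mesh_small, protocol):
    sim = SessionSimulator(mesh_small, protocol)
    p = make_participant(seed=0)
    spec = SessionSpec(reps_per_gesture=1, noise_snr_db=np.inf, seed=3)
    clean = simulate_session(spec, p, simulator=sim)
    drift = simulate_session(
        spec, p, confounder=ConfounderModel("time", seed=5), simulator=sim
    )
    assert all(f.condition_label == "time" for f in drift)
    rel_first = np.abs(drift[0].voltages / clean[0].voltages - 1.0).max()
    rel_last = np.abs(drift[-1].voltages / clean[-1].voltages - 1.0).max()
    assert rel_last > rel_first
    assert rel_last < 0.2  # slow drift, not a gross distortion


def test_participant_jitter_distinguishes_seeds(mesh_small):
    a = make_participant(seed=0)
    b = make_participant(seed=1)
    ca = a.templates["power"].inclusions[0].center
    cb = b.templates["power"].inclusions[0].center
    assert not np.allclose(ca, cb)
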