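"""Synthetic forearm phantoms and session simulation.

Gestures are emulated as sets of circular conductivity inclusions placed
near the angular positions of the forearm muscles that drive each hand
movement (electrode 0 sits over the extensor carpi radialis).  A session
reproduces the acquisition protocol: for every gesture instruction the
phantom ramps from rest to the gesture over a random 0.4-1.2 s transient,
holds for the 3 s instructed period, and relaxes during the 5 s interval;
frames are emitted at 23 fps and only frames inside the instructed period
carry the gesture label.  Three confounding-factor families perturb the
sessions: limb-position changes (smooth background conductivity shift
plus small inclusion displacements), slow multiplicative per-channel
drift (long-wear interference), and armband rotation by a fraction of an
electrode pitch (contact interference, implemented as the equivalent
counter-rotation of the phantom geometry so the mesh and its electrode
discretisation stay fixed).

"power" and "thumb" deliberately share three of four inclusions — the
same four-finger flexor chain — and differ in their onset-lag ordering,
so their steady-state patterns are similar while their transient states
differ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from eitgest.forward import FEMSolver
from eitgest.mesh import Mesh
from eitgest.protocol import GESTURES, DriveProtocol, MeasurementFrame

#: Background (rest) conductivity, S/m — bulk soft tissue at 100 kHz.
SIGMA0 = 0.3

#: Target upper bound of the baseline voltage span, mV.
BASELINE_VMAX = 800.0


def _pol(r, deg):
    a = math.radians(deg)
    return np.array([r * math.cos(a), r * math.sin(a)])


@dataclass(frozen=True)
class Inclusion:
    """A circular conductivity inclusion.

    ``contrast`` is the signed relative change of conductivity at full
    activation (sigma -> sigma * (1 + contrast)); ``onset_lag`` delays
    this inclusion's ramp relative to the gesture onset (finger-order
    effects), seconds.
    """

    center: np.ndarray
    radius: float
    contrast: float
    onset_lag: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if np.hypot(*self.center) + self.radius > 1.0 + 1e-12:
            raise ValueError("inclusion extends outside the unit disk")
        if self.contrast <= -1.0:
            raise ValueError("contrast must keep conductivity positive")


@dataclass(frozen=True)
class GestureTemplate:
    """Inclusion set of one gesture; 'rest' has no inclusions."""

    gesture_id: str
    inclusions: tuple = ()

    def __post_init__(self):
        if self.gesture_id not in GESTURES:
            raise ValueError(f"unknown gesture {self.gesture_id!r}")


# Angular positions (degrees) of the stylised forearm muscles used below:
# extensors on the posterolateral aspect near electrode 0, flexors on the
# anteromedial aspect.  Purely stylised anatomy, not subject-specific.
_M = {
    "ECR": 5,    # extensor carpi radialis (under electrode 0)
    "EI": 30,    # extensor indicis
    "ED": 60,    # extensor digitorum
    "ECU": 90,   # extensor carpi ulnaris
    "EPB": 100,  # extensor pollicis brevis
    "FPL": 130,  # flexor pollicis longus
    "FCR": 160,  # flexor carpi radialis
    "FDS": 190,  # flexor digitorum superficialis
    "FDP": 215,  # flexor digitorum profundus
    "PT": 250,   # pronator teres
    "SUP": 300,  # supinator
    "BR": 330,   # brachioradialis
}


def default_templates() -> dict:
    """The nine gesture templates (2-4 inclusions each, stylised anatomy)."""
    I = Inclusion
    # The shared flexor chain of power & thumb (same four-finger movement).
    shared = (
        I(_pol(0.55, _M["FDS"]), 0.16, 0.35, 0.00),
        I(_pol(0.55, _M["FDP"]), 0.15, 0.30, 0.10),
        I(_pol(0.55, _M["FCR"]), 0.13, 0.25, 0.20),
    )
    shared_rev = tuple(
        replace(inc, onset_lag=0.20 - inc.onset_lag) for inc in shared
    )
    t = {
        "pointer": (
            I(_pol(0.55, _M["EI"]), 0.14, 0.35, 0.00),
            I(_pol(0.55, _M["FDS"]), 0.15, 0.25, 0.15),
        ),
        "power": shared + (I(_pol(0.50, _M["FPL"]), 0.13, 0.25, 0.30),),
        "thumb": shared_rev + (I(_pol(0.52, _M["EPB"]), 0.12, 0.22, 0.00),),
        "pronation": (
            I(_pol(0.50, _M["PT"]), 0.17, 0.40, 0.00),
            I(_pol(0.55, _M["BR"]), 0.13, 0.20, 0.10),
        ),
        "supination": (
            I(_pol(0.52, _M["SUP"]), 0.17, 0.40, 0.00),
            I(_pol(0.55, _M["BR"]), 0.13, -0.20, 0.10),
        ),
        "tripod": (
            I(_pol(0.55, _M["FDS"]), 0.14, 0.30, 0.00),
            I(_pol(0.55, _M["EI"]), 0.12, 0.20, 0.10),
            I(_pol(0.50, _M["FPL"]), 0.13, 0.25, 0.20),
        ),
        "victory": (
            I(_pol(0.55, _M["EI"]), 0.14, 0.30, 0.00),
            I(_pol(0.55, _M["ED"]), 0.14, 0.25, 0.10),
        ),
        "open": (
            I(_pol(0.55, _M["ED"]), 0.16, 0.35, 0.00),
            I(_pol(0.58, _M["ECR"]), 0.13, 0.25, 0.10),
            I(_pol(0.55, _M["ECU"]), 0.13, 0.20, 0.20),
        ),
        "rest": (),
    }
    return {g: GestureTemplate(g, t[g]) for g in GESTURES}


#: Static background anatomy: two low-conductivity bone-like inclusions
#: (radius/ulna) that make the rest phantom inhomogeneous, so armband
#: rotation shifts the baseline pattern as it does on a real forearm.
def default_anatomy() -> tuple:
    return (
        Inclusion(_pol(0.28, 225), 0.14, -0.60),
        Inclusion(_pol(0.30, 300), 0.12, -0.55),
    )


@dataclass
class Participant:
    """One emulated participant: anatomy + gesture templates + base sigma."""

    templates: dict
    anatomy: tuple = field(default_factory=default_anatomy)
    sigma0: float = SIGMA0
    background: tuple = ()  # extra background inclusions (confounders)

    def base_field(self, mesh: Mesh) -> np.ndarray:
        sigma = np.full(mesh.n_elements, self.sigma0)
        for inc in self.anatomy + tuple(self.background):
            _apply_inclusion(sigma, inc, 1.0, mesh)
        return sigma


def make_participant(seed: int | None = None, jitter: float = 0.04) -> Participant:
    """Build a participant, optionally jittering template geometry.

    Distinct seeds stand in for distinct participants: inclusion centres
    are displaced by up to ``jitter`` (domain radii) and radii/contrasts
    scaled by a few percent.
    """
    templates = default_templates()
    anatomy = default_anatomy()
    if seed is not None:
        rng = np.random.default_rng(seed)

        def jit(inc: Inclusion) -> Inclusion:
            c = inc.center + rng.uniform(-jitter, jitter, 2)
            r = inc.radius * (1 + rng.uniform(-0.1, 0.1))
            k = inc.contrast * (1 + rng.uniform(-0.1, 0.1))
            if np.hypot(*c) + r > 1.0:
                c = c / np.hypot(*c) * (1.0 - r - 1e-6)
            return Inclusion(c, r, k, inc.onset_lag)

        templates = {
            g: GestureTemplate(g, tuple(jit(i) for i in t.inclusions))
            for g, t in templates.items()
        }
        anatomy = tuple(jit(i) for i in anatomy)
    return Participant(templates=templates, anatomy=anatomy)


def _apply_inclusion(sigma, inc: Inclusion, activation: float, mesh: Mesh) -> None:
    cent = getattr(mesh, "_centroid_cache", None)
    if cent is None:
        cent = mesh.element_centroids()
        mesh._centroid_cache = cent
    inside = np.hypot(cent[:, 0] - inc.center[0], cent[:, 1] - inc.center[1]) <= inc.radius
    sigma[inside] *= 1.0 + inc.contrast * activation


def make_gesture_field(
    template: GestureTemplate,
    activation,
    base: np.ndarray,
    mesh: Mesh,
) -> np.ndarray:
    """Apply a gesture template to a base conductivity field.

    ``activation`` is a scalar in [0, 1] or one value per inclusion;
    each inclusion's contrast is scaled by its activation and applied to
    elements whose centroid lies inside the inclusion circle.
    """
    act = np.broadcast_to(np.asarray(activation, float), (len(template.inclusions),))
    if np.any(act < -1e-12) or np.any(act > 1 + 1e-12):
        raise ValueError("activation must lie in [0, 1]")
    sigma = np.asarray(base, float).copy()
    for inc, a in zip(template.inclusions, act):
        if a > 0:
            _apply_inclusion(sigma, inc, float(a), mesh)
    return sigma


@dataclass(frozen=True)
class TransitionProfile:
    """Smooth monotone rest-to-gesture ramp (normalised logistic).

    Exactly 0 at onset and 1 at ``duration``; monotone non-decreasing.
    """

    duration: float
    steepness: float = 10.0

    def __post_init__(self):
        if not 0.0 < self.duration:
            raise ValueError("duration must be positive")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        k = self.steepness / self.duration
        raw = 1.0 / (1.0 + np.exp(-k * (t - self.duration / 2)))
        r0 = 1.0 / (1.0 + np.exp(k * self.duration / 2))
        r1 = 1.0 / (1.0 + np.exp(-k * self.duration / 2))
        out = (raw - r0) / (r1 - r0)
        return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Confounding factors.

_LIMB_DIRS = {"L": (-1.0, 0.0), "R": (1.0, 0.0), "U": (0.0, 1.0), "D": (0.0, -1.0)}


@dataclass(frozen=True)
class ConfounderModel:
    """One confounding-factor family.

    kind:
      * ``none`` — identity.
      * ``limb_L/R/U/D`` — low-amplitude smooth background conductivity
        perturbation offset towards the given direction plus a small
        rigid shift of all inclusion centres.
      * ``time`` — slow multiplicative per-channel baseline drift
        ``g(t) = 1 + A_ch (1 - exp(-t/tau))``.
      * ``contact`` — armband rotation by ``rotation_frac`` electrode
        pitches (anticlockwise), applied as the equivalent clockwise
        rotation of the phantom geometry, plus small per-electrode
        contact-gain perturbations (the measurement-level trace of the
        disturbed electrode-skin interface).
    """

    kind: str = "none"
    limb_amplitude: float = 0.03
    limb_shift: float = 0.02
    drift_amplitude: float = 0.02
    drift_tau: float = 60.0
    rotation_frac: float = 0.5
    contact_gain_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        valid = ("none", "limb_L", "limb_R", "limb_U", "limb_D", "time", "contact")
        if self.kind not in valid:
            raise ValueError(f"unknown confounder kind {self.kind!r}")

    @property
    def condition_label(self) -> str:
        return self.kind


def _rotate_inclusions(incs, angle: float):
    c, s = math.cos(angle), math.sin(angle)
    R = np.array([[c, -s], [s, c]])
    return tuple(replace(i, center=R @ i.center) for i in incs)


def _shift_inclusions(incs, shift):
    out = []
    for i in incs:
        c = i.center + shift
        r = np.hypot(*c)
        if r + i.radius > 1.0:
            c = c / r * (1.0 - i.radius - 1e-6)
        out.append(replace(i, center=c))
    return tuple(out)


def apply_confounder(target, model: ConfounderModel, n_electrodes: int = 16):
    """Apply a confounder to a participant (geometry) or frame stream.

    * ``Participant`` + limb/contact kinds -> perturbed participant.
    * list of :class:`MeasurementFrame` + ``time`` kind -> drifted copy.
    * ``kind='none'`` -> the input unchanged.
    """
    if model.kind == "none":
        return target
    if isinstance(target, Participant):
        if model.kind.startswith("limb_"):
            d = np.asarray(_LIMB_DIRS[model.kind[-1]])
            rng = np.random.default_rng(model.seed)
            shift = model.limb_shift * d
            blob = Inclusion(
                center=0.45 * d,
                radius=0.5,
                contrast=model.limb_amplitude * rng.choice([-1.0, 1.0]),
            )
            templates = {
                g: GestureTemplate(g, _shift_inclusions(t.inclusions, shift))
                for g, t in target.templates.items()
            }
            return Participant(
                templates=templates,
                anatomy=_shift_inclusions(target.anatomy, shift),
                sigma0=target.sigma0,
                background=target.background + (blob,),
            )
        if model.kind == "contact":
            angle = -model.rotation_frac * 2 * np.pi / n_electrodes
            templates = {
                g: GestureTemplate(g, _rotate_inclusions(t.inclusions, angle))
                for g, t in target.templates.items()
            }
            return Participant(
                templates=templates,
                anatomy=_rotate_inclusions(target.anatomy, angle),
                sigma0=target.sigma0,
                background=_rotate_inclusions(target.background, angle),
            )
        if model.kind == "time":
            return target  # drift acts on measurements, not geometry
        raise ValueError(f"cannot apply {model.kind!r} to a participant")
    # frame-stream level: temporal drift
    if model.kind == "time":
        rng = np.random.default_rng(model.seed)
        n_ch = target[0].voltages.shape[0]
        amp = rng.normal(0.0, model.drift_amplitude, n_ch)
        out = []
        for f in target:
            g = 1.0 + amp * (1.0 - np.exp(-f.t / model.drift_tau))
            out.append(
                MeasurementFrame(
                    voltages=f.voltages * g,
                    t=f.t,
                    gesture_label=f.gesture_label,
                    condition_label="time",
                )
            )
        return out
    raise ValueError(f"cannot apply {model.kind!r} to a frame stream")


def contact_channel_gains(model: ConfounderModel, protocol: DriveProtocol) -> np.ndarray:
    """Per-channel gain factors of the contact confounder.

    Each electrode's contact perturbation ``delta_e ~ N(0, sd)`` is drawn
    once per block; a channel touching electrodes (a, b, c, d) is scaled
    by ``1 + delta_a + delta_b + delta_c + delta_d``.
    """
    rng = np.random.default_rng(model.seed + 1)
    delta = rng.normal(0.0, model.contact_gain_sd, protocol.n_electrodes)
    g = np.ones(protocol.n_channels)
    for ch, (a, b), (c, d) in protocol.channels():
        g[ch] = 1.0 + delta[a] + delta[b] + delta[c] + delta[d]
    return g


def relabel_channels_for_rotation(voltages: np.ndarray, k: int) -> np.ndarray:
    """Cyclically relabel channels after a rotation by ``k`` whole pitches.

    Drive ``d`` of the rotated armband coincides with drive ``d+k`` of the
    original, so the canonical channel vector is shifted by ``13*k``.
    """
    v = np.asarray(voltages)
    return np.roll(v, -13 * k, axis=-1)


# ---------------------------------------------------------------------------
# Session simulation.


@dataclass
class SessionSpec:
    """Protocol parameters of one recording block.

    Defaults follow the acquisition protocol: each gesture instructed for
    3 s followed by a 5 s rest interval, 10 repetitions per gesture in a
    training session (5 in confounder blocks), frames at 23 per second,
    additive Gaussian measurement noise at 40 dB SNR.
    """

    gestures: tuple = GESTURES
    reps_per_gesture: int = 10
    gesture_duration: float = 3.0
    rest_interval: float = 5.0
    frame_rate: float = 23.0
    noise_snr_db: float = 40.0
    transition_range: tuple = (0.4, 1.2)
    activation_jitter: float = 0.05
    onset_lag_jitter: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if min(self.gesture_duration, self.rest_interval, self.frame_rate) <= 0:
            raise ValueError("durations and frame rate must be positive")

    @property
    def frames_per_rep(self) -> int:
        # floor: instructed-period frames per repetition (69 at 3 s, 23 fps)
        return int(math.floor(self.gesture_duration * self.frame_rate))

    @property
    def n_labeled_frames(self) -> int:
        return len(self.gestures) * self.reps_per_gesture * self.frames_per_rep


class SessionSimulator:
    """Forward-solves a participant's session with conductivity caching.

    Frames that share a conductivity field (rest intervals, steady-state
    plateaus) reuse one FEM solve, which keeps a full session tractable.
    """

    def __init__(self, mesh: Mesh, protocol: DriveProtocol):
        self.mesh = mesh
        self.protocol = protocol
        self.solver = FEMSolver(mesh, protocol)
        self._cache = {}

    def solve_cached(self, sigma: np.ndarray) -> np.ndarray:
        key = hash(sigma.tobytes())
        v = self._cache.get(key)
        if v is None:
            v = self.solver.solve(sigma)
            self._cache[key] = v
        return v

    def calibrate_gain(self, participant: Participant) -> float:
        """Global gain mapping the rest baseline onto the 20-800 mV span."""
        v = self.solver.solve(participant.base_field(self.mesh))
        return BASELINE_VMAX / np.abs(v).max()


def simulate_session(
    spec: SessionSpec,
    participant: Participant,
    confounder: ConfounderModel | None = None,
    mesh: Mesh | None = None,
    protocol: DriveProtocol | None = None,
    simulator: SessionSimulator | None = None,
    gain: float | None = None,
) -> list:
    """Emit the labelled frame stream of one recording block.

    Deterministic given ``spec.seed``: transition durations (uniform in
    ``spec.transition_range``), per-repetition activation jitter,
    per-inclusion onset-lag jitter and measurement noise all come from
    one seeded generator.  Frames inside each 3 s instructed period carry
    the gesture label; interval frames are unlabelled.
    """
    confounder = confounder or ConfounderModel("none")
    if simulator is None:
        if mesh is None or protocol is None:
            raise ValueError("need either a simulator or mesh + protocol")
        simulator = SessionSimulator(mesh, protocol)
    mesh = simulator.mesh

    geo = apply_confounder(participant, confounder, simulator.protocol.n_electrodes) \
        if confounder.kind in ("limb_L", "limb_R", "limb_U", "limb_D", "contact") \
        else participant

    if gain is None:
        gain = simulator.calibrate_gain(participant)

    rng = np.random.default_rng(spec.seed)
    base = geo.base_field(mesh)
    rest_v = simulator.solve_cached(base)
    fps = spec.frame_rate
    rep_len = spec.gesture_duration + spec.rest_interval
    cond = confounder.condition_label
    noise_scale = (
        0.0
        if np.isinf(spec.noise_snr_db)
        else 10.0 ** (-spec.noise_snr_db / 20.0)
    )
    noise_sd = np.abs(rest_v) * noise_scale
    channel_gain = (
        contact_channel_gains(confounder, simulator.protocol)
        if confounder.kind == "contact"
        else None
    )

    frames = []
    rep_index = 0
    for gesture in spec.gestures:
        template = geo.templates[gesture]
        n_inc = len(template.inclusions)
        for _ in range(spec.reps_per_gesture):
            t0 = rep_index * rep_len
            # per-repetition randomness (drawn also for 'rest' to keep the
            # stream layout identical across gestures)
            up = TransitionProfile(rng.uniform(*spec.transition_range))
            down = TransitionProfile(rng.uniform(*spec.transition_range))
            amp = float(np.clip(1.0 + rng.normal(0.0, spec.activation_jitter), 0.0, 1.0))
            lags = np.array([inc.onset_lag for inc in template.inclusions])
            if n_inc:
                lags = np.clip(
                    lags + rng.uniform(-spec.onset_lag_jitter, spec.onset_lag_jitter, n_inc),
                    0.0,
                    None,
                )
            n_frames = int(math.floor(rep_len * fps))
            start_idx = int(round(t0 * fps))
            for i in range(n_frames):
                t = (start_idx + i) / fps
                tl = t - t0
                labeled = tl < spec.gesture_duration
                if n_inc == 0:
                    sigma = base
                else:
                    if tl < spec.gesture_duration:
                        act = amp * up(tl - lags)
                    else:
                        td = tl - spec.gesture_duration
                        act = amp * (1.0 - down(td)) * np.ones(n_inc)
                    # quantise activations so neighbouring ramp frames can
                    # share one FEM solve (step 0.01 is far below noise)
                    act = np.round(np.clip(act, 0.0, 1.0), 2)
                    if np.all(act == 0.0):
                        sigma = base
                    else:
                        sigma = make_gesture_field(template, act, base, mesh)
                v = simulator.solve_cached(sigma) * gain
                if channel_gain is not None:
                    v = v * channel_gain
                if noise_scale > 0.0:
                    v = v + rng.normal(0.0, 1.0, v.shape) * noise_sd * gain
                frames.append(
                    MeasurementFrame(
                        voltages=v,
                        t=t,
                        gesture_label=gesture if labeled else None,
                        condition_label=cond if cond != "time" else "none",
                    )
                )
            rep_index += 1
    if confounder.kind == "time":
        frames = apply_confounder(frames, confounder)
    return frames
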