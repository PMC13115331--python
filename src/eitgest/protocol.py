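"""Measurement protocol and frame containers.

The armband drives current through adjacent electrode pairs and measures
differential voltages across all other adjacent pairs (four-point scheme).
With 16 electrodes this yields 16 drives x 13 measurements = 208 channels.

Canonical channel order (drive-major, measurement-minor): drives are
``(k, k+1 mod 16)`` for ``k = 0..15``; for drive ``k`` the 13 measurement
pairs are ``(m, m+1 mod 16)`` with ``m = k+2, k+3, ..., k+14 (mod 16)``,
i.e. ascending counter-clockwise from the first pair not touching an
injecting electrode.  Channel index = ``13 * drive + meas_offset``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Number of measurement channels for the 16-electrode adjacent protocol.
N_CHANNELS = 208

#: The nine gesture classes, in canonical label order.
GESTURES = (
    "pointer",
    "power",
    "pronation",
    "supination",
    "thumb",
    "tripod",
    "victory",
    "open",
    "rest",
)

#: Recording conditions: clean plus the three confounding-factor families
#: (limb position in four directions, long-wear temporal drift, armband
#: rotation / contact interference).
CONDITIONS = ("none", "limb_L", "limb_R", "limb_U", "limb_D", "time", "contact")

GESTURE_TO_INT = {g: i for i, g in enumerate(GESTURES)}
CONDITION_TO_INT = {c: i for i, c in enumerate(CONDITIONS)}


@dataclass(frozen=True)
class DriveProtocol:
    """Current-drive and voltage-measurement pattern.

    Parameters
    ----------
    n_electrodes : int
        Number of boundary electrodes.
    drive_pairs : tuple of (int, int)
        Ordered (source, sink) electrode pairs.
    meas_pairs_per_drive : tuple of tuple of (int, int)
        For each drive, the ordered (v+, v-) electrode pairs.
    current_amplitude : float
        Injected current in mA.
    """

    n_electrodes: int
    drive_pairs: tuple
    meas_pairs_per_drive: tuple
    current_amplitude: float = 1.0

    @property
    def n_channels(self) -> int:
        return sum(len(m) for m in self.meas_pairs_per_drive)

    def channels(self):
        """Yield ``(channel_index, drive_pair, meas_pair)`` in canonical order."""
        ch = 0
        for d, drive in enumerate(self.drive_pairs):
            for meas in self.meas_pairs_per_drive[d]:
                yield ch, drive, meas
                ch += 1


def adjacent_protocol(n_electrodes: int = 16, current_amplitude: float = 1.0) -> DriveProtocol:
    """Build the adjacent (neighbouring-pair) drive/measurement protocol.

    For every drive ``(k, k+1)`` the measurement pairs are the adjacent
    pairs ``(m, m+1)`` that do not contain an injecting electrode,
    ascending counter-clockwise from ``m = k+2``.
    """
    if n_electrodes < 4:
        raise ValueError("adjacent protocol needs at least 4 electrodes")
    n = n_electrodes
    drives = tuple((k, (k + 1) % n) for k in range(n))
    meas = tuple(
        tuple(((k + 2 + j) % n, (k + 3 + j) % n) for j in range(n - 3))
        for k in range(n)
    )
    return DriveProtocol(n, drives, meas, current_amplitude)


@dataclass
class MeasurementFrame:
    """One EIT frame: 208 boundary voltages (mV) plus metadata.

    ``gesture_label`` is one of :data:`GESTURES` or ``None`` for frames
    outside an instructed period; ``condition_label`` is one of
    :data:`CONDITIONS`.
    """

    voltages: np.ndarray
    t: float = 0.0
    gesture_label: str | None = None
    condition_label: str = "none"

    def __post_init__(self):
        self.voltages = np.asarray(self.voltages, dtype=float)
        if self.voltages.shape != (N_CHANNELS,):
            raise ValueError(
                f"expected {N_CHANNELS} voltages, got shape {self.voltages.shape}"
            )
        if self.gesture_label is not None and self.gesture_label not in GESTURE_TO_INT:
            raise ValueError(f"unknown gesture label {self.gesture_label!r}")
        if self.condition_label not in CONDITION_TO_INT:
            raise ValueError(f"unknown condition label {self.condition_label!r}")
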