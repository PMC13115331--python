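"""Dataset assembly: frame reshaping, windowing, labelling, splits, on-disk schema.

Frames are reshaped to 16 x 16 matrices (drive-major rows, the 13
measurements of drive ``d`` in columns 0-12, columns 13-15 zero padding),
windowed into fixed-length sequences (480 ms = 11 frames at 23 fps) and
split 70-15-15 into train/validation/test.  On disk a dataset is an HDF5
file with groups ``/frames`` (per-frame tables) and ``/meta`` (config
echo); a CSV mirror is provided for portability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from eitgest.protocol import (
    CONDITIONS,
    CONDITION_TO_INT,
    GESTURES,
    GESTURE_TO_INT,
    MeasurementFrame,
    N_CHANNELS,
)

#: Measurements per drive and grid side for the 16 x 16 padded matrix.
MEAS_PER_DRIVE = 13
GRID = 16


def frame_to_matrix(frame) -> np.ndarray:
    """Reshape a 208-channel frame into the padded 16 x 16 matrix.

    Row ``d`` holds the 13 measurements of drive ``d`` in columns 0-12;
    columns 13-15 are exactly zero.  Invertible on the true channels.
    """
    v = frame.voltages if isinstance(frame, MeasurementFrame) else np.asarray(frame, float)
    if v.shape != (N_CHANNELS,):
        raise ValueError(f"expected {N_CHANNELS} channels, got {v.shape}")
    grid = np.zeros((GRID, GRID), dtype=v.dtype)
    grid[:, :MEAS_PER_DRIVE] = v.reshape(GRID, MEAS_PER_DRIVE)
    return grid


def matrix_to_frame(grid: np.ndarray) -> np.ndarray:
    """Inverse of :func:`frame_to_matrix` (returns the 208-vector)."""
    grid = np.asarray(grid)
    if grid.shape != (GRID, GRID):
        raise ValueError(f"expected {GRID}x{GRID} matrix, got {grid.shape}")
    return grid[:, :MEAS_PER_DRIVE].reshape(-1).copy()


@dataclass
class GestureSequence:
    """A fixed-length window of frames with a single gesture label.

    ``voltages`` has shape (window, 208); ``label`` indexes
    :data:`eitgest.protocol.GESTURES`.
    """

    voltages: np.ndarray
    label: int
    condition: str = "none"
    t_start: float = 0.0

    @property
    def one_hot(self) -> np.ndarray:
        y = np.zeros(len(GESTURES))
        y[self.label] = 1.0
        return y

    def matrices(self) -> np.ndarray:
        """(window, 16, 16) stack of padded frame matrices."""
        T = self.voltages.shape[0]
        out = np.zeros((T, GRID, GRID), dtype=self.voltages.dtype)
        out[:, :, :MEAS_PER_DRIVE] = self.voltages.reshape(T, GRID, MEAS_PER_DRIVE)
        return out


def window_length(window_ms: float = 480.0, frame_rate: float = 23.0) -> int:
    return int(round(window_ms / 1000.0 * frame_rate))


def window_sequences(
    frames,
    window_ms: float = 480.0,
    overlap: float = 0.875,
    frame_rate: float = 23.0,
    stride: int | None = None,
) -> list:
    """Segment a frame stream into uniformly labelled gesture windows.

    The window is ``round(window_ms/1000 * frame_rate)`` frames (11 at
    23 fps) and the stride ``max(1, round(window * (1 - overlap)))``
    unless given explicitly.  A window is kept only when every frame in
    it carries the same non-null gesture label, so windows straddling a
    label change are discarded; transition frames inside an instructed
    period carry the instructed label and are retained.
    """
    w = window_length(window_ms, frame_rate)
    if stride is None:
        stride = max(1, int(round(w * (1.0 - overlap))))
    n = len(frames)
    out = []
    if n < w:
        return out
    labels = [f.gesture_label for f in frames]
    for s in range(0, n - w + 1, stride):
        lab = labels[s]
        if lab is None:
            continue
        if any(l != lab for l in labels[s + 1 : s + w]):
            continue
        v = np.stack([frames[s + i].voltages for i in range(w)])
        out.append(
            GestureSequence(
                voltages=v,
                label=GESTURE_TO_INT[lab],
                condition=frames[s].condition_label,
                t_start=frames[s].t,
            )
        )
    return out


@dataclass
class SplitSpec:
    """70-15-15 randomised split specification."""

    fractions: tuple = (0.70, 0.15, 0.15)
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


def split_dataset(sequences, spec: SplitSpec):
    """Random disjoint train/validation/test partition.

    Sizes are within +-1 of the exact fractions; the same seed yields the
    identical split.
    """
    n = len(sequences)
    if n < 10:
        raise ValueError("need at least 10 sequences to split")
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    n_tr = int(round(spec.fractions[0] * n))
    n_va = int(round(spec.fractions[1] * n))
    n_tr = min(n_tr, n)
    n_va = min(n_va, n - n_tr)
    idx_tr, idx_va, idx_te = (
        perm[:n_tr],
        perm[n_tr : n_tr + n_va],
        perm[n_tr + n_va :],
    )
    pick = lambda idx: [sequences[i] for i in idx]
    return pick(idx_tr), pick(idx_va), pick(idx_te)


def sequences_to_arrays(sequences):
    """Stack sequences into ``(X, y)`` arrays: X (n, T, 208), y (n,) int."""
    X = np.stack([s.voltages for s in sequences])
    y = np.array([s.label for s in sequences], dtype=np.int64)
    return X, y


# ---------------------------------------------------------------------------
# On-disk schema.


def save_frames_h5(path, frames, meta: dict | None = None) -> None:
    """Write a frame stream to HDF5 (/frames tables + /meta attrs)."""
    n = len(frames)
    volts = np.stack([f.voltages for f in frames]).astype(np.float64)
    t = np.array([f.t for f in frames], dtype=np.float64)
    gest = np.array(
        [GESTURE_TO_INT.get(f.gesture_label, -1) if f.gesture_label else -1 for f in frames],
        dtype=np.int8,
    )
    cond = np.array([CONDITION_TO_INT[f.condition_label] for f in frames], dtype=np.int8)
    with h5py.File(path, "w") as h5:
        g = h5.create_group("frames")
        g.create_dataset("voltages", data=volts)
        g.create_dataset("t", data=t)
        g.create_dataset("gesture", data=gest)
        g.create_dataset("condition", data=cond)
        m = h5.create_group("meta")
        m.attrs["n_frames"] = n
        m.attrs["gestures"] = json.dumps(list(GESTURES))
        m.attrs["conditions"] = json.dumps(list(CONDITIONS))
        if meta:
            m.attrs["config"] = json.dumps(meta, default=str)


def load_frames_h5(path) -> list:
    """Read a frame stream written by :func:`save_frames_h5`."""
    with h5py.File(path, "r") as h5:
        volts = h5["frames/voltages"][:]
        t = h5["frames/t"][:]
        gest = h5["frames/gesture"][:]
        cond = h5["frames/condition"][:]
    frames = []
    for i in range(len(t)):
        frames.append(
            MeasurementFrame(
                voltages=volts[i],
                t=float(t[i]),
                gesture_label=GESTURES[gest[i]] if gest[i] >= 0 else None,
                condition_label=CONDITIONS[cond[i]],
            )
        )
    return frames


def frames_to_csv(path, frames) -> None:
    """CSV mirror of the HDF5 schema (one row per frame)."""
    rows = {
        "t": [f.t for f in frames],
        "gesture": [f.gesture_label or "" for f in frames],
        "condition": [f.condition_label for f in frames],
    }
    volts = np.stack([f.voltages for f in frames])
    df = pd.DataFrame(rows)
    vcols = pd.DataFrame(volts, columns=[f"v{i:03d}" for i in range(N_CHANNELS)])
    pd.concat([df, vcols], axis=1).to_csv(path, index=False, float_format="%.17g")


def frames_from_csv(path) -> list:
    df = pd.read_csv(path, float_precision="round_trip")
    vcols = [f"v{i:03d}" for i in range(N_CHANNELS)]
    frames = []
    for _, row in df.iterrows():
        g = row["gesture"]
        frames.append(
            MeasurementFrame(
                voltages=row[vcols].to_numpy(dtype=float),
                t=float(row["t"]),
                gesture_label=None if (pd.isna(g) or g == "") else str(g),
                condition_label=str(row["condition"]),
            )
        )
    return frames
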