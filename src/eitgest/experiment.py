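"""End-to-end experiment harness: simulate -> window -> train -> evaluate.

Reproduces the study design in silico: participants (seeds) each record
three clean training sessions plus one block per confounding factor;
windows from the clean sessions are pooled and split 70-15-15; all four
classifiers are trained on the identical training windows; every model
is then evaluated on the held-out clean test split and on the
(test-only) confounder blocks, and the models are compared with a
Friedman test over participant blocks.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from eitgest import baselines
from eitgest.data import (
    GestureSequence,
    SplitSpec,
    sequences_to_arrays,
    split_dataset,
    window_sequences,
)
from eitgest.evaluation import (
    compute_metrics,
    confusion_matrix,
    friedman_test,
)
from eitgest.mesh import build_disk_mesh
from eitgest.nn.models import FASPPGRU, FASPPGRUConfig, CNNLSTMConfig
from eitgest.nn.training import TrainConfig, train_classifier
from eitgest.phantom import (
    ConfounderModel,
    SessionSimulator,
    SessionSpec,
    make_participant,
    simulate_session,
)
from eitgest.protocol import CONDITIONS, GESTURES, adjacent_protocol

CONFOUNDER_CONDITIONS = ("limb_L", "limb_R", "limb_U", "limb_D", "time", "contact")
MODEL_NAMES = ("knn", "svm", "cnn_lstm", "faspp_gru")


@dataclass
class RunConfig:
    """Configuration of one full experiment run.

    The defaults reproduce the study conditions at desk scale: two
    emulated participants, three 10-repetition training sessions each,
    five-repetition confounder blocks, 23 fps frames at 40 dB SNR,
    480 ms windows.  ``train_stride``/``eval_stride`` control window
    density (frames between window starts) and are the main runtime
    knob; the canonical dense segmentation is stride 1.
    """

    refinement_level: int = 1
    seeds: tuple = (0, 1)
    train_sessions: int = 3
    train_reps: int = 10
    confounder_reps: int = 5
    noise_snr_db: float = 40.0
    window_ms: float = 480.0
    overlap: float = 0.875
    train_stride: int = 15
    eval_stride: int = 11
    split_fractions: tuple = (0.70, 0.15, 0.15)
    models: tuple = MODEL_NAMES
    learning_rate: float = 5e-5
    batch_size: int = 64
    max_epochs: int = 60
    patience: int = 10
    standardize: bool = True
    global_seed: int = 1
    outdir: str | None = None
    save_plots: bool = False

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _derive_seed(global_seed: int, *parts) -> int:
    h = hashlib.sha256(("/".join(map(str, (global_seed,) + parts))).encode())
    return int.from_bytes(h.digest()[:4], "little") % (2**31 - 1)


def simulate_participant(cfg: RunConfig, seed_idx: int, mesh, protocol):
    """All recording blocks of one emulated participant.

    Returns ``(train_frame_blocks, {condition: frame_block})``.
    """
    gs = cfg.global_seed
    pseed = _derive_seed(gs, "participant", seed_idx)
    participant = make_participant(seed=pseed)
    sim = SessionSimulator(mesh, protocol)
    gain = sim.calibrate_gain(participant)

    train_blocks = []
    for s in range(cfg.train_sessions):
        spec = SessionSpec(
            reps_per_gesture=cfg.train_reps,
            noise_snr_db=cfg.noise_snr_db,
            seed=_derive_seed(gs, "train", seed_idx, s),
        )
        train_blocks.append(
            simulate_session(spec, participant, simulator=sim, gain=gain)
        )

    cond_blocks = {}
    for cond in CONFOUNDER_CONDITIONS:
        spec = SessionSpec(
            reps_per_gesture=cfg.confounder_reps,
            noise_snr_db=cfg.noise_snr_db,
            seed=_derive_seed(gs, "cond", seed_idx, cond),
        )
        conf = ConfounderModel(kind=cond, seed=_derive_seed(gs, "conf", seed_idx, cond))
        cond_blocks[cond] = simulate_session(
            spec, participant, confounder=conf, simulator=sim, gain=gain
        )
    return train_blocks, cond_blocks


class Standardizer:
    """Per-channel standardisation fitted on training windows."""

    def __init__(self, X_train: np.ndarray):
        flat = X_train.reshape(-1, X_train.shape[-1])
        self.mean = flat.mean(axis=0)
        self.std = np.maximum(flat.std(axis=0), 1e-9)

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.std


def _to_matrices(X: np.ndarray) -> np.ndarray:
    """(n, T, 208) -> (n, T, 16, 16) padded frame matrices."""
    n, T, _ = X.shape
    out = np.zeros((n, T, 16, 16), dtype=np.float32)
    out[:, :, :, :13] = X.reshape(n, T, 16, 13)
    return out


def build_datasets(cfg: RunConfig, mesh, protocol):
    """Simulate all participants and assemble the model-ready arrays.

    Returns a dict with training arrays, the standardiser, per-condition
    test sets (pooled), and per-participant test subsets for paired
    model comparison.
    """
    train_seqs = []
    train_pid = []
    cond_seqs = {c: [] for c in CONFOUNDER_CONDITIONS}
    cond_pid = {c: [] for c in CONFOUNDER_CONDITIONS}
    for i in range(len(cfg.seeds)):
        tr_blocks, cond_blocks = simulate_participant(cfg, i, mesh, protocol)
        for block in tr_blocks:
            seqs = window_sequences(
                block, cfg.window_ms, cfg.overlap, stride=cfg.train_stride
            )
            train_seqs.extend(seqs)
            train_pid.extend([i] * len(seqs))
        for cond, block in cond_blocks.items():
            seqs = window_sequences(
                block, cfg.window_ms, cfg.overlap, stride=cfg.eval_stride
            )
            cond_seqs[cond].extend(seqs)
            cond_pid[cond].extend([i] * len(seqs))

    # split the pooled clean windows (participant ids follow the windows)
    order = list(range(len(train_seqs)))
    split = split_dataset(order, SplitSpec(cfg.split_fractions, seed=cfg.global_seed))
    subsets = {}
    for name, idx in zip(("train", "val", "test"), split):
        seqs = [train_seqs[i] for i in idx]
        X, y = sequences_to_arrays(seqs)
        subsets[name] = {"X": X, "y": y, "pid": np.array([train_pid[i] for i in idx])}

    std = Standardizer(subsets["train"]["X"]) if cfg.standardize else None
    data = {"subsets": subsets, "standardizer": std, "conditions": {}}
    for cond in CONFOUNDER_CONDITIONS:
        X, y = sequences_to_arrays(cond_seqs[cond])
        data["conditions"][cond] = {"X": X, "y": y, "pid": np.array(cond_pid[cond])}
    return data


def _prep(std, X):
    return _to_matrices(std(X) if std is not None else X)


def train_models(cfg: RunConfig, data: dict):
    """Train every configured model on the identical training windows."""
    std = data["standardizer"]
    sub = data["subsets"]
    Xtr, ytr = _prep(std, sub["train"]["X"]), sub["train"]["y"]
    Xva, yva = _prep(std, sub["val"]["X"]), sub["val"]["y"]
    models = {}
    histories = {}
    tseed = _derive_seed(cfg.global_seed, "train-loop")
    tc = TrainConfig(
        learning_rate=cfg.learning_rate,
        batch_size=cfg.batch_size,
        max_epochs=cfg.max_epochs,
        patience=cfg.patience,
        seed=tseed,
    )
    for name in cfg.models:
        t0 = time.time()
        if name == "knn":
            models[name] = baselines.fit_knn(Xtr, ytr, Xva, yva)
        elif name == "svm":
            models[name] = baselines.fit_svm(Xtr, ytr, Xva, yva)
        elif name == "cnn_lstm":
            mcfg = CNNLSTMConfig(
                learning_rate=cfg.learning_rate,
                batch_size=cfg.batch_size,
                max_epochs=cfg.max_epochs,
                patience=cfg.patience,
                seed=tseed,
            )
            model, hist = baselines.fit_cnn_lstm(Xtr, ytr, Xva, yva, mcfg, tc)
            models[name] = model
            histories[name] = hist
        elif name == "faspp_gru":
            mcfg = FASPPGRUConfig(
                learning_rate=cfg.learning_rate,
                batch_size=cfg.batch_size,
                max_epochs=cfg.max_epochs,
                patience=cfg.patience,
                seed=tseed,
            )
            model = FASPPGRU(mcfg)
            histories[name] = train_classifier(model, Xtr, ytr, Xva, yva, tc)
            models[name] = model
        else:
            raise ValueError(f"unknown model {name!r}")
        histories.setdefault(name, {})
        histories[name]["fit_seconds"] = time.time() - t0
    return models, histories


def evaluate_models(cfg: RunConfig, data: dict, models: dict):
    """Per-condition metrics for every model plus the Friedman comparison.

    The clean ('none') condition uses the held-out test split; confounder
    conditions are entirely test data.  Per-participant accuracies under
    each condition form the paired blocks of the Friedman test.
    """
    std = data["standardizer"]
    eval_sets = {"none": data["subsets"]["test"]}
    eval_sets.update(data["conditions"])

    reports = {}
    cms = {}
    per_block_acc = {name: [] for name in models}
    for cond, ds in eval_sets.items():
        Xc, yc, pid = _prep(std, ds["X"]), ds["y"], ds["pid"]
        reports[cond] = {}
        cms[cond] = {}
        for name, model in models.items():
            y_pred = model.predict(Xc)
            cm = confusion_matrix(yc, y_pred)
            reports[cond][name] = compute_metrics(cm, condition=cond, model=name)
            cms[cond][name] = cm
            for p in np.unique(pid):
                mask = pid == p
                per_block_acc[name].append(float((y_pred[mask] == yc[mask]).mean()))

    names = list(models)
    fried = None
    if len(names) >= 2:
        A = np.column_stack([per_block_acc[n] for n in names])
        stat, p = friedman_test(A)
        fried = {"models": names, "statistic": stat, "p_value": p}
    return reports, cms, fried


def run_experiment(cfg: RunConfig):
    """Full pipeline; returns the results dict and optionally writes it.

    Every artifact embeds the configuration hash so a rerun with the
    same config is bit-identical where determinism is contracted.
    """
    t_start = time.time()
    mesh = build_disk_mesh(cfg.refinement_level)
    protocol = adjacent_protocol()
    data = build_datasets(cfg, mesh, protocol)
    models, histories = train_models(cfg, data)
    reports, cms, fried = evaluate_models(cfg, data, models)

    results = {
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "n_train_windows": int(len(data["subsets"]["train"]["y"])),
        "accuracy": {
            cond: {name: r.accuracy for name, r in rs.items()}
            for cond, rs in reports.items()
        },
        "macro_f1": {
            cond: {name: r.macro_f1 for name, r in rs.items()}
            for cond, rs in reports.items()
        },
        "friedman": fried,
        "histories": {
            k: {kk: vv for kk, vv in h.items()}
            for k, h in histories.items()
        },
        "runtime_seconds": None,
        "model_parameters": {
            name: int(m.n_parameters)
            for name, m in models.items()
            if hasattr(m, "n_parameters")
        },
    }
    results["runtime_seconds"] = time.time() - t_start

    if cfg.outdir:
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "results.json", "w") as fh:
            json.dump(results, fh, indent=2, default=float)
        if cfg.save_plots:
            from eitgest.evaluation import plot_confusion

            for cond, d in cms.items():
                for name, cm in d.items():
                    plot_confusion(
                        cm,
                        out / f"confusion_{name}_{cond}.png",
                        f"{name} / {cond} [{cfg.config_hash()}]",
                    )
    return results, models, data, reports
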