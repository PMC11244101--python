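"""Training/evaluation harness tying simulator, DSP chain and network together.

The canonical experiment: simulate a labeled cohort, run every record through
range processing -> phase extraction -> modal separation -> sliding windows,
split at *record* level 7:3 stratified by subject (windows from one record
never straddle the split, so overlapping windows cannot leak), train the
fusion network with cross-entropy/Adam, and report window-level accuracy with
a row-normalized confusion matrix.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix

from . import modal, phase, ranging
from .modal import ModalWindowSet
from .network import NetworkConfig, FusionNet, UnimodalNet, build_model
from .nn import Tensor, Adam, cross_entropy
from .simulate import RadarConfig, SceneConfig, RadarCube, iter_cohort, _DEFAULT_SCENE

logger = logging.getLogger("radarid")

__all__ = ["TrainConfig", "EvalReport", "PipelineConfig", "split_dataset",
           "build_windows", "build_cohort_windows", "train", "evaluate",
           "run_pipeline", "run_ablation", "run_unimodal",
           "run_modality_comparison", "ABLATION_AXES"]

MODALITY_INDEX = {"respiration": 0, "heartbeat": 1, "phase": 2}
ABLATION_AXES = ("distance_units", "window_length", "residual_blocks", "fusion_scheme")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 50
    batch_size: int = 32
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    split_fraction: tuple[float, float] = (0.7, 0.3)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if abs(sum(self.split_fraction) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")


@dataclass
class EvalReport:
    accuracy: float
    confusion: np.ndarray               # row-normalized by true class
    per_class_accuracy: dict[str, float]
    window_counts: dict[str, int]
    classes: list[str]
    unsupported_classes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"accuracy": self.accuracy,
                "per_class_accuracy": self.per_class_accuracy,
                "window_counts": self.window_counts,
                "classes": self.classes,
                "unsupported_classes": self.unsupported_classes,
                "confusion": self.confusion.tolist()}


def split_dataset(manifest: pd.DataFrame, fractions: tuple[float, float] = (0.7, 0.3),
                  seed: int = 0) -> pd.DataFrame:
    """Stratified record-level split: per subject, ~70% of records to train."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    out = manifest.copy()
    out["split"] = ""
    for subject, grp in manifest.groupby("subject_id"):
        idx = grp.index.to_numpy()
        if len(idx) < 2:
            raise ValueError(f"subject {subject!r} has fewer than 2 records")
        rng.shuffle(idx)
        n_train = int(np.clip(round(fractions[0] * len(idx)), 1, len(idx) - 1))
        out.loc[idx[:n_train], "split"] = "train"
        out.loc[idx[n_train:], "split"] = "test"
    return out


def process_record(cube: RadarCube, k_bins: int = 7, window_length: int = 512,
                   step: int = 50, lam: float = 0.9) -> ModalWindowSet | None:
    """One record through the full DSP chain into normalized modal windows."""
    m, chest_bin = ranging.preprocess_cube(cube, lam=lam)
    p = phase.phase_from_matrix(m, chest_bin, k=k_bins)
    modalities = modal.separate_modalities(p)
    return modal.slide_windows(modalities, window_length, step,
                               cube.subject_id, cube.record_id)


def build_windows(cubes, k_bins: int = 7, window_length: int = 512,
                  step: int = 50, lam: float = 0.9) -> ModalWindowSet:
    sets = []
    for cube in cubes:
        ws = process_record(cube, k_bins, window_length, step, lam)
        if ws is not None:
            sets.append(ws)
    if not sets:
        raise ValueError("no usable records")
    return ModalWindowSet.concatenate(sets)


def _encode_labels(labels: np.ndarray, classes: list[str]) -> np.ndarray:
    lut = {c: i for i, c in enumerate(classes)}
    return np.array([lut[l] for l in labels], dtype=np.int64)


def _select_modality(x: np.ndarray, modality: str | None) -> np.ndarray:
    if modality is None:
        return x
    if modality not in MODALITY_INDEX:
        raise ValueError(f"unknown modality {modality!r}")
    return x[:, MODALITY_INDEX[modality]:MODALITY_INDEX[modality] + 1]


def train(dataset: ModalWindowSet, net_cfg: NetworkConfig,
          train_cfg: TrainConfig = TrainConfig(), modality: str | None = None,
          eval_set: ModalWindowSet | None = None,
          classes: list[str] | None = None):
    """Minimize cross-entropy over the training windows; returns (model, history)."""
    if len(dataset.windows) == 0:
        raise ValueError("empty training set")
    classes = classes or sorted(set(dataset.labels))
    x = _select_modality(dataset.windows, modality)
    y = _encode_labels(dataset.labels, classes)
    model = build_model(net_cfg, modality)
    opt = Adam(model.parameters(), lr=train_cfg.learning_rate)
    rng = np.random.default_rng(train_cfg.seed)
    history = {"train_loss": [], "test_accuracy": []}
    n = len(x)
    for epoch in range(train_cfg.epochs):
        model.train()
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, train_cfg.batch_size):
            batch = order[start:start + train_cfg.batch_size]
            opt.zero_grad()
            logits = model(Tensor(x[batch]))
            loss = cross_entropy(logits, y[batch])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch}, batch {start // train_cfg.batch_size}"
                    " — check input normalization and learning rate")
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history["train_loss"].append(float(np.mean(losses)))
        msg = f"epoch {epoch + 1}/{train_cfg.epochs} loss {history['train_loss'][-1]:.4f}"
        if eval_set is not None:
            rep = evaluate(model, eval_set, modality=modality, classes=classes)
            history["test_accuracy"].append(rep.accuracy)
            msg += f" test_acc {rep.accuracy:.3f}"
        logger.info(msg)
    return model, history


def evaluate(model, dataset: ModalWindowSet, modality: str | None = None,
             classes: list[str] | None = None, batch_size: int = 64) -> EvalReport:
    """Window-level argmax classification with a row-normalized confusion matrix."""
    if len(dataset.windows) == 0:
        raise ValueError("empty evaluation set")
    classes = classes or sorted(set(dataset.labels))
    x = _select_modality(dataset.windows, modality)
    y = _encode_labels(dataset.labels, classes)
    preds = np.concatenate([model.predict(x[i:i + batch_size])
                            for i in range(0, len(x), batch_size)])
    acc = float((preds == y).mean())
    counts = confusion_matrix(y, preds, labels=range(len(classes)))
    support = counts.sum(axis=1)
    unsupported = [c for c, s in zip(classes, support) if s == 0]
    conf = counts / np.where(support[:, None] == 0, 1, support[:, None])
    per_class = {c: float(conf[i, i]) for i, c in enumerate(classes) if support[i] > 0}
    window_counts = {c: int(s) for c, s in zip(classes, support)}
    return EvalReport(acc, conf, per_class, window_counts, list(classes), unsupported)


# ---------------------------------------------------------------------------
# Full synthetic-cohort pipeline

@dataclass(frozen=True)
class PipelineConfig:
    """One reproducible synthetic-cohort experiment."""

    n_subjects: int = 5
    records_per_subject: int = 20
    radar: RadarConfig = RadarConfig()
    scene: SceneConfig = _DEFAULT_SCENE
    k_bins: int = 7
    window_length: int = 512
    window_step: int = 50
    abs_lambda: float = 0.9
    master_seed: int = 0


def build_cohort_windows(pipe: PipelineConfig, split_seed: int = 0,
                         fractions: tuple[float, float] = (0.7, 0.3)
                         ) -> tuple[ModalWindowSet, ModalWindowSet, list[str]]:
    """Simulate the cohort, run the DSP chain, split at record level.

    Records are processed one at a time so only windows stay in memory.
    Returns (train_set, test_set, class labels).
    """
    rows, sets = [], []
    for cube in iter_cohort(pipe.n_subjects, pipe.records_per_subject,
                            pipe.radar, pipe.scene, pipe.master_seed):
        ws = process_record(cube, pipe.k_bins, pipe.window_length,
                            pipe.window_step, pipe.abs_lambda)
        if ws is not None:
            sets.append(ws)
            rows.append({"record_id": cube.record_id, "subject_id": cube.subject_id,
                         "path": "", "split": ""})
    manifest = split_dataset(pd.DataFrame(rows), fractions, seed=split_seed)
    all_windows = ModalWindowSet.concatenate(sets)
    split_of = dict(zip(manifest.record_id, manifest.split))
    mask = np.array([split_of[r] == "train" for r in all_windows.record_ids])
    train_records = set(all_windows.record_ids[mask])
    test_records = set(all_windows.record_ids[~mask])
    if train_records & test_records:    # leakage guard, asserted every run
        raise RuntimeError("record-level train/test overlap detected")

    def subset(m):
        return ModalWindowSet(all_windows.windows[m], all_windows.labels[m],
                              all_windows.record_ids[m],
                              all_windows.window_length, all_windows.step)

    classes = sorted(set(all_windows.labels))
    logger.info("cohort: %d train / %d test windows, %d classes",
                int(mask.sum()), int((~mask).sum()), len(classes))
    return subset(mask), subset(~mask), classes


def _default_net(pipe: PipelineConfig, seed: int) -> NetworkConfig:
    return NetworkConfig(n_classes=pipe.n_subjects, k_bins=pipe.k_bins,
                         window_length=pipe.window_length, rng_seed=seed)


def run_pipeline(pipe: PipelineConfig = PipelineConfig(),
                 net_cfg: NetworkConfig | None = None,
                 train_cfg: TrainConfig = TrainConfig(),
                 modality: str | None = None,
                 track_test_accuracy: bool = False):
    """simulate -> preprocess -> extract -> split -> train -> evaluate.

    Returns (report, history, model).
    """
    t0 = time.time()
    if net_cfg is None:
        net_cfg = _default_net(pipe, train_cfg.seed)
    train_set, test_set, classes = build_cohort_windows(
        pipe, train_cfg.seed, train_cfg.split_fraction)
    model, history = train(train_set, net_cfg, train_cfg, modality=modality,
                           eval_set=test_set if track_test_accuracy else None,
                           classes=classes)
    report = evaluate(model, test_set, modality=modality, classes=classes)
    logger.info("pipeline done in %.1f s: accuracy %.3f", time.time() - t0,
                report.accuracy)
    return report, history, model


def run_modality_comparison(pipe: PipelineConfig = PipelineConfig(),
                            net_cfg: NetworkConfig | None = None,
                            train_cfg: TrainConfig = TrainConfig()
                            ) -> tuple[pd.DataFrame, dict[str, EvalReport]]:
    """Unimodal vs multimodal comparison on one shared cohort and split.

    The cohort is simulated and processed once; the three single-branch models
    and the fusion model are trained with identical seeds and settings.
    Returns (4-row accuracy table, reports keyed by model input).
    """
    if net_cfg is None:
        net_cfg = _default_net(pipe, train_cfg.seed)
    train_set, test_set, classes = build_cohort_windows(
        pipe, train_cfg.seed, train_cfg.split_fraction)
    reports: dict[str, EvalReport] = {}
    for modality in [*MODALITY_INDEX, None]:
        name = modality or "multimodal"
        model, _ = train(train_set, net_cfg, train_cfg, modality=modality,
                         classes=classes)
        reports[name] = evaluate(model, test_set, modality=modality, classes=classes)
        logger.info("%s accuracy %.3f", name, reports[name].accuracy)
    table = pd.DataFrame([{"model_input": k, "accuracy": v.accuracy}
                          for k, v in reports.items()])
    return table, reports


def run_unimodal(modality: str, pipe: PipelineConfig = PipelineConfig(),
                 net_cfg: NetworkConfig | None = None,
                 train_cfg: TrainConfig = TrainConfig()):
    """Single-branch run (no fusion module) on one modality."""
    if modality not in MODALITY_INDEX:
        raise ValueError(f"modality must be one of {tuple(MODALITY_INDEX)}")
    return run_pipeline(pipe, net_cfg, train_cfg, modality=modality)


def run_ablation(axis: str, values: list, pipe: PipelineConfig = PipelineConfig(),
                 net_cfg: NetworkConfig | None = None,
                 train_cfg: TrainConfig = TrainConfig()) -> pd.DataFrame:
    """Re-run the full pipeline per value of one ablation axis; shared seeds."""
    if axis not in ABLATION_AXES:
        raise ValueError(f"axis must be one of {ABLATION_AXES}")
    base_net = net_cfg or NetworkConfig(n_classes=pipe.n_subjects,
                                        k_bins=pipe.k_bins,
                                        window_length=pipe.window_length,
                                        rng_seed=train_cfg.seed)
    rows = []
    for value in values:
        p, ncfg = pipe, base_net
        if axis == "distance_units":
            if value not in (3, 5, 7, 9):
                raise ValueError("distance units must be in {3, 5, 7, 9}")
            p = replace(pipe, k_bins=int(value))
            ncfg = replace(base_net, k_bins=int(value))
        elif axis == "window_length":
            frames = int(round(value * pipe.radar.frame_rate))
            p = replace(pipe, window_length=frames)
            ncfg = replace(base_net, window_length=frames)
        elif axis == "residual_blocks":
            ncfg = replace(base_net, n_residual_blocks=int(value))
        else:
            ncfg = replace(base_net, fusion=str(value))
        report, _, _ = run_pipeline(p, ncfg, train_cfg)
        rows.append({"axis": axis, "value": value, "accuracy": report.accuracy})
        logger.info("ablation %s=%s -> accuracy %.3f", axis, value, report.accuracy)
    return pd.DataFrame(rows)
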