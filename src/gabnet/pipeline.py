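"""Training and evaluation orchestration.

The training recipe: softmax cross-entropy, Adam at 1e-4, batch size 10,
up to 300 epochs, learning rate scaled by 0.1 when validation accuracy
has not improved for 5 consecutive epochs, early stop after 11
stagnant epochs, best-validation weights restored at the end.
"Improved" means a strict increase; both counters reset on improvement
and the plateau counter also resets after a learning-rate drop.
"""

from __future__ import annotations

import copy
import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .metrics import MetricsReport, compute_report
from .model import ArchitectureConfig, GABNet, build_gabnet
from .nn import Adam, Tensor, softmax, softmax_cross_entropy
from .synthetic import DatasetSpec, generate_arrays

__all__ = [
    "TrainConfig",
    "RunRecord",
    "PlateauEarlyStopping",
    "SplitData",
    "train",
    "evaluate",
    "dataset_from_arrays",
    "dataset_from_directory",
    "run_scaled_experiment",
]


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 10
    max_epochs: int = 300
    plateau_factor: float = 0.1
    plateau_patience: int = 5
    early_stop_patience: int = 11
    seed: int = 0
    preset: str = "tiny"
    use_gab: bool = True
    arch_overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.early_stop_patience <= self.plateau_patience:
            raise ValueError("early_stop_patience must exceed plateau_patience")
        if min(self.learning_rate, self.batch_size, self.max_epochs,
               self.plateau_factor) <= 0:
            raise ValueError("all training hyper-parameters must be positive")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


class PlateauEarlyStopping:
    """Reduce-on-plateau + early-stopping bookkeeping on validation accuracy.

    ``update`` returns ``(drop_lr, stop)`` for the epoch just finished.
    With a constant accuracy sequence and patiences (5, 11), the LR drop
    fires at epoch 6 and the stop at epoch 12.
    """

    def __init__(self, plateau_patience: int = 5, early_stop_patience: int = 11):
        if early_stop_patience <= plateau_patience:
            raise ValueError("early_stop_patience must exceed plateau_patience")
        self.plateau_patience = plateau_patience
        self.early_stop_patience = early_stop_patience
        self.best: float | None = None
        self.plateau_count = 0
        self.stop_count = 0

    def update(self, val_accuracy: float) -> tuple[bool, bool]:
        if self.best is None or val_accuracy > self.best:  # strict improvement
            self.best = val_accuracy
            self.plateau_count = 0
            self.stop_count = 0
            return False, False
        self.plateau_count += 1
        self.stop_count += 1
        drop = self.plateau_count >= self.plateau_patience
        if drop:
            self.plateau_count = 0
        stop = self.stop_count >= self.early_stop_patience
        return drop, stop


@dataclass
class SplitData:
    """Preprocessed images in [0, 1], shape (N, H, W, C), per split."""

    x_train: np.ndarray
    y_train: np.ndarray
    x_val: np.ndarray
    y_val: np.ndarray
    x_test: np.ndarray
    y_test: np.ndarray
    class_names: list[str]


def dataset_from_arrays(data: dict) -> SplitData:
    """Build splits from :func:`gabnet.synthetic.generate_arrays` output."""
    images = data["images"].astype(np.float64) / 255.0
    if images.ndim == 3:
        images = images[..., None]
    labels = data["labels"]
    splits = data["splits"]
    parts = {}
    for name in ("train", "val", "test"):
        sel = splits == name
        parts[name] = (images[sel], labels[sel])
    return SplitData(
        x_train=parts["train"][0], y_train=parts["train"][1],
        x_val=parts["val"][0], y_val=parts["val"][1],
        x_test=parts["test"][0], y_test=parts["test"][1],
        class_names=list(data["class_names"]),
    )


def dataset_from_directory(root, input_size: tuple[int, int, int],
                           per_class_cap: int | None = None, seed: int = 0,
                           val_frac: float = 0.1, test_frac: float = 0.1) -> SplitData:
    """Load a directory-per-class tree and split it (stratified, seeded).

    If the directory contains a ``manifest.csv`` with a ``split`` column
    (as written by the synthetic generator), that split assignment is
    reused instead.
    """
    from .preprocessing import load_dataset, prepare_image

    root = Path(root)
    h, w, c = input_size
    manifest = root / "manifest.csv"
    records: list[tuple[Path, int, str]] = []
    if manifest.exists():
        import pandas as pd

        df = pd.read_csv(manifest, keep_default_na=False)
        class_names = sorted(df["label"].unique())
        for _, row in df.iterrows():
            records.append((root / row["path"], class_names.index(row["label"]), row["split"]))
        if per_class_cap is not None:
            capped, seen = [], {}
            for rec in records:
                seen[rec[1]] = seen.get(rec[1], 0)
                if seen[rec[1]] < per_class_cap:
                    capped.append(rec)
                    seen[rec[1]] += 1
            records = capped
    else:
        pairs, class_names = load_dataset(root, per_class_cap=per_class_cap, seed=seed)
        rng = np.random.default_rng(seed)
        by_class: dict[int, list[Path]] = {}
        for path, label in pairs:
            by_class.setdefault(label, []).append(path)
        for label, paths in by_class.items():
            n = len(paths)
            n_test = int(round(test_frac * n))
            n_val = int(round(val_frac * n))
            names = ["test"] * n_test + ["val"] * n_val + ["train"] * (n - n_test - n_val)
            names = [names[i] for i in np.argsort(rng.permutation(n))]
            records.extend((p, label, s) for p, s in zip(paths, names))
    parts: dict[str, list] = {"train": [], "val": [], "test": []}
    for path, label, split in records:
        img = prepare_image(path, h, w, to_rgb=(c == 3))
        parts[split].append((img, label))

    def stack(items):
        if not items:
            return np.zeros((0, h, w, c)), np.zeros(0, dtype=np.int64)
        xs, ys = zip(*items)
        return np.stack(xs), np.asarray(ys, dtype=np.int64)

    (xtr, ytr), (xv, yv), (xte, yte) = (stack(parts[s]) for s in ("train", "val", "test"))
    return SplitData(xtr, ytr, xv, yv, xte, yte, list(class_names))


@dataclass
class RunRecord:
    epochs: list[dict]
    lr_trace: list[float]
    stop_reason: str
    best_val_accuracy: float
    best_epoch: int
    config: dict
    config_hash: str
    wall_time_s: float

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def epoch_csv(self, path) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(
                fh, fieldnames=["epoch", "train_loss", "train_accuracy", "val_accuracy", "lr"]
            )
            writer.writeheader()
            writer.writerows(self.epochs)


def _accuracy_of(model: GABNet, x: np.ndarray, y: np.ndarray, batch_size: int) -> float:
    if len(x) == 0:
        return 0.0
    return float((model.predict(x, batch_size=batch_size) == y).mean())


def train(cfg: TrainConfig, dataset: SplitData, model: GABNet | None = None,
          verbose: bool = False) -> tuple[RunRecord, GABNet]:
    """Run the full recipe on a dataset; returns the run record and the
    best-validation model (weights restored)."""
    if len(dataset.x_train) == 0 or len(dataset.x_val) == 0:
        raise ValueError("training requires nonempty train and val splits")
    rng = np.random.default_rng(cfg.seed)
    if model is None:
        h, w, c = dataset.x_train.shape[1:]
        kwargs = dict(
            input_size=(h, w, c),
            num_classes=len(dataset.class_names),
            use_gab=cfg.use_gab,
            seed=cfg.seed,
        ) | cfg.arch_overrides
        arch = ArchitectureConfig.preset(cfg.preset, **kwargs)
        model = build_gabnet(arch)
    optimizer = Adam(model.parameters(), lr=cfg.learning_rate)
    scheduler = PlateauEarlyStopping(cfg.plateau_patience, cfg.early_stop_patience)
    epochs: list[dict] = []
    lr_trace: list[float] = []
    best_state: dict | None = None
    best_acc, best_epoch = -np.inf, 0
    stop_reason = "max_epochs"
    t0 = time.time()
    n = len(dataset.x_train)
    for epoch in range(1, cfg.max_epochs + 1):
        model.train()
        order = rng.permutation(n)
        losses, correct = [], 0
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo : lo + cfg.batch_size]
            xb = Tensor(dataset.x_train[idx])
            yb = dataset.y_train[idx]
            logits = model(xb)
            loss = softmax_cross_entropy(logits, yb)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}; last finite losses: {losses[-3:]}"
                )
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(float(loss.data))
            correct += int((logits.data.argmax(axis=1) == yb).sum())
        val_acc = _accuracy_of(model, dataset.x_val, dataset.y_val, cfg.batch_size * 4)
        epochs.append({
            "epoch": epoch,
            "train_loss": float(np.mean(losses)),
            "train_accuracy": correct / n,
            "val_accuracy": val_acc,
            "lr": optimizer.lr,
        })
        lr_trace.append(optimizer.lr)
        if verbose:
            print(
                f"epoch {epoch:3d}  loss {epochs[-1]['train_loss']:.4f}  "
                f"train acc {epochs[-1]['train_accuracy']:.3f}  "
                f"val acc {val_acc:.3f}  lr {optimizer.lr:g}",
                flush=True,
            )
        if val_acc > best_acc:
            best_acc, best_epoch = val_acc, epoch
            best_state = copy.deepcopy(model.state_dict())
        drop, stop = scheduler.update(val_acc)
        if drop:
            optimizer.lr *= cfg.plateau_factor
        if stop:
            stop_reason = "early_stop"
            break
    if best_state is not None:
        model.load_state_dict(best_state)
    record = RunRecord(
        epochs=epochs,
        lr_trace=lr_trace,
        stop_reason=stop_reason,
        best_val_accuracy=float(best_acc),
        best_epoch=best_epoch,
        config=asdict(cfg),
        config_hash=cfg.config_hash(),
        wall_time_s=time.time() - t0,
    )
    return record, model


def run_scaled_experiment(seed: int = 0, n_per_class: int = 200, use_gab: bool = True,
                          learning_rate: float = 2e-3, batch_size: int = 16,
                          max_epochs: int = 25, verbose: bool = False) -> dict:
    """The desk-scale end-to-end experiment: synth -> train -> eval.

    Generates ``n_per_class`` synthetic B-scans per class (stratified
    80/10/10 split), trains the ``tiny`` preset and evaluates on the
    held-out test split.  The learning rate and batch size are raised
    from the full-scale recipe defaults so the run converges within a
    CPU-minutes budget; the plateau/early-stop schedule is unchanged.

    Returns a dict with the generated ``data`` arrays, the ``dataset``
    splits, the ``record``, the trained ``model`` and the test-split
    ``report``.
    """
    data = generate_arrays(DatasetSpec(n_per_class=n_per_class, seed=seed + 1))
    dataset = dataset_from_arrays(data)
    cfg = TrainConfig(learning_rate=learning_rate, batch_size=batch_size,
                      max_epochs=max_epochs, seed=seed, preset="tiny", use_gab=use_gab)
    record, model = train(cfg, dataset, verbose=verbose)
    report = evaluate(model, dataset.x_test, dataset.y_test,
                      class_names=dataset.class_names)
    return {"data": data, "dataset": dataset, "record": record,
            "model": model, "report": report, "config": cfg}


def evaluate(model: GABNet, x: np.ndarray, y: np.ndarray,
             class_names: list[str] | None = None, batch_size: int = 32) -> MetricsReport:
    """Argmax predictions -> confusion matrix -> full weighted report."""
    if len(x) == 0:
        raise ValueError("evaluation set is empty")
    scores = model.predict_proba(x, batch_size=batch_size)
    preds = scores.argmax(axis=1)
    return compute_report(y, preds, score_matrix=scores, class_names=class_names)
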