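"""Training loop, early stopping, confusion-matrix metrics.

Training minimizes the cross-entropy of the main head plus a weighted
cross-entropy of the two auxiliary heads (deep supervision),

    L = CE(main) + aux_loss_weight * (CE(aux1) + CE(aux2)),

with Adam.  Early stopping monitors validation loss: when it fails to
improve for ``early_stop_patience`` consecutive epochs the loop stops
and the best-validation weights are restored.  Everything is seeded, so
one configuration + seed gives a bit-identical history.

Evaluation predicts the argmax of the main head (ties resolve to the
lower class index), accumulates a K x K confusion matrix (rows = actual,
columns = predicted) and derives accuracy, precision, recall and F1.
Per-class ratios with an empty denominator are defined as 0; macro
averaging weights classes equally, weighted averaging by class support.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .autograd import Adam, Tensor, cross_entropy_from_probs
from .imaging_io import LabeledDataset, split_train_test
from .model import GranuloNet

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "TrainConfig",
    "ConfusionMatrix",
    "MetricsReport",
    "TrainingHistory",
    "dataset_to_arrays",
    "train",
    "evaluate",
    "predict",
    "metrics_from_confusion",
]


@dataclass
class TrainConfig:
    """Optimization settings; defaults follow the full-scale recipe
    (Adam, lr 1e-4, 100 epochs, batch 32, dropout 0.5, early stopping)."""

    learning_rate: float = 1e-4
    max_epochs: int = 100
    batch_size: int = 32
    early_stop_patience: int = 10
    aux_loss_weight: float = 0.3
    val_frac: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0.0 <= self.aux_loss_weight <= 1.0:
            raise ValueError("aux_loss_weight must be in [0, 1]")

    @classmethod
    def small(cls, **overrides) -> "TrainConfig":
        """Desk-scale profile paired with ModelConfig.small: fewer, larger
        steps (lr 1e-3, up to 12 epochs, patience 4)."""
        defaults = dict(learning_rate=1e-3, max_epochs=12, early_stop_patience=4)
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # (K, K) ints, rows = actual, cols = predicted
    class_names: list[str]

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.class_names)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be K x K for K class names")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def misclassified(self) -> int:
        return int(self.counts.sum() - np.trace(self.counts))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts,
                            index=[f"actual_{c}" for c in self.class_names],
                            columns=[f"predicted_{c}" for c in self.class_names])


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    loss: float
    averaging: str
    per_class: pd.DataFrame | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {"accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "f1": self.f1, "loss": self.loss,
                "averaging": self.averaging}


@dataclass
class TrainingHistory:
    frame: pd.DataFrame  # epoch, train_loss, train_acc, val_loss, val_acc
    best_epoch: int
    stopped_epoch: int


# ---------------------------------------------------------------------------
# Data plumbing
# ---------------------------------------------------------------------------

def dataset_to_arrays(ds: LabeledDataset) -> tuple[np.ndarray, np.ndarray]:
    """Stack a dataset into (N, C, H, W) float32 images and int64 labels."""
    x = np.stack([np.moveaxis(s.pixels, 2, 0) for s in ds.samples])
    return x.astype(np.float32), ds.labels


def _match_channels(x: np.ndarray, c_wanted: int) -> np.ndarray:
    if x.shape[1] == c_wanted:
        return x
    if x.shape[1] == 1 and c_wanted == 3:
        return np.repeat(x, 3, axis=1)
    if x.shape[1] == 3 and c_wanted == 1:
        return x.mean(axis=1, keepdims=True)
    raise ValueError(f"cannot adapt {x.shape[1]} channels to {c_wanted}")


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _epoch_pass(model: GranuloNet, x: np.ndarray, y: np.ndarray,
                cfg: TrainConfig, opt: Adam | None,
                rng: np.random.Generator | None) -> tuple[float, float]:
    """One pass over (x, y); optimizes when ``opt`` is given. Returns
    (mean main-head loss, accuracy)."""
    n = len(y)
    order = rng.permutation(n) if rng is not None else np.arange(n)
    total_loss = 0.0
    correct = 0
    for start in range(0, n, cfg.batch_size):
        idx = order[start:start + cfg.batch_size]
        xb, yb = x[idx], y[idx]
        out = model(Tensor(xb))
        loss_main = cross_entropy_from_probs(out.tensors["main"], yb)
        loss = loss_main
        if model.cfg.aux_enabled and opt is not None:
            aux = cross_entropy_from_probs(out.tensors["aux1"], yb) + \
                cross_entropy_from_probs(out.tensors["aux2"], yb)
            loss = loss + aux * cfg.aux_loss_weight
        if not np.isfinite(loss.data):
            raise FloatingPointError(
                "training loss became non-finite; lower the learning rate "
                "or check the input scaling")
        if opt is not None:
            opt.zero_grad()
            loss.backward()
            opt.step()
        total_loss += float(loss_main.data) * len(idx)
        correct += int((out.main.argmax(axis=1) == yb).sum())
        out = loss = loss_main = None  # release the batch graph promptly
    return total_loss / n, correct / n


def train(model: GranuloNet, train_ds: LabeledDataset,
          val_ds: LabeledDataset | None, cfg: TrainConfig
          ) -> tuple[GranuloNet, TrainingHistory]:
    """Fit the model; returns it with the best-validation weights restored.

    When ``val_ds`` is None a fraction ``cfg.val_frac`` of the training
    side is carved out (group-aware, stratified, seeded) to monitor early
    stopping.
    """
    if len(train_ds) == 0:
        raise ValueError("training dataset is empty")
    if val_ds is None:
        if cfg.val_frac <= 0:
            raise ValueError("early stopping requires a validation set")
        train_ds, val_ds = split_train_test(train_ds, 1.0 - cfg.val_frac,
                                            seed=cfg.seed)
    if len(val_ds) == 0:
        raise ValueError("validation dataset is empty")
    c_in = model.cfg.input_shape[2]
    xtr, ytr = dataset_to_arrays(train_ds)
    xva, yva = dataset_to_arrays(val_ds)
    xtr, xva = _match_channels(xtr, c_in), _match_channels(xva, c_in)
    if ytr.max() >= model.cfg.n_classes:
        raise ValueError("label out of range for the configured class count")

    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    best_val = np.inf
    best_state = None
    best_epoch = 0
    bad_epochs = 0
    rows = []
    stopped = cfg.max_epochs
    for epoch in range(1, cfg.max_epochs + 1):
        model.train()
        tr_loss, tr_acc = _epoch_pass(model, xtr, ytr, cfg, opt, rng)
        model.eval()
        va_loss, va_acc = _epoch_pass(model, xva, yva, cfg, None, None)
        rows.append({"epoch": epoch, "train_loss": tr_loss, "train_acc": tr_acc,
                     "val_loss": va_loss, "val_acc": va_acc})
        if va_loss < best_val:
            best_val = va_loss
            best_state = copy.deepcopy(model.state_dict())
            best_epoch = epoch
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs > cfg.early_stop_patience:
                stopped = epoch
                break
    if best_state is not None:
        model.load_state_dict(best_state)
    history = TrainingHistory(frame=pd.DataFrame(rows), best_epoch=best_epoch,
                              stopped_epoch=min(stopped, len(rows)))
    return model, history


# ---------------------------------------------------------------------------
# Evaluation and metrics
# ---------------------------------------------------------------------------

def predict(model: GranuloNet, x: np.ndarray,
            batch_size: int = 64) -> np.ndarray:
    """Main-head probabilities for (N, C, H, W) images, in eval mode."""
    model.eval()
    x = _match_channels(np.asarray(x, dtype=np.float32), model.cfg.input_shape[2])
    probs = []
    for start in range(0, len(x), batch_size):
        out = model(Tensor(x[start:start + batch_size]))
        probs.append(out.main)
    return np.concatenate(probs)


def evaluate(model: GranuloNet, test_ds: LabeledDataset,
             averaging: str = "macro") -> tuple[ConfusionMatrix, MetricsReport]:
    """Confusion matrix and metrics of the main head on a test dataset."""
    x, y = dataset_to_arrays(test_ds)
    probs = predict(model, x)
    # np.argmax resolves ties toward the lower index
    pred = probs.argmax(axis=1)
    k = model.cfg.n_classes
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (y, pred), 1)
    names = list(test_ds.class_names) if len(test_ds.class_names) == k \
        else [str(i) for i in range(k)]
    cm = ConfusionMatrix(counts=counts, class_names=names)
    eps_probs = np.clip(probs[np.arange(len(y)), y], 1e-12, None)
    loss = float(-np.log(eps_probs).mean())
    report = metrics_from_confusion(cm, averaging=averaging, loss=loss)
    return cm, report


def metrics_from_confusion(cm: ConfusionMatrix, averaging: str = "macro",
                           loss: float = float("nan")) -> MetricsReport:
    """Accuracy, precision, recall and F1 from a confusion matrix.

    Per-class precision = TP / (TP + FP) over the predicted column,
    recall = TP / (TP + FN) over the actual row, F1 their harmonic mean;
    0/0 ratios are defined as 0.
    """
    if averaging not in ("macro", "weighted"):
        raise ValueError("averaging must be 'macro' or 'weighted'")
    counts = cm.counts.astype(np.float64)
    total = counts.sum()
    if total == 0:
        raise ValueError("confusion matrix is empty")
    tp = np.diag(counts)
    support = counts.sum(axis=1)
    predicted = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(predicted > 0, tp / predicted, 0.0)
        recall = np.where(support > 0, tp / support, 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / denom, 0.0)
    if averaging == "macro":
        w = np.ones_like(support) / len(support)
    else:
        w = support / total
    per_class = pd.DataFrame({"precision": precision, "recall": recall,
                              "f1": f1, "support": support.astype(int)},
                             index=cm.class_names)
    return MetricsReport(
        accuracy=float(np.trace(counts) / total),
        precision=float((precision * w).sum()),
        recall=float((recall * w).sum()),
        f1=float((f1 * w).sum()),
        loss=float(loss),
        averaging=averaging,
        per_class=per_class,
    )


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """One reproducible run: preparation -> granulation -> training -> metrics.

    Every random stage draws its seed from ``seed`` plus a fixed offset, so
    an identical configuration gives a bit-identical manifest, history and
    evaluation report.
    """

    model: "ModelConfig"
    train: TrainConfig
    balance: bool = True
    augment: bool = True
    shift_frac: float = 0.1
    train_frac: float = 0.8
    granulation_mode: str = "highlight"  # "highlight" or "none"
    granule_size: int = 16
    backbone: str = "tile_stats"
    seed: int = 0


@dataclass
class PipelineResult:
    model: "GranuloNet"
    manifest: pd.DataFrame         # post-split manifest with split column
    history: TrainingHistory
    confusion: ConfusionMatrix
    metrics: MetricsReport


def run_pipeline(ds: LabeledDataset, cfg: PipelineConfig) -> PipelineResult:
    """Run the full pipeline on a labeled dataset and return all artifacts."""
    from .granulation import get_backbone, granulation_highlight
    from .imaging_io import augment_triple, balance_classes, resize_cubic
    from .model import build_model

    if cfg.balance:
        ds = balance_classes(ds, seed=cfg.seed)
    if cfg.augment:
        ds = augment_triple(ds, shift_frac=cfg.shift_frac, seed=cfg.seed + 1)
    train_ds, test_ds = split_train_test(ds, train_frac=cfg.train_frac,
                                         seed=cfg.seed + 2)
    h, w, _ = cfg.model.input_shape

    def prepare(d: LabeledDataset) -> LabeledDataset:
        samples = [resize_cubic(s, (h, w)) for s in d.samples]
        if cfg.granulation_mode == "highlight":
            bb = get_backbone(cfg.backbone)
            samples = [granulation_highlight(s, bb, g=cfg.granule_size)
                       for s in samples]
        elif cfg.granulation_mode != "none":
            raise ValueError("granulation_mode must be 'highlight' or 'none'")
        return LabeledDataset(samples=samples, class_names=list(d.class_names),
                              split_tag=d.split_tag)

    train_ds, test_ds = prepare(train_ds), prepare(test_ds)
    manifest = pd.concat([
        train_ds.manifest().assign(split="train"),
        test_ds.manifest().assign(split="test"),
    ], ignore_index=True)
    model = build_model(cfg.model)
    model, history = train(model, train_ds, None, cfg.train)
    cm, metrics = evaluate(model, test_ds)
    return PipelineResult(model=model, manifest=manifest, history=history,
                          confusion=cm, metrics=metrics)
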