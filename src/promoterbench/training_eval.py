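"""Training, sampling, metrics and cross-testing.

The positive class is the ``I`` (promoter) tag throughout.  Metrics are
sensitivity Sn = TP/(TP+FN), specificity Sp = TN/(TN+FP), precision
PPV = TP/(TP+FP), and the Matthews correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).

Any zero denominator yields 0 for the affected metric together with an
explicit "undefined" flag, so degenerate cells never poison a matrix
silently.

Training is mini-batch gradient descent with stratified batches (class
proportions preserved per batch to within one example), a fixed learning
rate (default 0.001), at most 50 epochs, and early stopping once the
validation MCC has not improved for 5 consecutive epochs.  The validation
set is a 10% stratified holdout carved from the training data with the
run seed.  Each improvement writes a checkpoint; the best one is
retained.
"""

from __future__ import annotations

import copy
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import autodiff as ad
from .dataset_builder import LabeledWindow, PromoterDataset
from .models import ArchitectureSpec, Model, build_model, predict, save_checkpoint

logger = logging.getLogger(__name__)


@dataclass
class TrainingConfig:
    learning_rate: float = 0.001
    max_epochs: int = 50
    patience: int = 5
    batch_size: int = 32
    optimizer_name: str = "adam"
    weight_decay: float = 0.0
    sampling: str = "normal"           # normal | oversample | undersample
    sampling_ratio: int = 10           # non-promoters per promoter
    validation_fraction: float = 0.1
    seed: int = 0
    checkpoint_dir: str | None = None

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")
        if self.sampling not in ("normal", "oversample", "undersample"):
            raise ValueError(f"unknown sampling strategy {self.sampling!r}")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class MetricsReport:
    Sn: float
    Sp: float
    PPV: float
    MCC: float
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {"Sn": self.Sn, "Sp": self.Sp, "PPV": self.PPV, "MCC": self.MCC}


def confusion(predicted: Sequence[str], true: Sequence[str]) -> ConfusionCounts:
    """Count TP/FP/TN/FN with ``I`` as the positive class."""
    if len(predicted) != len(true):
        raise ValueError(f"length mismatch: {len(predicted)} predictions, {len(true)} truths")
    tp = fp = tn = fn = 0
    for p, t in zip(predicted, true):
        if t == "I":
            if p == "I":
                tp += 1
            else:
                fn += 1
        else:
            if p == "I":
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)


def metrics(c: ConfusionCounts) -> MetricsReport:
    undefined: list[str] = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    sn = ratio(c.TP, c.TP + c.FN, "Sn")
    sp = ratio(c.TN, c.TN + c.FP, "Sp")
    ppv = ratio(c.TP, c.TP + c.FP, "PPV")
    denom = (
        float(c.TP + c.FP) * float(c.TP + c.FN)
        * float(c.TN + c.FP) * float(c.TN + c.FN)
    )
    if denom == 0:
        undefined.append("MCC")
        mcc = 0.0
    else:
        mcc = (float(c.TP) * c.TN - float(c.FP) * c.FN) / math.sqrt(denom)
    return MetricsReport(Sn=sn, Sp=sp, PPV=ppv, MCC=mcc, undefined=tuple(undefined))


def evaluate(model: Model, ds: PromoterDataset, threshold: float = 0.5) -> MetricsReport:
    tags, _ = predict(model, ds.sequences, threshold=threshold)
    return metrics(confusion(tags, ds.tags))


# -- sampling ----------------------------------------------------------------

def apply_sampling(
    ds: PromoterDataset, strategy: str, ratio: int, rng_seed: int
) -> PromoterDataset:
    """Rebalance classes: ``undersample`` discards non-promoters down to at
    most ``ratio`` per promoter; ``oversample`` duplicates promoters (with
    replacement) until the O:I ratio is at most ``ratio``; ``normal`` is
    the identity."""
    i_idx = [k for k, w in enumerate(ds.windows) if w.tag == "I"]
    o_idx = [k for k, w in enumerate(ds.windows) if w.tag == "O"]
    if not i_idx:
        raise ValueError("dataset contains no promoter (I) windows")
    if strategy == "normal":
        return ds
    rng = np.random.default_rng(rng_seed)
    if strategy == "undersample":
        keep_o = min(len(o_idx), ratio * len(i_idx))
        chosen = rng.choice(o_idx, size=keep_o, replace=False)
        keep = sorted(i_idx + [int(j) for j in chosen])
        out = ds.subset(keep)
    elif strategy == "oversample":
        target_i = math.ceil(len(o_idx) / ratio)
        extra = max(0, target_i - len(i_idx))
        dup = [int(j) for j in rng.choice(i_idx, size=extra, replace=True)]
        order = i_idx + dup + o_idx
        order = [order[int(j)] for j in rng.permutation(len(order))]
        out = ds.subset(order)
    else:
        raise ValueError(f"unknown sampling strategy {strategy!r}")
    out.metadata.update({"sampling": strategy, "sampling_ratio": ratio, "sampling_seed": rng_seed})
    return out


# -- training ----------------------------------------------------------------

class EarlyStopper:
    """Stop after ``patience`` consecutive epochs without improvement."""

    def __init__(self, patience: int, min_delta: float = 0.0):
        self.patience = patience
        self.min_delta = min_delta
        self.best = -np.inf
        self.best_epoch = -1
        self.stale = 0

    def update(self, epoch: int, value: float) -> bool:
        """Record an epoch's metric; return True when training should stop."""
        if value > self.best + self.min_delta:
            self.best = value
            self.best_epoch = epoch
            self.stale = 0
            return False
        self.stale += 1
        return self.stale >= self.patience


def _stratified_batches(
    labels: np.ndarray, batch_size: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Batches whose class proportions match the dataset's to within 1."""
    pos = rng.permutation(np.flatnonzero(labels == 1))
    neg = rng.permutation(np.flatnonzero(labels == 0))
    n = len(labels)
    n_batches = math.ceil(n / batch_size)
    batches = []
    p_cursor = n_cursor = seen = 0
    for b in range(n_batches):
        size = min(batch_size, n - b * batch_size)
        # positives allocated proportionally to cumulative examples served,
        # so each batch's class fraction is within 1 of the dataset's
        p_take = round(len(pos) * (seen + size) / n) - round(len(pos) * seen / n)
        p_take = min(p_take, size)
        batch = np.concatenate(
            [pos[p_cursor : p_cursor + p_take], neg[n_cursor : n_cursor + size - p_take]]
        )
        p_cursor += p_take
        n_cursor += size - p_take
        seen += size
        batches.append(rng.permutation(batch))
    return batches


@dataclass
class TrainingResult:
    model: Model
    history: list[dict]
    best_epoch: int
    best_val_mcc: float
    checkpoints: list[str] = field(default_factory=list)


def _snapshot(model: Model) -> dict[str, np.ndarray]:
    return {k: v.data.copy() for k, v in model.params.items()}


def _restore(model: Model, snap: Mapping[str, np.ndarray]) -> None:
    for k, v in snap.items():
        model.params[k].data = v.copy()


def train(model: Model, train_ds: PromoterDataset, config: TrainingConfig) -> TrainingResult:
    """Train a model in place; returns it restored to the best checkpoint."""
    if len(train_ds) == 0:
        raise ValueError("empty training dataset")
    ds = apply_sampling(train_ds, config.sampling, config.sampling_ratio, config.seed)
    labels = np.array([1 if t == "I" else 0 for t in ds.tags])
    if labels.min() == labels.max():
        raise ValueError("training data must contain both classes after sampling")

    seqs = ds.sequences
    idx_train, idx_val = train_test_split(
        np.arange(len(seqs)),
        test_size=config.validation_fraction,
        stratify=labels,
        random_state=config.seed % (2**32),
    )
    val_seqs = [seqs[i] for i in idx_val]
    val_tags = [ds.tags[i] for i in idx_val]
    tr_labels = labels[idx_train]
    tr_seqs = [seqs[i] for i in idx_train]

    if config.optimizer_name == "adam":
        opt = ad.Adam(model.trainable_params(), lr=config.learning_rate,
                      weight_decay=config.weight_decay)
    else:
        opt = ad.SGD(model.trainable_params(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    stopper = EarlyStopper(config.patience)
    history: list[dict] = []
    best_snap = _snapshot(model)
    checkpoints: list[str] = []
    ckpt_dir = Path(config.checkpoint_dir) if config.checkpoint_dir else None
    if ckpt_dir:
        ckpt_dir.mkdir(parents=True, exist_ok=True)

    sigmoid_head = model.spec.output_head == "sigmoid"
    for epoch in range(config.max_epochs):
        epoch_loss = 0.0
        n_seen = 0
        for batch in _stratified_batches(tr_labels, config.batch_size, rng):
            enc = model.encode([tr_seqs[i] for i in batch])
            logits = model.forward(enc, train=True, rng=rng)
            y = tr_labels[batch]
            if sigmoid_head:
                loss = ad.bce_with_logits(logits[:, 0], y)
            else:
                loss = ad.softmax_cross_entropy(logits, y)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: {float(loss.data)!r}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(batch)
            n_seen += len(batch)

        val_tags_pred, _ = predict(model, val_seqs)
        val_mcc = metrics(confusion(val_tags_pred, val_tags)).MCC
        history.append(
            {"epoch": epoch, "train_loss": epoch_loss / max(1, n_seen), "val_mcc": val_mcc}
        )
        improved = val_mcc > stopper.best
        stop = stopper.update(epoch, val_mcc)
        if improved:
            best_snap = _snapshot(model)
            if ckpt_dir:
                path = ckpt_dir / f"epoch_{epoch:03d}.json"
                save_checkpoint(model, path, extra={"epoch": epoch, "val_mcc": val_mcc})
                checkpoints.append(str(path))
        logger.info("epoch %d: loss=%.4f val_mcc=%.4f", epoch,
                    epoch_loss / max(1, n_seen), val_mcc)
        if stop:
            break

    _restore(model, best_snap)
    if ckpt_dir:
        best_path = ckpt_dir / "best.json"
        save_checkpoint(
            model, best_path,
            extra={"epoch": stopper.best_epoch, "val_mcc": stopper.best},
        )
        checkpoints.append(str(best_path))
    return TrainingResult(
        model=model,
        history=history,
        best_epoch=stopper.best_epoch,
        best_val_mcc=float(stopper.best),
        checkpoints=checkpoints,
    )


# -- cross-validation --------------------------------------------------------

@dataclass
class CvReport:
    folds: list[MetricsReport]
    mean: dict[str, float]
    ci: dict[str, tuple[float, float]]
    level: float = 0.99
    method: str = "student-t"


def t_confidence_interval(values: Sequence[float], level: float = 0.99) -> tuple[float, float]:
    """Student-t interval on the mean with k-1 degrees of freedom."""
    v = np.asarray(values, dtype=float)
    k = len(v)
    if k < 2:
        raise ValueError("need at least two fold scores for an interval")
    m = float(v.mean())
    sd = float(v.std(ddof=1))
    if sd == 0.0:
        return (m, m)
    half = stats.t.ppf(0.5 + level / 2, df=k - 1) * sd / math.sqrt(k)
    return (m - half, m + half)


def kfold_cv(
    spec: ArchitectureSpec,
    dataset: PromoterDataset,
    k: int = 10,
    config: TrainingConfig | None = None,
    **model_kwargs,
) -> CvReport:
    """Stratified k-fold cross-validation training a fresh model per fold."""
    if k < 2:
        raise ValueError("k must be >= 2")
    config = config or TrainingConfig()
    labels = np.array([1 if t == "I" else 0 for t in dataset.tags])
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=config.seed % (2**32))
    folds: list[MetricsReport] = []
    for fold_i, (tr, te) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        model = build_model(spec, seed=config.seed + fold_i, **model_kwargs)
        train(model, dataset.subset(tr), config)
        folds.append(evaluate(model, dataset.subset(te)))
    names = ("Sn", "Sp", "PPV", "MCC")
    mean = {n: float(np.mean([getattr(f, n) for f in folds])) for n in names}
    ci = {n: t_confidence_interval([getattr(f, n) for f in folds]) for n in names}
    return CvReport(folds=folds, mean=mean, ci=ci)


# -- cross-testing -----------------------------------------------------------

INCOMPATIBLE = "incompatible"


@dataclass
class CrossTestMatrix:
    cells: dict[tuple[str, str], MetricsReport | str]
    provenance: dict[tuple[str, str], dict] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {}
        for (m, d), cell in self.cells.items():
            key = f"{m}|{d}"
            if isinstance(cell, MetricsReport):
                payload[key] = cell.as_dict() | {"undefined": list(cell.undefined)}
            else:
                payload[key] = cell
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    def to_tsv(self, path: str | Path, metric: str = "MCC") -> None:
        models = sorted({m for m, _ in self.cells})
        datasets = sorted({d for _, d in self.cells})
        with open(path, "w") as fh:
            fh.write("model\t" + "\t".join(datasets) + "\n")
            for m in models:
                row = [m]
                for d in datasets:
                    cell = self.cells[(m, d)]
                    row.append(
                        f"{getattr(cell, metric):.4f}"
                        if isinstance(cell, MetricsReport) else INCOMPATIBLE
                    )
                fh.write("\t".join(row) + "\n")


def cross_test(
    models: Mapping[str, Model], datasets: Mapping[str, PromoterDataset]
) -> CrossTestMatrix:
    """Evaluate every model on every dataset's full contents.

    Input-length mismatches are recorded as explicit ``incompatible``
    cells, never silently skipped.
    """
    cells: dict[tuple[str, str], MetricsReport | str] = {}
    provenance: dict[tuple[str, str], dict] = {}
    for mname, model in models.items():
        for dname, ds in datasets.items():
            lengths = {len(s) for s in ds.sequences}
            if lengths and lengths != {model.spec.input_length}:
                cells[(mname, dname)] = INCOMPATIBLE
            else:
                cells[(mname, dname)] = evaluate(model, ds)
            provenance[(mname, dname)] = {
                "model": mname,
                "dataset": dname,
                "n": len(ds),
                "input_length": model.spec.input_length,
            }
    return CrossTestMatrix(cells=cells, provenance=provenance)
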