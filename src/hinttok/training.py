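"""Training protocol: weighted metrics, early stopping, full experiments.

An experiment fine-tunes the classifier on HTL-augmented or control
tokenizations under a fixed protocol: optional TPE hyperparameter search
maximizing validation weighted F1, refit of the best trial with early
stopping (up to 50 epochs, patience 15, best-checkpoint restore), and a
single evaluation on the held-out test set.  Class imbalance is handled
through support-weighted metrics only; reported values are rounded to
two decimals while full precision is kept internally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Protocol, Sequence

import numpy as np
from sklearn.metrics import precision_recall_fscore_support

from .encoder import EncoderSpec, TinyTransformerClassifier, TrainingDivergedError
from .mutation import (
    MutantRecord,
    STANDARD_AA,
    base_vocabulary,
    extend_vocabulary,
    tokenize_record,
)
from .search import SearchSpace, SearchResult, tpe_search
from .splitting import DatasetSplit, LabeledDataset


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetricsReport:
    """Support-weighted precision/recall/F1 with per-class detail.

    Weighted recall equals accuracy by construction (support weighting is
    an algebraic identity).  ``rounded()`` applies the two-decimal
    reporting policy; the stored fields keep full precision.
    """

    weighted_f1: float
    weighted_precision: float
    weighted_recall: float
    per_class: dict[str, dict[str, float]]
    n: int

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        return {
            "weighted_f1": round(self.weighted_f1, ndigits),
            "weighted_precision": round(self.weighted_precision, ndigits),
            "weighted_recall": round(self.weighted_recall, ndigits),
        }

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


def evaluate_weighted_metrics(
    y_true: Sequence, y_pred: Sequence, labels: Optional[Sequence] = None
) -> MetricsReport:
    """Weighted metrics: each class's score weighted by its true support.

    Classes absent from ``y_true`` carry zero weight.
    """
    y_true, y_pred = list(y_true), list(y_pred)
    if len(y_true) == 0 or len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must be non-empty and equal length")
    if labels is None:
        labels = sorted(set(y_true) | set(y_pred))
    p, r, f, s = precision_recall_fscore_support(
        y_true, y_pred, labels=list(labels), zero_division=0
    )
    wp, wr, wf, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=list(labels), average="weighted", zero_division=0
    )
    per_class = {
        str(lab): {
            "precision": float(p[i]),
            "recall": float(r[i]),
            "f1": float(f[i]),
            "support": int(s[i]),
        }
        for i, lab in enumerate(labels)
    }
    return MetricsReport(float(wf), float(wp), float(wr), per_class, len(y_true))


def relative_improvement(f1_htl: float, f1_ctrl: float) -> float:
    """Percent change, ``100 * (f1_htl - f1_ctrl) / f1_ctrl``."""
    if f1_ctrl <= 0:
        raise ValueError("relative improvement undefined for baseline <= 0")
    return 100.0 * (f1_htl - f1_ctrl) / f1_ctrl


def absolute_improvement(f1_htl: float, f1_ctrl: float) -> float:
    """Gain in percentage points, ``100 * (f1_htl - f1_ctrl)``."""
    return 100.0 * (f1_htl - f1_ctrl)


# ---------------------------------------------------------------------------
# Early stopping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    """Protocol constants: 50-epoch cap, patience 15, weighted-F1 selection."""

    max_epochs: int = 50
    patience: int = 15
    batch_size: int = 32
    learning_rate: float = 1e-3
    dropout: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.patience <= self.max_epochs:
            raise ValueError("require 0 < patience <= max_epochs")


class EarlyStopper:
    """Stops when the score has not strictly improved for `patience` epochs."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best_score = -np.inf
        self.best_epoch = 0
        self.stale = 0

    def update(self, epoch: int, score: float) -> bool:
        """Record an epoch score; returns True when training should stop."""
        if score > self.best_score:
            self.best_score = score
            self.best_epoch = epoch
            self.stale = 0
        else:
            self.stale += 1
        return self.stale >= self.patience


class TrainableModel(Protocol):
    """What :func:`fit_with_early_stopping` needs from a model."""

    def train_epoch(self, ids, y, rng, lr, batch_size, dropout) -> float: ...
    def predict(self, ids) -> np.ndarray: ...
    def state_dict(self) -> dict: ...
    def load_state_dict(self, state: dict) -> None: ...


@dataclass
class FitResult:
    validation_curve: list[float]
    stopping_epoch: int
    best_epoch: int
    best_score: float


def fit_with_early_stopping(
    model: TrainableModel,
    train_data: tuple[np.ndarray, np.ndarray],
    val_data: tuple[np.ndarray, np.ndarray],
    cfg: TrainConfig,
    class_labels: Optional[Sequence] = None,
) -> FitResult:
    """Train with best-checkpoint restore and patience-based stopping.

    The validation score is weighted F1.  Stops after the first epoch at
    which the score has failed to improve for ``cfg.patience`` consecutive
    epochs, otherwise at ``cfg.max_epochs``; the parameters from the best
    validation epoch are restored before returning.
    """
    Xtr, ytr = train_data
    Xva, yva = val_data
    rng = np.random.default_rng(cfg.seed)
    stopper = EarlyStopper(cfg.patience)
    best_state = model.state_dict()
    curve: list[float] = []
    epoch = 0
    for epoch in range(1, cfg.max_epochs + 1):
        model.train_epoch(
            Xtr, ytr, rng,
            lr=cfg.learning_rate, batch_size=cfg.batch_size, dropout=cfg.dropout,
        )
        pred = model.predict(Xva)
        score = evaluate_weighted_metrics(yva, pred, labels=class_labels).weighted_f1
        curve.append(score)
        if score > stopper.best_score:
            best_state = model.state_dict()
        if stopper.update(epoch, score):
            break
    model.load_state_dict(best_state)
    return FitResult(curve, epoch, stopper.best_epoch, stopper.best_score)


# ---------------------------------------------------------------------------
# Full experiment
# ---------------------------------------------------------------------------

@dataclass
class TrainingResult:
    """Everything needed to replay one experiment."""

    htl: bool
    best_params: dict
    validation_curve: list[float]
    stopping_epoch: int
    best_epoch: int
    best_val_f1: float
    test_metrics: MetricsReport
    seeds: dict[str, int]
    search: Optional[SearchResult] = field(default=None, repr=False)

    def metrics_json(self) -> str:
        payload = {
            "htl": self.htl,
            "best_params": self.best_params,
            "stopping_epoch": self.stopping_epoch,
            "best_epoch": self.best_epoch,
            "best_val_f1": self.best_val_f1,
            "validation_curve": self.validation_curve,
            "test": asdict(self.test_metrics),
            "seeds": self.seeds,
        }
        return json.dumps(payload, sort_keys=True)


def encode_dataset(
    ds: LabeledDataset,
    htl: bool,
    alphabet: str = STANDARD_AA,
    max_len: Optional[int] = None,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Tokenize every record into a padded id matrix plus integer labels.

    Returns ``(ids, y, meta)`` where ``meta`` carries the vocabulary, the
    class ordering and each record's residue-position map (hint and pad
    slots marked -1), used later for embedding extraction.
    """
    vocab = extend_vocabulary(base_vocabulary(alphabet))
    encoded = []
    maps = []
    for rec in ds.records:
        aug, ids = tokenize_record(rec, vocab, htl=htl, max_len=max_len)
        encoded.append(ids)
        maps.append([(-1 if p is None else p) for p in aug.residue_index_map])
    T = max(len(e) for e in encoded)
    pad_id = vocab.base_map["<pad>"]
    X = np.full((len(encoded), T), pad_id, dtype=np.int64)
    M = np.full((len(encoded), T), -1, dtype=np.int64)
    for i, (ids, pm) in enumerate(zip(encoded, maps)):
        X[i, : len(ids)] = ids
        M[i, : len(pm)] = pm
    y = np.array([ds.classes.index(r.label) for r in ds.records], dtype=np.int64)
    meta = {"vocab": vocab, "classes": ds.classes, "residue_positions": M}
    return X, y, meta


def run_experiment(
    ds: LabeledDataset,
    split: DatasetSplit,
    htl: bool,
    encoder_spec: EncoderSpec,
    search_space: Optional[SearchSpace],
    cfg: TrainConfig,
    alphabet: str = STANDARD_AA,
    search_cfg: Optional[TrainConfig] = None,
    return_model: bool = False,
):
    """Search → refit best trial → one held-out test evaluation.

    ``search_space=None`` skips the search and trains with ``cfg``'s own
    hyperparameters.  ``search_cfg`` may shorten the per-trial budget used
    inside the search.  Fully deterministic for fixed seeds.
    """
    if not split.audit.get("partition_valid", True):
        raise ValueError("split does not partition the dataset")
    X, y, meta = encode_dataset(ds, htl, alphabet, max_len=encoder_spec.max_len)
    if htl and encoder_spec.vocab_size < meta["vocab"].size:
        raise ValueError(
            f"vocab_size {encoder_spec.vocab_size} < required {meta['vocab'].size}"
        )
    tr, va, te = list(split.train), list(split.val), list(split.test)
    labels = list(range(len(ds.classes)))

    def make_model(seed: int) -> TinyTransformerClassifier:
        model = TinyTransformerClassifier(encoder_spec, seed=seed)
        return model

    def trial_cfg(params: dict, base: TrainConfig) -> TrainConfig:
        return TrainConfig(
            max_epochs=base.max_epochs,
            patience=base.patience,
            batch_size=int(params.get("batch_size", base.batch_size)),
            learning_rate=float(params.get("lr", base.learning_rate)),
            dropout=float(params.get("dropout", base.dropout)),
            seed=base.seed,
        )

    search_result: Optional[SearchResult] = None
    if search_space is not None:
        per_trial = search_cfg or cfg

        def objective(params: dict) -> float:
            model = make_model(cfg.seed)
            try:
                fit = fit_with_early_stopping(
                    model, (X[tr], y[tr]), (X[va], y[va]),
                    trial_cfg(params, per_trial), class_labels=labels,
                )
            except TrainingDivergedError:
                return float("-inf")
            return fit.best_score

        search_result = tpe_search(search_space, objective)
        best_params = search_result.best_params
    else:
        best_params = {
            "lr": cfg.learning_rate,
            "batch_size": cfg.batch_size,
            "dropout": cfg.dropout,
        }

    model = make_model(cfg.seed)
    fit = fit_with_early_stopping(
        model, (X[tr], y[tr]), (X[va], y[va]),
        trial_cfg(best_params, cfg), class_labels=labels,
    )
    pred = model.predict(X[te])
    test_metrics = evaluate_weighted_metrics(y[te], pred, labels=labels)
    result = TrainingResult(
        htl=htl,
        best_params=dict(best_params),
        validation_curve=fit.validation_curve,
        stopping_epoch=fit.stopping_epoch,
        best_epoch=fit.best_epoch,
        best_val_f1=fit.best_score,
        test_metrics=test_metrics,
        seeds={
            "train": cfg.seed,
            "model": cfg.seed,
            "search": search_space.seed if search_space else -1,
            "split": split.spec.seed,
        },
        search=search_result,
    )
    if return_model:
        return result, model, (X, y, meta)
    return result
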