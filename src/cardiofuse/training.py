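"""Training protocol: weighted cross-entropy, Adam with plateau decay,
early stopping, and the cross-validated experiment runner.

The schedule follows the experimental protocol exactly: Adam from a
learning rate of 0.01, multiplied by 0.1 whenever the *training* loss
has not strictly decreased for 5 consecutive epochs, training stopped
after 20 consecutive non-improving epochs or 100 epochs, batch sizes 32
(train) / 128 (eval), class weights inversely proportional to class
frequency, He initialization (applied at layer construction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .errors import TrainingError
from .network import FusionNetwork


@dataclass
class TrainConfig:
    max_epochs: int = 100
    learning_rate: float = 0.01
    lr_decay_factor: float = 0.1
    lr_patience: int = 5
    early_stop_patience: int = 20
    batch_size: int = 32
    eval_batch_size: int = 128
    l2: float = 1e-4
    loss_tol: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.lr_patience <= 0 or self.early_stop_patience <= 0:
            raise ValueError("patience values must be positive")
        if self.early_stop_patience <= self.lr_patience:
            raise ValueError(
                "early_stop_patience must exceed lr_plateau_patience"
            )


@dataclass
class TrainHistory:
    loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    stop_reason: str = "max_epochs"

    @property
    def n_epochs(self) -> int:
        return len(self.loss)


def class_weights(counts) -> np.ndarray:
    """Inverse-frequency weights, ``w_c = N_total / (K * N_c)``.

    Normalized so a balanced dataset gives all-ones; only the ratio
    matters for the gradients.
    """
    counts = np.asarray(counts, dtype=np.float64)
    if np.any(counts <= 0):
        raise ValueError(f"all class counts must be positive, got {counts}")
    return counts.sum() / (counts.size * counts)


class PlateauSchedule:
    """Multiply the lr by ``factor`` after ``patience`` consecutive epochs
    without a strict loss decrease (improvement = best - tol)."""

    def __init__(self, lr: float, factor: float = 0.1, patience: int = 5,
                 tol: float = 0.0):
        self.lr = lr
        self.factor = factor
        self.patience = patience
        self.tol = tol
        self.best = np.inf
        self.bad = 0

    def step(self, loss: float) -> float:
        if loss < self.best - self.tol:
            self.best = loss
            self.bad = 0
        else:
            self.bad += 1
            if self.bad >= self.patience:
                self.lr *= self.factor
                self.bad = 0
        return self.lr


class EarlyStopping:
    """Signal a stop after ``patience`` consecutive non-improving epochs."""

    def __init__(self, patience: int = 20, tol: float = 0.0):
        self.patience = patience
        self.tol = tol
        self.best = np.inf
        self.bad = 0

    def step(self, loss: float) -> bool:
        if loss < self.best - self.tol:
            self.best = loss
            self.bad = 0
            return False
        self.bad += 1
        return self.bad >= self.patience


def _decay_parameters(net: FusionNetwork):
    """Conv/dense weight matrices; BN parameters and biases are exempt."""
    return [p for name, p in net.named_parameters()
            if name.endswith("weight") and p.data.ndim >= 2]


def fit_network(net: FusionNetwork, X: np.ndarray, y: np.ndarray,
                cfg: TrainConfig,
                weights: np.ndarray | None = None,
                epoch_callback=None) -> TrainHistory:
    """Train ``net`` in place on (N, 2, L) inputs; returns the history.

    ``epoch_callback(epoch, loss)`` may return True to request a stop
    (recorded as ``"callback"``); used for accuracy-targeted runs.
    """
    n = X.shape[0]
    if n == 0:
        raise TrainingError("empty training set")
    X = np.asarray(X, dtype=nn.default_dtype())
    y = np.asarray(y, dtype=np.int64)
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(net.parameters(), lr=cfg.learning_rate, l2=cfg.l2,
                  decay_params=_decay_parameters(net))
    sched = PlateauSchedule(cfg.learning_rate, cfg.lr_decay_factor,
                            cfg.lr_patience, cfg.loss_tol)
    stopper = EarlyStopping(cfg.early_stop_patience, cfg.loss_tol)
    history = TrainHistory()
    net.train()
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        total, seen = 0.0, 0
        for i in range(0, n, cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            xb = nn.Tensor(X[idx])
            logits = net(xb)
            loss = nn.softmax_cross_entropy(logits, y[idx], weights)
            if not np.isfinite(loss.data):
                raise TrainingError(f"divergent loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += loss.item() * len(idx)
            seen += len(idx)
        epoch_loss = total / seen
        history.loss.append(epoch_loss)
        history.lr.append(opt.lr)
        opt.lr = sched.step(epoch_loss)
        if stopper.step(epoch_loss):
            history.stop_reason = "early_stop"
            break
        if epoch_callback is not None and epoch_callback(epoch, epoch_loss):
            history.stop_reason = "callback"
            break
    return history


def run_cross_validation(variant: str, dataset, k: int = 5, seed: int = 0,
                         estimator_params: dict | None = None,
                         folds: np.ndarray | None = None):
    """k-fold CV of one variant over a SegmentDataset.

    The fold assignment is seed-pinned, so different variants evaluated
    with the same seed see identical splits.  Returns
    ``(per_fold_reports, summary)`` where summary holds the mean and sd
    of each metric plus pooled-confusion metrics.
    """
    from .evaluation import metrics_report, summarize_reports
    from .model import CrossModalFusionClassifier
    from .preprocessing import make_folds

    if folds is None:
        folds = make_folds(dataset, k=k, seed=seed)
    params = dict(estimator_params or {})
    length = params.pop("input_len", None)
    X, y = dataset.arrays(length)
    reports = []
    for f in range(k):
        test = folds == f
        clf = CrossModalFusionClassifier(
            variant=variant, random_state=seed,
            **({"input_len": length} if length else {}), **params,
        )
        clf.fit(X[~test], y[~test])
        prob = clf.predict_proba(X[test])[:, 1]
        reports.append(metrics_report(y[test], prob))
    return reports, summarize_reports(reports)
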