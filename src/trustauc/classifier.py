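"""Supervised fine-tuning of the encoder with a binary score head.

Two training objectives: the AUC min-max margin surrogate (primal-dual
stochastic optimisation, stratified batches) and plain cross-entropy (the
ablation baseline). When a validation set is supplied, five model snapshots
are tracked per run — best validation accuracy, AUC, F1, lowest validation
loss, and last epoch — with first-epoch-wins tie-breaking.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .losses import (
    AUCMarginState,
    auc_margin_grads,
    auc_margin_objective,
    cross_entropy,
    pdsg_update,
)
from .nn import Dense, SGD, load_checkpoint, sigmoid, small_cnn

__all__ = [
    "FinetuneConfig",
    "CheckpointSet",
    "AUCMarginClassifier",
    "finetune",
    "CHECKPOINT_CRITERIA",
]

CHECKPOINT_CRITERIA = (
    "best_val_accuracy",
    "best_val_auc",
    "best_val_f1",
    "lowest_val_loss",
    "last_epoch",
)


@dataclass(frozen=True)
class FinetuneConfig:
    """Hyper-parameters for supervised fine-tuning."""

    loss: str = "auc_margin"  # or "cross_entropy"
    lr_primal: float = 0.05
    lr_dual: float | None = None  # defaults to lr_primal
    margin: float = 1.0
    epochs: int = 30
    batch_size: int = 32
    image_side: int = 32
    momentum: float = 0.9
    encoder_widths: tuple[int, ...] = (8, 16)
    seed: int = 0

    def __post_init__(self):
        if self.loss not in ("auc_margin", "cross_entropy"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.lr_primal <= 0 or (self.lr_dual is not None and self.lr_dual <= 0):
            raise ValueError("learning rates must be positive")
        if self.epochs < 1 or self.batch_size < 2:
            raise ValueError("epochs >= 1 and batch_size >= 2 required")


@dataclass
class CheckpointSet:
    """Paths (or in-memory snapshots) keyed by model-selection criterion."""

    entries: dict[str, dict] = field(default_factory=dict)

    def __getitem__(self, criterion: str) -> dict:
        if criterion not in self.entries:
            raise KeyError(
                f"unknown criterion {criterion!r}; have {sorted(self.entries)}"
            )
        return self.entries[criterion]

    def complete(self) -> bool:
        return all(c in self.entries for c in CHECKPOINT_CRITERIA)


def _f1_at(scores, labels, thr=0.5):
    pred = scores >= thr
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


class AUCMarginClassifier(ClassifierMixin, BaseEstimator):
    """CNN binary classifier trained by AUC maximisation or cross-entropy.

    scikit-learn interface over the in-package CNN engine. ``fit`` accepts
    image arrays (n, h, w) or (n, c, h, w) in [0, 1] and binary labels;
    an optional validation set enables per-epoch metric history and the
    five-criterion checkpoint set.

    Parameters mirror :class:`FinetuneConfig`. ``init_encoder_state`` may
    be a state dict or a checkpoint path (e.g. from contrastive
    pre-training); the score head is always freshly initialised.

    Fitted attributes: ``encoder_``, ``head_``, ``state_`` (final
    AUC-margin auxiliaries), ``history_`` (list of per-epoch dicts),
    ``checkpoints_`` (CheckpointSet or None), ``alpha_history_`` (dual
    trajectory, one value per update), ``classes_``.
    """

    def __init__(
        self,
        loss: str = "auc_margin",
        lr: float = 0.05,
        lr_dual: float | None = None,
        margin: float = 1.0,
        epochs: int = 30,
        batch_size: int = 32,
        momentum: float = 0.9,
        encoder_widths: tuple[int, ...] = (8, 16),
        ksize: int = 3,
        init_encoder_state=None,
        seed: int = 0,
    ):
        self.loss = loss
        self.lr = lr
        self.lr_dual = lr_dual
        self.margin = margin
        self.epochs = epochs
        self.batch_size = batch_size
        self.momentum = momentum
        self.encoder_widths = encoder_widths
        self.ksize = ksize
        self.init_encoder_state = init_encoder_state
        self.seed = seed

    # ------------------------------------------------------------------
    @staticmethod
    def _check_X(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 3:
            X = X[:, None, :, :]
        if X.ndim != 4:
            raise ValueError("X must be (n, c, h, w) or (n, h, w)")
        return X

    def _batches(self, y: np.ndarray, rng) -> list[np.ndarray]:
        """Index batches for one epoch.

        Cross-entropy uses plain shuffled batches. The AUC margin loss is
        undefined on single-class batches, so it uses a stratified sampler:
        positives and negatives are shuffled separately and dealt across
        batches so every batch holds at least one of each.
        """
        n = len(y)
        n_batches = max(1, int(np.ceil(n / self.batch_size)))
        if self.loss == "cross_entropy":
            order = rng.permutation(n)
            return np.array_split(order, n_batches)
        pos = rng.permutation(np.flatnonzero(y == 1))
        neg = rng.permutation(np.flatnonzero(y == 0))
        if len(pos) == 0 or len(neg) == 0:
            raise ValueError("auc_margin requires both classes in the training set")
        n_batches = min(n_batches, len(pos), len(neg))
        pos_chunks = np.array_split(pos, n_batches)
        neg_chunks = np.array_split(neg, n_batches)
        return [
            rng.permutation(np.concatenate([p, q]))
            for p, q in zip(pos_chunks, neg_chunks)
        ]

    def _forward_scores(self, X: np.ndarray) -> np.ndarray:
        feats = self.encoder_.forward(X)
        logits = self.head_.forward(feats)[:, 0]
        return sigmoid(logits)

    def _snapshot(self) -> dict:
        return {
            "encoder": copy.deepcopy(self.encoder_.state_dict()),
            "head": {str(j): p.value.copy() for j, p in enumerate(self.head_.params())},
        }

    def _restore(self, snap: dict) -> None:
        self.encoder_.load_state_dict(snap["encoder"])
        for j, p in enumerate(self.head_.params()):
            p.value = np.asarray(snap["head"][str(j)], dtype=float).copy()
            p.grad = np.zeros_like(p.value)

    # ------------------------------------------------------------------
    def fit(self, X, y, X_val=None, y_val=None):
        cfg = FinetuneConfig(
            loss=self.loss,
            lr_primal=self.lr,
            lr_dual=self.lr_dual,
            margin=self.margin,
            epochs=self.epochs,
            batch_size=self.batch_size,
            momentum=self.momentum,
            encoder_widths=tuple(self.encoder_widths),
            seed=self.seed,
        )
        X = self._check_X(X)
        y = np.asarray(y, dtype=int)
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("labels must be binary {0, 1}")
        has_val = X_val is not None
        if has_val:
            X_val = self._check_X(X_val)
            y_val = np.asarray(y_val, dtype=int)
            if len(np.unique(y_val)) < 2:
                raise ValueError("validation split must contain both classes")

        rng = np.random.default_rng(self.seed)
        self.encoder_ = small_cnn(
            in_ch=X.shape[1], widths=tuple(self.encoder_widths), ksize=self.ksize, rng=rng
        )
        if self.init_encoder_state is not None:
            state = self.init_encoder_state
            if isinstance(state, (str, Path)):
                state, _ = load_checkpoint(state)
            self.encoder_.load_state_dict(state)
        self.head_ = Dense(self.encoder_widths[-1], 1, rng=rng)
        opt = SGD(
            self.encoder_.params() + self.head_.params(),
            lr=self.lr,
            momentum=self.momentum,
        )
        lr_dual = self.lr_dual if self.lr_dual is not None else self.lr
        # auxiliaries start at the sigmoid-score midpoint: an untrained head
        # emits scores near 0.5, so a = b = 0.5 avoids the saturation
        # collapse that a = b = 0 causes in the first updates
        state = AUCMarginState(a=0.5, b=0.5, margin=self.margin)

        from .evalviz import roc_auc  # local import avoids a cycle

        self.history_ = []
        self.alpha_history_ = []
        best: dict[str, tuple[float, int]] = {}
        checkpoints = CheckpointSet() if has_val else None

        for epoch in range(cfg.epochs):
            losses = []
            for idx in self._batches(y, rng):
                xb, yb = X[idx], y[idx]
                s = self._forward_scores(xb)
                if self.loss == "auc_margin":
                    loss = auc_margin_objective(s, yb, state)
                    g = auc_margin_grads(s, yb, state)
                    dlogit = g["score"] * s * (1.0 - s)
                    state = pdsg_update(state, g, self.lr, lr_dual)
                    self.alpha_history_.append(state.alpha_dual)
                else:
                    loss = cross_entropy(s, yb)
                    dlogit = (s - yb) / len(yb)
                opt.zero_grad()
                dfeat = self.head_.backward(dlogit[:, None])
                self.encoder_.backward(dfeat)
                opt.step()
                losses.append(loss)

            entry = {"epoch": epoch, "train_loss": float(np.mean(losses))}
            if has_val:
                vs = self._forward_scores(X_val)
                entry.update(
                    val_accuracy=float(np.mean((vs >= 0.5) == (y_val == 1))),
                    val_auc=roc_auc(vs, y_val),
                    val_f1=_f1_at(vs, y_val),
                    val_loss=(
                        auc_margin_objective(vs, y_val, state)
                        if self.loss == "auc_margin"
                        else cross_entropy(vs, y_val)
                    ),
                )
                for crit, key, sign in (
                    ("best_val_accuracy", "val_accuracy", 1),
                    ("best_val_auc", "val_auc", 1),
                    ("best_val_f1", "val_f1", 1),
                    ("lowest_val_loss", "val_loss", -1),
                ):
                    score = sign * entry[key]
                    if crit not in best or score > best[crit][0]:
                        best[crit] = (score, epoch)
                        checkpoints.entries[crit] = {
                            "epoch": epoch,
                            "metrics": {k: v for k, v in entry.items() if k != "epoch"},
                            "snapshot": self._snapshot(),
                        }
            self.history_.append(entry)

        if has_val:
            checkpoints.entries["last_epoch"] = {
                "epoch": cfg.epochs - 1,
                "metrics": {k: v for k, v in self.history_[-1].items() if k != "epoch"},
                "snapshot": self._snapshot(),
            }
        self.state_ = state
        self.checkpoints_ = checkpoints
        self.classes_ = np.array([0, 1])
        return self

    # ------------------------------------------------------------------
    def decision_function(self, X) -> np.ndarray:
        self._require_fitted()
        feats = self.encoder_.forward(self._check_X(X))
        return self.head_.forward(feats)[:, 0]

    def predict_proba(self, X) -> np.ndarray:
        s = sigmoid(self.decision_function(X))
        return np.column_stack([1.0 - s, s])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def scores(self, X) -> np.ndarray:
        """Post-sigmoid positive-class scores in (0, 1)."""
        return self.predict_proba(X)[:, 1]

    def _require_fitted(self):
        if not hasattr(self, "encoder_"):
            raise RuntimeError("AUCMarginClassifier is not fitted")

    # ------------------------------------------------------------------
    def load_snapshot(self, snap: dict) -> "AUCMarginClassifier":
        """Restore weights from a checkpoint snapshot (in place)."""
        self._require_fitted()
        self._restore(snap)
        return self

    def save(self, path, meta: dict | None = None) -> Path:
        """Persist encoder+head weights as .npz with a JSON sidecar."""
        self._require_fitted()
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        state = {f"encoder.{k}": v for k, v in self.encoder_.state_dict().items()}
        state.update(
            {f"head.{j}": p.value.copy() for j, p in enumerate(self.head_.params())}
        )
        np.savez(path, **state)
        sidecar = {
            "encoder_widths": list(self.encoder_widths),
            "ksize": self.ksize,
            "loss": self.loss,
            "margin": self.margin,
        }
        sidecar.update(meta or {})
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, default=float))
        return path

    @classmethod
    def from_checkpoint(cls, path, in_ch: int = 1) -> "AUCMarginClassifier":
        """Rebuild a fitted classifier from :meth:`save` output."""
        path = Path(path)
        with np.load(path) as npz:
            state = {k: npz[k] for k in npz.files}
        meta = json.loads(path.with_suffix(".json").read_text())
        clf = cls(
            loss=meta.get("loss", "auc_margin"),
            margin=meta.get("margin", 1.0),
            encoder_widths=tuple(meta.get("encoder_widths", (8, 16))),
            ksize=meta.get("ksize", 3),
        )
        clf.encoder_ = small_cnn(
            in_ch=in_ch, widths=tuple(clf.encoder_widths), ksize=clf.ksize
        )
        clf.head_ = Dense(clf.encoder_widths[-1], 1)
        clf.encoder_.load_state_dict(
            {k[len("encoder.") :]: v for k, v in state.items() if k.startswith("encoder.")}
        )
        head_state = {
            k[len("head.") :]: v for k, v in state.items() if k.startswith("head.")
        }
        for j, p in enumerate(clf.head_.params()):
            p.value = np.asarray(head_state[str(j)], dtype=float)
            p.grad = np.zeros_like(p.value)
        clf.classes_ = np.array([0, 1])
        clf.history_ = []
        clf.checkpoints_ = None
        clf.state_ = AUCMarginState(margin=clf.margin)
        return clf


def finetune(dataset, config: FinetuneConfig, init_encoder_state=None, out_dir=None):
    """Fine-tune on a dataset's train/val splits; optionally persist artifacts.

    Returns ``(clf, checkpoint_set, history)``. With ``out_dir`` set, each
    of the five checkpoints is written as ``<criterion>.npz`` (+ JSON
    sidecar) and the history as ``history.csv``.
    """
    train = dataset.subset("train")
    val = dataset.subset("val")
    for name, part in (("train", train), ("val", val)):
        n_neg, n_pos = part.counts()
        if n_neg == 0 or n_pos == 0:
            raise ValueError(f"{name} split must contain both classes")
    X, y = train.load(), train.labels()
    Xv, yv = val.load(), val.labels()
    clf = AUCMarginClassifier(
        loss=config.loss,
        lr=config.lr_primal,
        lr_dual=config.lr_dual,
        margin=config.margin,
        epochs=config.epochs,
        batch_size=config.batch_size,
        momentum=config.momentum,
        encoder_widths=config.encoder_widths,
        init_encoder_state=init_encoder_state,
        seed=config.seed,
    ).fit(X, y, X_val=Xv, y_val=yv)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for crit, entry in clf.checkpoints_.entries.items():
            snap = entry["snapshot"]
            keep = clf._snapshot()
            clf._restore(snap)
            clf.save(
                out_dir / f"{crit}.npz",
                meta={"criterion": crit, "epoch": entry["epoch"], **entry["metrics"]},
            )
            clf._restore(keep)
            entry["path"] = str(out_dir / f"{crit}.npz")
        pd.DataFrame(clf.history_).to_csv(out_dir / "history.csv", index=False)
    return clf, clf.checkpoints_, clf.history_
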