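"""Question-answer trust quantification.

A prediction is framed as a model answering a question: sample x, answer
y = M(x), correct answer z. Per-sample trust rewards deserved confidence and
penalises undeserved confidence:

    Q = C^alpha          if y == z   (correct answer)
    Q = (1 - C)^beta     if y != z   (incorrect answer)

where C is the model's confidence in the answer it actually gave, and
alpha/beta are reward/penalty relaxation coefficients (both default 1).

The practical procedure: (1) calibrate a decision threshold t maximising
positive-class F1 on the validation split; (2) map raw sigmoid scores
through a piecewise-linear normalisation so scores below t land in
[0, 0.5) and scores at/above t in [0.5, 1]; (3) take C = p for positive
answers and C = 1 - p for negative ones; (4) report the mean Q over
ground-truth-positive test samples as the model's positive-class trust
score.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "PredictionRecord",
    "TrustParams",
    "TrustReport",
    "select_threshold",
    "normalize_confidence",
    "qa_trust",
    "make_prediction_records",
    "positive_trust_score",
    "TrustScorer",
]


@dataclass(frozen=True)
class PredictionRecord:
    """One scored sample: raw score, thresholded answer, confidence, truth."""

    id: str
    raw_score: float
    true_label: int
    predicted_label: int
    confidence: float

    def __post_init__(self):
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError("confidence must be in [0, 1]")
        if self.true_label not in (0, 1) or self.predicted_label not in (0, 1):
            raise ValueError("labels must be 0 or 1")

    @property
    def correct(self) -> bool:
        return self.predicted_label == self.true_label


@dataclass(frozen=True)
class TrustParams:
    alpha: float = 1.0
    beta: float = 1.0
    threshold: float = 0.5

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must be in (0, 1)")


@dataclass
class TrustReport:
    per_sample_Q: list[tuple[str, float]]
    positive_trust: float
    n_positive: int
    negative_trust: float | None = None
    params: TrustParams | None = None

    def to_json(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = {
            "threshold": self.params.threshold if self.params else None,
            "alpha": self.params.alpha if self.params else None,
            "beta": self.params.beta if self.params else None,
            "positive_trust": self.positive_trust,
            "negative_trust": self.negative_trust,
            "n_positive": self.n_positive,
        }
        path.write_text(json.dumps(payload, indent=2))
        return path

    def per_sample_csv(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.per_sample_Q, columns=["id", "Q"]).to_csv(path, index=False)
        return path


def select_threshold(scores, labels) -> float:
    """F1-optimal decision threshold on a validation split.

    Candidates are the midpoints between consecutive distinct sorted
    scores plus the boundary candidates ``0.5*min`` and ``0.5*(1+max)``;
    classification rule is ``score >= t -> positive`` (ties at the
    threshold go to the minority positive class). Among F1 ties the
    smallest candidate wins, again favouring sensitivity.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.ndim != 1 or s.shape != y.shape:
        raise ValueError("scores and labels must be 1-D and aligned")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to calibrate a threshold")
    uniq = np.unique(s)
    cands = np.concatenate(
        [[0.5 * uniq[0]], (uniq[:-1] + uniq[1:]) / 2.0, [0.5 * (1.0 + uniq[-1])]]
    )
    cands = np.sort(cands)
    pred = s[None, :] >= cands[:, None]
    pos = y == 1
    tp = (pred & pos).sum(axis=1)
    fp = (pred & ~pos).sum(axis=1)
    fn = (~pred & pos).sum(axis=1)
    denom = 2 * tp + fp + fn
    f1 = np.where(denom > 0, 2 * tp / np.maximum(denom, 1), 0.0)
    return float(cands[int(np.argmax(f1))])  # argmax -> first (smallest) maximiser


def normalize_confidence(s, t: float):
    """Piecewise-linear score normalisation anchored at (0, t, 1).

    Maps raw sigmoid scores so negative-side scores land in [0, 0.5) and
    positive-side scores in [0.5, 1]: ``p = 0.5*s/t`` for s < t and
    ``p = 0.5 + 0.5*(s-t)/(1-t)`` otherwise. Continuous, strictly
    increasing, with p(t) = 0.5. Accepts scalars or arrays.
    """
    if not (0.0 < t < 1.0):
        raise ValueError("threshold must be strictly inside (0, 1)")
    s_arr = np.asarray(s, dtype=float)
    p = np.where(s_arr < t, 0.5 * s_arr / t, 0.5 + 0.5 * (s_arr - t) / (1.0 - t))
    return float(p) if np.isscalar(s) or s_arr.ndim == 0 else p


def qa_trust(C, correct, alpha: float = 1.0, beta: float = 1.0):
    """Per-answer question-answer trust Q. Vectorised over C/correct."""
    if alpha < 0 or beta < 0:
        raise ValueError("alpha and beta must be >= 0")
    C_arr = np.asarray(C, dtype=float)
    if np.any((C_arr < 0) | (C_arr > 1)):
        raise ValueError("confidence must lie in [0, 1]")
    corr = np.asarray(correct, dtype=bool)
    q = np.where(corr, C_arr**alpha, (1.0 - C_arr) ** beta)
    return float(q) if np.isscalar(C) or C_arr.ndim == 0 else q


def make_prediction_records(ids, scores, labels, params: TrustParams) -> list[PredictionRecord]:
    """Assign answers and confidences to raw scores under a threshold.

    y = 1 iff score >= t; confidence is the normalised score for positive
    answers and its complement for negative ones.
    """
    s = np.asarray(scores, dtype=float)
    z = np.asarray(labels, dtype=int)
    p = normalize_confidence(s, params.threshold)
    y = (s >= params.threshold).astype(int)
    C = np.where(y == 1, p, 1.0 - p)
    return [
        PredictionRecord(str(i), float(si), int(zi), int(yi), float(ci))
        for i, si, zi, yi, ci in zip(ids, s, z, y, C)
    ]


def positive_trust_score(records: list[PredictionRecord], params: TrustParams) -> TrustReport:
    """Mean question-answer trust over ground-truth-positive samples.

    Also computes the symmetric negative-class mean as auxiliary output;
    the headline number is the positive-class score.
    """
    z = np.array([r.true_label for r in records])
    if not np.any(z == 1):
        raise ValueError("no ground-truth-positive records: positive trust undefined")
    C = np.array([r.confidence for r in records])
    correct = np.array([r.correct for r in records])
    q = qa_trust(C, correct, params.alpha, params.beta)
    pos_mask = z == 1
    per_sample = [
        (r.id, float(qi)) for r, qi, m in zip(records, q, pos_mask) if m
    ]
    neg_mask = ~pos_mask
    neg_trust = float(q[neg_mask].mean()) if np.any(neg_mask) else None
    return TrustReport(
        per_sample_Q=per_sample,
        positive_trust=float(q[pos_mask].mean()),
        n_positive=int(pos_mask.sum()),
        negative_trust=neg_trust,
        params=params,
    )


class TrustScorer(BaseEstimator):
    """Threshold calibration + trust reporting as a small estimator.

    ``fit(scores_val, labels_val)`` selects the F1-optimal threshold on
    validation predictions; ``report(ids, scores, labels)`` then builds
    prediction records for a test set and returns its TrustReport.
    """

    def __init__(self, alpha: float = 1.0, beta: float = 1.0):
        self.alpha = alpha
        self.beta = beta

    def fit(self, scores, labels):
        self.threshold_ = select_threshold(scores, labels)
        return self

    def params_(self) -> TrustParams:
        if not hasattr(self, "threshold_"):
            raise RuntimeError("TrustScorer is not fitted")
        return TrustParams(alpha=self.alpha, beta=self.beta, threshold=self.threshold_)

    def report(self, ids, scores, labels) -> TrustReport:
        params = self.params_()
        records = make_prediction_records(ids, scores, labels, params)
        return positive_trust_score(records, params)
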