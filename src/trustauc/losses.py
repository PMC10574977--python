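"""Training objectives: AUC min-max margin surrogate and cross-entropy.

The AUC surrogate replaces pairwise AUC counting with a saddle-point
objective over two primal auxiliaries ``a``/``b`` (running surrogates for
the class-conditional score means), a non-negative dual ``alpha_dual`` and a
fixed margin ``m``:

    F = mean_pos (h-a)^2 + mean_neg (h-b)^2
        + 2 * alpha * (m - mean_pos h + mean_neg h) - alpha^2

minimised over (model, a, b) and maximised over alpha >= 0. At the analytic
saddle (a = mean_pos h, b = mean_neg h, alpha = max(0, m - mean_pos h +
mean_neg h)) its value is VarPos + VarNeg + max(0, m - mean_pos +
mean_neg)^2 — pushing the positive score mean above the negative one by at
least the margin while shrinking within-class score variance. Optimised by
primal-dual stochastic gradient steps with the dual projected onto [0, inf).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "AUCMarginState",
    "auc_margin_objective",
    "auc_margin_grads",
    "pdsg_update",
    "cross_entropy",
    "cross_entropy_grad",
]


@dataclass(frozen=True)
class AUCMarginState:
    """Persistent auxiliary state of the AUC margin saddle problem.

    ``alpha_dual`` is kept non-negative by projection after every update;
    ``margin`` is fixed within a run.
    """

    a: float = 0.0
    b: float = 0.0
    alpha_dual: float = 0.0
    margin: float = 1.0

    def __post_init__(self):
        if self.margin <= 0:
            raise ValueError("margin must be > 0")
        if self.alpha_dual < 0:
            raise ValueError("alpha_dual must be >= 0")


def _split_scores(scores, labels):
    h = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if h.shape != y.shape:
        raise ValueError("scores and labels must have the same shape")
    pos = h[y == 1]
    neg = h[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError(
            "batch must contain at least one positive and one negative; "
            "use a class-aware batch sampler"
        )
    return h, y, pos, neg


def auc_margin_objective(scores, labels, state: AUCMarginState) -> float:
    """Evaluate the min-max margin surrogate F on one mixed batch."""
    _, _, pos, neg = _split_scores(scores, labels)
    a, b, al, m = state.a, state.b, state.alpha_dual, state.margin
    return float(
        np.mean((pos - a) ** 2)
        + np.mean((neg - b) ** 2)
        + 2.0 * al * (m - pos.mean() + neg.mean())
        - al**2
    )


def auc_margin_grads(scores, labels, state: AUCMarginState) -> dict:
    """Analytic partials of F wrt each score, a, b and alpha_dual.

    Returned dict keys: ``score`` (array aligned with the batch), ``a``,
    ``b``, ``alpha_dual``.
    """
    h, y, pos, neg = _split_scores(scores, labels)
    a, b, al, m = state.a, state.b, state.alpha_dual, state.margin
    n_pos, n_neg = len(pos), len(neg)
    dscore = np.empty_like(h)
    dscore[y == 1] = 2.0 * (pos - a) / n_pos - 2.0 * al / n_pos
    dscore[y == 0] = 2.0 * (neg - b) / n_neg + 2.0 * al / n_neg
    return {
        "score": dscore,
        "a": float(-2.0 * np.mean(pos - a)),
        "b": float(-2.0 * np.mean(neg - b)),
        "alpha_dual": float(2.0 * (m - pos.mean() + neg.mean()) - 2.0 * al),
    }


def pdsg_update(
    state: AUCMarginState, grads: dict, lr_primal: float, lr_dual: float
) -> AUCMarginState:
    """One primal-dual stochastic step on (a, b, alpha_dual).

    Primal variables descend, the dual ascends and is projected back onto
    [0, inf). Model weights are updated separately through the ``score``
    gradients by the caller's optimiser.
    """
    vals = [grads["a"], grads["b"], grads["alpha_dual"]]
    if not np.all(np.isfinite(vals)):
        raise FloatingPointError(f"non-finite auxiliary gradient: {vals}")
    return replace(
        state,
        a=state.a - lr_primal * grads["a"],
        b=state.b - lr_primal * grads["b"],
        alpha_dual=max(0.0, state.alpha_dual + lr_dual * grads["alpha_dual"]),
    )


def cross_entropy(scores, labels, eps: float = 1e-12) -> float:
    """Mean binary cross-entropy on post-sigmoid scores.

    Scores exactly at 0 or 1 are clamped by ``eps`` (with a warning) so the
    logarithms stay finite.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if np.any((s <= 0) | (s >= 1)):
        warnings.warn("scores at the boundary of (0,1); clamping", stacklevel=2)
    s = np.clip(s, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(s) + (1.0 - y) * np.log(1.0 - s)))


def cross_entropy_grad(scores, labels, eps: float = 1e-12) -> np.ndarray:
    """d(mean BCE)/d(score) for post-sigmoid scores."""
    s = np.clip(np.asarray(scores, dtype=float), eps, 1.0 - eps)
    y = np.asarray(labels, dtype=float)
    return (s - y) / (s * (1.0 - s)) / len(s)
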