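"""Contrastive self-supervised pre-training of the backbone encoder.

Two independently augmented views of each image form a positive pair; all
other views in the batch act as negatives. Embeddings from a throwaway
projection head are L2-normalised and scored with the normalised-temperature
cross-entropy (NT-Xent) contrastive loss. Labels are never read: the whole
stage is unsupervised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.transform import resize
from sklearn.base import BaseEstimator, TransformerMixin

from .nn import SGD, projection_head, save_checkpoint, small_cnn

__all__ = [
    "AugmentationPolicy",
    "SSLConfig",
    "make_views",
    "nt_xent",
    "nt_xent_grad",
    "ContrastivePretrainer",
    "pretrain_encoder",
]


@dataclass(frozen=True)
class AugmentationPolicy:
    """Stochastic view-generation policy for contrastive pairs.

    ``crop_scale`` is the (min, max) fraction of image *area* retained by a
    random resized crop; ``intensity_jitter`` bounds both the additive
    brightness shift and the multiplicative contrast deviation;
    ``blur_sigma`` is a (min, max) Gaussian-blur range or None for off.
    The identity policy (crop (1,1), flip 0, jitter 0, blur None) is a no-op.
    """

    crop_scale: tuple[float, float] = (0.5, 1.0)
    flip_prob: float = 0.5
    intensity_jitter: float = 0.4
    blur_sigma: tuple[float, float] | None = None

    def __post_init__(self):
        lo, hi = self.crop_scale
        if not (0 < lo <= hi <= 1):
            raise ValueError("crop_scale must satisfy 0 < min <= max <= 1")
        if not (0.0 <= self.flip_prob <= 1.0):
            raise ValueError("flip_prob must be in [0, 1]")
        if self.intensity_jitter < 0:
            raise ValueError("intensity_jitter must be >= 0")
        if self.blur_sigma is not None:
            blo, bhi = self.blur_sigma
            if not (0 <= blo <= bhi):
                raise ValueError("blur_sigma range must be well-ordered")

    @classmethod
    def identity(cls) -> "AugmentationPolicy":
        return cls(crop_scale=(1.0, 1.0), flip_prob=0.0, intensity_jitter=0.0, blur_sigma=None)


@dataclass(frozen=True)
class SSLConfig:
    """Contrastive pre-training hyper-parameters.

    ``batch_pairs`` is N, the number of images per batch (2N views);
    the loss is undefined for N < 2. Canonical defaults: temperature 0.5,
    128-dimensional projection.
    """

    temperature: float = 0.5
    batch_pairs: int = 16
    epochs: int = 10
    learning_rate: float = 0.05
    projection_dim: int = 128
    hidden_dim: int = 64
    momentum: float = 0.9
    seed: int = 0

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.batch_pairs < 2:
            raise ValueError("batch_pairs must be >= 2")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


def _augment_one(img: np.ndarray, policy: AugmentationPolicy, rng) -> np.ndarray:
    """Apply one sampled augmentation chain to a (c, h, w) image in [0,1]."""
    c, h, w = img.shape
    out = img
    # random resized crop (area fraction -> side fraction)
    lo, hi = policy.crop_scale
    if hi < 1.0 or lo < 1.0:
        scale = rng.uniform(lo, hi)
        side = max(1, int(round(h * math.sqrt(scale))))
        if side < h:
            top = rng.integers(0, h - side + 1)
            left = rng.integers(0, w - side + 1)
            crop = out[:, top : top + side, left : left + side]
            out = np.stack(
                [
                    resize(crop[ch], (h, w), order=1, preserve_range=True,
                           anti_aliasing=False)
                    for ch in range(c)
                ]
            )
    if policy.flip_prob > 0 and rng.random() < policy.flip_prob:
        out = out[:, :, ::-1]
    if policy.intensity_jitter > 0:
        j = policy.intensity_jitter
        contrast = 1.0 + rng.uniform(-j, j)
        brightness = rng.uniform(-j, j)
        out = (out - 0.5) * contrast + 0.5 + brightness
    if policy.blur_sigma is not None:
        blo, bhi = policy.blur_sigma
        sigma = rng.uniform(blo, bhi)
        if sigma > 0:
            out = np.stack([gaussian_filter(out[ch], sigma) for ch in range(c)])
    return np.clip(np.ascontiguousarray(out, dtype=float), 0.0, 1.0)


def make_views(image: np.ndarray, policy: AugmentationPolicy, rng) -> tuple[np.ndarray, np.ndarray]:
    """Two independently augmented views of one image.

    ``image`` is (c, h, w) or (h, w) in [0, 1]; outputs keep the input
    dimensions and pixel range (clipped).
    """
    img = np.asarray(image, dtype=float)
    squeeze = img.ndim == 2
    if squeeze:
        img = img[None]
    a = _augment_one(img, policy, rng)
    b = _augment_one(img, policy, rng)
    if squeeze:
        a, b = a[0], b[0]
    return a, b


# --------------------------------------------------------------------------
# NT-Xent


def _similarity_logits(emb: np.ndarray, temperature: float):
    z = np.asarray(emb, dtype=float)
    if z.ndim != 2 or z.shape[0] % 2 != 0:
        raise ValueError("embeddings must be a 2N x d matrix")
    n2 = z.shape[0]
    if n2 < 4:
        raise ValueError("need at least N=2 pairs (4 rows)")
    norms = np.linalg.norm(z, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero embedding row: cosine similarity undefined")
    u = z / norms[:, None]
    s = (u @ u.T) / temperature
    np.fill_diagonal(s, -np.inf)
    partner = np.arange(n2) ^ 1  # rows 2i, 2i+1 are a pair
    return z, u, norms, s, partner


def nt_xent(embeddings: np.ndarray, temperature: float = 0.5) -> float:
    """Normalised-temperature cross-entropy contrastive loss.

    Rows 2i and 2i+1 of ``embeddings`` are the two views of image i. For
    each of the 2N anchors the partner view is the positive and the other
    2N-2 rows are negatives; the loss is the mean over anchors of
    ``-log softmax(sim(anchor, partner)/t)`` with cosine similarity.
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    _, _, _, s, partner = _similarity_logits(embeddings, temperature)
    smax = s.max(axis=1, keepdims=True)
    lse = smax[:, 0] + np.log(np.exp(s - smax).sum(axis=1))
    losses = lse - s[np.arange(len(partner)), partner]
    return float(losses.mean())


def nt_xent_grad(embeddings: np.ndarray, temperature: float = 0.5):
    """(loss, d loss / d embeddings) for the NT-Xent loss."""
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    z, u, norms, s, partner = _similarity_logits(embeddings, temperature)
    n2 = z.shape[0]
    smax = s.max(axis=1, keepdims=True)
    ex = np.exp(s - smax)
    p = ex / ex.sum(axis=1, keepdims=True)  # softmax rows, diag ~ 0
    loss = float(
        (smax[:, 0] + np.log(ex.sum(axis=1)) - s[np.arange(n2), partner]).mean()
    )
    g = p.copy()
    g[np.arange(n2), partner] -= 1.0
    g /= n2
    # s = u u^T / t  =>  dL/du = (g + g^T) u / t
    du = (g + g.T) @ u / temperature
    # chain through row normalisation u = z / ||z||
    dz = (du - u * (du * u).sum(axis=1, keepdims=True)) / norms[:, None]
    return loss, dz


# --------------------------------------------------------------------------
# Pre-trainer


class ContrastivePretrainer(TransformerMixin, BaseEstimator):
    """Self-supervised encoder pre-training via augmented-pair contrast.

    scikit-learn style: ``fit(X)`` on an unlabeled image array
    (n, c, h, w) or (n, h, w); ``transform(X)`` returns backbone features.
    The projection head exists only during fitting and is discarded.

    Attributes after fit: ``encoder_`` (the backbone), ``loss_history_``
    (per-epoch mean NT-Xent loss), ``feature_dim_``.
    """

    def __init__(
        self,
        temperature: float = 0.5,
        batch_pairs: int = 16,
        epochs: int = 10,
        learning_rate: float = 0.05,
        projection_dim: int = 128,
        hidden_dim: int = 64,
        momentum: float = 0.9,
        encoder_widths: tuple[int, ...] = (8, 16),
        ksize: int = 3,
        policy: AugmentationPolicy | None = None,
        init_encoder_state: dict | str | None = None,
        seed: int = 0,
    ):
        self.temperature = temperature
        self.batch_pairs = batch_pairs
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.projection_dim = projection_dim
        self.hidden_dim = hidden_dim
        self.momentum = momentum
        self.encoder_widths = encoder_widths
        self.ksize = ksize
        self.policy = policy
        self.init_encoder_state = init_encoder_state
        self.seed = seed

    @staticmethod
    def _check_X(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 3:
            X = X[:, None, :, :]
        if X.ndim != 4:
            raise ValueError("X must be (n, c, h, w) or (n, h, w)")
        if len(X) == 0:
            raise ValueError("empty image array")
        return X

    def fit(self, X, y=None):
        # validates the config eagerly
        SSLConfig(
            temperature=self.temperature,
            batch_pairs=self.batch_pairs,
            epochs=self.epochs,
            learning_rate=self.learning_rate,
            projection_dim=self.projection_dim,
            hidden_dim=self.hidden_dim,
            momentum=self.momentum,
            seed=self.seed,
        )
        X = self._check_X(X)
        n = len(X)
        if self.batch_pairs > n:
            raise ValueError(f"batch_pairs={self.batch_pairs} exceeds dataset size {n}")
        rng = np.random.default_rng(self.seed)
        policy = self.policy if self.policy is not None else AugmentationPolicy()

        encoder = small_cnn(in_ch=X.shape[1], widths=tuple(self.encoder_widths),
                            ksize=self.ksize, rng=rng)
        if self.init_encoder_state is not None:
            state = self.init_encoder_state
            if isinstance(state, (str, Path)):
                from .nn import load_checkpoint

                state, _ = load_checkpoint(state)
            encoder.load_state_dict(state)
        feat_dim = self.encoder_widths[-1]
        head = projection_head(feat_dim, self.hidden_dim, self.projection_dim, rng=rng)
        opt = SGD(encoder.params() + head.params(), lr=self.learning_rate,
                  momentum=self.momentum)

        history: list[float] = []
        for _ in range(self.epochs):
            order = rng.permutation(n)
            batch_losses = []
            for start in range(0, n - self.batch_pairs + 1, self.batch_pairs):
                idx = order[start : start + self.batch_pairs]
                views = np.empty((2 * len(idx),) + X.shape[1:])
                for j, i in enumerate(idx):
                    va, vb = make_views(X[i], policy, rng)
                    views[2 * j], views[2 * j + 1] = va, vb
                feats = encoder.forward(views)
                emb = head.forward(feats)
                loss, demb = nt_xent_grad(emb, self.temperature)
                opt.zero_grad()
                dfeat = head.backward(demb)
                encoder.backward(dfeat)
                opt.step()
                batch_losses.append(loss)
            history.append(float(np.mean(batch_losses)))

        self.encoder_ = encoder
        self.loss_history_ = history
        self.feature_dim_ = feat_dim
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "encoder_"):
            raise RuntimeError("ContrastivePretrainer is not fitted")
        return self.encoder_.forward(self._check_X(X))


def pretrain_encoder(dataset, policy, config: SSLConfig, out_dir):
    """Pre-train a backbone on a dataset's images and checkpoint it.

    Operates on image files only — record labels are never accessed.
    Returns ``(weights_path, loss_history)``; the checkpoint holds backbone
    weights only (projection head stripped) with a JSON config sidecar.
    """
    recs = list(dataset.records)
    if not recs:
        raise ValueError("empty dataset")
    X = np.stack(
        [
            np.asarray(_open_gray(dataset.resolve(r), dataset.image_side)) / 255.0
            for r in recs
        ]
    )[:, None, :, :]
    pre = ContrastivePretrainer(
        temperature=config.temperature,
        batch_pairs=config.batch_pairs,
        epochs=config.epochs,
        learning_rate=config.learning_rate,
        projection_dim=config.projection_dim,
        hidden_dim=config.hidden_dim,
        momentum=config.momentum,
        policy=policy,
        seed=config.seed,
    ).fit(X)
    out_dir = Path(out_dir)
    path = save_checkpoint(
        out_dir / "encoder_ssl.npz",
        pre.encoder_,
        {
            "stage": "ssl_pretrain",
            "epochs": config.epochs,
            "temperature": config.temperature,
            "batch_pairs": config.batch_pairs,
            "learning_rate": config.learning_rate,
            "projection_dim": config.projection_dim,
            "seed": config.seed,
            "encoder_widths": list(pre.encoder_widths),
            "final_loss": pre.loss_history_[-1] if pre.loss_history_ else None,
        },
    )
    return path, pre.loss_history_


def _open_gray(path, side):
    from PIL import Image

    with Image.open(path) as im:
        im = im.convert("L")
        if im.size != (side, side):
            im = im.resize((side, side), Image.BILINEAR)
        return np.asarray(im, dtype=float)
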