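"""Encoder and head builders plus checkpoint I/O.

The backbone is a plug-in: anything mapping an image batch (n, c, h, w) to a
feature matrix (n, d) works. The default used throughout tests and desk-scale
runs is a two-block CNN (conv-relu-pool twice, then global average pooling),
small enough to train on one CPU yet deep enough for class-activation maps.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .layers import Conv2d, Dense, GlobalAvgPool, MaxPool2, ReLU, Sequential

__all__ = [
    "small_cnn",
    "projection_head",
    "save_checkpoint",
    "load_checkpoint",
]


def small_cnn(
    in_ch: int = 1,
    widths: tuple[int, ...] = (8, 16),
    ksize: int = 3,
    rng=None,
) -> Sequential:
    """Two (or more) conv blocks followed by global average pooling.

    Feature dimension equals ``widths[-1]``. Layer names follow the pattern
    conv1/relu1/pool1, ..., so the last convolution (the canonical
    class-activation-map target) is ``conv{len(widths)}``.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    layers: list[tuple[str, object]] = []
    prev = in_ch
    for i, w in enumerate(widths, start=1):
        layers.append((f"conv{i}", Conv2d(prev, w, ksize=ksize, rng=rng)))
        layers.append((f"relu{i}", ReLU()))
        layers.append((f"pool{i}", MaxPool2()))
        prev = w
    layers.append(("gap", GlobalAvgPool()))
    return Sequential(layers)


def projection_head(in_dim: int, hidden_dim: int, out_dim: int, rng=None) -> Sequential:
    """Two-layer MLP used only during contrastive pre-training."""
    rng = np.random.default_rng(0) if rng is None else rng
    return Sequential(
        [
            ("proj1", Dense(in_dim, hidden_dim, rng=rng)),
            ("projrelu", ReLU()),
            ("proj2", Dense(hidden_dim, out_dim, rng=rng)),
        ]
    )


def save_checkpoint(path, model: Sequential, meta: dict) -> Path:
    """Write weights as ``.npz`` with a JSON sidecar (same stem, ``.json``)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.state_dict())
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(meta, indent=2, default=float))
    return path


def load_checkpoint(path) -> tuple[dict, dict]:
    """Return (state_dict, meta) for a checkpoint written by save_checkpoint."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with np.load(path) as npz:
        state = {k: npz[k] for k in npz.files}
    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return state, meta
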