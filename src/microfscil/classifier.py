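"""Feature extraction and the cosine-similarity classifier head.

Every similarity used downstream (prototypes, relation graphs, logits) is a
cosine, so embeddings are L2-normalized once here and the rest of the stack
works with unit vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tensor import Tensor, l2_normalize, no_grad
from .nn import Module


@dataclass
class EmbeddingSet:
    """A batch of d-dimensional features with their integer labels."""

    features: np.ndarray  # (N, d)
    labels: np.ndarray    # (N,)

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.features.ndim != 2 or self.features.shape[0] != self.labels.shape[0]:
            raise ValueError("features must be (N, d) aligned with N labels")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("non-finite feature rows")

    def __len__(self):
        return self.features.shape[0]


def _to_batch(images) -> np.ndarray:
    """Stack ImageSample pixels into an (N, C, H, W) float32 batch."""
    arrs = []
    for im in images:
        px = im.pixels if hasattr(im, "pixels") else np.asarray(im)
        if px.ndim == 2:
            px = px[..., None]
        arrs.append(np.transpose(px, (2, 0, 1)))
    return np.stack(arrs).astype(np.float32)


def embed(model: Module, images, labels=None, *, normalize: bool = True,
          batch_size: int = 256) -> EmbeddingSet:
    """Run the backbone in inference mode and return (optionally unit-norm)
    embeddings for a sequence of images.

    ``images`` may be ImageSamples (labels taken from them) or raw arrays with
    ``labels`` supplied separately.
    """
    if len(images) == 0:
        raise ValueError("embed() requires a nonempty batch")
    if labels is None:
        labels = [im.label for im in images]
    batch = _to_batch(images)
    feats = []
    with no_grad():
        for i in range(0, len(batch), batch_size):
            out = model(Tensor(batch[i:i + batch_size]))
            if normalize:
                out = l2_normalize(out)
            feats.append(out.data)
    return EmbeddingSet(np.concatenate(feats, axis=0), np.asarray(labels))


def embed_tensor(model: Module, images, *, normalize: bool = True) -> Tensor:
    """Differentiable embedding pass (gradient flows to the model)."""
    out = model(Tensor(_to_batch(images)))
    return l2_normalize(out) if normalize else out


@dataclass
class CosineHead:
    """Classifier whose logit for class c is ``scale * cos(f, w_c)``.

    Rows are class directions; growing the head appends rows for new classes.
    """

    weights: Tensor
    scale: float = 16.0
    frozen_rows: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @classmethod
    def init(cls, n_classes: int, dim: int, scale: float = 16.0, seed: int = 0) -> "CosineHead":
        rng = np.random.default_rng(seed)
        w = rng.normal(0.0, 1.0, (n_classes, dim)).astype(np.float32)
        w /= np.linalg.norm(w, axis=1, keepdims=True)
        return cls(weights=Tensor(w, requires_grad=True), scale=float(scale))

    @property
    def n_classes(self) -> int:
        return self.weights.shape[0]

    @property
    def dim(self) -> int:
        return self.weights.shape[1]

    def grow(self, new_rows: np.ndarray) -> None:
        """Append one direction per new class (e.g. rectified prototypes)."""
        new_rows = np.asarray(new_rows, dtype=np.float32)
        if new_rows.ndim != 2 or new_rows.shape[1] != self.dim:
            raise ValueError("new rows must be (C_new, d) matching the head dimension")
        self.weights.data = np.concatenate([self.weights.data, new_rows], axis=0)

    def set_rows(self, class_ids, rows: np.ndarray) -> None:
        self.weights.data[np.asarray(class_ids)] = np.asarray(rows, dtype=np.float32)

    def logits_tensor(self, features: Tensor) -> Tensor:
        """Differentiable cosine logits for an (N, d) feature tensor."""
        f = l2_normalize(features)
        w = l2_normalize(self.weights)
        return (f @ w.T) * self.scale

    def logits(self, features: np.ndarray) -> np.ndarray:
        f = np.asarray(features, dtype=np.float64)
        norms = np.linalg.norm(f, axis=1)
        if np.any(norms == 0):
            raise FloatingPointError("zero-norm feature row passed to cosine classifier")
        f = f / norms[:, None]
        w = self.weights.data.astype(np.float64)
        wn = np.linalg.norm(w, axis=1)
        if np.any(wn == 0):
            raise FloatingPointError("zero-norm classifier row")
        return (f @ (w / wn[:, None]).T) * self.scale


def classify(head: CosineHead, features) -> tuple[np.ndarray, np.ndarray]:
    """Cosine logits and argmax labels; ties broken toward the lowest class index.

    Accepts an :class:`EmbeddingSet` or a raw (N, d) array.
    """
    f = features.features if isinstance(features, EmbeddingSet) else np.asarray(features)
    if f.ndim == 1:
        f = f[None, :]
    if f.shape[1] != head.dim:
        raise ValueError(f"feature dim {f.shape[1]} does not match head dim {head.dim}")
    logits = head.logits(f)
    preds = logits.argmax(axis=1)  # np.argmax returns the first (lowest) index on ties
    return logits, preds
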