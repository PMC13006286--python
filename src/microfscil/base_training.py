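"""Base-session optimization with consistency-filtered pseudo-sample mining.

Each base epoch is divided into inner cycles. A cycle (i) trains on the
current working set with cross-entropy on cosine logits, (ii) draws one
stochastic "locally magnified" view of every *original* sample, (iii)
forwards the views inference-only and keeps exactly those whose predicted
label matches the ground truth, and (iv) merges the survivors into the
working set for the next cycle. The working set resets to the original
data at every epoch boundary, so the pseudo-sample pool is bounded.

No contrastive loss is optimized anywhere: the consistency filter alone is
what pulls augmented views of a class together, because views the model
already places on the wrong side of a decision boundary never re-enter
training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .classifier import CosineHead, EmbeddingSet, classify, embed, embed_tensor
from .config import OptimConfig
from .errors import PreconditionError
from .nn import SGD, Module
from .tensor import softmax_cross_entropy


@dataclass
class AugmentationPolicy:
    """Stochastic local-magnification policy T(.).

    A sub-window whose side is a fraction drawn from ``crop_scale_range`` is
    cropped at a random position and bilinearly resized back to the input
    size (magnification), optionally flipped, then brightness/color jittered.
    Sampling is reproducible: the view for draw index ``k`` depends only on
    ``(seed, k)``.
    """

    crop_scale_range: Tuple[float, float] = (0.3, 0.8)
    flip_prob: float = 0.5
    jitter_strength: float = 0.1
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.crop_scale_range
        if not (0.0 < lo <= hi <= 1.0):
            raise PreconditionError("crop_scale_range must satisfy 0 < min <= max <= 1")
        if not 0.0 <= self.flip_prob <= 1.0:
            raise PreconditionError("flip_prob must be in [0, 1]")
        if self.jitter_strength < 0:
            raise PreconditionError("jitter_strength must be >= 0")


@dataclass
class PseudoSampleSet:
    """Augmented views admitted by the consistency filter, with provenance."""

    samples: List[Tuple[np.ndarray, int]]
    provenance: List[Tuple[int, int]]  # (source sample index, cycle index)

    def __len__(self):
        return len(self.samples)


def _bilinear_resize(img: np.ndarray, out_size: int) -> np.ndarray:
    """Deterministic bilinear resize of (h, w, c) to (out_size, out_size, c)."""
    h, w = img.shape[:2]
    ys = np.linspace(0, h - 1, out_size)
    xs = np.linspace(0, w - 1, out_size)
    y0 = np.floor(ys).astype(int)
    x0 = np.floor(xs).astype(int)
    y1 = np.minimum(y0 + 1, h - 1)
    x1 = np.minimum(x0 + 1, w - 1)
    wy = (ys - y0)[:, None, None]
    wx = (xs - x0)[None, :, None]
    top = img[y0][:, x0] * (1 - wx) + img[y0][:, x1] * wx
    bot = img[y1][:, x0] * (1 - wx) + img[y1][:, x1] * wx
    return top * (1 - wy) + bot * wy


def augment(x: np.ndarray, policy: AugmentationPolicy, draw: int) -> np.ndarray:
    """One augmented view of ``x``; deterministic given ``(policy.seed, draw)``."""
    px = x.pixels if hasattr(x, "pixels") else np.asarray(x)
    H = px.shape[0]
    rng = np.random.default_rng(np.random.SeedSequence([int(policy.seed), int(draw)]))

    lo, hi = policy.crop_scale_range
    frac = rng.uniform(lo, hi)
    side = int(round(frac * H))
    if side < 1:
        raise PreconditionError("degenerate crop: window collapsed to zero pixels")
    out = px
    if side < H:
        top = rng.integers(0, H - side + 1)
        left = rng.integers(0, H - side + 1)
        out = _bilinear_resize(px[top:top + side, left:left + side], H)
    if rng.random() < policy.flip_prob:
        out = out[:, ::-1]
    if policy.jitter_strength > 0:
        shift = rng.uniform(-policy.jitter_strength, policy.jitter_strength)
        gains = 1.0 + rng.uniform(-policy.jitter_strength, policy.jitter_strength,
                                  size=(1, 1, px.shape[2]))
        out = out * gains + shift
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def consistency_filter(model: Module, head: CosineHead,
                       samples: Sequence[Tuple[np.ndarray, int]],
                       cycle: int = 0,
                       label_to_row: Optional[dict] = None) -> PseudoSampleSet:
    """Keep exactly the (view, label) pairs the current model classifies as
    their own label; the model is used inference-only and never updated."""
    if len(samples) == 0:
        return PseudoSampleSet([], [])
    images = [s[0] for s in samples]
    labels = np.array([s[1] for s in samples])
    rows = labels if label_to_row is None else np.array([label_to_row[l] for l in labels])
    es = embed(model, images, labels=labels)
    _, preds = classify(head, es)
    keep = preds == rows
    return PseudoSampleSet(
        samples=[(images[i], int(labels[i])) for i in np.flatnonzero(keep)],
        provenance=[(int(i), int(cycle)) for i in np.flatnonzero(keep)],
    )


@dataclass
class TrainLog:
    retention: List[float] = field(default_factory=list)       # per cycle
    working_set_sizes: List[int] = field(default_factory=list)  # per cycle
    epoch_loss: List[float] = field(default_factory=list)
    epoch_accuracy: List[float] = field(default_factory=list)
    gradient_steps: int = 0


def _train_one_pass(model: Module, head: CosineHead, images, rows, optimizer: SGD,
                    batch_size: int, rng: np.random.Generator) -> Tuple[float, float, int]:
    """One shuffled pass of CE-on-cosine-logits; returns (loss, acc, steps)."""
    order = rng.permutation(len(images))
    losses, correct, steps = [], 0, 0
    for i in range(0, len(order), batch_size):
        idx = order[i:i + batch_size]
        feats = embed_tensor(model, [images[j] for j in idx])
        logits = head.logits_tensor(feats)
        batch_rows = rows[idx]
        loss = softmax_cross_entropy(logits, batch_rows)
        optimizer.zero_grad()
        loss.backward()
        optimizer.step()
        losses.append(float(loss.data) * len(idx))
        correct += int((logits.data.argmax(axis=1) == batch_rows).sum())
        steps += 1
    return sum(losses) / len(images), correct / len(images), steps


def base_session_train(model: Module, head: CosineHead, base_data: Sequence,
                       policy: AugmentationPolicy, epochs: int,
                       cycles_per_epoch: int = 10,
                       optim_config: Optional[OptimConfig] = None,
                       seed: int = 0, mining: bool = True,
                       label_to_row: Optional[dict] = None) -> TrainLog:
    """Run the base session, mutating ``model`` and ``head`` in place.

    With ``mining=False`` (or a filter that retains nothing) every cycle is
    plain supervised cross-entropy on the original data.
    """
    if len(base_data) == 0:
        raise PreconditionError("base_data must be nonempty")
    if cycles_per_epoch < 1:
        raise PreconditionError("cycles_per_epoch must be >= 1")
    cfg = optim_config or OptimConfig()
    if label_to_row is None:
        label_to_row = {l: i for i, l in enumerate(sorted({s.label for s in base_data}))}

    params = list(model.parameters()) + [head.weights]
    optimizer = SGD(params, lr=cfg.lr, momentum=cfg.momentum,
                    weight_decay=cfg.weight_decay, clip_norm=cfg.clip_norm)
    milestones = set(cfg.resolved_milestones(epochs))
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 404]))
    log = TrainLog()

    originals = [(s.pixels if hasattr(s, "pixels") else np.asarray(s), s.label)
                 for s in base_data]
    n_orig = len(originals)
    draw_counter = 0

    for epoch in range(epochs):
        if epoch in milestones:
            optimizer.lr *= cfg.lr_decay
        working = list(originals)  # pseudo-sample pool resets every epoch
        ep_losses, ep_accs = [], []
        for cycle in range(cycles_per_epoch):
            images = [w[0] for w in working]
            rows = np.array([label_to_row[w[1]] for w in working])
            loss, acc, steps = _train_one_pass(model, head, images, rows, optimizer,
                                               cfg.batch_size, rng)
            log.gradient_steps += steps
            ep_losses.append(loss)
            ep_accs.append(acc)
            if mining:
                views = []
                for src, (px, lab) in enumerate(originals):
                    views.append((augment(px, policy, draw_counter), lab))
                    draw_counter += 1
                kept = consistency_filter(model, head, views, cycle=cycle,
                                          label_to_row=label_to_row)
                log.retention.append(len(kept) / n_orig)
                working.extend(kept.samples)
            else:
                log.retention.append(0.0)
            log.working_set_sizes.append(len(working))
        log.epoch_loss.append(float(np.mean(ep_losses)))
        log.epoch_accuracy.append(float(np.mean(ep_accs)))
    return log


def train_supervised_steps(model: Module, head: CosineHead, data: Sequence,
                           n_steps: int, optim_config: Optional[OptimConfig] = None,
                           seed: int = 0,
                           label_to_row: Optional[dict] = None) -> TrainLog:
    """Plain supervised training for an exact number of gradient steps —
    the equal-compute control arm for the mining ablation."""
    cfg = optim_config or OptimConfig()
    if label_to_row is None:
        label_to_row = {l: i for i, l in enumerate(sorted({s.label for s in data}))}
    params = list(model.parameters()) + [head.weights]
    optimizer = SGD(params, lr=cfg.lr, momentum=cfg.momentum,
                    weight_decay=cfg.weight_decay, clip_norm=cfg.clip_norm)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 404]))
    images = [s.pixels if hasattr(s, "pixels") else np.asarray(s) for s in data]
    rows = np.array([label_to_row[s.label] for s in data])
    log = TrainLog()
    # decay the lr at the same fraction of total steps as the mining arm would
    decay_points = {int(0.6 * n_steps), int(0.8 * n_steps)}
    while log.gradient_steps < n_steps:
        order = rng.permutation(len(images))
        for i in range(0, len(order), cfg.batch_size):
            if log.gradient_steps >= n_steps:
                break
            if log.gradient_steps in decay_points:
                optimizer.lr *= cfg.lr_decay
            idx = order[i:i + cfg.batch_size]
            feats = embed_tensor(model, [images[j] for j in idx])
            logits = head.logits_tensor(feats)
            loss = softmax_cross_entropy(logits, rows[idx])
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            log.gradient_steps += 1
    return log


def within_class_variance(embeddings: EmbeddingSet) -> float:
    """Mean (over classes) of the mean squared distance of unit-norm
    embeddings to their class centroid — the intra-class compactness measure."""
    f = embeddings.features / np.linalg.norm(embeddings.features, axis=1, keepdims=True)
    total, n_classes = 0.0, 0
    for c in np.unique(embeddings.labels):
        fc = f[embeddings.labels == c]
        total += float(((fc - fc.mean(axis=0)) ** 2).sum(axis=1).mean())
        n_classes += 1
    return total / n_classes
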