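"""Reusable scaled-down study protocols.

These drive both the test suite and the reproduction script: a 10-class
synthetic dataset (50 images/class, 32x32, inter-class similarity 0.3) is
carved into a 6-base / 2-way 2-shot protocol with two incremental sessions,
and three paired comparisons are run per seed:

* full method vs distillation-ablated (alpha = gamma = 0) — performance drop;
* mining-enabled vs plain supervised base training at equal gradient steps —
  intra-class compactness of the embedding space;
* plain 20-epoch training on all 10 classes — held-out accuracy of the
  synthetic benchmark (chance 10%).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np

from .base_training import (AugmentationPolicy, augment, base_session_train,
                            train_supervised_steps, within_class_variance)
from .classifier import CosineHead, EmbeddingSet, classify, embed
from .config import ExperimentConfig, OptimConfig, desk_scale_config
from .experiment import FSCILModel
from .nn import build_backbone
from .prototypes import compute_prototypes
from .protocol import split_fscil
from .runner import (SessionState, evaluate_session, run_incremental_session,
                     select_representatives)
from .synthetic import generate_dataset

#: dataset conditions of the scaled-down study
STUDY = dict(n_classes=10, n_per_class=50, image_size=32, similarity=0.3)


def between_class_variance(embeddings: EmbeddingSet) -> float:
    """Variance of the class-mean directions around their grand mean."""
    f = embeddings.features / np.linalg.norm(embeddings.features, axis=1,
                                             keepdims=True)
    means = np.stack([f[embeddings.labels == c].mean(axis=0)
                      for c in np.unique(embeddings.labels)])
    g = means.mean(axis=0)
    return float(((means - g) ** 2).sum(axis=1).mean())


def compactness_ratio(embeddings: EmbeddingSet) -> float:
    """Within-class variance normalized by between-class spread.

    On unit-norm embeddings the absolute within-class variance conflates
    class compactness with global shrinkage of the feature distribution;
    dividing by the between-class-mean variance isolates how tight classes
    are *relative to* how separable they are (lower is better)."""
    return within_class_variance(embeddings) / between_class_variance(embeddings)


@dataclass
class SeedOutcome:
    full_accs: List[float]
    ablated_accs: List[float]
    base_holdout_acc: float
    var_mining: float
    var_plain: float
    ratio_mining: float
    ratio_plain: float
    retention_first_epoch: float
    retention_last_epoch: float
    gradient_steps: int

    @property
    def full_pd(self) -> float:
        return self.full_accs[0] - self.full_accs[-1]

    @property
    def ablated_pd(self) -> float:
        return self.ablated_accs[0] - self.ablated_accs[-1]


def _clone(obj):
    return copy.deepcopy(obj)


def _probe_views(train, n_views: int = 3):
    """Fixed augmented views of the base training set, shared across arms."""
    policy = AugmentationPolicy(seed=999)
    images, labels = [], []
    for i, s in enumerate(train):
        for k in range(n_views):
            images.append(augment(s.pixels, policy, n_views * i + k))
            labels.append(s.label)
    return images, np.array(labels)


def run_seed_study(seed: int, config: ExperimentConfig | None = None) -> SeedOutcome:
    """One seed of the scaled-down comparison study (shared base session)."""
    cfg = config or desk_scale_config()
    samples, _ = generate_dataset(STUDY["n_classes"], STUDY["n_per_class"],
                                  STUDY["image_size"], STUDY["similarity"],
                                  seed=seed)
    prot = split_fscil(samples, cfg.n_base_classes, cfg.n_way, cfg.k_shot,
                       seed=seed)
    prot.begin_session(0)
    train = prot.train_samples(samples, 0)
    base_classes = prot.sessions[0].class_ids
    l2r = {c: i for i, c in enumerate(base_classes)}

    model = build_backbone(cfg.backbone, in_channels=3,
                           embed_dim=cfg.embed_dim, seed=seed)
    head = CosineHead.init(len(base_classes), cfg.embed_dim,
                           scale=cfg.classifier_scale, seed=seed)
    log = base_session_train(model, head, train, AugmentationPolicy(
        cfg.crop_scale_range, cfg.flip_prob, cfg.jitter_strength, seed=seed),
        epochs=cfg.base_epochs, cycles_per_epoch=cfg.cycles_per_epoch,
        optim_config=cfg.optim, seed=seed, mining=True, label_to_row=l2r)

    es = embed(model, train)
    bank = compute_prototypes(es, class_ids=base_classes)
    head.set_rows(np.arange(bank.n_classes), bank.matrix)
    memory = select_representatives(es, cfg.memory_per_class, bank)

    state0 = SessionState(0, model, head, bank, memory, cfg)
    acc0 = evaluate_session(state0, prot.test_samples(samples, 0))

    # --- the two incremental arms branch from the same base state
    arm_accs = {}
    for label, (a, g) in (("full", (cfg.alpha, cfg.gamma)),
                          ("ablated", (0.0, 0.0))):
        arm_cfg = _clone(cfg)
        arm_cfg.alpha, arm_cfg.gamma = a, g
        st = SessionState(0, _clone(model), _clone(head), _clone(bank),
                          _clone(memory), arm_cfg)
        accs = [acc0]
        for s in range(1, prot.n_sessions):
            prot.begin_session(s)
            imgs = prot.train_samples(samples, s)
            st, _ = run_incremental_session(st, prot.sessions[s], imgs,
                                            seed=seed + s)
            accs.append(evaluate_session(st, prot.test_samples(samples, s)))
        arm_accs[label] = accs
    prot.assert_no_cross_session_reads()

    # --- mining vs plain compactness at equal gradient steps
    plain_model = build_backbone(cfg.backbone, in_channels=3,
                                 embed_dim=cfg.embed_dim, seed=seed)
    plain_head = CosineHead.init(len(base_classes), cfg.embed_dim,
                                 scale=cfg.classifier_scale, seed=seed)
    train_supervised_steps(plain_model, plain_head, train, log.gradient_steps,
                           optim_config=cfg.optim, seed=seed, label_to_row=l2r)
    probe_imgs, probe_labels = _probe_views(train)
    es_m = embed(model, probe_imgs, labels=probe_labels)
    es_p = embed(plain_model, probe_imgs, labels=probe_labels)

    cpe = cfg.cycles_per_epoch
    return SeedOutcome(
        full_accs=arm_accs["full"], ablated_accs=arm_accs["ablated"],
        base_holdout_acc=acc0,
        var_mining=within_class_variance(es_m),
        var_plain=within_class_variance(es_p),
        ratio_mining=compactness_ratio(es_m),
        ratio_plain=compactness_ratio(es_p),
        retention_first_epoch=float(np.mean(log.retention[:cpe])),
        retention_last_epoch=float(np.mean(log.retention[-cpe:])),
        gradient_steps=log.gradient_steps,
    )


def run_scaled_study(seeds: Sequence[int]) -> Dict:
    """The full multi-seed study; returns per-seed outcomes and arm means."""
    outcomes = [run_seed_study(s) for s in seeds]
    return {
        "outcomes": outcomes,
        "mean_full_pd": float(np.mean([o.full_pd for o in outcomes])),
        "mean_ablated_pd": float(np.mean([o.ablated_pd for o in outcomes])),
        "mean_var_mining": float(np.mean([o.var_mining for o in outcomes])),
        "mean_var_plain": float(np.mean([o.var_plain for o in outcomes])),
        "mean_ratio_mining": float(np.mean([o.ratio_mining for o in outcomes])),
        "mean_ratio_plain": float(np.mean([o.ratio_plain for o in outcomes])),
        "mean_base_acc": float(np.mean([o.base_holdout_acc for o in outcomes])),
    }


def run_tenclass_benchmark(seed: int, epochs: int = 20) -> float:
    """Plain supervised training on all 10 synthetic classes (80/20 split);
    returns held-out accuracy as a fraction. Chance is 0.1."""
    samples, _ = generate_dataset(STUDY["n_classes"], STUDY["n_per_class"],
                                  STUDY["image_size"], STUDY["similarity"],
                                  seed=seed)
    labels = np.array([s.label for s in samples])
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 606]))
    tr_idx, te_idx = [], []
    for c in np.unique(labels):
        idx = rng.permutation(np.flatnonzero(labels == c))
        n_tr = int(round(0.8 * len(idx)))
        tr_idx += list(idx[:n_tr]); te_idx += list(idx[n_tr:])
    train = [samples[i] for i in tr_idx]
    test = [samples[i] for i in te_idx]
    cfg = desk_scale_config()
    model = build_backbone(cfg.backbone, in_channels=3,
                           embed_dim=cfg.embed_dim, seed=seed)
    head = CosineHead.init(len(np.unique(labels)), cfg.embed_dim,
                           scale=cfg.classifier_scale, seed=seed)
    base_session_train(model, head, train, AugmentationPolicy(seed=seed),
                       epochs=epochs, cycles_per_epoch=1,
                       optim_config=cfg.optim, seed=seed, mining=False)
    es = embed(model, test)
    _, pred = classify(head, es)
    return float((pred == es.labels).mean())


def tiny_determinism_config() -> ExperimentConfig:
    cfg = desk_scale_config()
    cfg.n_base_classes = 4
    cfg.n_way = 1
    cfg.k_shot = 2
    cfg.base_epochs = 3
    cfg.cycles_per_epoch = 2
    cfg.incremental_epochs = 5
    cfg.warmup_epochs = 2
    return cfg


def run_tiny_experiment(seed: int) -> List[float]:
    """A miniature but complete run (4 base classes + 2 one-way sessions on
    16x16 images) used for exact-replay determinism checks."""
    samples, _ = generate_dataset(6, 16, 16, 0.3, seed=seed)
    result = FSCILModel(samples, config=tiny_determinism_config()).fit(seed=seed)
    return result.accs
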