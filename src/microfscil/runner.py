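"""Incremental-session orchestration.

Each session, in order: (1) the teacher is re-initialized as an exact copy
of the current student; (2) the few-shot data is embedded and prototypes
for the new classes are computed, growing the prototype bank and the cosine
head; (3) the new prototypes are rectified toward their nearest base-class
prototype; (4) the student trains under the warm-up-mixed objective
L = w*L_CE + alpha*L_inst + gamma*L_proto with an EMA teacher update after
every optimizer step; (5) the new-class prototypes are refreshed from the
final student; (6) per-class representative features of the new classes are
added to the feature memory.

The feature memory stores embeddings only — never images — so earlier
sessions' raw data is never re-read (exemplar-free at the image level).
Stored vectors enter the student and teacher instance graphs identically;
only current-session images are re-embedded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence

import numpy as np

from .base_training import TrainLog
from .classifier import CosineHead, EmbeddingSet, classify, embed, embed_tensor
from .config import ExperimentConfig
from .distillation import (LossWeights, TeacherState, build_instance_graph,
                           build_prototype_graph, ema_update, graph_loss,
                           init_teacher, total_loss)
from .errors import PreconditionError, ProtocolError
from .nn import SGD, Module
from .prototypes import PrototypeBank, apply_rectification, compute_prototypes
from .protocol import FSCILProtocol, SessionSpec
from .tensor import Tensor, concat, no_grad, softmax_cross_entropy


@dataclass
class FeatureMemory:
    """Budgeted store of representative embeddings per seen class."""

    features: np.ndarray            # (M, d)
    labels: np.ndarray              # (M,)
    per_class_budget: int = 5

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.per_class_budget < 1:
            raise PreconditionError("per_class_budget must be >= 1")

    def __len__(self):
        return self.features.shape[0]

    def extend(self, other: "FeatureMemory") -> "FeatureMemory":
        return FeatureMemory(np.vstack([self.features, other.features]),
                             np.concatenate([self.labels, other.labels]),
                             self.per_class_budget)


def select_representatives(embeddings: EmbeddingSet, budget: int,
                           prototypes: PrototypeBank) -> FeatureMemory:
    """Per class, keep the ``budget`` embeddings most cosine-similar to the
    class prototype (the whole class if it is smaller than the budget)."""
    if budget < 1:
        raise PreconditionError("budget must be >= 1")
    f = embeddings.features
    fn = f / np.linalg.norm(f, axis=1, keepdims=True)
    keep_f, keep_l = [], []
    for c in np.unique(embeddings.labels):
        sel = np.flatnonzero(embeddings.labels == c)
        proto = prototypes.row_for_class(int(c))
        proto = proto / np.linalg.norm(proto)
        sims = fn[sel] @ proto
        top = sel[np.argsort(-sims, kind="stable")[:budget]]
        keep_f.append(fn[top])
        keep_l.append(np.full(len(top), c))
    return FeatureMemory(np.vstack(keep_f), np.concatenate(keep_l), budget)


@dataclass
class SessionState:
    """Everything carried from one session to the next."""

    session_id: int
    model: Module
    head: CosineHead
    bank: PrototypeBank
    memory: FeatureMemory
    config: ExperimentConfig
    logs: Dict[int, TrainLog] = field(default_factory=dict)

    def row_of(self, class_id: int) -> int:
        pos = np.flatnonzero(self.bank.class_ids == class_id)
        if len(pos) == 0:
            raise ProtocolError(f"class {class_id} unknown to the bank")
        return int(pos[0])


def evaluate_session(state: SessionState, test_images: Sequence) -> float:
    """Accuracy (percent) of the cosine head over all seen classes."""
    es = embed(state.model, test_images)
    _, pred_rows = classify(state.head, es)
    pred_classes = state.bank.class_ids[pred_rows]
    return 100.0 * float((pred_classes == es.labels).mean())


def _group_mean_matrix(labels: np.ndarray, class_ids: Sequence[int]) -> np.ndarray:
    """(C, N) averaging matrix M with M @ F = per-class mean of F's rows."""
    M = np.zeros((len(class_ids), len(labels)), dtype=np.float32)
    for i, c in enumerate(class_ids):
        sel = labels == c
        M[i, sel] = 1.0 / sel.sum()
    return M


def run_incremental_session(state: SessionState, spec: SessionSpec,
                            session_images: Sequence,
                            seed: int = 0) -> tuple[SessionState, TrainLog]:
    """Train one incremental session in place and return the updated state."""
    cfg = state.config
    new_classes = [int(c) for c in spec.class_ids]
    if any(c in set(state.bank.class_ids.tolist()) for c in new_classes):
        raise ProtocolError("session introduces a class that was already seen")
    labels = np.array([im.label for im in session_images])
    if set(labels.tolist()) != set(new_classes):
        raise ProtocolError("session data labels do not match the session spec")

    model, head = state.model, state.head
    # (1) teacher anchored to the previous session's knowledge
    teacher: TeacherState = init_teacher(model, head, momentum=cfg.ema_momentum)

    # (2) prototypes of the new classes from the k-shot data
    es = embed(model, session_images)
    new_protos = compute_prototypes(es, class_ids=new_classes)
    bank = state.bank.append(new_protos.matrix, new_classes)

    # (3) rectify only the rows introduced this session
    scratch = PrototypeBank(
        np.vstack([bank.matrix[: bank.n_base], new_protos.matrix]),
        n_base=bank.n_base,
        class_ids=np.concatenate([bank.class_ids[: bank.n_base], new_classes]))
    rectified = apply_rectification(scratch, cfg.beta)
    bank.matrix[-len(new_classes):] = rectified.matrix[bank.n_base:]
    head.grow(bank.matrix[-len(new_classes):])

    state = replace(state, session_id=spec.session_id, bank=bank)
    rows = np.array([state.row_of(int(l)) for l in labels])

    # (4) distillation-regularized few-shot training
    weights = LossWeights(alpha=cfg.alpha, gamma=cfg.gamma,
                          warmup_epochs=cfg.warmup_epochs)
    params = [] if cfg.freeze_backbone else list(model.parameters())
    params = params + [head.weights]
    opt = SGD(params, lr=cfg.optim.lr * cfg.incremental_lr_factor,
              momentum=cfg.optim.momentum, weight_decay=cfg.optim.weight_decay,
              clip_norm=cfg.optim.clip_norm)
    old_rows = np.arange(head.n_classes - len(new_classes))
    if len(old_rows):
        opt.mask_rows(head.weights, old_rows)  # few-shot CE must not erode old directions

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 505, spec.session_id]))
    base_matrix = bank.matrix[: bank.n_base]
    gm = _group_mean_matrix(labels, new_classes)
    mem_feats32 = state.memory.features.astype(np.float32)
    log = TrainLog()

    for epoch in range(cfg.incremental_epochs):
        feats_s = embed_tensor(model, session_images)           # unit-norm, differentiable
        logits = head.logits_tensor(feats_s)
        l_ce = softmax_cross_entropy(logits, rows)

        with no_grad():
            feats_t = embed_tensor(teacher.model, session_images)
        # prototype graph: per-class means of unit embeddings under both models
        protos_s = Tensor(gm) @ feats_s
        protos_t = gm @ feats_t.data
        h_s = build_prototype_graph(protos_s, base_matrix)
        h_t = build_prototype_graph(protos_t, base_matrix)
        l_proto = graph_loss(h_s, h_t)

        # instance graph over current embeddings + stored memory features
        pool_s = concat([feats_s, Tensor(mem_feats32)]) if len(state.memory) else feats_s
        pool_t = (np.vstack([feats_t.data, mem_feats32]) if len(state.memory)
                  else feats_t.data)
        n_pool = pool_s.shape[0]
        n_draw = min(cfg.distill_batch_size, n_pool)
        pick = rng.choice(n_pool, size=n_draw, replace=False)
        sel = np.zeros((n_draw, n_pool), dtype=np.float32)
        sel[np.arange(n_draw), pick] = 1.0
        g_s = build_instance_graph(Tensor(sel) @ pool_s)
        g_t = build_instance_graph(pool_t[pick])
        l_inst = graph_loss(g_s, g_t)

        loss = total_loss(l_ce, l_inst, l_proto, weights, epoch)
        opt.zero_grad()
        loss.backward()
        opt.step()
        ema_update(teacher, model)  # teacher tracks the feature extractor;
        # its head copy stays anchored at session start (graphs use features only)
        log.gradient_steps += 1
        log.epoch_loss.append(float(loss.data))
        log.retention.append(weights.ce_weight(epoch))  # ce ramp, for the record

    # (5) refresh the new-class prototypes from the final student
    es_final = embed(model, session_images)
    refreshed = compute_prototypes(es_final, class_ids=new_classes)
    bank.matrix[-len(new_classes):] = refreshed.matrix

    # (6) grow the feature memory with new-class representatives
    new_mem = select_representatives(es_final, state.memory.per_class_budget, bank)
    state = replace(state, memory=state.memory.extend(new_mem))
    state.logs[spec.session_id] = log
    return state, log
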