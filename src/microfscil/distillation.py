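"""Dual-graph knowledge distillation under an EMA teacher.

The teacher starts each incremental session as an exact copy of the student
and thereafter is updated only by an exponential moving average of the
student's parameters (never by back-propagation):

    theta_t <- m * theta_t + (1 - m) * theta_s,   m in [0, 1).

Two relational graphs are aligned between student and teacher by squared
Frobenius losses: the instance graph (N x N pairwise cosine similarities of
a feature batch) and the prototype graph (C_n x C_b cosine similarities of
incremental vs base prototypes). The total objective

    L = w(epoch) * L_CE + alpha * L_inst + gamma * L_proto

ramps the cross-entropy weight w linearly from 0 to 1 over a warm-up so the
relational constraints dominate early few-shot training.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from enum import Enum
from typing import Union

import numpy as np

from .classifier import EmbeddingSet
from .errors import NumericError, PreconditionError
from .nn import Module
from .tensor import Tensor, l2_normalize


class GraphKind(Enum):
    INSTANCE = "instance"
    PROTOTYPE = "prototype"


@dataclass
class SimilarityGraph:
    """Pairwise-cosine matrix; instance graphs are square/symmetric with unit
    diagonal, prototype graphs are C_n x C_b."""

    matrix: Union[np.ndarray, Tensor]
    kind: GraphKind

    @property
    def data(self) -> np.ndarray:
        return self.matrix.data if isinstance(self.matrix, Tensor) else self.matrix


@dataclass
class LossWeights:
    alpha: float = 1.0
    gamma: float = 1.0
    warmup_epochs: int = 0

    def __post_init__(self):
        if self.alpha < 0 or self.gamma < 0:
            raise PreconditionError("loss weights must be >= 0")
        if self.warmup_epochs < 0:
            raise PreconditionError("warmup_epochs must be >= 0")

    def ce_weight(self, epoch: int) -> float:
        """Linear ramp from 0 at epoch 0 to 1 at ``warmup_epochs``."""
        if self.warmup_epochs == 0:
            return 1.0
        return float(min(1.0, max(0.0, epoch / self.warmup_epochs)))


@dataclass
class TeacherState:
    """A by-value copy of the student, updated only by EMA."""

    model: Module
    head_weights: np.ndarray
    momentum: float = 0.99

    def __post_init__(self):
        if not 0.0 <= self.momentum <= 1.0:
            raise PreconditionError("momentum must be in [0, 1] "
                                    "(1.0 = fully frozen teacher)")


def init_teacher(student: Module, head=None, momentum: float = 0.99) -> TeacherState:
    """Deep-copy the student (and optionally its head rows) into a teacher."""
    teacher_model = copy.deepcopy(student)
    for p in teacher_model.parameters():
        p.grad = None  # isolated by the deep copy; forwards run under no_grad()
    hw = head.weights.data.copy() if head is not None else np.zeros((0, 0), np.float32)
    return TeacherState(model=teacher_model, head_weights=hw, momentum=momentum)


def ema_update(teacher: TeacherState, student: Module, head=None) -> TeacherState:
    """In-place EMA step: theta_t <- m theta_t + (1 - m) theta_s."""
    m = teacher.momentum
    t_params = dict(teacher.model.named_parameters())
    s_params = dict(student.named_parameters())
    if set(t_params) != set(s_params):
        raise PreconditionError("teacher/student parameter sets do not match")
    for k, tp in t_params.items():
        sp = s_params[k]
        if tp.data.shape != sp.data.shape:
            raise PreconditionError(f"shape mismatch for {k}")
        tp.data = m * tp.data + (1.0 - m) * sp.data
    if head is not None and teacher.head_weights.size:
        if teacher.head_weights.shape != head.weights.data.shape:
            raise PreconditionError("teacher/student head shapes do not match")
        teacher.head_weights = m * teacher.head_weights + (1.0 - m) * head.weights.data
    return teacher


def _normalize_rows(x: np.ndarray, what: str) -> np.ndarray:
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise NumericError(f"zero-norm {what} row in similarity graph")
    return x / norms


def build_instance_graph(features) -> SimilarityGraph:
    """N x N pairwise-cosine graph. Accepts an EmbeddingSet / ndarray (values
    only) or a Tensor (differentiable, for the student side of the loss)."""
    if isinstance(features, Tensor):
        if features.shape[0] < 2:
            raise PreconditionError("instance graph needs N >= 2")
        if np.any(np.linalg.norm(features.data, axis=1) == 0):
            raise NumericError("zero-norm feature row in similarity graph")
        fn = l2_normalize(features)
        return SimilarityGraph(fn @ fn.T, GraphKind.INSTANCE)
    f = features.features if isinstance(features, EmbeddingSet) else np.asarray(features)
    if f.shape[0] < 2:
        raise PreconditionError("instance graph needs N >= 2")
    fn = _normalize_rows(f.astype(np.float64), "feature")
    return SimilarityGraph(fn @ fn.T, GraphKind.INSTANCE)


def build_prototype_graph(p_incremental, p_base) -> SimilarityGraph:
    """C_n x C_b cosine graph between incremental and base prototypes."""
    if isinstance(p_incremental, Tensor):
        if np.any(np.linalg.norm(p_incremental.data, axis=1) == 0):
            raise NumericError("zero-norm prototype")
        pn = l2_normalize(p_incremental)
        pb = Tensor(_normalize_rows(np.asarray(p_base, dtype=np.float32), "prototype"))
        return SimilarityGraph(pn @ pb.T, GraphKind.PROTOTYPE)
    pn = _normalize_rows(np.asarray(p_incremental, dtype=np.float64), "prototype")
    pb = _normalize_rows(np.asarray(p_base, dtype=np.float64), "prototype")
    return SimilarityGraph(pn @ pb.T, GraphKind.PROTOTYPE)


def graph_loss(g_student: SimilarityGraph, g_teacher: SimilarityGraph):
    """Squared Frobenius norm of the graph difference; Tensor if the student
    graph is differentiable, float otherwise."""
    if g_student.kind != g_teacher.kind:
        raise PreconditionError("graph kinds do not match")
    if g_student.data.shape != g_teacher.data.shape:
        raise PreconditionError("graph shapes do not match")
    if isinstance(g_student.matrix, Tensor):
        diff = g_student.matrix - Tensor(g_teacher.data.astype(np.float32))
        return (diff * diff).sum()
    return float(((g_student.data - g_teacher.data) ** 2).sum())


def total_loss(l_ce, l_inst, l_proto, weights: LossWeights, epoch: int):
    """w(epoch) * L_CE + alpha * L_inst + gamma * L_proto.

    Works on floats or Tensors; with ``warmup_epochs=0`` this is the plain
    weighted sum."""
    for name, v in (("l_ce", l_ce), ("l_inst", l_inst), ("l_proto", l_proto)):
        val = float(v.data) if isinstance(v, Tensor) else float(v)
        if not np.isfinite(val) or val < 0:
            raise PreconditionError(f"{name} must be finite and >= 0, got {val}")
    w = weights.ce_weight(epoch)
    return l_ce * w + l_inst * weights.alpha + l_proto * weights.gamma
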