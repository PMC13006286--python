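"""Class prototypes and base-anchored rectification of few-shot prototypes.

A prototype is the arithmetic mean of a class's unit-normalized embeddings.
Prototypes of incremental classes are estimated from k-shot samples and are
therefore noisy; rectification pulls each one toward its most cosine-similar
base-class prototype by a convex combination with coefficient beta:

    p_tilde = (1 - beta) * p_new + beta * p_base[j*],   j* = argmax_j cos(p_new, p_base[j]).

Only base classes are matching candidates — previously learned incremental
classes never anchor a new one.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List

import numpy as np

from .classifier import EmbeddingSet
from .errors import DataError, NumericError, PreconditionError


@dataclass
class PrototypeBank:
    """C x d prototype matrix whose first ``n_base`` rows are base classes."""

    matrix: np.ndarray
    n_base: int
    class_ids: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.class_ids = np.asarray(self.class_ids, dtype=np.int64)
        if self.matrix.shape[0] != self.class_ids.shape[0]:
            raise PreconditionError("one class id per prototype row required")
        if not (0 <= self.n_base <= self.matrix.shape[0]):
            raise PreconditionError("n_base out of range")
        if not np.all(np.isfinite(self.matrix)):
            raise NumericError("non-finite prototype rows")
        norms = np.linalg.norm(self.matrix, axis=1)
        if self.matrix.shape[0] and np.any(norms == 0):
            raise NumericError("zero-norm prototype row")

    @property
    def n_classes(self) -> int:
        return self.matrix.shape[0]

    @property
    def base(self) -> "PrototypeBank":
        return PrototypeBank(self.matrix[: self.n_base].copy(), self.n_base,
                             self.class_ids[: self.n_base].copy())

    @property
    def incremental_matrix(self) -> np.ndarray:
        return self.matrix[self.n_base:]

    def append(self, rows: np.ndarray, class_ids) -> "PrototypeBank":
        return PrototypeBank(np.vstack([self.matrix, rows]), self.n_base,
                             np.concatenate([self.class_ids, np.asarray(class_ids)]))

    def row_for_class(self, class_id: int) -> np.ndarray:
        pos = np.flatnonzero(self.class_ids == class_id)
        if len(pos) == 0:
            raise DataError(f"class {class_id} not in bank")
        return self.matrix[pos[0]]


def compute_prototypes(embeddings: EmbeddingSet, class_ids=None) -> PrototypeBank:
    """Mean of L2-normalized embeddings per class; rows ordered by ``class_ids``
    (default: sorted classes present). ``n_base`` is set to the row count —
    callers repartition when growing a bank."""
    present = np.unique(embeddings.labels)
    if class_ids is None:
        class_ids = present
    rows = []
    f = embeddings.features
    norms = np.linalg.norm(f, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise NumericError("zero-norm embedding")
    fn = f / norms
    for c in class_ids:
        sel = embeddings.labels == c
        if not np.any(sel):
            raise DataError(f"class {c} has no embeddings")
        mean = fn[sel].mean(axis=0)
        if np.linalg.norm(mean) == 0:
            raise NumericError(f"class {c}: normalized embeddings average to the "
                               "zero vector")
        rows.append(mean)
    mat = np.vstack(rows)
    return PrototypeBank(mat, n_base=len(class_ids), class_ids=np.asarray(class_ids))


def _cosine_to_base(p: np.ndarray, base_matrix: np.ndarray) -> np.ndarray:
    pn = np.linalg.norm(p)
    if pn == 0:
        raise NumericError("zero-norm prototype cannot be rectified")
    bn = np.linalg.norm(base_matrix, axis=1)
    if np.any(bn == 0):
        raise NumericError("zero-norm base prototype")
    return (base_matrix @ p) / (bn * pn)


def rectify_prototype(p_new: np.ndarray, base_bank: PrototypeBank,
                      beta: float) -> tuple[np.ndarray, int]:
    """Convex-combine ``p_new`` with its most cosine-similar base prototype.

    Returns the rectified vector and the matched base row index (ties go to
    the lowest index).
    """
    if not 0.0 <= beta <= 1.0:
        raise PreconditionError("beta must be in [0, 1]")
    base = base_bank.matrix[: base_bank.n_base]
    if base.shape[0] == 0:
        raise PreconditionError("base bank is empty")
    p_new = np.asarray(p_new, dtype=np.float64)
    sims = _cosine_to_base(p_new, base)
    j_star = int(np.argmax(sims))  # first occurrence = lowest index on ties
    rectified = (1.0 - beta) * p_new + beta * base[j_star]
    return rectified, j_star


def apply_rectification(bank: PrototypeBank, beta: float) -> PrototypeBank:
    """Rectify every incremental row against the base rows; base rows untouched."""
    if bank.n_base < 1:
        raise PreconditionError("bank must contain at least one base row")
    if bank.n_base == bank.n_classes:
        return replace(bank, matrix=bank.matrix.copy(),
                       class_ids=bank.class_ids.copy())
    new_matrix = bank.matrix.copy()
    for i in range(bank.n_base, bank.n_classes):
        new_matrix[i], _ = rectify_prototype(bank.matrix[i], bank, beta)
    return replace(bank, matrix=new_matrix, class_ids=bank.class_ids.copy())
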