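"""Carving a labeled dataset into the few-shot class-incremental protocol.

Session 0 (the base session) holds ``n_base_classes`` with all of their
training samples; every later session introduces ``n_way`` novel classes
with exactly ``k_shot`` training samples each. After session *s* the model
is evaluated on the test samples of **every** class seen through session
*s*, and training images of earlier sessions are never exposed again — an
audit log enforces that exemplar-free contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Union

import numpy as np

from .errors import DataError, ProtocolError
from .synthetic import ImageSample


@dataclass
class SessionSpec:
    """Classes and shot budget of one session; session 0 is the base session."""

    session_id: int
    class_ids: List[int]
    shots_per_class: Union[int, str]  # "all" for the base session

    def __post_init__(self):
        if self.session_id < 0:
            raise ProtocolError("session_id must be >= 0")
        if self.shots_per_class != "all" and int(self.shots_per_class) < 1:
            raise ProtocolError("shots_per_class must be >= 1 or 'all'")


@dataclass
class FSCILProtocol:
    """The full session layout plus per-session train / cumulative test pools."""

    sessions: List[SessionSpec]
    train_idx: Dict[int, np.ndarray]   # session_id -> indices into the dataset
    test_idx: Dict[int, np.ndarray]    # session_id -> cumulative test pool indices
    n_way: int
    k_shot: int
    _active_session: int = field(default=-1, repr=False)
    access_log: List[tuple] = field(default_factory=list, repr=False)

    @property
    def n_sessions(self) -> int:
        return len(self.sessions)

    def classes_through(self, session_id: int) -> List[int]:
        out: List[int] = []
        for spec in self.sessions[: session_id + 1]:
            out.extend(spec.class_ids)
        return out

    # -- audited access -------------------------------------------------
    def begin_session(self, session_id: int) -> None:
        self._active_session = session_id

    def train_samples(self, dataset: Sequence[ImageSample], session_id: int
                      ) -> List[ImageSample]:
        """Fetch a session's training images, recording the access."""
        self.access_log.append((self._active_session, session_id))
        return [dataset[i] for i in self.train_idx[session_id]]

    def test_samples(self, dataset: Sequence[ImageSample], session_id: int
                     ) -> List[ImageSample]:
        return [dataset[i] for i in self.test_idx[session_id]]

    def assert_no_cross_session_reads(self) -> None:
        """Raise if any training images were read outside their own session."""
        bad = [(a, s) for a, s in self.access_log if a != s]
        if bad:
            raise ProtocolError(f"cross-session training-image reads: {bad}")


def split_fscil(dataset: Sequence[ImageSample], n_base_classes: int, n_way: int,
                k_shot: int, seed: int = 0, train_fraction: float = 0.8
                ) -> FSCILProtocol:
    """Split a labeled dataset into base + incremental sessions.

    Within each class an 80/20 train/test split is made by seeded shuffle;
    non-base classes are shuffled and chunked into consecutive groups of
    ``n_way``; each incremental class contributes exactly ``k_shot`` training
    samples drawn from its train split.
    """
    labels = np.array([s.label for s in dataset])
    classes = np.unique(labels)
    n_classes = len(classes)
    if n_base_classes < 1 or n_base_classes > n_classes:
        raise ProtocolError("n_base_classes out of range")
    n_novel = n_classes - n_base_classes
    if n_novel % n_way != 0:
        raise ProtocolError(
            f"{n_novel} non-base classes are not divisible into {n_way}-way sessions")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 303]))
    order = rng.permutation(classes)
    base_classes = np.sort(order[:n_base_classes])
    novel_classes = rng.permutation(order[n_base_classes:])

    train_by_class: Dict[int, np.ndarray] = {}
    test_by_class: Dict[int, np.ndarray] = {}
    for c in classes:
        idx = np.flatnonzero(labels == c)
        idx = idx[rng.permutation(len(idx))]
        n_train = max(1, int(round(train_fraction * len(idx)))) if len(idx) > 1 else 1
        n_train = min(n_train, len(idx) - 1) if len(idx) > 1 else 1
        train_by_class[int(c)] = np.sort(idx[:n_train])
        test_by_class[int(c)] = np.sort(idx[n_train:])

    for c in novel_classes:
        if len(train_by_class[int(c)]) < k_shot:
            raise DataError(f"class {int(c)} has fewer than k_shot={k_shot} "
                            "training samples")

    sessions = [SessionSpec(0, [int(c) for c in base_classes], "all")]
    train_idx = {0: np.concatenate([train_by_class[int(c)] for c in base_classes])}
    for s, start in enumerate(range(0, n_novel, n_way), start=1):
        chunk = [int(c) for c in novel_classes[start:start + n_way]]
        sessions.append(SessionSpec(s, chunk, k_shot))
        picks = []
        for c in chunk:
            pool = train_by_class[c]
            picks.append(pool[rng.choice(len(pool), size=k_shot, replace=False)])
        train_idx[s] = np.concatenate(picks)

    for s, idxs in train_idx.items():  # tag samples with their session of origin
        for i in idxs:
            dataset[i].session_id = s

    test_idx: Dict[int, np.ndarray] = {}
    for s in range(len(sessions)):
        seen: List[int] = []
        for spec in sessions[: s + 1]:
            seen.extend(spec.class_ids)
        test_idx[s] = np.concatenate([test_by_class[c] for c in seen])

    return FSCILProtocol(sessions=sessions, train_idx=train_idx, test_idx=test_idx,
                         n_way=n_way, k_shot=k_shot)
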