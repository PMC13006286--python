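"""Incremental-session orchestration: memory, growth, degenerate runs."""

import copy

import numpy as np
import pytest

from microfscil.classifier import CosineHead, EmbeddingSet, classify, embed
from microfscil.config import desk_scale_config
from microfscil.errors import ProtocolError
from microfscil.nn import build_backbone
from microfscil.prototypes import PrototypeBank, compute_prototypes, \
    rectify_prototype
from microfscil.protocol import split_fscil
from microfscil.runner import (FeatureMemory, SessionState, evaluate_session,
                               run_incremental_session, select_representatives)
from microfscil.synthetic import generate_dataset


# ------------------------------------------------- representative memory

def test_budget_saturation_stores_whole_class(rng):
    f = rng.normal(size=(4, 3))
    es = EmbeddingSet(f, np.zeros(4, int))
    bank = compute_prototypes(es)
    mem = select_representatives(es, budget=10, prototypes=bank)
    assert len(mem) == 4


def test_budget_one_matches_brute_force_scan(rng):
    f = rng.normal(size=(6, 4))
    labels = np.array([0, 0, 0, 1, 1, 1])
    es = EmbeddingSet(f, labels)
    bank = compute_prototypes(es)
    mem = select_representatives(es, budget=1, prototypes=bank)
    fn = f / np.linalg.norm(f, axis=1, keepdims=True)
    for c in (0, 1):
        proto = bank.row_for_class(c) / np.linalg.norm(bank.row_for_class(c))
        sims = fn[labels == c] @ proto
        best = fn[labels == c][np.argmax(sims)]
        assert np.allclose(mem.features[mem.labels == c][0], best)


def test_memory_labels_subset_of_input_labels(rng):
    f = rng.normal(size=(9, 3))
    labels = np.repeat([2, 5, 7], 3)
    es = EmbeddingSet(f, labels)
    mem = select_representatives(es, 2, compute_prototypes(es))
    assert set(mem.labels.tolist()) <= set(labels.tolist())
    assert all((mem.labels == c).sum() <= 2 for c in np.unique(labels))


# -------------------------------------------------- incremental sessions

@pytest.fixture(scope="module")
def tiny_state():
    """A small trained-ish base state: 4 base classes on 16px images."""
    cfg = desk_scale_config(n_base_classes=4, n_way=2, k_shot=2,
                            incremental_epochs=4, warmup_epochs=2)
    samples, _ = generate_dataset(8, 10, 16, 0.2, seed=21)
    prot = split_fscil(samples, 4, 2, 2, seed=21)
    prot.begin_session(0)
    train = prot.train_samples(samples, 0)
    base_classes = prot.sessions[0].class_ids
    model = build_backbone("convnet4", in_channels=3, embed_dim=32, seed=21)
    head = CosineHead.init(4, 32, seed=21)
    es = embed(model, train)
    bank = compute_prototypes(es, class_ids=base_classes)
    head.set_rows(np.arange(4), bank.matrix)
    memory = select_representatives(es, cfg.memory_per_class, bank)
    state = SessionState(0, model, head, bank, memory, cfg)
    return state, prot, samples


def _fresh(state):
    return copy.deepcopy(state)


def test_zero_epoch_session_is_rectified_prototype_classifier(tiny_state):
    """With epochs=0 the classifier after the session is exactly the base
    prototypes plus the rectified new-class prototypes."""
    state, prot, samples = tiny_state
    st = _fresh(state)
    st.config.incremental_epochs = 0
    prot.begin_session(1)
    imgs = prot.train_samples(samples, 1)
    es = embed(st.model, imgs)
    new_classes = prot.sessions[1].class_ids
    expected_rows = []
    raw = compute_prototypes(es, class_ids=new_classes)
    for r in raw.matrix:
        rect, _ = rectify_prototype(r, state.bank, st.config.beta)
        expected_rows.append(rect)
    st2, _ = run_incremental_session(st, prot.sessions[1], imgs, seed=0)
    assert np.allclose(st2.head.weights.data[-2:],
                       np.array(expected_rows, np.float32), atol=1e-6)
    # and evaluation equals nearest-prototype classification with those rows
    test_imgs = prot.test_samples(samples, 1)
    acc = evaluate_session(st2, test_imgs)
    es_t = embed(st2.model, test_imgs)
    _, pred_rows = classify(st2.head, es_t)
    manual = 100.0 * (st2.bank.class_ids[pred_rows] == es_t.labels).mean()
    assert acc == pytest.approx(manual)


def test_session_grows_bank_head_and_memory_consistently(tiny_state):
    state, prot, samples = tiny_state
    st = _fresh(state)
    prot.begin_session(1)
    imgs = prot.train_samples(samples, 1)
    st2, log = run_incremental_session(st, prot.sessions[1], imgs, seed=3)
    assert st2.bank.n_classes == state.bank.n_classes + 2
    assert st2.head.n_classes == st2.bank.n_classes
    assert st2.bank.n_base == state.bank.n_base          # base partition fixed
    assert len(np.unique(st2.memory.labels)) == 6
    assert log.gradient_steps == st.config.incremental_epochs


def test_session_rejects_already_seen_classes(tiny_state):
    state, prot, samples = tiny_state
    st = _fresh(state)
    spec = copy.deepcopy(prot.sessions[1])
    spec.class_ids = [state.bank.class_ids[0], 999]
    with pytest.raises(ProtocolError):
        run_incremental_session(st, spec, [], seed=0)


def test_base_prototype_rows_survive_the_session(tiny_state):
    """Base rows of the bank are never rewritten by an incremental session."""
    state, prot, samples = tiny_state
    st = _fresh(state)
    before = st.bank.matrix[: st.bank.n_base].copy()
    prot.begin_session(1)
    imgs = prot.train_samples(samples, 1)
    st2, _ = run_incremental_session(st, prot.sessions[1], imgs, seed=5)
    assert np.array_equal(st2.bank.matrix[: st2.bank.n_base], before)


def test_old_head_rows_frozen_during_few_shot_training(tiny_state):
    state, prot, samples = tiny_state
    st = _fresh(state)
    before = st.head.weights.data.copy()
    prot.begin_session(1)
    imgs = prot.train_samples(samples, 1)
    st2, _ = run_incremental_session(st, prot.sessions[1], imgs, seed=7)
    assert np.array_equal(st2.head.weights.data[: len(before)], before)
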