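"""Prototype computation and base-anchored rectification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from microfscil.classifier import EmbeddingSet
from microfscil.errors import DataError, NumericError, PreconditionError
from microfscil.prototypes import (PrototypeBank, apply_rectification,
                                   compute_prototypes, rectify_prototype)


def _bank(rows, n_base=None):
    rows = np.asarray(rows, float)
    return PrototypeBank(rows, n_base if n_base is not None else len(rows),
                         np.arange(len(rows)))


def test_prototype_of_single_sample_is_its_unit_embedding(rng):
    f = rng.normal(size=(3, 4))
    bank = compute_prototypes(EmbeddingSet(f, np.array([0, 1, 2])))
    for c in range(3):
        assert np.allclose(bank.matrix[c], f[c] / np.linalg.norm(f[c]))


def test_antipodal_embeddings_raise_numeric_error():
    f = np.array([[1.0, 0.0], [-1.0, 0.0]])
    with pytest.raises(NumericError):
        compute_prototypes(EmbeddingSet(f, np.array([0, 0])))


def test_prototypes_match_groupby_mean_oracle(rng):
    f = rng.normal(size=(15, 6))
    labels = np.repeat([0, 1, 2], 5)
    bank = compute_prototypes(EmbeddingSet(f, labels))
    fn = f / np.linalg.norm(f, axis=1, keepdims=True)
    for c in range(3):
        assert np.allclose(bank.matrix[c], fn[labels == c].mean(axis=0))


def test_missing_class_raises_naming_it():
    f = np.ones((2, 3))
    with pytest.raises(DataError, match="5"):
        compute_prototypes(EmbeddingSet(f, np.array([0, 0])), class_ids=[0, 5])


@pytest.mark.parametrize("beta,expect_self", [(0.0, True), (1.0, False)])
def test_rectification_endpoints(beta, expect_self, rng):
    base = _bank(rng.normal(size=(4, 3)))
    p = rng.normal(size=3)
    out, j = rectify_prototype(p, base, beta)
    if expect_self:
        assert np.allclose(out, p)
    else:
        assert np.allclose(out, base.matrix[j])


def test_hand_checked_two_dimensional_case():
    """p_new=(1,0) vs base rows (0,1) and (0.8,0.6) at beta=0.3: the second
    row wins (cos 0.8 > 0) and the output is 0.7*p + 0.3*row = (0.94, 0.18)."""
    base = _bank([[0.0, 1.0], [0.8, 0.6]])
    out, j = rectify_prototype(np.array([1.0, 0.0]), base, beta=0.3)
    assert j == 1
    assert np.allclose(out, [0.94, 0.18])


def test_matching_agrees_with_exhaustive_scan(rng):
    for _ in range(20):
        base = _bank(rng.normal(size=(6, 5)))
        p = rng.normal(size=5)
        _, j = rectify_prototype(p, base, 0.5)
        sims = [p @ b / (np.linalg.norm(p) * np.linalg.norm(b))
                for b in base.matrix]
        assert j == int(np.argmax(sims))


def test_rectification_moves_toward_match(rng):
    base = _bank(rng.normal(size=(3, 4)))
    p = rng.normal(size=4)
    _, j = rectify_prototype(p, base, 0.0)
    cos = lambda a, b: a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
    before = cos(p, base.matrix[j])
    for beta in (0.25, 0.5, 1.0):
        out, j2 = rectify_prototype(p, base, beta)
        assert j2 == j
        assert cos(out, base.matrix[j]) >= before - 1e-12


@settings(max_examples=40, deadline=None)
@given(st.integers(0, 10**6), st.floats(0.0, 1.0))
def test_rectified_is_convex_combination(seed, beta):
    rng = np.random.default_rng(seed)
    base = _bank(rng.normal(size=(3, 4)) + 0.1)
    p = rng.normal(size=4) + 0.1
    out, j = rectify_prototype(p, base, beta)
    lo = np.minimum(p, base.matrix[j]) - 1e-9
    hi = np.maximum(p, base.matrix[j]) + 1e-9
    assert np.all(out >= lo) and np.all(out <= hi)


def test_beta_out_of_range_rejected(rng):
    with pytest.raises(PreconditionError):
        rectify_prototype(np.ones(2), _bank(np.eye(2)), 1.5)


def test_apply_rectification_base_rows_untouched(rng):
    mat = rng.normal(size=(5, 4))
    bank = PrototypeBank(mat.copy(), n_base=3, class_ids=np.arange(5))
    out = apply_rectification(bank, 0.5)
    assert np.array_equal(out.matrix[:3], mat[:3])
    # each incremental row is the midpoint with its exhaustively matched base row
    for i in (3, 4):
        sims = [mat[i] @ b / (np.linalg.norm(mat[i]) * np.linalg.norm(b))
                for b in mat[:3]]
        j = int(np.argmax(sims))
        assert np.allclose(out.matrix[i], 0.5 * mat[i] + 0.5 * mat[j])


def test_apply_rectification_without_incremental_rows_is_identity(rng):
    mat = rng.normal(size=(3, 4))
    bank = PrototypeBank(mat.copy(), n_base=3, class_ids=np.arange(3))
    out = apply_rectification(bank, 0.7)
    assert np.array_equal(out.matrix, mat)
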