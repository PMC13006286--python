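"""EMA teacher semantics, similarity graphs, and the warm-up loss mixer."""

import numpy as np
import pytest

from microfscil.classifier import CosineHead, embed
from microfscil.distillation import (GraphKind, LossWeights, SimilarityGraph,
                                     build_instance_graph,
                                     build_prototype_graph, ema_update,
                                     graph_loss, init_teacher, total_loss)
from microfscil.errors import NumericError, PreconditionError
from microfscil.nn import ConvNet4
from microfscil.synthetic import ImageSample


@pytest.fixture
def student():
    return ConvNet4(in_channels=3, embed_dim=32, seed=4)


def _imgs(rng, n=3):
    return [ImageSample(rng.random((16, 16, 3)).astype(np.float32), 0)
            for _ in range(n)]


# ------------------------------------------------------------- teacher

def test_teacher_starts_as_exact_copy_with_zero_graph_losses(student, rng):
    teacher = init_teacher(student)
    imgs = _imgs(rng, 4)
    f_s = embed(student, imgs, labels=[0] * 4).features
    f_t = embed(teacher.model, imgs, labels=[0] * 4).features
    assert np.array_equal(f_s, f_t)
    g_s, g_t = build_instance_graph(f_s), build_instance_graph(f_t)
    assert graph_loss(g_s, g_t) == 0.0


def test_teacher_isolated_from_student_mutation(student):
    teacher = init_teacher(student)
    for p in student.parameters():
        p.data = p.data + 1.0
    for ts, ss in zip(teacher.model.parameters(), student.parameters()):
        assert not np.allclose(ts.data, ss.data)


def test_teacher_reproduces_checkpointed_forward(student, rng):
    state = student.state_dict()
    teacher = init_teacher(student)
    for p in student.parameters():
        p.data = p.data * 0.5
    fresh = ConvNet4(in_channels=3, embed_dim=32, seed=99)
    fresh.load_state_dict(state)
    imgs = _imgs(rng, 2)
    assert np.array_equal(embed(teacher.model, imgs, labels=[0, 0]).features,
                          embed(fresh, imgs, labels=[0, 0]).features)


def test_ema_momentum_zero_copies_student(student):
    teacher = init_teacher(student, momentum=0.0)
    for p in student.parameters():
        p.data = p.data + 2.0
    ema_update(teacher, student)
    for ts, ss in zip(teacher.model.parameters(), student.parameters()):
        assert np.allclose(ts.data, ss.data)


def test_ema_fixed_point_when_equal(student):
    teacher = init_teacher(student, momentum=0.7)
    before = teacher.model.state_dict()
    ema_update(teacher, student)
    after = teacher.model.state_dict()
    assert all(np.allclose(before[k], after[k]) for k in before)


def test_ema_closed_form_geometric_recursion(student):
    """k updates toward a constant student: theta_t = m^k theta_0 + (1-m^k) s,
    checked at k=5, m=0.9 against the step-by-step iteration."""
    m, k = 0.9, 5
    teacher = init_teacher(student, momentum=m)
    theta0 = teacher.model.state_dict()
    for p in student.parameters():
        p.data = p.data + 3.0
    target = student.state_dict()
    for _ in range(k):
        ema_update(teacher, student)
    got = teacher.model.state_dict()
    for key in theta0:
        expect = m ** k * theta0[key] + (1 - m ** k) * target[key]
        assert np.allclose(got[key], expect, atol=1e-5)


def test_ema_stays_in_convex_hull(student):
    teacher = init_teacher(student, momentum=0.8)
    lo = {k: v.copy() for k, v in teacher.model.state_dict().items()}
    hi = {k: v.copy() for k, v in teacher.model.state_dict().items()}
    rng = np.random.default_rng(0)
    for _ in range(4):
        for p in student.parameters():
            p.data = p.data + rng.normal(0, 0.1, p.data.shape).astype(p.data.dtype)
        s = student.state_dict()
        lo = {k: np.minimum(lo[k], s[k]) for k in lo}
        hi = {k: np.maximum(hi[k], s[k]) for k in hi}
        ema_update(teacher, student)
        t = teacher.model.state_dict()
        for k in t:
            assert np.all(t[k] >= lo[k] - 1e-7) and np.all(t[k] <= hi[k] + 1e-7)


# -------------------------------------------------------------- graphs

def test_orthonormal_rows_give_identity_graph():
    g = build_instance_graph(np.eye(4))
    assert np.allclose(g.matrix, np.eye(4))
    assert g.kind == GraphKind.INSTANCE


def test_duplicated_row_yields_unit_off_diagonal(rng):
    v = rng.normal(size=5)
    g = build_instance_graph(np.stack([v, 2 * v, rng.normal(size=5)]))
    assert g.matrix[0, 1] == pytest.approx(1.0)
    assert np.allclose(g.matrix, g.matrix.T)
    assert np.allclose(np.diag(g.matrix), 1.0)


def test_instance_graph_matches_double_loop_oracle(rng):
    f = rng.normal(size=(4, 3))
    g = build_instance_graph(f)
    for i in range(4):
        for j in range(4):
            expect = f[i] @ f[j] / (np.linalg.norm(f[i]) * np.linalg.norm(f[j]))
            assert g.matrix[i, j] == pytest.approx(expect, abs=1e-9)


def test_prototype_graph_cases(rng):
    g1 = build_prototype_graph(np.array([[1.0, 1.0]]), np.array([[2.0, 2.0]]))
    assert g1.matrix[0, 0] == pytest.approx(1.0)
    pn, pb = rng.normal(size=(2, 4)), rng.normal(size=(3, 4))
    g = build_prototype_graph(pn, pb)
    assert g.matrix.shape == (2, 3) and g.kind == GraphKind.PROTOTYPE
    for i in range(2):
        for j in range(3):
            expect = pn[i] @ pb[j] / (np.linalg.norm(pn[i]) * np.linalg.norm(pb[j]))
            assert g.matrix[i, j] == pytest.approx(expect, abs=1e-9)
    scaled = build_prototype_graph(5.0 * pn, pb)
    assert np.allclose(scaled.matrix, g.matrix)


def test_zero_norm_rows_rejected():
    with pytest.raises(NumericError):
        build_instance_graph(np.array([[0.0, 0.0], [1.0, 0.0]]))
    with pytest.raises(NumericError):
        build_prototype_graph(np.zeros((1, 2)), np.ones((1, 2)))


# -------------------------------------------------------------- losses

def test_graph_loss_oracle_and_symmetry(rng):
    a = rng.uniform(-1, 1, (5, 5))
    b = rng.uniform(-1, 1, (5, 5))
    ga = SimilarityGraph(a, GraphKind.INSTANCE)
    gb = SimilarityGraph(b, GraphKind.INSTANCE)
    expect = sum((a[i, j] - b[i, j]) ** 2 for i in range(5) for j in range(5))
    assert graph_loss(ga, gb) == pytest.approx(expect)
    assert graph_loss(gb, ga) == pytest.approx(expect)
    assert graph_loss(ga, ga) == 0.0


def test_graph_loss_single_entry_difference():
    a = np.zeros((2, 2)); b = a.copy(); b[0, 1] = 0.5
    assert graph_loss(SimilarityGraph(a, GraphKind.INSTANCE),
                      SimilarityGraph(b, GraphKind.INSTANCE)) == pytest.approx(0.25)


def test_graph_loss_rejects_kind_or_shape_mismatch():
    a = SimilarityGraph(np.zeros((2, 2)), GraphKind.INSTANCE)
    b = SimilarityGraph(np.zeros((2, 2)), GraphKind.PROTOTYPE)
    with pytest.raises(PreconditionError):
        graph_loss(a, b)
    c = SimilarityGraph(np.zeros((3, 3)), GraphKind.INSTANCE)
    with pytest.raises(PreconditionError):
        graph_loss(a, c)


def test_total_loss_plain_sum_and_warmup():
    w0 = LossWeights(alpha=1.0, gamma=1.0, warmup_epochs=0)
    assert total_loss(1.0, 2.0, 3.0, w0, epoch=0) == pytest.approx(6.0)
    w = LossWeights(alpha=0.5, gamma=2.0, warmup_epochs=10)
    assert total_loss(7.0, 2.0, 3.0, w, epoch=0) == pytest.approx(0.5 * 2 + 2 * 3)
    assert total_loss(4.0, 1.0, 1.0, w, epoch=5) == pytest.approx(0.5 * 4 + 2.5)
    assert total_loss(4.0, 1.0, 1.0, w, epoch=25) == pytest.approx(4 + 2.5)


def test_total_loss_rejects_negative_components():
    with pytest.raises(PreconditionError):
        total_loss(-1.0, 0.0, 0.0, LossWeights(), epoch=0)
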