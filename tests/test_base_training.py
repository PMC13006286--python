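"""Augmentation policy, consistency filtering, and the mining loop."""

import numpy as np
import pytest

from microfscil.base_training import (AugmentationPolicy, augment,
                                      base_session_train, consistency_filter)
from microfscil.classifier import CosineHead, classify, embed
from microfscil.config import OptimConfig
from microfscil.errors import PreconditionError
from microfscil.nn import ConvNet4, Module
from microfscil.synthetic import ImageSample, generate_dataset

IDENTITY = AugmentationPolicy(crop_scale_range=(1.0, 1.0), flip_prob=0.0,
                              jitter_strength=0.0, seed=0)


class ChannelMeanNet(Module):
    """Parameter-free stub backbone: embedding = per-channel pixel means."""

    def forward(self, x):
        return x.mean(axis=(2, 3))


def color_dataset():
    """Two perfectly separable color classes plus a head aligned to them."""
    red = np.zeros((16, 16, 3), np.float32); red[..., 0] = 0.9; red[..., 1] = 0.1
    blue = np.zeros((16, 16, 3), np.float32); blue[..., 2] = 0.9; blue[..., 1] = 0.1
    data = [ImageSample(red + 0.01 * k, label=0) for k in range(3)] + \
           [ImageSample(blue + 0.01 * k, label=1) for k in range(3)]
    head = CosineHead.init(2, 3, scale=16.0)
    head.weights.data = np.array([[1, 0, 0], [0, 0, 1]], np.float32)
    return data, ChannelMeanNet(), head


# ---------------------------------------------------------------- augment

def test_identity_policy_is_pixel_exact():
    rng = np.random.default_rng(0)
    x = rng.random((32, 32, 3)).astype(np.float32)
    assert np.array_equal(augment(x, IDENTITY, draw=5), x)


def test_augment_preserves_range_and_shape():
    rng = np.random.default_rng(1)
    x = rng.random((32, 32, 3)).astype(np.float32)
    pol = AugmentationPolicy(seed=4)
    for draw in range(6):
        out = augment(x, pol, draw)
        assert out.shape == x.shape
        assert out.min() >= 0.0 and out.max() <= 1.0


def test_augment_replays_exactly_per_draw():
    rng = np.random.default_rng(2)
    x = rng.random((32, 32, 3)).astype(np.float32)
    pol = AugmentationPolicy(seed=11)
    assert np.array_equal(augment(x, pol, 3), augment(x, pol, 3))
    assert not np.array_equal(augment(x, pol, 3), augment(x, pol, 4))


def test_policy_validation():
    with pytest.raises(PreconditionError):
        AugmentationPolicy(crop_scale_range=(0.9, 0.2))
    with pytest.raises(PreconditionError):
        AugmentationPolicy(flip_prob=1.5)


# ---------------------------------------------------- consistency filter

def test_perfect_model_retains_everything():
    data, net, head = color_dataset()
    views = [(s.pixels, s.label) for s in data]
    kept = consistency_filter(net, head, views)
    assert len(kept) == len(views)
    assert [l for _, l in kept.samples] == [l for _, l in views]


def test_constant_predictor_keeps_only_its_class():
    data, net, head = color_dataset()
    head.weights.data = np.array([[0, 1, 0], [0, -1, 0]], np.float32)  # always 0
    kept = consistency_filter(net, head, [(s.pixels, s.label) for s in data])
    assert all(l == 0 for _, l in kept.samples)
    assert len(kept) == sum(1 for s in data if s.label == 0)


def test_filter_matches_elementwise_argmax_oracle(rng):
    net = ConvNet4(in_channels=3, embed_dim=32, seed=5)
    head = CosineHead.init(4, 32, seed=5)
    views = [(rng.random((32, 32, 3)).astype(np.float32), int(rng.integers(4)))
             for _ in range(20)]
    kept = consistency_filter(net, head, views, cycle=2)
    expected = []
    for i, (img, lab) in enumerate(views):
        es = embed(net, [img], labels=[lab])
        _, pred = classify(head, es)
        if pred[0] == lab:
            expected.append(i)
    assert [src for src, _ in kept.provenance] == expected
    assert all(cyc == 2 for _, cyc in kept.provenance)


def test_filter_never_updates_parameters(rng):
    net = ConvNet4(in_channels=3, embed_dim=32, seed=6)
    head = CosineHead.init(3, 32, seed=6)
    before = {k: v.copy() for k, v in net.state_dict().items()}
    consistency_filter(net, head,
                       [(rng.random((32, 32, 3)).astype(np.float32), 0)] * 4)
    after = net.state_dict()
    assert all(np.array_equal(before[k], after[k]) for k in before)


# ------------------------------------------------------------ mining loop

def test_interpolating_model_grows_working_set_linearly():
    """Identity policy + a model that always predicts correctly: after k
    cycles the working set holds exactly (k+1)x the original samples."""
    data, net, head = color_dataset()
    log = base_session_train(net, head, data, IDENTITY, epochs=2,
                             cycles_per_epoch=3,
                             optim_config=OptimConfig(lr=1e-4, batch_size=8),
                             seed=0)
    n = len(data)
    assert log.working_set_sizes == [2 * n, 3 * n, 4 * n] * 2  # resets per epoch
    assert log.retention == [1.0] * 6


def test_mining_disabled_reduces_to_plain_supervised():
    samples, _ = generate_dataset(3, 4, 16, 0.0, seed=2)
    net = ConvNet4(in_channels=3, embed_dim=32, seed=2)
    head = CosineHead.init(3, 32, seed=2)
    log = base_session_train(net, head, samples, IDENTITY, epochs=2,
                             cycles_per_epoch=1,
                             optim_config=OptimConfig(lr=0.01, batch_size=8),
                             seed=2, mining=False)
    assert log.retention == [0.0, 0.0]
    assert log.working_set_sizes == [len(samples)] * 2
    assert log.gradient_steps == 2 * 1 * int(np.ceil(len(samples) / 8))


def test_retention_fraction_logged_each_cycle_within_bounds():
    samples, _ = generate_dataset(4, 6, 16, 0.3, seed=3)
    net = ConvNet4(in_channels=3, embed_dim=32, seed=3)
    head = CosineHead.init(4, 32, seed=3)
    log = base_session_train(net, head, samples, AugmentationPolicy(seed=3),
                             epochs=2, cycles_per_epoch=3,
                             optim_config=OptimConfig(lr=0.01, batch_size=16),
                             seed=3)
    assert len(log.retention) == 6
    assert all(0.0 <= r <= 1.0 for r in log.retention)
    # working set never shrinks within an epoch
    for e in range(2):
        sizes = log.working_set_sizes[3 * e: 3 * e + 3]
        assert sizes == sorted(sizes)


def test_mining_improves_relative_compactness(scaled_study):
    """Consistency mining tightens classes relative to their separation:
    the within/between compactness ratio on augmented probe views is lower
    for the mining arm than for the equal-step plain arm (mean over seeds)."""
    assert scaled_study["mean_ratio_mining"] <= scaled_study["mean_ratio_plain"]


def test_retention_grows_as_the_model_fits(scaled_study):
    """Mean final-epoch retention fraction exceeds the first epoch's: views
    become prediction-consistent as the representation stabilizes."""
    first = np.mean([o.retention_first_epoch for o in scaled_study["outcomes"]])
    last = np.mean([o.retention_last_epoch for o in scaled_study["outcomes"]])
    assert last >= first
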