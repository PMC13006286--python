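"""Neural-network building blocks on top of the autodiff core.

Layers hold their parameters as :class:`~microfscil.tensor.Tensor` leaves;
``state_dict`` / ``load_state_dict`` move plain NumPy copies in and out,
which is what checkpointing and the EMA teacher rely on.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .tensor import Tensor, conv2d, maxpool2


class Module:
    def parameters(self) -> Iterator[Tensor]:
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                yield v
            elif isinstance(v, Module):
                yield from v.parameters()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.parameters()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, v in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(v, Tensor) and v.requires_grad:
                yield full, v
            elif isinstance(v, Module):
                yield from v.named_parameters(full + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        if set(params) != set(state):
            missing = set(params) ^ set(state)
            raise ValueError(f"state dict keys do not match module: {sorted(missing)}")
        for k, p in params.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}: {p.data.shape} vs {state[k].shape}")
            p.data = state[k].astype(p.data.dtype).copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator):
        fan_in = in_ch * k * k
        std = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.weight = Tensor(rng.normal(0.0, std, (out_ch, in_ch, k, k)).astype(np.float32),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias)


class GroupNorm(Module):
    """Group normalization over (C/groups, H, W) blocks; batch-size independent,
    so a 4-image few-shot batch normalizes exactly like a 128-image base batch,
    and the teacher copy needs no running statistics."""

    def __init__(self, n_channels: int, n_groups: int = 4, eps: float = 1e-5):
        if n_channels % n_groups:
            raise ValueError("n_channels must be divisible by n_groups")
        self.n_groups = n_groups
        self.eps = eps
        self.gamma = Tensor(np.ones(n_channels, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(n_channels, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        N, C, H, W = x.shape
        g = self.n_groups
        xg = x.reshape(N, g, (C // g) * H * W)
        mu = xg.mean(axis=2, keepdims=True)
        var = ((xg - mu) ** 2.0).mean(axis=2, keepdims=True)
        xn = (xg - mu) * (var + self.eps) ** -0.5
        xn = xn.reshape(N, C, H, W)
        gamma = self.gamma.reshape(1, C, 1, 1)
        beta = self.beta.reshape(1, C, 1, 1)
        return xn * gamma + beta


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / d_in)
        self.weight = Tensor(rng.normal(0.0, std, (d_in, d_out)).astype(np.float32),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(d_out, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class ConvBlock(Module):
    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.conv = Conv2d(in_ch, out_ch, 3, rng)
        self.norm = GroupNorm(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        return maxpool2(self.norm(self.conv(x)).relu())


class ConvNet4(Module):
    """Desk-scale default backbone: four conv-norm-relu-pool blocks followed by
    global average pooling. With the default channel plan the embedding
    dimension equals the last block's channel count."""

    def __init__(self, in_channels: int = 3, embed_dim: int = 64, seed: int = 0):
        rng = np.random.default_rng(seed)
        chans = [16, 32, 64, embed_dim]
        self.blocks = []
        c_prev = in_channels
        for c in chans:
            self.blocks.append(ConvBlock(c_prev, c, rng))
            c_prev = c
        self.embed_dim = embed_dim

    def forward(self, x: Tensor) -> Tensor:
        for b in self.blocks:
            x = b(x)
        return x.mean(axis=(2, 3))  # global average pool -> (N, d)


class ResidualBlock(Module):
    def __init__(self, ch: int, rng: np.random.Generator):
        self.conv1 = Conv2d(ch, ch, 3, rng)
        self.norm1 = GroupNorm(ch)
        self.conv2 = Conv2d(ch, ch, 3, rng)
        self.norm2 = GroupNorm(ch)

    def forward(self, x: Tensor) -> Tensor:
        h = self.norm1(self.conv1(x)).relu()
        h = self.norm2(self.conv2(h))
        return (h + x).relu()


class ResNetSmall(Module):
    """Deeper residual backbone, trained from scratch. Selectable by config;
    no pretrained weights are shipped or downloadable, so ``pretrained=True``
    is rejected at construction."""

    def __init__(self, in_channels: int = 3, embed_dim: int = 64, seed: int = 0,
                 pretrained: bool = False):
        if pretrained:
            raise ValueError("no pretrained weights are available for ResNetSmall; "
                             "set pretrained=false")
        rng = np.random.default_rng(seed)
        chans = [16, 32, 64, embed_dim]
        self.stems = []
        self.resblocks = []
        c_prev = in_channels
        for c in chans:
            self.stems.append(ConvBlock(c_prev, c, rng))
            self.resblocks.append(ResidualBlock(c, rng))
            c_prev = c
        self.embed_dim = embed_dim

    def forward(self, x: Tensor) -> Tensor:
        for stem, res in zip(self.stems, self.resblocks):
            x = res(stem(x))
        return x.mean(axis=(2, 3))


BACKBONES = {"convnet4": ConvNet4, "resnet": ResNetSmall}


def build_backbone(name: str = "convnet4", **kwargs) -> Module:
    try:
        cls = BACKBONES[name]
    except KeyError:
        raise ValueError(f"unknown backbone {name!r}; available: {sorted(BACKBONES)}") from None
    return cls(**kwargs)


class SGD:
    """SGD with classical momentum and decoupled-from-nothing L2 weight decay,
    matching the training recipe (momentum 0.9, weight decay 5e-4)."""

    def __init__(self, params, lr: float = 0.1, momentum: float = 0.9,
                 weight_decay: float = 5e-4, clip_norm: float = 5.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.clip_norm = clip_norm  # global grad-norm clip; None disables
        self._velocity = [np.zeros_like(p.data) for p in self.params]
        self.grad_masks: dict[int, np.ndarray] = {}

    def mask_rows(self, param: Tensor, rows: np.ndarray) -> None:
        """Freeze the given rows of a 2-D parameter (their gradient is zeroed)."""
        mask = np.ones(param.data.shape[0], dtype=bool)
        mask[rows] = False
        self.grad_masks[id(param)] = mask

    def step(self) -> None:
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((p.grad ** 2).sum())
                                for p in self.params if p.grad is not None))
            if total > self.clip_norm:
                scale = self.clip_norm / total
                for p in self.params:
                    if p.grad is not None:
                        p.grad = p.grad * scale
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            mask = self.grad_masks.get(id(p))
            if mask is not None:
                g = g * mask[:, None]
            v *= self.momentum
            v += g
            p.data = p.data - self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
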