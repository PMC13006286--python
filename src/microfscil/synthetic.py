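"""Procedural generator of microorganism-like microscopy images.

Real environmental microscopy data is fine-grained: strong intra-class
variability, high inter-class similarity, small organisms on cluttered
backgrounds. The generator reproduces those *statistical* difficulties —
not the appearance of any particular taxon — by layered composition:

1. a smooth value-noise background (out-of-focus medium),
2. faint clutter blobs (debris/detritus),
3. one foreground organism drawn from a parametric shape family
   (ellipse, rod, spiral, star, filament) with multiplicative sinusoidal
   texture and a class-specific hue.

Class identity lives in a :class:`ClassRecipe`; per-sample jitter of the
recipe (rotation, ±20% scale, small hue shifts) creates intra-class
variability, and an ``inter_class_similarity`` knob draws class recipes as
perturbations of one shared template so that discrimination gets harder as
it approaches 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np
from scipy import ndimage

from .errors import PreconditionError

SHAPE_FAMILIES = ("ellipse", "rod", "spiral", "star", "filament")

#: number of shape parameters each family consumes
SHAPE_ARITY = {"ellipse": 2, "rod": 2, "spiral": 3, "star": 2, "filament": 3}


@dataclass
class ClassRecipe:
    """Morphology of one synthetic class."""

    class_id: int
    shape_family: str
    shape_params: np.ndarray
    texture_freq: float        # cycles per image, > 0
    texture_amp: float         # in [0, 1]
    base_hue: float            # in [0, 1)
    clutter_density: float     # distractor blobs per unit area, in [0, 1]

    def __post_init__(self):
        if self.shape_family not in SHAPE_FAMILIES:
            raise PreconditionError(f"unknown shape_family {self.shape_family!r}")
        self.shape_params = np.asarray(self.shape_params, dtype=np.float64)
        if self.shape_params.shape != (SHAPE_ARITY[self.shape_family],):
            raise PreconditionError(
                f"shape_params must have length {SHAPE_ARITY[self.shape_family]} "
                f"for family {self.shape_family!r}")
        if not self.texture_freq > 0:
            raise PreconditionError("texture_freq must be > 0")
        if not 0.0 <= self.texture_amp <= 1.0:
            raise PreconditionError("texture_amp must be in [0, 1]")
        if not 0.0 <= self.base_hue < 1.0:
            raise PreconditionError("base_hue must be in [0, 1)")
        if not 0.0 <= self.clutter_density <= 1.0:
            raise PreconditionError("clutter_density must be in [0, 1]")

    def to_dict(self) -> dict:
        return {"class_id": self.class_id, "shape_family": self.shape_family,
                "shape_params": self.shape_params.tolist(),
                "texture_freq": self.texture_freq, "texture_amp": self.texture_amp,
                "base_hue": self.base_hue, "clutter_density": self.clutter_density}


@dataclass
class ImageSample:
    """One image with its class label and the session it belongs to."""

    pixels: np.ndarray  # (H, W, C) in [0, 1]
    label: int
    session_id: int = 0

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 3 or self.pixels.shape[2] not in (1, 3):
            raise PreconditionError("pixels must be H x W x C with C in {1, 3}")
        if min(self.pixels.shape[:2]) < 16:
            raise PreconditionError("images must be at least 16 x 16")
        if not np.all(np.isfinite(self.pixels)):
            raise PreconditionError("pixels must be finite")
        if self.pixels.min() < 0.0 or self.pixels.max() > 1.0:
            raise PreconditionError("pixels must lie in [0, 1]")


# ---------------------------------------------------------------------------
# recipe sampling


def _draw_recipe(rng: np.random.Generator, class_id: int) -> ClassRecipe:
    family = SHAPE_FAMILIES[rng.integers(len(SHAPE_FAMILIES))]
    params = rng.uniform(0.25, 0.9, SHAPE_ARITY[family])
    return ClassRecipe(
        class_id=class_id,
        shape_family=family,
        shape_params=params,
        texture_freq=float(rng.uniform(2.0, 9.0)),
        texture_amp=float(rng.uniform(0.3, 0.9)),
        base_hue=float(rng.uniform(0.0, 1.0) % 1.0),
        clutter_density=float(rng.uniform(0.1, 0.6)),
    )


def _blend_recipe(own: ClassRecipe, template: ClassRecipe, sim: float,
                  rng: np.random.Generator) -> ClassRecipe:
    """Pull a class recipe toward the shared template by ``sim``."""
    take_template_family = rng.random() < sim
    family = template.shape_family if take_template_family else own.shape_family
    if family == template.shape_family:
        base = template.shape_params
    else:
        base = own.shape_params
    own_params = own.shape_params
    if own_params.shape != base.shape:
        own_params = rng.uniform(0.25, 0.9, base.shape[0])
    params = sim * base + (1.0 - sim) * own_params
    # hues blended on the circle via the shorter arc
    dh = ((template.base_hue - own.base_hue + 0.5) % 1.0) - 0.5
    hue = (own.base_hue + sim * dh) % 1.0
    return ClassRecipe(
        class_id=own.class_id,
        shape_family=family,
        shape_params=params,
        texture_freq=sim * template.texture_freq + (1 - sim) * own.texture_freq,
        texture_amp=sim * template.texture_amp + (1 - sim) * own.texture_amp,
        base_hue=hue,
        clutter_density=sim * template.clutter_density + (1 - sim) * own.clutter_density,
    )


def make_recipes(n_classes: int, inter_class_similarity: float,
                 seed: int) -> List[ClassRecipe]:
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 101]))
    template = _draw_recipe(rng, class_id=-1)
    recipes = []
    for c in range(n_classes):
        own = _draw_recipe(rng, class_id=c)
        if inter_class_similarity > 0:
            recipes.append(_blend_recipe(own, template, inter_class_similarity, rng))
        else:
            recipes.append(own)
    return recipes


# ---------------------------------------------------------------------------
# rendering


def _hsv_to_rgb(h, s, v):
    """Vectorized HSV -> RGB on arrays in [0, 1]."""
    h = np.asarray(h) % 1.0
    i = np.floor(h * 6.0).astype(int) % 6
    f = h * 6.0 - np.floor(h * 6.0)
    p = v * (1.0 - s)
    q = v * (1.0 - s * f)
    t = v * (1.0 - s * (1.0 - f))
    r = np.choose(i, [v, q, p, p, t, v])
    g = np.choose(i, [t, v, v, q, p, p])
    b = np.choose(i, [p, p, t, v, v, q])
    return np.stack([r, g, b], axis=-1)


def _soft(d: np.ndarray, width: float = 0.03) -> np.ndarray:
    """Signed distance -> soft occupancy in [0, 1] (negative d = inside)."""
    return 1.0 / (1.0 + np.exp(np.clip(d / width, -40, 40)))


def _organism_mask(recipe: ClassRecipe, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Soft foreground mask on rotated/scaled body coordinates in roughly [-1, 1]."""
    f = recipe.shape_family
    p = recipe.shape_params
    if f == "ellipse":
        ratio = 0.3 + 0.7 * p[0]
        r = np.sqrt((X / 0.55) ** 2 + (Y / (0.55 * ratio)) ** 2)
        return _soft(r - 1.0, 0.04 + 0.08 * p[1])
    if f == "rod":
        half_len = 0.45 + 0.25 * p[0]
        half_w = 0.08 + 0.12 * p[1]
        dx = np.maximum(np.abs(X) - half_len, 0.0)
        d = np.sqrt(dx ** 2 + Y ** 2) - half_w
        return _soft(d)
    if f == "spiral":
        turns = 1.5 + 2.0 * p[0]
        thick = 0.04 + 0.06 * p[1]
        growth = 0.12 + 0.12 * p[2]
        theta = np.arctan2(Y, X)
        r = np.sqrt(X ** 2 + Y ** 2)
        # distance to nearest arm of r = growth * (theta + 2 pi k)
        k = (r / growth - theta) / (2 * np.pi)
        d = np.full_like(r, np.inf)
        for kk in (np.floor(k), np.ceil(k)):
            arm_r = growth * (theta + 2 * np.pi * np.clip(kk, 0, turns))
            d = np.minimum(d, np.abs(r - arm_r))
        return _soft(d - thick, 0.02) * _soft(r - 0.85, 0.05)
    if f == "star":
        lobes = int(round(3 + 5 * p[0]))
        depth = 0.15 + 0.45 * p[1]
        theta = np.arctan2(Y, X)
        r = np.sqrt(X ** 2 + Y ** 2)
        radius = 0.55 * (1.0 + depth * np.cos(lobes * theta)) / (1 + depth)
        return _soft(r - radius, 0.03)
    if f == "filament":
        amp = 0.15 + 0.3 * p[0]
        freq = 1.0 + 3.0 * p[1]
        thick = 0.05 + 0.08 * p[2]
        d = np.abs(Y - amp * np.sin(freq * np.pi * X)) - thick
        return _soft(d) * _soft(np.abs(X) - 0.8, 0.05)
    raise PreconditionError(f"unknown family {f!r}")


def render_sample(recipe: ClassRecipe, image_size: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Render one jittered sample of a class recipe as (H, W, 3) in [0, 1]."""
    S = image_size
    lin = np.linspace(-1.0, 1.0, S)
    Xg, Yg = np.meshgrid(lin, lin)

    # --- background: coarse value noise, bilinearly upsampled
    coarse = rng.uniform(0.25, 0.55, (4, 4))
    bg_v = ndimage.zoom(coarse, S / 4.0, order=1, mode="nearest", grid_mode=True)
    bg_hue = (0.28 + rng.normal(0, 0.02)) % 1.0  # watery green-gray medium
    img = _hsv_to_rgb(np.full((S, S), bg_hue), 0.15, bg_v)

    # --- clutter distractors
    n_clutter = rng.poisson(recipe.clutter_density * 8.0)
    for _ in range(n_clutter):
        cx, cy = rng.uniform(-1, 1, 2)
        rad = rng.uniform(0.03, 0.12)
        blob = np.exp(-(((Xg - cx) ** 2 + (Yg - cy) ** 2) / (2 * rad ** 2)))
        shade = rng.uniform(-0.25, 0.2)
        img = np.clip(img + shade * blob[..., None] * 0.6, 0.0, 1.0)

    # --- foreground organism with per-sample jitter
    angle = rng.uniform(0, 2 * np.pi)
    scale = rng.uniform(0.8, 1.2)          # ±20 %
    ox, oy = rng.uniform(-0.25, 0.25, 2)   # off-center placement
    ca, sa = np.cos(angle), np.sin(angle)
    Xb = ((Xg - ox) * ca + (Yg - oy) * sa) / (0.75 * scale)
    Yb = (-(Xg - ox) * sa + (Yg - oy) * ca) / (0.75 * scale)
    mask = _organism_mask(recipe, Xb, Yb)

    phase = rng.uniform(0, 2 * np.pi)
    tex_dir = rng.uniform(0, np.pi)
    carrier = np.sin(2 * np.pi * recipe.texture_freq *
                     (Xb * np.cos(tex_dir) + Yb * np.sin(tex_dir)) / 2.0 + phase)
    texture = 1.0 - recipe.texture_amp * 0.5 * (1.0 + carrier) * 0.6

    hue = (recipe.base_hue + rng.normal(0, 0.05)) % 1.0
    value = np.clip(0.85 * texture, 0.0, 1.0)
    fg = _hsv_to_rgb(np.full((S, S), hue), 0.65, value)

    out = img * (1.0 - mask[..., None]) + fg * mask[..., None]
    # mild sensor noise
    out = out + rng.normal(0.0, 0.015, out.shape)
    return np.clip(out, 0.0, 1.0).astype(np.float32)


# ---------------------------------------------------------------------------
# public API


def generate_dataset(n_classes: int, n_per_class: int, image_size: int = 32,
                     inter_class_similarity: float = 0.0, seed: int = 0,
                     ) -> tuple[List[ImageSample], List[ClassRecipe]]:
    """Generate ``n_classes * n_per_class`` labeled images.

    ``inter_class_similarity`` = 0 draws class morphologies independently;
    values near 1 draw them as small perturbations of one shared template,
    making discrimination progressively harder. Fully deterministic in
    ``seed``.
    """
    if n_classes < 2:
        raise PreconditionError("n_classes must be >= 2")
    if n_per_class < 1:
        raise PreconditionError("n_per_class must be >= 1")
    if image_size < 16:
        raise PreconditionError("image_size must be >= 16")
    if not 0.0 <= inter_class_similarity <= 1.0:
        raise PreconditionError("inter_class_similarity must be in [0, 1]")

    recipes = make_recipes(n_classes, inter_class_similarity, seed)
    samples: List[ImageSample] = []
    root = np.random.SeedSequence([int(seed), 202])
    class_seeds = root.spawn(n_classes)
    for c, recipe in enumerate(recipes):
        rng = np.random.default_rng(class_seeds[c])
        for _ in range(n_per_class):
            samples.append(ImageSample(render_sample(recipe, image_size, rng), label=c))
    return samples, recipes
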