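# microfscil

Few-shot class-incremental learning (FSCIL) for fine-grained microorganism
image recognition.

Environmental microscopy datasets grow over time: new microorganism
categories keep appearing, usually with only a handful of annotated images,
while a classifier must keep recognizing every category seen so far. After a
data-rich **base session** (session 0), each **incremental session** adds
`n_way` novel classes with `k_shot` labeled images each, and the model is
evaluated on the test samples of *all* classes encountered so far. The twin
failure modes are catastrophic forgetting of old classes and overfitting the
few new samples.

`microfscil` implements a complete FSCIL pipeline built from three
mechanisms:

1. **Consistency-filtered pseudo-sample mining (base session).** Each epoch
   is split into inner cycles. Every cycle draws one "locally magnified"
   stochastic view `x̃ᵢ = T(xᵢ)` of each original image, forwards it
   inference-only, and keeps the pair `(x̃ᵢ, yᵢ)` only if
   `argmax_c f_θ(x̃ᵢ)_c = yᵢ`. Survivors are merged into the working set for
   the next cycle; the pool resets each epoch. No contrastive loss is ever
   optimized — the filter alone enforces view invariance.
2. **Prototype rectification (each incremental session).** A new class's
   prototype `p` (mean of unit-norm embeddings of its k shots) is pulled
   toward its most cosine-similar base-class prototype:
   `p̃ = (1−β)·p + β·p_b[j*]`, `j* = argmax_j cos(p, p_b[j])`, with β = 0.3.
3. **Dual-graph distillation under an EMA teacher.** The teacher starts each
   session as an exact copy of the student and is updated only by
   `θ_t ← m·θ_t + (1−m)·θ_s`. Training minimizes
   `L = w(e)·L_CE + α·‖G_s − G_t‖²_F + γ·‖H_s − H_t‖²_F`, where `G` is the
   N×N pairwise-cosine graph of a feature batch (current few-shot embeddings
   plus stored representative features), `H` the C_n×C_b cosine graph
   between incremental and base prototypes, and `w(e)` ramps linearly from 0
   to 1 over a warm-up so relational alignment dominates early training.

Classification is by a cosine head (logit = `scale · cos(f, w_c)`); after
the base session the head rows *are* the class prototypes. Only embeddings
are carried across sessions (a budgeted feature memory) — never images.

There is no dependency on GPU frameworks: the backbone (a 4-block GroupNorm
CNN by default), SGD, EMA teacher and all losses run on a small
reverse-mode autodiff core over NumPy, verified against finite differences.

A procedural generator (`microfscil.synthetic`) produces microorganism-like
images — parametric shape families (ellipse, rod, spiral, star, filament)
with multiplicative texture, class hues, clutter blobs and value-noise
backgrounds — with a tunable inter-class similarity knob, so the entire
pipeline is exercisable without any external dataset.

## Worked example

```python
from microfscil import FSCILModel, desk_scale_config

model = FSCILModel.from_synthetic(n_classes=10, n_per_class=50,
                                  image_size=32, inter_class_similarity=0.3,
                                  seed=1, config=desk_scale_config())
result = model.fit(seed=1)
print(result.summary())
```

prints

```
      Few-shot class-incremental results
================================================
Sessions: 3   classes seen: 10   (2-way 2-shot)
------------------------------------------------
 session   new  seen  test n     acc %
       0     6     6      60     93.33
       1     2     8      80     66.25
       2     2    10     100     48.00
------------------------------------------------
Average Accuracy (AA): 69.19 %
Performance Drop (PD): 45.33 %
================================================
```

Session 0 is the 6-class base session (93.3% on its held-out pool); each
later row adds two classes from two images each, evaluated over the growing
cumulative test pool. AA is the mean accuracy over all sessions; PD is the
base-minus-final accuracy, the standard forgetting measure. With the graph
losses ablated (`alpha=0, gamma=0`) the same seeds lose roughly 15 more
points of PD — that comparison is exactly what the reproduction script
recomputes.

## Command line

```bash
microfscil generate --classes 10 --per-class 50 --size 32 --similarity 0.3 --seed 1 --out data/
microfscil train-base --data data/ --config cfg.yaml --seed 1 --out run/
microfscil run-incremental --checkpoint run/base.npz --data data/ --config cfg.yaml --out run/
microfscil report --csv run/results.csv --format markdown
```

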