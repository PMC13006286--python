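"""Model/Results facade tying the whole pipeline together.

``FSCILModel`` holds a labeled dataset plus the protocol/training
configuration; ``fit(seed)`` carves the FSCIL sessions, runs the base
session with consistency-filtered pseudo-sample mining, then each
incremental session with prototype rectification and dual-graph
distillation, and returns an ``FSCILResults`` carrying the per-session
accuracy trajectory, AA, PD, training logs and the final session state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .base_training import AugmentationPolicy, TrainLog, base_session_train
from .classifier import CosineHead, embed
from .config import ExperimentConfig
from .evaluation import (SessionResult, average_accuracy, performance_drop,
                         session_accuracy)
from .nn import build_backbone
from .prototypes import compute_prototypes
from .protocol import FSCILProtocol, split_fscil
from .runner import (FeatureMemory, SessionState, evaluate_session,
                     run_incremental_session, select_representatives)
from .synthetic import ImageSample, generate_dataset


class FSCILModel:
    """A few-shot class-incremental recognition experiment on one dataset.

    Parameters
    ----------
    dataset : sequence of ImageSample
        Labeled images; class labels must be 0..C-1.
    config : ExperimentConfig, optional
        Protocol and training recipe; defaults mirror the reference setup
        (cosine head, SGD momentum 0.9 / weight decay 5e-4, beta = 0.3,
        10 mining cycles per base epoch, EMA teacher).
    """

    def __init__(self, dataset: Sequence[ImageSample],
                 config: Optional[ExperimentConfig] = None):
        if len(dataset) == 0:
            raise ValueError("dataset must be nonempty")
        self.dataset = list(dataset)
        self.config = config or ExperimentConfig()

    @classmethod
    def from_synthetic(cls, n_classes: int = 10, n_per_class: int = 50,
                       image_size: int = 32, inter_class_similarity: float = 0.3,
                       seed: int = 0, config: Optional[ExperimentConfig] = None
                       ) -> "FSCILModel":
        samples, _ = generate_dataset(n_classes, n_per_class, image_size,
                                      inter_class_similarity, seed)
        return cls(samples, config)

    def fit(self, seed: int = 0) -> "FSCILResults":
        cfg = self.config
        root = np.random.SeedSequence(int(seed))
        s_split, s_init, s_base, s_inc = (int(s.generate_state(1)[0] % (2**31))
                                          for s in root.spawn(4))

        protocol = split_fscil(self.dataset, cfg.n_base_classes, cfg.n_way,
                               cfg.k_shot, seed=s_split)
        in_ch = self.dataset[0].pixels.shape[2]
        kwargs = dict(in_channels=in_ch, embed_dim=cfg.embed_dim, seed=s_init)
        if cfg.backbone == "resnet":
            kwargs["pretrained"] = cfg.pretrained
        model = build_backbone(cfg.backbone, **kwargs)
        base_spec = protocol.sessions[0]
        head = CosineHead.init(len(base_spec.class_ids), cfg.embed_dim,
                               scale=cfg.classifier_scale, seed=s_init)

        # ---- base session -------------------------------------------------
        protocol.begin_session(0)
        base_train = protocol.train_samples(self.dataset, 0)
        policy = AugmentationPolicy(cfg.crop_scale_range, cfg.flip_prob,
                                    cfg.jitter_strength, seed=s_base)
        label_to_row = {c: i for i, c in enumerate(base_spec.class_ids)}
        base_log = base_session_train(
            model, head, base_train, policy, epochs=cfg.base_epochs,
            cycles_per_epoch=cfg.cycles_per_epoch, optim_config=cfg.optim,
            seed=s_base, mining=cfg.mining, label_to_row=label_to_row)

        es = embed(model, base_train)
        bank = compute_prototypes(es, class_ids=base_spec.class_ids)
        # the classifier becomes the prototype bank: every row (base now,
        # incremental later) is a class-mean direction in the same geometry
        head.set_rows(np.arange(bank.n_classes), bank.matrix)
        memory = select_representatives(es, cfg.memory_per_class, bank)
        state = SessionState(session_id=0, model=model, head=head, bank=bank,
                             memory=memory, config=cfg, logs={0: base_log})

        accs = [evaluate_session(state, protocol.test_samples(self.dataset, 0))]

        # ---- incremental sessions -----------------------------------------
        for s in range(1, protocol.n_sessions):
            protocol.begin_session(s)
            session_images = protocol.train_samples(self.dataset, s)
            state, _ = run_incremental_session(state, protocol.sessions[s],
                                               session_images, seed=s_inc + s)
            accs.append(evaluate_session(state, protocol.test_samples(self.dataset, s)))
        protocol.assert_no_cross_session_reads()

        result = SessionResult(accs, method_label="microfscil")
        return FSCILResults(model=self, protocol=protocol, state=state,
                            session_result=result)


@dataclass
class FSCILResults:
    """Fitted trajectory plus diagnostics and the final model state."""

    model: FSCILModel
    protocol: FSCILProtocol
    state: SessionState
    session_result: SessionResult

    @property
    def accs(self) -> List[float]:
        return self.session_result.accs

    @property
    def average_accuracy(self) -> float:
        return average_accuracy(self.session_result)

    @property
    def performance_drop(self) -> float:
        return performance_drop(self.session_result)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s, acc in enumerate(self.accs):
            spec = self.protocol.sessions[s]
            rows.append({"session": s, "new_classes": len(spec.class_ids),
                         "classes_seen": len(self.protocol.classes_through(s)),
                         "test_pool": len(self.protocol.test_idx[s]),
                         "accuracy_pct": acc})
        return pd.DataFrame(rows).set_index("session")

    def summary(self) -> str:
        df = self.to_frame()
        lines = [
            "      Few-shot class-incremental results",
            "=" * 48,
            f"Sessions: {len(self.accs)}   "
            f"classes seen: {len(self.protocol.classes_through(len(self.accs) - 1))}   "
            f"({self.model.config.n_way}-way {self.model.config.k_shot}-shot)",
            "-" * 48,
            f"{'session':>8}{'new':>6}{'seen':>6}{'test n':>8}{'acc %':>10}",
        ]
        for s, row in df.iterrows():
            lines.append(f"{s:>8}{int(row.new_classes):>6}{int(row.classes_seen):>6}"
                         f"{int(row.test_pool):>8}{row.accuracy_pct:>10.2f}")
        lines += ["-" * 48,
                  f"Average Accuracy (AA): {self.average_accuracy:.2f} %",
                  f"Performance Drop (PD): "
                  f"{self.performance_drop:.2f} %" if len(self.accs) > 1 else
                  "Performance Drop (PD): n/a (single session)",
                  "=" * 48]
        return "\n".join(lines)
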