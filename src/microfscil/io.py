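"""Dataset and checkpoint serialization.

Datasets live on disk as a class-per-subdirectory PNG tree
(``root/class_<k>/img_<i>.png``) with a JSON manifest of the generating
recipes; user-supplied real data in the same layout is read identically.
Checkpoints are a single ``.npz`` parameter archive plus a JSON sidecar
(session id, class count, config hash).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
from PIL import Image

from .classifier import CosineHead
from .config import ExperimentConfig
from .errors import DataError
from .nn import Module, build_backbone
from .prototypes import PrototypeBank
from .runner import FeatureMemory, SessionState
from .synthetic import ClassRecipe, ImageSample


def write_dataset(samples: Sequence[ImageSample], root,
                  recipes: Optional[Sequence[ClassRecipe]] = None) -> None:
    root = Path(root)
    counters: dict[int, int] = {}
    for s in samples:
        d = root / f"class_{s.label}"
        d.mkdir(parents=True, exist_ok=True)
        i = counters.get(s.label, 0)
        counters[s.label] = i + 1
        arr = (np.clip(s.pixels, 0, 1) * 255).round().astype(np.uint8)
        if arr.shape[2] == 1:
            arr = arr[..., 0]
        Image.fromarray(arr).save(d / f"img_{i}.png")
    manifest = {"n_classes": len(counters),
                "per_class_counts": {str(k): v for k, v in sorted(counters.items())}}
    if recipes is not None:
        manifest["recipes"] = [r.to_dict() for r in recipes]
    (root / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_dataset(root) -> List[ImageSample]:
    root = Path(root)
    class_dirs = sorted(root.glob("class_*"), key=lambda p: int(p.name.split("_")[1]))
    if not class_dirs:
        raise DataError(f"no class_* subdirectories under {root}")
    samples: List[ImageSample] = []
    for d in class_dirs:
        label = int(d.name.split("_")[1])
        for f in sorted(d.glob("*.png")) + sorted(d.glob("*.jpg")):
            arr = np.asarray(Image.open(f).convert("RGB"), dtype=np.float32) / 255.0
            samples.append(ImageSample(arr, label=label))
    return samples


def _config_hash(config: ExperimentConfig) -> str:
    import dataclasses
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def save_checkpoint(path, model: Module, head: CosineHead, config: ExperimentConfig,
                    session_id: int = 0, bank: Optional[PrototypeBank] = None,
                    memory: Optional[FeatureMemory] = None,
                    extra: Optional[dict] = None) -> None:
    path = Path(path)
    arrays = {f"model.{k}": v for k, v in model.state_dict().items()}
    arrays["head.weights"] = head.weights.data
    if bank is not None:
        arrays["bank.matrix"] = bank.matrix
        arrays["bank.class_ids"] = bank.class_ids
        arrays["bank.n_base"] = np.array(bank.n_base)
    if memory is not None:
        arrays["memory.features"] = memory.features
        arrays["memory.labels"] = memory.labels
    np.savez(path, **arrays)
    sidecar = {"session_id": session_id, "n_classes": head.n_classes,
               "config_hash": _config_hash(config),
               "classifier_scale": head.scale,
               "backbone": config.backbone, "embed_dim": config.embed_dim}
    if extra:
        sidecar.update(extra)
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path, config: ExperimentConfig, in_channels: int = 3
                    ) -> SessionState:
    path = Path(path)
    with np.load(path if path.suffix == ".npz" else str(path) + ".npz") as z:
        arrays = dict(z)
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    kwargs = dict(in_channels=in_channels, embed_dim=config.embed_dim, seed=0)
    if config.backbone == "resnet":
        kwargs["pretrained"] = False
    model = build_backbone(config.backbone, **kwargs)
    model.load_state_dict({k[len("model."):]: v for k, v in arrays.items()
                           if k.startswith("model.")})
    head = CosineHead.init(arrays["head.weights"].shape[0], config.embed_dim,
                           scale=sidecar.get("classifier_scale", config.classifier_scale))
    head.weights.data = arrays["head.weights"].astype(np.float32)
    bank = memory = None
    if "bank.matrix" in arrays:
        bank = PrototypeBank(arrays["bank.matrix"], int(arrays["bank.n_base"]),
                             arrays["bank.class_ids"])
    if "memory.features" in arrays:
        memory = FeatureMemory(arrays["memory.features"], arrays["memory.labels"],
                               config.memory_per_class)
    if bank is None or memory is None:
        raise DataError("checkpoint lacks prototype bank / feature memory; "
                        "run the base session first")
    return SessionState(session_id=int(sidecar["session_id"]), model=model,
                        head=head, bank=bank, memory=memory, config=config)
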