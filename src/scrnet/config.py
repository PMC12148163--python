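"""YAML model configs and weight checkpoints.

A model is fully reconstructable from (variant name, nc, input size, seed)
plus the code version; checkpoints embed that config next to the weights so
a saved model can be rebuilt and loaded without external context.
Checkpoints are NumPy ``.npz`` archives.
"""

from __future__ import annotations

import json

import numpy as np
import yaml

from .assembly import ModelGraph, VariantSpec, build_variant
from .blocks import RepConv
from .reparam import fuse_model


def spec_to_yaml(spec: VariantSpec, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(spec.to_dict(), fh, sort_keys=False)


def spec_from_yaml(path: str) -> VariantSpec:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return VariantSpec.from_name(d["variant"], d.get("num_classes", 4),
                                 d.get("input_size", 640), d.get("seed", 0))


def _is_fused(model: ModelGraph) -> bool:
    reps = [m for m in model.modules() if isinstance(m, RepConv)]
    return bool(reps) and all(r.deployed for r in reps)


def save_checkpoint(model: ModelGraph, path: str) -> None:
    meta = dict(model.spec.to_dict(), fused=_is_fused(model))
    arrays = {f"w/{k}": v for k, v in model.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str) -> ModelGraph:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        sd = {k[2:]: z[k] for k in z.files if k.startswith("w/")}
    spec = VariantSpec.from_name(meta["variant"], meta["num_classes"],
                                 meta["input_size"], meta["seed"])
    model = build_variant(spec)
    if meta.get("fused"):
        model.eval()
        fuse_model(model)
    model.load_state_dict(sd)
    return model
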