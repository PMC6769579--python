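"""Checkpointing of trained models.

A checkpoint is a single NumPy ``.npz`` archive holding every parameter
tensor of both branches, the (fold-masked) network adjacency they were
trained against, and a JSON metadata blob with the catalog (names + digest)
and the training configuration.  Loading restores a model whose eval-mode
scores are bitwise identical to the saved one.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .attention_gcn import LeftBranch
from .catalog import EntityCatalog
from .hetnet import HeteroAdjacency, normalize
from .pair_cnn import RightBranch
from .train_eval import TrainConfig, TrainedModel


def config_from_dict(d: dict) -> TrainConfig:
    d = dict(d)
    for key in ("n_conv", "topk_values"):
        if key in d:
            d[key] = tuple(d[key])
    return TrainConfig(**d)


def save_checkpoint(path: str | Path, model: TrainedModel) -> None:
    cat = model.catalog
    meta = {
        "format": "lncdis-checkpoint-v1",
        "catalog": {
            "lncRNAs": list(cat.lncRNAs),
            "diseases": list(cat.diseases),
            "miRNAs": list(cat.miRNAs),
            "digest": cat.digest(),
        },
        "config": model.config.__dict__ | {
            "n_conv": list(model.config.n_conv),
            "topk_values": list(model.config.topk_values),
        },
    }
    arrays = {"U": model.het.U, "meta": np.array(json.dumps(meta))}
    for k, v in model.left.params.items():
        arrays[f"left_{k}"] = v
    for k, v in model.right.params.items():
        arrays[f"right_{k}"] = v
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path) -> TrainedModel:
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["meta"]))
        if meta.get("format") != "lncdis-checkpoint-v1":
            raise ValueError(f"{path}: not a recognised checkpoint")
        catalog = EntityCatalog(
            lncRNAs=meta["catalog"]["lncRNAs"],
            diseases=meta["catalog"]["diseases"],
            miRNAs=meta["catalog"]["miRNAs"],
        )
        if catalog.digest() != meta["catalog"]["digest"]:
            raise ValueError(f"{path}: catalog digest mismatch")
        config = config_from_dict(meta["config"])
        U = archive["U"]
        left = LeftBranch(catalog.N, config.n, seed=0, lr=config.lr_left)
        for k in left.params:
            left.params[k] = archive[f"left_{k}"]
        right = RightBranch(catalog.N, seed=0, lr=config.lr_right,
                            config=config.right_config(),
                            dtype=np.dtype(config.right_dtype))
        for k in right.params:
            right.params[k] = archive[f"right_{k}"]
    het = HeteroAdjacency(U=U, catalog=catalog)
    return TrainedModel(catalog=catalog, config=config, left=left, right=right,
                        het=het, Utilde=normalize(het).Utilde)
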