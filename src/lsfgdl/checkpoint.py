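"""Model checkpointing: weights + config + condition vocabulary in one archive.

A checkpoint is a single ``.npz`` archive holding every parameter array
plus a JSON metadata blob (model config, condition vocabulary, charge
provider id, conformer count, seed).  Loading rebuilds the network and
refuses vocabulary mismatches.
"""

from __future__ import annotations

import json

import numpy as np

from .conditions import ConditionVocabulary
from .networks import BorylationNet, ModelConfig

__all__ = ["save_checkpoint", "load_checkpoint"]


def save_checkpoint(
    path,
    network: BorylationNet,
    vocab: ConditionVocabulary | None,
    charge_provider: str,
    n_conformers: int,
    seed: int,
) -> None:
    meta = {
        "model_config": network.config.to_dict(),
        "vocabulary": None if vocab is None else json.loads(vocab.to_json()),
        "charge_provider": charge_provider,
        "n_conformers": n_conformers,
        "seed": seed,
    }
    arrays = {f"p{i}": p.data for i, p in enumerate(network.parameters())}
    np.savez(path, meta=np.array(json.dumps(meta)), **arrays)


def load_checkpoint(path) -> tuple[BorylationNet, ConditionVocabulary | None, dict]:
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["meta"]))
        cfg = ModelConfig.from_dict(meta["model_config"])
        vocab = None
        if meta["vocabulary"] is not None:
            vocab = ConditionVocabulary.from_json(json.dumps(meta["vocabulary"]))
        net = BorylationNet(
            cfg,
            condition_width=0 if cfg.task == "regio" else vocab.width,
            seed=meta["seed"],
        )
        state = [archive[f"p{i}"] for i in range(len(archive.files) - 1)]
    net.load_state_dict(state)
    return net, vocab, meta
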