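"""Single-file weight checkpoints.

A checkpoint is an ``.npz`` archive holding every named parameter plus a
JSON header (model configuration, block type, library version) stored as a
byte array under ``__meta__``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .backbone import Backbone
from .config import ModelConfig

__all__ = ["save_checkpoint", "load_checkpoint"]


def save_checkpoint(model: Backbone, path) -> None:
    from .. import __version__

    meta = {
        "format": "jujubenet-checkpoint-v1",
        "library_version": __version__,
        "block_type": model.block_type,
        "model_config": model.config.to_dict(),
    }
    header = np.frombuffer(json.dumps(meta).encode("utf-8"), dtype=np.uint8)
    arrays = {f"param/{k}": v for k, v in model.state_dict().items()}
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "wb") as fh:
        np.savez(fh, __meta__=header, **arrays)


def load_checkpoint(path) -> Backbone:
    with np.load(Path(path)) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode("utf-8"))
        state = {k[len("param/"):]: archive[k] for k in archive.files if k.startswith("param/")}
    config = ModelConfig.from_dict(meta["model_config"])
    model = Backbone(config, block_type=meta["block_type"])
    model.load_state_dict(state)
    return model
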