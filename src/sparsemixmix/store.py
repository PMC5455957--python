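"""On-disk draw store: one array per parameter block plus a JSON sidecar."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .hyperprior import HyperParams
from .sampler import ChainDraws

__all__ = ["save_draws", "load_draws", "hyperparams_from_dict"]

_ARRAY_FIELDS = ("eta", "w", "mu", "Sigma", "b0", "C0", "lam", "S", "I", "K0_per_draw")


def save_draws(draws: ChainDraws, directory: str | Path) -> Path:
    """Write the draw store (draws.npz + meta.json) into `directory`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / "draws.npz", **{f: getattr(draws, f) for f in _ARRAY_FIELDS})
    with open(directory / "meta.json", "w") as fh:
        json.dump(draws.meta, fh, indent=2)
    return directory


def load_draws(directory: str | Path) -> ChainDraws:
    """Reload a draw store; raises naming the missing block if incomplete."""
    directory = Path(directory)
    npz_path = directory / "draws.npz"
    meta_path = directory / "meta.json"
    if not npz_path.exists():
        raise FileNotFoundError(f"draw store incomplete: missing {npz_path}")
    with np.load(npz_path) as npz:
        arrays = {}
        for f in _ARRAY_FIELDS:
            if f not in npz:
                raise KeyError(f"draw store incomplete: missing array block '{f}'")
            arrays[f] = npz[f]
    meta = {}
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = json.load(fh)
    return ChainDraws(meta=meta, **arrays)


def hyperparams_from_dict(d: dict) -> HyperParams:
    """Rebuild HyperParams from the serialized meta entry."""
    kwargs = dict(d)
    for name in ("G0", "B0", "m0", "M0"):
        kwargs[name] = np.asarray(kwargs[name], dtype=float)
    return HyperParams(**kwargs).validate()
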