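"""Checkpoint I/O: one directory per scenario member plus ``meta/``.

Each member directory holds ``params.npz`` (all weight arrays, keyed by
their path in the parameter tree) and ``config.json`` (encoder config and
embedder spec), enough to rebuild the model byte-identically.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .encoder import EncoderConfig, PairEncoder, make_embedder
from .gba import SCENARIO_ORDER, Scenario
from .nn import init_mlp
from .training import TrainedEnsemble

__all__ = ["save_member", "load_member", "save_ensemble", "load_ensemble"]


def _walk(node, prefix, out: dict) -> None:
    if isinstance(node, np.ndarray):
        out[prefix] = node
    elif isinstance(node, dict):
        for k in sorted(node):
            _walk(node[k], f"{prefix}/{k}" if prefix else k, out)
    elif isinstance(node, (list, tuple)):
        for i, item in enumerate(node):
            _walk(item, f"{prefix}/{i}" if prefix else str(i), out)


def _params_to_flat(params) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    _walk(params, "", out)
    return out


def _restore_from_flat(params, flat: dict[str, np.ndarray]) -> None:
    skeleton = _params_to_flat(params)
    if set(skeleton) != set(flat):
        raise ValueError(
            f"checkpoint keys do not match model: missing={sorted(set(skeleton) - set(flat))}, "
            f"extra={sorted(set(flat) - set(skeleton))}"
        )
    for key, arr in skeleton.items():
        arr[...] = flat[key]


def _encoder_cfg_dict(cfg: EncoderConfig) -> dict:
    return {
        "aggregator": cfg.aggregator,
        "d": cfg.d,
        "d_in": cfg.d_in,
        "n_heads": cfg.n_heads,
        "head_layers": list(cfg.head_layers) if cfg.head_layers else None,
        "dropout": cfg.dropout,
        "embedder": cfg.embedder,
    }


def _encoder_cfg_from(obj: dict) -> EncoderConfig:
    hl = obj.get("head_layers")
    return EncoderConfig(
        aggregator=obj["aggregator"],
        d=obj["d"],
        d_in=obj["d_in"],
        n_heads=obj["n_heads"],
        head_layers=tuple(hl) if hl else None,
        dropout=obj["dropout"],
        embedder=obj["embedder"],
    )


def save_member(model: PairEncoder, out_dir: str | Path, extra: dict | None = None) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savez(out / "params.npz", **_params_to_flat(model.params))
    cfg = {
        "encoder": _encoder_cfg_dict(model.cfg),
        "embedder_seed": getattr(model.embedder, "seed", None),
        **(extra or {}),
    }
    (out / "config.json").write_text(json.dumps(cfg, indent=2, sort_keys=True))


def load_member(in_dir: str | Path, embedder=None) -> PairEncoder:
    path = Path(in_dir)
    cfg_obj = json.loads((path / "config.json").read_text())
    cfg = _encoder_cfg_from(cfg_obj["encoder"])
    if embedder is None:
        embedder = make_embedder(
            cfg.embedder, d_in=cfg.d_in, seed=cfg_obj.get("embedder_seed") or 0
        )
    model = PairEncoder(cfg, seed=0, embedder=embedder)
    with np.load(path / "params.npz") as npz:
        _restore_from_flat(model.params, dict(npz))
    return model


def save_ensemble(ensemble: TrainedEnsemble, out_dir: str | Path, extra: dict | None = None) -> None:
    out = Path(out_dir)
    for s, m in ensemble.members.items():
        save_member(m, out / s.value, extra={"scenario": s.value, **(extra or {})})
    meta_dir = out / "meta"
    meta_dir.mkdir(parents=True, exist_ok=True)
    np.savez(meta_dir / "params.npz", **_params_to_flat(ensemble.meta))
    (meta_dir / "config.json").write_text(
        json.dumps(
            {
                "encoder": _encoder_cfg_dict(ensemble.encoder_cfg),
                "meta_config": ensemble.meta_config,
                "embedder_seed": getattr(ensemble.embedder, "seed", None),
                **(extra or {}),
            },
            indent=2,
            sort_keys=True,
        )
    )


def load_ensemble(in_dir: str | Path) -> TrainedEnsemble:
    path = Path(in_dir)
    meta_obj = json.loads((path / "meta" / "config.json").read_text())
    cfg = _encoder_cfg_from(meta_obj["encoder"])
    embedder = make_embedder(cfg.embedder, d_in=cfg.d_in, seed=meta_obj.get("embedder_seed") or 0)
    members = {s: load_member(path / s.value, embedder=embedder) for s in SCENARIO_ORDER}
    # rebuild the meta MLP skeleton, then overwrite with stored weights
    with np.load(path / "meta" / "params.npz") as npz:
        flat = dict(npz)
    n_features = flat["0/W"].shape[1]
    plan = [n_features] + cfg.head_plan()[1:]
    meta = init_mlp(plan, np.random.default_rng(0))
    _restore_from_flat(meta, flat)
    return TrainedEnsemble(
        members=members,
        meta=meta,
        encoder_cfg=cfg,
        embedder=embedder,
        meta_config=meta_obj.get("meta_config", {}),
    )
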