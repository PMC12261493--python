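"""Warm and cold-start cross-validation splits for DTA datasets.

Three modes:

``warm``
    Pairs are shuffled and partitioned train:valid:test (default 6:2:2);
    drugs and proteins may appear in every block.
``cold_drug``
    The *drug* set is partitioned by the ratios; every pair follows its
    drug, so no drug is shared between train, valid and test.
``cold_target``
    Symmetric hold-out of proteins.

Each of the ``n_folds`` folds is an independent seeded shuffle (seed +
fold index) -- a 6:2:2 ratio is incompatible with plain rotation of five
fixed quintiles.  Block sizes follow largest-remainder apportionment, so
they deviate from the exact ratios by less than one unit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .data import DTADataset

__all__ = ["Fold", "FoldAssignment", "InfeasibleSplitError", "make_folds", "apportion"]

MODES = ("warm", "cold_drug", "cold_target")


class InfeasibleSplitError(ValueError):
    """Too few pairs or entities to form the requested folds."""


@dataclass(frozen=True)
class Fold:
    train: np.ndarray  # pair indices, sorted
    valid: np.ndarray
    test: np.ndarray


@dataclass(frozen=True)
class FoldAssignment:
    mode: str
    folds: tuple[Fold, ...]
    seed: int

    def to_json(self, path: str | Path) -> None:
        obj = {
            "mode": self.mode,
            "seed": self.seed,
            "folds": [
                {
                    "train": f.train.tolist(),
                    "valid": f.valid.tolist(),
                    "test": f.test.tolist(),
                }
                for f in self.folds
            ],
        }
        Path(path).write_text(json.dumps(obj))

    @staticmethod
    def from_json(path: str | Path) -> "FoldAssignment":
        obj = json.loads(Path(path).read_text())
        folds = tuple(
            Fold(
                train=np.asarray(f["train"], dtype=np.int64),
                valid=np.asarray(f["valid"], dtype=np.int64),
                test=np.asarray(f["test"], dtype=np.int64),
            )
            for f in obj["folds"]
        )
        return FoldAssignment(mode=obj["mode"], folds=folds, seed=obj["seed"])


def apportion(n: int, ratios: Sequence[float]) -> list[int]:
    """Split ``n`` items into blocks by largest-remainder apportionment."""
    quotas = [n * r for r in ratios]
    base = [int(np.floor(q)) for q in quotas]
    short = n - sum(base)
    # hand leftover units to the largest fractional remainders (ties: first)
    order = sorted(range(len(ratios)), key=lambda i: quotas[i] - base[i], reverse=True)
    for i in order[:short]:
        base[i] += 1
    return base


def make_folds(
    ds: DTADataset,
    mode: str = "warm",
    ratios: Sequence[float] = (0.6, 0.2, 0.2),
    n_folds: int = 5,
    seed: int = 0,
) -> FoldAssignment:
    """Build train/valid/test folds over the pair indices of ``ds``."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    if len(ratios) != 3 or any(r <= 0 for r in ratios):
        raise ValueError("ratios must be three positive reals")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {sum(ratios)}")
    if n_folds < 1:
        raise ValueError("n_folds must be >= 1")

    n_pairs = ds.n_pairs
    if mode == "warm":
        if n_pairs < max(n_folds, 3):
            raise InfeasibleSplitError(f"warm split needs >= 3 pairs, got {n_pairs}")
        folds = tuple(
            _warm_fold(n_pairs, ratios, np.random.default_rng(seed + k))
            for k in range(n_folds)
        )
    else:
        entity_of_pair, entity_ids = _split_entities(ds, mode)
        if len(entity_ids) < 3:
            raise InfeasibleSplitError(
                f"{mode} split needs >= 3 distinct entities, got {len(entity_ids)}"
            )
        folds = tuple(
            _cold_fold(entity_of_pair, len(entity_ids), ratios, np.random.default_rng(seed + k))
            for k in range(n_folds)
        )
    return FoldAssignment(mode=mode, folds=folds, seed=seed)


def _warm_fold(n_pairs: int, ratios: Sequence[float], rng: np.random.Generator) -> Fold:
    perm = rng.permutation(n_pairs)
    n_tr, n_va, n_te = apportion(n_pairs, ratios)
    return Fold(
        train=np.sort(perm[:n_tr]),
        valid=np.sort(perm[n_tr : n_tr + n_va]),
        test=np.sort(perm[n_tr + n_va :]),
    )


def _split_entities(ds: DTADataset, mode: str) -> tuple[np.ndarray, list[str]]:
    ids = list(ds.drugs if mode == "cold_drug" else ds.proteins)
    index = {e: i for i, e in enumerate(ids)}
    attr = "drug_id" if mode == "cold_drug" else "protein_id"
    entity_of_pair = np.array([index[getattr(p, attr)] for p in ds.pairs], dtype=np.int64)
    return entity_of_pair, ids

def _cold_fold(
    entity_of_pair: np.ndarray,
    n_entities: int,
    ratios: Sequence[float],
    rng: np.random.Generator,
) -> Fold:
    perm = rng.permutation(n_entities)
    n_tr, n_va, _ = apportion(n_entities, ratios)
    block = np.empty(n_entities, dtype=np.int64)  # 0=train 1=valid 2=test
    block[perm[:n_tr]] = 0
    block[perm[n_tr : n_tr + n_va]] = 1
    block[perm[n_tr + n_va :]] = 2
    pair_block = block[entity_of_pair]
    all_idx = np.arange(len(entity_of_pair))
    return Fold(
        train=all_idx[pair_block == 0],
        valid=all_idx[pair_block == 1],
        test=all_idx[pair_block == 2],
    )
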