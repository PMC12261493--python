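"""Guilt-by-association (GBA) neighborhoods over drug-target pair nodes.

Every observed (drug, protein) pair is a node carrying its affinity as a
label.  Six neighborhood scenarios connect nodes by which components they
share:

================  ==================================================
``none``          no edges; training proceeds without augmentation
``all_pair``      every other training node is a neighbor
``drug``          nodes sharing the same drug
``protein``       nodes sharing the same protein (target)
``protein_or_drug``  union of the two previous scenarios
``complement``    nodes sharing *neither* drug nor protein
================  ==================================================

Mixup partners are drawn from the neighborhood with probability
proportional to the affinity-similarity kernel
``w(i, j) = exp(-|y_i - y_j| / tau)``, so label-similar neighbors are
preferred.  Neighborhoods are always restricted to the training block of
the active fold, so augmentation can never leak validation or test pairs.

The index is lazy: for the dense ``all_pair``/``complement`` scenarios
neighbor sets are never materialized above ``exact_threshold`` candidates;
a uniform-proposal / weight-acceptance rejection sampler is used instead
(edge weights lie in (0, 1], so the acceptance step is exact).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .data import DTADataset

__all__ = [
    "Scenario",
    "SCENARIO_ORDER",
    "GBAConfig",
    "NeighborIndex",
    "build_neighbor_index",
    "edge_weight",
    "sample_partner",
]


class Scenario(str, Enum):
    NONE = "none"
    ALL_PAIR = "all_pair"
    DRUG = "drug"
    PROTEIN = "protein"
    PROTEIN_OR_DRUG = "protein_or_drug"
    COMPLEMENT = "complement"


#: Fixed ordering used everywhere a per-scenario vector is produced.
SCENARIO_ORDER: tuple[Scenario, ...] = (
    Scenario.NONE,
    Scenario.ALL_PAIR,
    Scenario.DRUG,
    Scenario.PROTEIN,
    Scenario.PROTEIN_OR_DRUG,
    Scenario.COMPLEMENT,
)


@dataclass(frozen=True)
class GBAConfig:
    """Similarity-kernel temperature and sampling knobs.

    tau
        Temperature of ``exp(-|dy|/tau)``; smaller tau concentrates the
        sampling on label-similar neighbors.
    exact_threshold
        Candidate-set size above which the dense scenarios switch from
        exact weighted choice to rejection sampling.
    """

    tau: float = 1.0
    allow_self: bool = False
    exact_threshold: int = 10_000
    max_rejection_attempts: int = 10_000

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.allow_self:
            raise ValueError("self-pairing is not supported")


@dataclass
class NeighborIndex:
    """Per-scenario adjacency over the training block's pair nodes."""

    scenario: Scenario
    by_drug: dict[str, np.ndarray]
    by_protein: dict[str, np.ndarray]
    node_labels: np.ndarray  # full-dataset label vector, indexed by pair index
    restricted_to: np.ndarray  # sorted train pair indices
    _drug_of: dict[int, str] = field(default_factory=dict, repr=False)
    _protein_of: dict[int, str] = field(default_factory=dict, repr=False)
    _restricted_set: frozenset = field(default_factory=frozenset, repr=False)

    def neighbors(self, node: int) -> np.ndarray:
        """Materialize the neighbor set of ``node`` (for small scenarios
        and for oracle checks; the samplers avoid this for dense ones)."""
        self._check(node)
        s = self.scenario
        if s is Scenario.NONE:
            return np.empty(0, dtype=np.int64)
        same_d = self.by_drug[self._drug_of[node]]
        same_p = self.by_protein[self._protein_of[node]]
        if s is Scenario.DRUG:
            out = same_d
        elif s is Scenario.PROTEIN:
            out = same_p
        elif s is Scenario.PROTEIN_OR_DRUG:
            out = np.union1d(same_d, same_p)
        elif s is Scenario.ALL_PAIR:
            out = self.restricted_to
        else:  # COMPLEMENT
            shared = np.union1d(same_d, same_p)
            out = np.setdiff1d(self.restricted_to, shared, assume_unique=True)
        return out[out != node]

    def degree(self, node: int) -> int:
        return len(self.neighbors(node))

    def _check(self, node: int) -> None:
        if node not in self._restricted_set:
            raise IndexError(f"node {node} is not in the training block")


def build_neighbor_index(
    ds: DTADataset, train_ids, scenario: Scenario | str
) -> NeighborIndex:
    """Index the training block of ``ds`` for one neighborhood scenario."""
    scenario = Scenario(scenario)
    train = np.unique(np.asarray(list(train_ids), dtype=np.int64))
    if train.size == 0:
        raise ValueError("train_ids must be non-empty")
    if train.min() < 0 or train.max() >= ds.n_pairs:
        raise IndexError("train_ids out of range")

    by_drug: dict[str, list[int]] = {}
    by_protein: dict[str, list[int]] = {}
    drug_of: dict[int, str] = {}
    protein_of: dict[int, str] = {}
    for i in train:
        p = ds.pairs[int(i)]
        by_drug.setdefault(p.drug_id, []).append(int(i))
        by_protein.setdefault(p.protein_id, []).append(int(i))
        drug_of[int(i)] = p.drug_id
        protein_of[int(i)] = p.protein_id

    return NeighborIndex(
        scenario=scenario,
        by_drug={k: np.asarray(v, dtype=np.int64) for k, v in by_drug.items()},
        by_protein={k: np.asarray(v, dtype=np.int64) for k, v in by_protein.items()},
        node_labels=ds.labels(),
        restricted_to=train,
        _drug_of=drug_of,
        _protein_of=protein_of,
        _restricted_set=frozenset(int(i) for i in train),
    )


def edge_weight(y_i, y_j, cfg: GBAConfig) -> float | np.ndarray:
    """Affinity-similarity kernel ``exp(-|y_i - y_j| / tau)`` in (0, 1]."""
    w = np.exp(-np.abs(np.asarray(y_i) - np.asarray(y_j)) / cfg.tau)
    return float(w) if w.ndim == 0 else w


def sample_partner(
    idx: NeighborIndex,
    node: int,
    cfg: GBAConfig,
    rng: np.random.Generator,
) -> int | None:
    """Draw a mixup partner for ``node`` with weight-proportional probability.

    Returns ``None`` when the neighborhood is empty (scenario ``none``, or
    an isolated node).  Dense scenarios above ``cfg.exact_threshold``
    candidates use rejection sampling and never materialize the set.
    """
    idx._check(node)
    s = idx.scenario
    if s is Scenario.NONE:
        return None

    if s in (Scenario.ALL_PAIR, Scenario.COMPLEMENT):
        n_candidates = idx.restricted_to.size
        if n_candidates > cfg.exact_threshold:
            j = _rejection_sample(idx, node, cfg, rng)
            if j is not None:
                return j
            # fall through to the exact path if rejection failed to accept

    nbrs = idx.neighbors(node)
    if nbrs.size == 0:
        return None
    w = edge_weight(idx.node_labels[node], idx.node_labels[nbrs], cfg)
    return int(rng.choice(nbrs, p=w / w.sum()))


def _rejection_sample(
    idx: NeighborIndex, node: int, cfg: GBAConfig, rng: np.random.Generator
) -> int | None:
    """Uniform proposal over the training block, acceptance ∝ edge weight."""
    pool = idx.restricted_to
    y_node = idx.node_labels[node]
    d_node = idx._drug_of[node]
    p_node = idx._protein_of[node]
    complement = idx.scenario is Scenario.COMPLEMENT
    for _ in range(cfg.max_rejection_attempts):
        j = int(pool[rng.integers(pool.size)])
        if j == node:
            continue
        if complement and (idx._drug_of[j] == d_node or idx._protein_of[j] == p_node):
            continue
        if rng.random() < edge_weight(y_node, idx.node_labels[j], cfg):
            return j
    return None
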