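"""Two-stage training: per-scenario encoders with GBA-mixup, then a
multiview meta-predictor.

Stage 1 trains one :class:`~mixdta.encoder.PairEncoder` per neighborhood
scenario.  Each training sample draws a mixup partner from its scenario
neighborhood (restricted to the training block), a coefficient
``lam ~ Beta(alpha, alpha)``, and contributes the mixed representation and
label to the MSE loss; the ``none`` scenario trains on the plain stream.
Validation loss is always computed on unmixed validation pairs, with
early stopping on patience.

Stage 2 freezes the six members, extracts for every pair the element-wise
sum of the members' pooled representations plus the six scalar
predictions, and trains a meta MLP (same layer plan as the member heads)
on those fused features with MSE, early-stopped on the same validation
block.  All randomness is seeded; identical configs reproduce identical
loss trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .data import DTADataset
from .encoder import EncoderConfig, PairEncoder, TokenMatrix, embed_entity
from .gba import (
    GBAConfig,
    NeighborIndex,
    SCENARIO_ORDER,
    Scenario,
    build_neighbor_index,
    sample_partner,
)
from .mixup import MixupConfig, mix_pair, pad_to, sample_lambda
from .nn import Adam, assign_params, copy_params, flatten_params, init_mlp, mlp_backward, mlp_forward
from .splitting import Fold

__all__ = [
    "TrainConfig",
    "TrainedMember",
    "MetaFeature",
    "TrainedEnsemble",
    "training_stream",
    "train_scenario",
    "extract_meta_features",
    "train_meta",
    "train_ensemble",
    "predict",
    "predict_member",
]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 200
    batch_size: int = 64
    learning_rate: float = 1e-3
    patience: int = 20
    seed: int = 0
    scenario: Scenario = Scenario.NONE
    mixup: MixupConfig = field(default_factory=MixupConfig)
    gba: GBAConfig = field(default_factory=GBAConfig)

    def __post_init__(self) -> None:
        if min(self.epochs, self.batch_size, self.patience) < 1:
            raise ValueError("epochs, batch_size and patience must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class TrainedMember:
    model: PairEncoder
    scenario: Scenario
    history: list[dict]
    best_valid_mse: float
    used_pair_indices: set[int]  # every pair index touched during training


@dataclass(frozen=True)
class MetaFeature:
    fused_embedding: np.ndarray  # (2d,) sum of members' concat representations
    member_predictions: np.ndarray  # (6,) in SCENARIO_ORDER

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate([self.fused_embedding, self.member_predictions])


@dataclass
class TrainedEnsemble:
    members: dict[Scenario, PairEncoder]
    meta: list[dict]  # MLP layers of the meta-predictor
    encoder_cfg: EncoderConfig
    embedder: object
    meta_config: dict = field(default_factory=lambda: {"include_predictions": True})
    meta_history: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [s for s in SCENARIO_ORDER if s not in self.members]
        if missing:
            raise ValueError(f"ensemble needs all six scenario members; missing {missing}")


def _token_cache(ds: DTADataset, embedder) -> tuple[dict, dict]:
    d_tok = {d.id: embed_entity(d, embedder) for d in ds.drugs.values()}
    p_tok = {p.id: embed_entity(p, embedder) for p in ds.proteins.values()}
    return d_tok, p_tok


def training_stream(
    train_ids: np.ndarray,
    index: Optional[NeighborIndex],
    scenario: Scenario,
    mix_cfg: MixupConfig,
    gba_cfg: GBAConfig,
    rng: np.random.Generator,
) -> list[tuple[int, Optional[int], float]]:
    """One epoch's augmentation plan: (anchor, partner-or-None, lam) triples.

    With scenario ``none`` every triple is (i, None, 1.0): the stream is
    the unaugmented stream, sample for sample.  Isolated nodes pass
    through clean the same way.
    """
    out = []
    for i in train_ids:
        i = int(i)
        if scenario is Scenario.NONE or index is None:
            out.append((i, None, 1.0))
            continue
        j = sample_partner(index, i, gba_cfg, rng)
        if j is None:
            out.append((i, None, 1.0))
        else:
            out.append((i, j, sample_lambda(mix_cfg, rng)))
    return out


def _flatten_grad_tree(model: PairEncoder, head_grads, enc_grads_list) -> list[np.ndarray]:
    """Assemble a gradient tree shaped exactly like ``model.params`` and
    flatten it in the same deterministic order."""
    tree: dict = {"head": head_grads}
    acc: dict = {}
    for g in enc_grads_list:
        for key, sub in g.items():
            if key not in acc:
                acc[key] = {k: v.copy() for k, v in sub.items()}
            else:
                for k, v in sub.items():
                    acc[key][k] += v
    tree.update(acc)
    if "embed_table" in model.params:
        tree["embed_table"] = np.zeros_like(model.params["embed_table"])
    return flatten_params(tree)


def _valid_mse(model: PairEncoder, ds, d_tok, p_tok, indices) -> float:
    errs = []
    for i in indices:
        p = ds.pairs[int(i)]
        yhat = model.predict_pair(d_tok[p.drug_id], p_tok[p.protein_id])
        errs.append((yhat - p.label) ** 2)
    return float(np.mean(errs))


def train_scenario(
    ds: DTADataset,
    fold: Fold,
    cfg: TrainConfig,
    encoder_cfg: EncoderConfig,
    embedder=None,
) -> TrainedMember:
    """Stage-1 training of one scenario member on one fold."""
    if fold.train.size == 0:
        raise ValueError("empty train block")
    ss = np.random.SeedSequence([cfg.seed, int(_scenario_code(cfg.scenario))])
    seed_init, seed_shuffle, seed_mix, seed_drop = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)
    )
    model = PairEncoder(encoder_cfg, seed=seed_init, embedder=embedder)
    # start the scalar output at the training-label mean so the optimizer
    # fits structure instead of spending its budget on the offset
    model.params["head"][-1]["b"][0] = float(ds.labels()[fold.train].mean())
    if getattr(model.embedder, "trainable", False):
        raise NotImplementedError(
            "stage-1 training currently expects a fixed (hashed/file) embedder"
        )
    d_tok, p_tok = _token_cache(ds, model.embedder)
    labels = ds.labels()

    index = None
    if cfg.scenario is not Scenario.NONE:
        index = build_neighbor_index(ds, fold.train, cfg.scenario)

    rng_shuffle = np.random.default_rng(seed_shuffle)
    rng_mix = np.random.default_rng(seed_mix)
    rng_drop = np.random.default_rng(seed_drop)
    adam = Adam(flatten_params(model.params), lr=cfg.learning_rate)

    def tokens_of(i: int) -> tuple[TokenMatrix, TokenMatrix]:
        p = ds.pairs[i]
        return d_tok[p.drug_id], p_tok[p.protein_id]

    used: set[int] = set(int(i) for i in fold.train) | set(int(i) for i in fold.valid)
    history: list[dict] = []
    best_mse = np.inf
    best_params = copy_params(model.params)
    stale = 0

    for epoch in range(cfg.epochs):
        order = fold.train[rng_shuffle.permutation(fold.train.size)]
        plan = training_stream(order, index, cfg.scenario, cfg.mixup, cfg.gba, rng_mix)
        train_loss = 0.0
        for start in range(0, len(plan), cfg.batch_size):
            batch = plan[start : start + cfg.batch_size]
            acc: Optional[list[np.ndarray]] = None
            for i, j, lam in batch:
                used.add(i)
                if j is not None:
                    used.add(j)
                loss, flat = _sample_grads(
                    model, tokens_of, labels, i, j, lam, cfg, rng_drop, len(batch)
                )
                train_loss += loss
                if acc is None:
                    acc = flat
                else:
                    for a, g in zip(acc, flat):
                        a += g
            adam.step(acc)
        valid_mse = _valid_mse(model, ds, d_tok, p_tok, fold.valid)
        history.append(
            {
                "epoch": epoch,
                "train_mse": train_loss / len(plan),
                "valid_mse": valid_mse,
                "lr": cfg.learning_rate,
                "seed": cfg.seed,
            }
        )
        if valid_mse < best_mse - 1e-12:
            best_mse = valid_mse
            best_params = copy_params(model.params)
            stale = 0
        else:
            stale += 1
            if stale > cfg.patience:
                break
    assign_params(model.params, best_params)
    return TrainedMember(
        model=model,
        scenario=cfg.scenario,
        history=history,
        best_valid_mse=best_mse,
        used_pair_indices=used,
    )


def _sample_grads(model, tokens_of, labels, i, j, lam, cfg, rng_drop, batch_n):
    """Loss and flattened gradients of one (possibly mixed) sample."""
    d_i, p_i = tokens_of(i)
    if j is None or cfg.mixup.mix_space == "pooled_representation":
        rep_i, cache_i = model.encode(d_i, p_i, return_cache=True)
        if j is None:
            rep_vec, y_mix = rep_i.concat, labels[i]
        else:
            d_j, p_j = tokens_of(j)
            rep_j, cache_j = model.encode(d_j, p_j, return_cache=True)
            mixed = mix_pair(rep_i.concat, rep_j.concat, labels[i], labels[j], lam, (i, j))
            rep_vec, y_mix = mixed.rep, mixed.label
        yhat, hcache = model.head_forward(rep_vec, train=True, rng=rng_drop)
        dy = 2.0 * (yhat - y_mix) / batch_n
        hgrads, drep = model.head_backward(hcache, dy)
        enc_grads = []
        g_i, _, _ = model.encoder_backward(cache_i, drep if j is None else lam * drep)
        enc_grads.append(g_i)
        if j is not None:
            g_j, _, _ = model.encoder_backward(cache_j, (1.0 - lam) * drep)
            enc_grads.append(g_j)
        loss = (yhat - y_mix) ** 2
    else:  # padded_token: mix the token matrices, encode once
        d_j, p_j = tokens_of(j)
        Td = max(d_i.T, d_j.T)
        Tp = max(p_i.T, p_j.T)
        d_mix = TokenMatrix(lam * pad_to(d_i.values, Td) + (1 - lam) * pad_to(d_j.values, Td))
        p_mix = TokenMatrix(lam * pad_to(p_i.values, Tp) + (1 - lam) * pad_to(p_j.values, Tp))
        y_mix = lam * labels[i] + (1 - lam) * labels[j]
        rep, cache = model.encode(d_mix, p_mix, return_cache=True)
        yhat, hcache = model.head_forward(rep.concat, train=True, rng=rng_drop)
        dy = 2.0 * (yhat - y_mix) / batch_n
        hgrads, drep = model.head_backward(hcache, dy)
        g, _, _ = model.encoder_backward(cache, drep)
        enc_grads = [g]
        loss = (yhat - y_mix) ** 2
    return loss, _flatten_grad_tree(model, hgrads, enc_grads)


def _scenario_code(s: Scenario) -> int:
    return SCENARIO_ORDER.index(s)


def extract_meta_features(
    members: dict[Scenario, PairEncoder], drug: TokenMatrix, protein: TokenMatrix
) -> MetaFeature:
    """Fused embedding (sum of members' pooled representations) plus the six
    member predictions in fixed scenario order."""
    widths = {m.cfg.d for m in members.values()}
    if len(widths) != 1:
        raise ValueError(f"members disagree on hidden width d: {sorted(widths)}")
    fused = None
    preds = []
    for s in SCENARIO_ORDER:
        m = members[s]
        rep = m.encode(drug, protein)
        concat = rep.concat
        fused = concat.copy() if fused is None else fused + concat
        y, _ = m.head_forward(concat)
        preds.append(y)
    return MetaFeature(fused_embedding=fused, member_predictions=np.asarray(preds))


def _meta_plan(encoder_cfg: EncoderConfig, n_features: int) -> list[int]:
    # same fully connected layer plan as the member head, re-based on the
    # meta input width
    plan = encoder_cfg.head_plan()
    return [n_features] + plan[1:]


def train_meta(
    members: dict[Scenario, PairEncoder],
    ds: DTADataset,
    fold: Fold,
    cfg: TrainConfig,
    encoder_cfg: EncoderConfig,
    embedder=None,
) -> TrainedEnsemble:
    """Stage-2: freeze the members, train the meta MLP on fused features."""
    embedder = embedder or members[Scenario.NONE].embedder
    d_tok, p_tok = _token_cache(ds, embedder)
    labels = ds.labels()

    def feature(i: int) -> np.ndarray:
        p = ds.pairs[int(i)]
        return extract_meta_features(members, d_tok[p.drug_id], p_tok[p.protein_id]).vector

    X_train = np.stack([feature(i) for i in fold.train])
    y_train = labels[fold.train]
    X_valid = np.stack([feature(i) for i in fold.valid])
    y_valid = labels[fold.valid]

    # the meta MLP learns a correction on top of the mean member
    # prediction, so its untrained state already equals the robust
    # prediction average and early stopping can only improve on it
    base_train = X_train[:, -len(SCENARIO_ORDER):].mean(axis=1)
    base_valid = X_valid[:, -len(SCENARIO_ORDER):].mean(axis=1)
    r_train = y_train - base_train
    r_valid = y_valid - base_valid

    # z-score the fused features with training-block statistics: embedding
    # sums and scalar predictions live on very different scales
    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0)
    sd[sd < 1e-8] = 1.0
    X_train = (X_train - mu) / sd
    X_valid = (X_valid - mu) / sd

    ss = np.random.SeedSequence([cfg.seed, 97])
    seed_init, seed_shuffle, seed_drop = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)
    )
    layers = init_mlp(_meta_plan(encoder_cfg, X_train.shape[1]), np.random.default_rng(seed_init))
    # zero-init the output layer: the untrained meta then predicts exactly
    # the mean member prediction (plus the mean residual), and training
    # grows the correction from that robust baseline
    layers[-1]["W"][...] = 0.0
    layers[-1]["b"][0] = float(r_train.mean())
    adam = Adam(flatten_params(layers), lr=cfg.learning_rate, weight_decay=1e-3)
    rng_shuffle = np.random.default_rng(seed_shuffle)
    rng_drop = np.random.default_rng(seed_drop)

    def eval_mse(X, r) -> float:
        preds = np.array([mlp_forward(layers, x)[0][0] for x in X])
        return float(np.mean((preds - r) ** 2))

    best = eval_mse(X_valid, r_valid)  # untrained state = prediction average
    best_layers = copy_params(layers)
    stale = 0
    history = [{"epoch": -1, "train_mse": eval_mse(X_train, r_train), "valid_mse": best}]
    for epoch in range(cfg.epochs):
        order = rng_shuffle.permutation(len(X_train))
        train_loss = 0.0
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            acc = None
            for k in batch:
                yhat, cache = mlp_forward(
                    layers, X_train[k], dropout=encoder_cfg.dropout, rng=rng_drop
                )
                err = float(yhat[0]) - r_train[k]
                train_loss += err * err
                grads, _ = mlp_backward(layers, cache, np.array([2.0 * err / len(batch)]))
                flat = flatten_params(grads)
                if acc is None:
                    acc = flat
                else:
                    for a, g in zip(acc, flat):
                        a += g
            adam.step(acc)
        valid_mse = eval_mse(X_valid, r_valid)
        history.append(
            {"epoch": epoch, "train_mse": train_loss / len(order), "valid_mse": valid_mse}
        )
        if valid_mse < best - 1e-12:
            best, best_layers, stale = valid_mse, copy_params(layers), 0
        else:
            stale += 1
            if stale > cfg.patience:
                break
    assign_params(layers, best_layers)
    return TrainedEnsemble(
        members=members,
        meta=layers,
        encoder_cfg=encoder_cfg,
        embedder=embedder,
        meta_config={
            "include_predictions": True,
            "residual_base": "mean_member_prediction",
            "feature_mean": mu.tolist(),
            "feature_sd": sd.tolist(),
        },
        meta_history=history,
    )


def train_ensemble(
    ds: DTADataset,
    fold: Fold,
    cfg: TrainConfig,
    encoder_cfg: EncoderConfig,
    embedder=None,
    scenarios: Sequence[Scenario] = SCENARIO_ORDER,
) -> tuple[TrainedEnsemble, dict[Scenario, TrainedMember]]:
    """Train all six scenario members plus the meta-predictor."""
    if embedder is None:
        from .encoder import make_embedder

        embedder = make_embedder(encoder_cfg.embedder, d_in=encoder_cfg.d_in, seed=cfg.seed)
    trained: dict[Scenario, TrainedMember] = {}
    for s in scenarios:
        trained[s] = train_scenario(
            ds, fold, replace(cfg, scenario=s), encoder_cfg, embedder=embedder
        )
    members = {s: tm.model for s, tm in trained.items()}
    ensemble = train_meta(members, ds, fold, cfg, encoder_cfg, embedder=embedder)
    return ensemble, trained


def predict(ensemble: TrainedEnsemble, pairs) -> np.ndarray:
    """Ensemble prediction for a list of (Drug, Protein) entity pairs."""
    mu = np.asarray(ensemble.meta_config.get("feature_mean", 0.0))
    sd = np.asarray(ensemble.meta_config.get("feature_sd", 1.0))
    residual = ensemble.meta_config.get("residual_base") == "mean_member_prediction"
    out = []
    for drug, protein in pairs:
        d_tm = embed_entity(drug, ensemble.embedder)
        p_tm = embed_entity(protein, ensemble.embedder)
        feat = extract_meta_features(ensemble.members, d_tm, p_tm)
        y, _ = mlp_forward(ensemble.meta, (feat.vector - mu) / sd)
        base = float(feat.member_predictions.mean()) if residual else 0.0
        out.append(base + float(y[0]))
    return np.asarray(out)


def predict_member(model: PairEncoder, ds: DTADataset, indices, embedder=None) -> np.ndarray:
    """Single-member predictions for the given pair indices of ``ds``."""
    embedder = embedder or model.embedder
    d_tok, p_tok = _token_cache(ds, embedder)
    return np.array(
        [
            model.predict_pair(d_tok[ds.pairs[int(i)].drug_id], p_tok[ds.pairs[int(i)].protein_id])
            for i in indices
        ]
    )
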