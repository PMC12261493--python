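"""Twin cross-aggregation encoder for drug-target pairs.

The encoder consumes two token-embedding matrices -- one per entity of the
pair -- and produces a fixed-length :class:`PairRepresentation`:

1. each side's tokens are embedded (pluggable embedder: a trainable
   per-character lookup, a fixed seeded hash, or precomputed matrices from
   an HDF5 archive);
2. a cross-aggregation step attends each side's tokens over the *other*
   side's tokens, either with attention-free aggregation (AFA) or with
   standard multi-head attention (MHA);
3. a token-wise max-pool over each side's aggregated tokens yields two
   length-``d`` vectors whose concatenation is the pair representation;
4. a dense ReLU head maps the representation to a scalar affinity.

AFA replaces the quadratic query-key dot product with per-dimension
element-wise operations.  With projected queries ``Q0 = X_q W_Q``, keys
``K0 = X_c W_K`` and values ``V0 = X_c W_V``, the output for query token
``t`` and dimension ``m`` is

    Y[t, m] = sigmoid(Q0[t, m]) * sum_t' softmax_m(K0)[t'] * V0[t', m],

where ``softmax_m`` normalizes ``exp(K0[:, m])`` over the context tokens
of each dimension independently.  The cost is linear in the context
length, and a single head is used.  The exponent is shifted by the
per-dimension max of ``K0`` before exponentiation; the softmax is
invariant to that shift, so the result is unchanged while overflow is
impossible.

Backward passes are analytic (verified against finite differences in the
test suite), so the whole stack trains under plain NumPy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Protocol, Union

import numpy as np

from .data import Drug, Protein
from .nn import init_mlp, mlp_backward, mlp_forward, sigmoid

__all__ = [
    "TokenMatrix",
    "MissingEmbeddingError",
    "HashedEmbedder",
    "LookupEmbedder",
    "FileEmbedder",
    "make_embedder",
    "embed_entity",
    "init_afa_params",
    "init_mha_params",
    "afa_aggregate",
    "afa_backward",
    "mha_aggregate",
    "mha_backward",
    "aggregate",
    "aggregate_backward",
    "PairRepresentation",
    "EncoderConfig",
    "PairEncoder",
    "votes_from_activation",
    "residue_attribution",
]

logger = logging.getLogger(__name__)

DRUG_ALPHABET = "ABCDEFGHIJKLMNOP"  # 16 symbols, SMILES-like granularity
PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"  # the 20 amino acids
EXTRA_SYMBOLS = "X()=#+-.0123456789@/\\[]"  # tolerated in real SMILES/sequences


@dataclass(frozen=True)
class TokenMatrix:
    """A (T, d_in) matrix of per-token embedding vectors for one entity."""

    values: np.ndarray
    entity_id: str = ""

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] < 1:
            raise ValueError("token matrix must be 2-D with at least one token")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"token matrix for {self.entity_id!r} has non-finite entries")

    @property
    def T(self) -> int:
        return self.values.shape[0]

    @property
    def d_in(self) -> int:
        return self.values.shape[1]


class MissingEmbeddingError(KeyError):
    """The file embedder has no matrix for a requested entity id."""


class Embedder(Protocol):
    trainable: bool

    def embed(self, text: str, entity_id: str = "") -> TokenMatrix: ...


class HashedEmbedder:
    """Deterministic per-character vectors from a seeded hash (not trained).

    Every character maps to a fixed pseudo-random vector derived from
    ``(seed, ord(char))``, so identical strings always embed identically
    across processes -- the workhorse embedder for tests and synthetic
    benchmarks.
    """

    trainable = False

    def __init__(self, d_in: int = 16, seed: int = 0) -> None:
        self.d_in = d_in
        self.seed = seed
        self._cache: dict[str, np.ndarray] = {}

    def _vector(self, ch: str) -> np.ndarray:
        vec = self._cache.get(ch)
        if vec is None:
            rng = np.random.default_rng(np.random.SeedSequence([self.seed, ord(ch)]))
            vec = rng.normal(0.0, 1.0, size=self.d_in)
            self._cache[ch] = vec
        return vec

    def embed(self, text: str, entity_id: str = "") -> TokenMatrix:
        if not text:
            raise ValueError(f"cannot embed empty string for {entity_id!r}")
        return TokenMatrix(
            values=np.stack([self._vector(c) for c in text]), entity_id=entity_id
        )


class LookupEmbedder:
    """Trainable per-character embedding table over a fixed alphabet."""

    trainable = True

    def __init__(
        self,
        d_in: int = 16,
        seed: int = 0,
        alphabet: str = DRUG_ALPHABET + PROTEIN_ALPHABET + EXTRA_SYMBOLS,
    ) -> None:
        self.d_in = d_in
        self.alphabet = alphabet
        self.index = {c: i for i, c in enumerate(alphabet)}
        rng = np.random.default_rng(seed)
        self.table = rng.normal(0.0, 1.0, size=(len(alphabet), d_in))

    def token_ids(self, text: str) -> np.ndarray:
        try:
            return np.array([self.index[c] for c in text], dtype=np.int64)
        except KeyError as exc:
            raise ValueError(f"character {exc.args[0]!r} not in embedder alphabet") from exc

    def embed(self, text: str, entity_id: str = "") -> TokenMatrix:
        if not text:
            raise ValueError(f"cannot embed empty string for {entity_id!r}")
        return TokenMatrix(values=self.table[self.token_ids(text)], entity_id=entity_id)

    def accumulate_grad(self, text: str, dX: np.ndarray, grad_table: np.ndarray) -> None:
        np.add.at(grad_table, self.token_ids(text), dX)


class FileEmbedder:
    """Serves precomputed token matrices (e.g. from protein/molecule
    language models) loaded from an embedding archive."""

    trainable = False

    def __init__(self, archive: dict[str, np.ndarray]) -> None:
        self.archive = archive
        widths = {m.shape[1] for m in archive.values()}
        if len(widths) > 1:
            raise ValueError(f"inconsistent embedding widths in archive: {sorted(widths)}")
        self.d_in = widths.pop() if widths else 0

    def embed(self, text: str, entity_id: str = "") -> TokenMatrix:
        if entity_id not in self.archive:
            raise MissingEmbeddingError(entity_id)
        return TokenMatrix(values=self.archive[entity_id], entity_id=entity_id)


def make_embedder(kind: str, d_in: int = 16, seed: int = 0, archive=None) -> Embedder:
    if kind == "hashed":
        return HashedEmbedder(d_in=d_in, seed=seed)
    if kind == "lookup":
        return LookupEmbedder(d_in=d_in, seed=seed)
    if kind == "file":
        if archive is None:
            raise ValueError("file embedder needs an archive mapping")
        return FileEmbedder(archive)
    raise ValueError(f"unknown embedder kind {kind!r}")


def embed_entity(entity: Union[Drug, Protein], embedder: Embedder) -> TokenMatrix:
    """Character-tokenize an entity's string and embed it (T = string length)."""
    text = entity.smiles if isinstance(entity, Drug) else entity.sequence
    return embedder.embed(text, entity_id=entity.id)


# ---------------------------------------------------------------------------
# Aggregators
# ---------------------------------------------------------------------------


def init_afa_params(d_in: int, d: int, rng: np.random.Generator) -> dict:
    s = 1.0 / np.sqrt(d_in)
    return {
        "W_Q": rng.normal(0.0, s, size=(d_in, d)),
        "W_K": rng.normal(0.0, s, size=(d_in, d)),
        "W_V": rng.normal(0.0, s, size=(d_in, d)),
    }


def init_mha_params(
    d_in: int, d: int, n_heads: int, rng: np.random.Generator
) -> dict:
    if d % n_heads != 0:
        raise ValueError(f"d={d} not divisible by n_heads={n_heads}")
    d_k = d // n_heads
    s = 1.0 / np.sqrt(d_in)
    return {
        "W_Q": rng.normal(0.0, s, size=(n_heads, d_in, d_k)),
        "W_K": rng.normal(0.0, s, size=(n_heads, d_in, d_k)),
        "W_V": rng.normal(0.0, s, size=(n_heads, d_in, d_k)),
        "W_O": rng.normal(0.0, 1.0 / np.sqrt(n_heads * d_k), size=(n_heads * d_k, d)),
    }


def afa_aggregate(
    Xq: np.ndarray, Xc: np.ndarray, params: dict, return_cache: bool = False
):
    """Attention-free cross-aggregation, linear in the context length.

    Per dimension ``m``, the context tokens are softmax-weighted by their
    projected keys and averaged over their projected values; each query
    token then gates that shared context summary with a sigmoid of its
    projected query.
    """
    if Xq.shape[1] != params["W_Q"].shape[0] or Xc.shape[1] != params["W_K"].shape[0]:
        raise ValueError(
            f"input width {Xq.shape[1]}/{Xc.shape[1]} does not match "
            f"projection fan-in {params['W_Q'].shape[0]}"
        )
    Q0 = Xq @ params["W_Q"]  # (Tq, d)
    K0 = Xc @ params["W_K"]  # (Tc, d)
    V0 = Xc @ params["W_V"]  # (Tc, d)
    E = np.exp(K0 - K0.max(axis=0, keepdims=True))  # shift-invariant softmax
    S = E / E.sum(axis=0, keepdims=True)  # (Tc, d), columns sum to 1
    c = (S * V0).sum(axis=0)  # (d,) context summary per dimension
    G = sigmoid(Q0)  # (Tq, d)
    Y = G * c[None, :]
    if not return_cache:
        return Y
    return Y, {"Xq": Xq, "Xc": Xc, "Q0": Q0, "S": S, "V0": V0, "c": c, "G": G}


def afa_backward(dY: np.ndarray, cache: dict, params: dict):
    """Analytic gradients of :func:`afa_aggregate`."""
    G, c, S, V0 = cache["G"], cache["c"], cache["S"], cache["V0"]
    dG = dY * c[None, :]
    dc = (dY * G).sum(axis=0)  # (d,)
    dQ0 = dG * G * (1.0 - G)
    dV0 = S * dc[None, :]
    dS = V0 * dc[None, :]
    dK0 = S * (dS - (S * dS).sum(axis=0, keepdims=True))
    grads = {
        "W_Q": cache["Xq"].T @ dQ0,
        "W_K": cache["Xc"].T @ dK0,
        "W_V": cache["Xc"].T @ dV0,
    }
    dXq = dQ0 @ params["W_Q"].T
    dXc = dK0 @ params["W_K"].T + dV0 @ params["W_V"].T
    return grads, dXq, dXc


def mha_aggregate(
    Xq: np.ndarray, Xc: np.ndarray, params: dict, return_cache: bool = False
):
    """Standard multi-head scaled dot-product cross-attention (quadratic)."""
    if Xq.shape[1] != params["W_Q"].shape[1]:
        raise ValueError("input width does not match projection fan-in")
    d_k = params["W_Q"].shape[2]
    Q = np.einsum("ti,hik->htk", Xq, params["W_Q"])  # (H, Tq, d_k)
    K = np.einsum("ti,hik->htk", Xc, params["W_K"])  # (H, Tc, d_k)
    V = np.einsum("ti,hik->htk", Xc, params["W_V"])  # (H, Tc, d_k)
    scores = np.einsum("htk,hsk->hts", Q, K) / np.sqrt(d_k)  # (H, Tq, Tc)
    scores -= scores.max(axis=-1, keepdims=True)
    A = np.exp(scores)
    A /= A.sum(axis=-1, keepdims=True)  # row-stochastic per head
    O = np.einsum("hts,hsk->htk", A, V)  # (H, Tq, d_k)
    concat = O.transpose(1, 0, 2).reshape(Xq.shape[0], -1)  # (Tq, H*d_k)
    Y = concat @ params["W_O"]
    if not return_cache:
        return Y
    return Y, {"Xq": Xq, "Xc": Xc, "Q": Q, "K": K, "V": V, "A": A, "concat": concat}


def mha_backward(dY: np.ndarray, cache: dict, params: dict):
    Q, K, V, A = cache["Q"], cache["K"], cache["V"], cache["A"]
    H, Tq, d_k = Q.shape
    dW_O = cache["concat"].T @ dY
    dconcat = dY @ params["W_O"].T
    dO = dconcat.reshape(Tq, H, d_k).transpose(1, 0, 2)
    dA = np.einsum("htk,hsk->hts", dO, V)
    dV = np.einsum("hts,htk->hsk", A, dO)
    dscores = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
    dscores /= np.sqrt(d_k)
    dQ = np.einsum("hts,hsk->htk", dscores, K)
    dK = np.einsum("hts,htk->hsk", dscores, Q)
    grads = {
        "W_Q": np.einsum("ti,htk->hik", cache["Xq"], dQ),
        "W_K": np.einsum("ti,htk->hik", cache["Xc"], dK),
        "W_V": np.einsum("ti,htk->hik", cache["Xc"], dV),
        "W_O": dW_O,
    }
    dXq = np.einsum("htk,hik->ti", dQ, params["W_Q"])
    dXc = np.einsum("htk,hik->ti", dK, params["W_K"]) + np.einsum(
        "htk,hik->ti", dV, params["W_V"]
    )
    return grads, dXq, dXc


def aggregate(kind: str, Xq, Xc, params, return_cache: bool = False):
    if kind == "afa":
        return afa_aggregate(Xq, Xc, params, return_cache)
    if kind == "mha":
        return mha_aggregate(Xq, Xc, params, return_cache)
    raise ValueError(f"unknown aggregator {kind!r}")


def aggregate_backward(kind: str, dY, cache, params):
    return (afa_backward if kind == "afa" else mha_backward)(dY, cache, params)


# ---------------------------------------------------------------------------
# Pair encoder
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairRepresentation:
    drug_side: np.ndarray  # (d,) max-pooled cross-attended drug tokens
    protein_side: np.ndarray  # (d,)

    @property
    def concat(self) -> np.ndarray:
        return np.concatenate([self.drug_side, self.protein_side])


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture knobs of the twin encoder.

    ``d`` is the shared hidden width of the aggregated representations
    (256 by default, matching the dimension count used for residue
    voting); ``head_layers`` defaults to [2d, d, d/2, 1].
    """

    aggregator: str = "afa"
    d: int = 256
    d_in: int = 16
    n_heads: int = 4
    head_layers: Optional[tuple[int, ...]] = None
    dropout: float = 0.1
    embedder: str = "hashed"

    def __post_init__(self) -> None:
        if self.aggregator not in ("afa", "mha"):
            raise ValueError("aggregator must be 'afa' or 'mha'")
        if self.d < 1:
            raise ValueError("d must be >= 1")

    def head_plan(self) -> list[int]:
        if self.head_layers is not None:
            plan = list(self.head_layers)
            if plan[-1] != 1:
                raise ValueError("prediction head must end in width 1")
            return plan
        return [2 * self.d, self.d, max(self.d // 2, 1), 1]


class PairEncoder:
    """One scenario member: embedder + twin cross-aggregator + scalar head."""

    def __init__(self, cfg: EncoderConfig, seed: int = 0, embedder=None) -> None:
        self.cfg = cfg
        self.embedder = embedder or make_embedder(cfg.embedder, d_in=cfg.d_in, seed=seed)
        d_in = self.embedder.d_in
        rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
        if cfg.aggregator == "afa":
            agg_dq = init_afa_params(d_in, cfg.d, rng)
            agg_pq = init_afa_params(d_in, cfg.d, rng)
        else:
            agg_dq = init_mha_params(d_in, cfg.d, cfg.n_heads, rng)
            agg_pq = init_mha_params(d_in, cfg.d, cfg.n_heads, rng)
        self.params: dict = {
            "agg_dq": agg_dq,  # drug tokens query the protein context
            "agg_pq": agg_pq,  # protein tokens query the drug context
            "head": init_mlp(cfg.head_plan(), rng),
        }
        if getattr(self.embedder, "trainable", False):
            self.params["embed_table"] = self.embedder.table

    # -- forward -----------------------------------------------------------

    def tokenize(self, entity: Union[Drug, Protein]) -> TokenMatrix:
        return embed_entity(entity, self.embedder)

    def encode(
        self, drug: TokenMatrix, protein: TokenMatrix, return_cache: bool = False
    ):
        """Cross-aggregate both directions and max-pool token-wise."""
        kind = self.cfg.aggregator
        Yd, cache_d = aggregate(kind, drug.values, protein.values, self.params["agg_dq"], True)
        Yp, cache_p = aggregate(kind, protein.values, drug.values, self.params["agg_pq"], True)
        arg_d = Yd.argmax(axis=0)  # first index wins ties
        arg_p = Yp.argmax(axis=0)
        rep = PairRepresentation(
            drug_side=Yd[arg_d, np.arange(self.cfg.d)],
            protein_side=Yp[arg_p, np.arange(self.cfg.d)],
        )
        if not return_cache:
            return rep
        cache = {
            "cache_d": cache_d,
            "cache_p": cache_p,
            "arg_d": arg_d,
            "arg_p": arg_p,
            "Td": drug.T,
            "Tp": protein.T,
            "drug": drug,
            "protein": protein,
        }
        return rep, cache

    def head_forward(self, rep_vec: np.ndarray, train: bool = False, rng=None):
        drop = self.cfg.dropout if train else 0.0
        y, cache = mlp_forward(self.params["head"], rep_vec, dropout=drop, rng=rng)
        return float(y[0]), cache

    def predict_pair(self, drug: TokenMatrix, protein: TokenMatrix) -> float:
        rep = self.encode(drug, protein)
        y, _ = self.head_forward(rep.concat)
        return y

    # -- backward ----------------------------------------------------------

    def head_backward(self, head_cache: dict, dy: float):
        grads, drep = mlp_backward(self.params["head"], head_cache, np.array([dy]))
        return grads, drep

    def encoder_backward(self, cache: dict, drep: np.ndarray):
        """Backprop a gradient on the concatenated representation through the
        max-pool and both aggregation directions.

        Returns ``(grads, dX_drug, dX_protein)`` where ``grads`` matches the
        aggregator entries of ``self.params`` and the two ``dX`` terms are
        gradients w.r.t. the input token matrices (used to update a
        trainable lookup embedder).
        """
        d = self.cfg.d
        kind = self.cfg.aggregator
        dYd = np.zeros((cache["Td"], d))
        dYd[cache["arg_d"], np.arange(d)] = drep[:d]
        dYp = np.zeros((cache["Tp"], d))
        dYp[cache["arg_p"], np.arange(d)] = drep[d:]
        g_dq, dXd_q, dXp_c = aggregate_backward(kind, dYd, cache["cache_d"], self.params["agg_dq"])
        g_pq, dXp_q, dXd_c = aggregate_backward(kind, dYp, cache["cache_p"], self.params["agg_pq"])
        grads: dict = {"agg_dq": g_dq, "agg_pq": g_pq}
        return grads, dXd_q + dXd_c, dXp_q + dXp_c


# ---------------------------------------------------------------------------
# Residue attribution
# ---------------------------------------------------------------------------


def votes_from_activation(Yp: np.ndarray) -> np.ndarray:
    """Count, per residue, the dimensions in which it attains the max.

    ``Yp`` is the protein-side aggregated matrix (T_p, d).  Each of the d
    dimensions votes for the residue with the maximum activation (first
    index wins ties); the votes always sum to d.
    """
    winners = Yp.argmax(axis=0)
    return np.bincount(winners, minlength=Yp.shape[0])


def residue_attribution(
    model: PairEncoder, drug: TokenMatrix, protein: TokenMatrix, k: int
) -> list[tuple[int, int]]:
    """Rank protein residues by max-pool votes (1-based positions).

    Returns the top ``k`` (position, votes) tuples, ordered by vote count
    then by smaller position.  ``k`` is clamped to the protein length.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    Yp = aggregate(model.cfg.aggregator, protein.values, drug.values, model.params["agg_pq"])
    votes = votes_from_activation(Yp)
    if k > protein.T:
        logger.warning("k=%d exceeds protein length %d; clamping", k, protein.T)
        k = protein.T
    order = sorted(range(protein.T), key=lambda i: (-votes[i], i))
    return [(i + 1, int(votes[i])) for i in order[:k]]
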