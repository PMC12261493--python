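import logging
import math

import numpy as np
import pytest

from mixdta.data import Drug, Protein
from mixdta.encoder import (
    EncoderConfig,
    FileEmbedder,
    HashedEmbedder,
    LookupEmbedder,
    MissingEmbeddingError,
    PairEncoder,
    TokenMatrix,
    afa_aggregate,
    embed_entity,
    init_afa_params,
    init_mha_params,
    mha_aggregate,
    residue_attribution,
    votes_from_activation,
)

# ---------------------------------------------------------------------------
# Independent scalar-loop oracles (kept deliberately naive)
# ---------------------------------------------------------------------------


def afa_reference(Xq, Xc, params, count_ops=False):
    """Per-dimension scalar-loop implementation of the attention-free
    aggregation formula: sigmoid-gated, exp(K)-weighted value average."""
    Q0 = Xq @ params["W_Q"]
    K0 = Xc @ params["W_K"]
    V0 = Xc @ params["W_V"]
    Tq, d = Q0.shape
    Tc = K0.shape[0]
    ops = 0
    ctx = np.zeros(d)
    for m in range(d):
        num = den = 0.0
        for tp in range(Tc):
            e = math.exp(K0[tp, m])
            num += e * V0[tp, m]
            den += e
            ops += 2
        ctx[m] = num / den
    Y = np.zeros((Tq, d))
    for t in range(Tq):
        for m in range(d):
            Y[t, m] = 1.0 / (1.0 + math.exp(-Q0[t, m])) * ctx[m]
            ops += 1
    return (Y, ops) if count_ops else Y


def mha_reference_single_head(Xq, Xc, count_ops=False):
    """Hand-computed softmax(Q K^T / sqrt(d)) V with identity projections."""
    d = Xq.shape[1]
    ops = 0
    Y = np.zeros((Xq.shape[0], d))
    for t in range(Xq.shape[0]):
        scores = np.zeros(Xc.shape[0])
        for s in range(Xc.shape[0]):
            scores[s] = float(Xq[t] @ Xc[s]) / math.sqrt(d)
            ops += d
        w = np.exp(scores - scores.max())
        w /= w.sum()
        for s in range(Xc.shape[0]):
            Y[t] += w[s] * Xc[s]
            ops += d
    return (Y, ops) if count_ops else Y


def random_instance(rng, Tq, Tc, d_in, d):
    Xq = rng.normal(size=(Tq, d_in))
    Xc = rng.normal(size=(Tc, d_in))
    params = init_afa_params(d_in, d, rng)
    return Xq, Xc, params


# ---------------------------------------------------------------------------
# AFA
# ---------------------------------------------------------------------------


class TestAFA:
    def test_vectorized_matches_scalar_oracle_on_100_instances(self):
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(100):
            Tq, Tc = rng.integers(1, 9, size=2)
            d_in, d = int(rng.integers(2, 7)), int(rng.integers(2, 7))
            Xq, Xc, params = random_instance(rng, Tq, Tc, d_in, d)
            err = np.max(np.abs(afa_aggregate(Xq, Xc, params) - afa_reference(Xq, Xc, params)))
            worst = max(worst, err)
        assert worst < 1e-6

    def test_identity_projection_instance_matches_printed_formula(self):
        rng = np.random.default_rng(1)
        Xq, Xc = rng.normal(size=(3, 4)), rng.normal(size=(3, 4))
        eye = {"W_Q": np.eye(4), "W_K": np.eye(4), "W_V": np.eye(4)}
        assert np.allclose(afa_aggregate(Xq, Xc, eye), afa_reference(Xq, Xc, eye), atol=1e-10)

    def test_single_context_token_identity(self):
        rng = np.random.default_rng(2)
        Xq, Xc, params = random_instance(rng, 4, 1, 5, 3)
        Q0 = Xq @ params["W_Q"]
        V0 = Xc @ params["W_V"]
        expected = 1.0 / (1.0 + np.exp(-Q0)) * V0[0][None, :]
        assert np.allclose(afa_aggregate(Xq, Xc, params), expected, atol=1e-12)

    def test_constant_keys_give_column_mean_of_values(self):
        rng = np.random.default_rng(3)
        Xq = rng.normal(size=(3, 4))
        Xc = rng.normal(size=(5, 4))
        params = init_afa_params(4, 3, rng)
        params = {**params, "W_K": np.zeros((4, 3))}  # K0 constant (zero)
        Q0 = Xq @ params["W_Q"]
        V0 = Xc @ params["W_V"]
        expected = 1.0 / (1.0 + np.exp(-Q0)) * V0.mean(axis=0)[None, :]
        assert np.allclose(afa_aggregate(Xq, Xc, params), expected, atol=1e-12)

    def test_shift_invariance_of_keys(self):
        # a constant input feature lets us shift every K0 column uniformly
        rng = np.random.default_rng(4)
        Tc, d_in, d = 6, 4, 3
        Xq = rng.normal(size=(2, d_in))
        Xc = np.hstack([rng.normal(size=(Tc, d_in - 1)), np.ones((Tc, 1))])
        params = init_afa_params(d_in, d, rng)
        shifted = {k: v.copy() for k, v in params.items()}
        shifted["W_K"] = shifted["W_K"].copy()
        shifted["W_K"][-1, :] += rng.normal(scale=50.0, size=d)
        a = afa_aggregate(Xq, Xc, params)
        b = afa_aggregate(Xq, Xc, shifted)
        assert np.allclose(a, b, atol=1e-6)

    def test_output_is_gated_convex_combination_of_values(self):
        rng = np.random.default_rng(5)
        Xq, Xc, params = random_instance(rng, 3, 7, 4, 4)
        Y = afa_aggregate(Xq, Xc, params)
        G = 1.0 / (1.0 + np.exp(-(Xq @ params["W_Q"])))
        V0 = Xc @ params["W_V"]
        ctx = Y / G  # rows identical: the per-dimension context summary
        for m in range(4):
            assert V0[:, m].min() - 1e-9 <= ctx[0, m] <= V0[:, m].max() + 1e-9

    def test_dimension_mismatch_rejected(self):
        rng = np.random.default_rng(6)
        Xq, Xc, params = random_instance(rng, 2, 2, 4, 3)
        with pytest.raises(ValueError):
            afa_aggregate(Xq[:, :3], Xc, params)

    def test_no_overflow_for_extreme_keys(self):
        rng = np.random.default_rng(7)
        Xq, Xc, params = random_instance(rng, 2, 4, 3, 2)
        Y = afa_aggregate(Xq, Xc * 1e3, params)
        assert np.all(np.isfinite(Y))


# ---------------------------------------------------------------------------
# MHA
# ---------------------------------------------------------------------------


class TestMHA:
    def test_single_head_identity_matches_hand_computation(self):
        rng = np.random.default_rng(8)
        d = 4
        Xq, Xc = rng.normal(size=(3, d)), rng.normal(size=(2, d))
        params = {
            "W_Q": np.eye(d)[None],
            "W_K": np.eye(d)[None],
            "W_V": np.eye(d)[None],
            "W_O": np.eye(d),
        }
        assert np.allclose(
            mha_aggregate(Xq, Xc, params), mha_reference_single_head(Xq, Xc), atol=1e-10
        )

    def test_constant_values_make_attention_irrelevant(self):
        rng = np.random.default_rng(9)
        d_in, d, H = 4, 6, 2
        params = init_mha_params(d_in, d, H, rng)
        Xq = rng.normal(size=(3, d_in))
        xc_row = rng.normal(size=d_in)
        Xc = np.tile(xc_row, (5, 1))
        Y = mha_aggregate(Xq, Xc, params)
        v = np.concatenate([xc_row @ params["W_V"][h] for h in range(H)])
        assert np.allclose(Y, np.tile(v @ params["W_O"], (3, 1)), atol=1e-10)

    def test_attention_weights_are_row_stochastic(self):
        rng = np.random.default_rng(10)
        params = init_mha_params(4, 6, 3, rng)
        _, cache = mha_aggregate(rng.normal(size=(3, 4)), rng.normal(size=(5, 4)), params, True)
        assert np.allclose(cache["A"].sum(axis=-1), 1.0, atol=1e-12)

    def test_head_count_must_divide_width(self):
        with pytest.raises(ValueError):
            init_mha_params(4, 5, 2, np.random.default_rng(0))


def test_afa_work_grows_linearly_and_mha_quadratically_in_token_count():
    rng = np.random.default_rng(11)
    d_in = d = 4
    counts = {}
    for T in (8, 16):
        Xq, Xc, params = random_instance(rng, T, T, d_in, d)
        _, afa_ops = afa_reference(Xq, Xc, params, count_ops=True)
        _, mha_ops = mha_reference_single_head(Xq, Xc, count_ops=True)
        counts[T] = (afa_ops, mha_ops)
    afa_ratio = counts[16][0] / counts[8][0]
    mha_ratio = counts[16][1] / counts[8][1]
    assert afa_ratio < 2.5  # ~T scaling
    assert mha_ratio > 3.5  # ~T^2 scaling


# ---------------------------------------------------------------------------
# Embedders and cross-encoding
# ---------------------------------------------------------------------------


class TestEmbedders:
    def test_hashed_embedder_is_deterministic_and_character_level(self):
        e1, e2 = HashedEmbedder(d_in=8, seed=3), HashedEmbedder(d_in=8, seed=3)
        a, b = e1.embed("MKVLITA"), e2.embed("MKVLITA")
        assert a.T == 7 and a.d_in == 8
        assert np.array_equal(a.values, b.values)
        assert not np.array_equal(
            a.values, HashedEmbedder(d_in=8, seed=4).embed("MKVLITA").values
        )

    def test_lookup_embedder_rows_come_from_table(self):
        e = LookupEmbedder(d_in=4, seed=0, alphabet="ACGT")
        tm = e.embed("GATA")
        assert np.array_equal(tm.values, e.table[[2, 0, 3, 0]])
        with pytest.raises(ValueError):
            e.embed("Z")

    def test_file_embedder_round_trip_and_missing_id(self, tmp_path):
        from mixdta.data import read_embedding_archive, write_embedding_archive

        mats = {"P1": np.arange(12.0).reshape(3, 4) + 1.0}
        path = tmp_path / "a.h5"
        write_embedding_archive(path, mats)
        emb = FileEmbedder(read_embedding_archive(path))
        tm = embed_entity(Protein(id="P1", sequence="MKV"), emb)
        assert np.array_equal(tm.values, mats["P1"])
        with pytest.raises(MissingEmbeddingError):
            embed_entity(Drug(id="D9", smiles="CC"), emb)


class TestCrossEncode:
    def cfgmodel(self, aggregator="afa", d=6):
        cfg = EncoderConfig(aggregator=aggregator, d=d, d_in=8, n_heads=2, dropout=0.0)
        return PairEncoder(cfg, seed=0)

    def test_representation_length_is_2d(self):
        model = self.cfgmodel()
        d_tm = model.embedder.embed("ABBA")
        p_tm = model.embedder.embed("MKVLIT")
        rep = model.encode(d_tm, p_tm)
        assert rep.concat.shape == (12,)
        assert np.array_equal(rep.concat[:6], rep.drug_side)
        assert np.array_equal(rep.concat[6:], rep.protein_side)

    @pytest.mark.parametrize("aggregator", ["afa", "mha"])
    def test_token_order_invariance(self, aggregator):
        model = self.cfgmodel(aggregator)
        rng = np.random.default_rng(12)
        d_tm = model.embedder.embed("ABCDAB")
        p_tm = model.embedder.embed("MKVLITMM")
        rep = model.encode(d_tm, p_tm)
        for _ in range(3):
            dp = TokenMatrix(d_tm.values[rng.permutation(d_tm.T)])
            pp = TokenMatrix(p_tm.values[rng.permutation(p_tm.T)])
            rep2 = model.encode(dp, pp)
            assert np.allclose(rep.concat, rep2.concat, atol=1e-10)

    def test_single_token_pair_reduces_to_gated_value(self):
        model = self.cfgmodel()
        d_tm = model.embedder.embed("A")
        p_tm = model.embedder.embed("M")
        rep = model.encode(d_tm, p_tm)
        p = model.params["agg_dq"]
        expected = (1 / (1 + np.exp(-(d_tm.values @ p["W_Q"])))) * (p_tm.values @ p["W_V"])
        assert np.allclose(rep.drug_side, expected[0], atol=1e-12)

    def test_head_is_deterministic_and_finite(self):
        model = self.cfgmodel()
        d_tm = model.embedder.embed("ABAB")
        p_tm = model.embedder.embed("MKVL")
        y1 = model.predict_pair(d_tm, p_tm)
        y2 = model.predict_pair(d_tm, p_tm)
        assert y1 == y2 and np.isfinite(y1)

    def test_zero_weight_head_outputs_its_bias(self):
        model = self.cfgmodel()
        for layer in model.params["head"]:
            layer["W"][...] = 0.0
            layer["b"][...] = 0.0
        model.params["head"][-1]["b"][0] = 3.25
        rep = model.encode(model.embedder.embed("AB"), model.embedder.embed("MK"))
        y, _ = model.head_forward(rep.concat)
        assert y == pytest.approx(3.25)


# ---------------------------------------------------------------------------
# Residue attribution
# ---------------------------------------------------------------------------


class TestResidueAttribution:
    def test_constructed_two_residue_vote_split(self):
        # residue 1 wins dimensions {1,2}; residue 2 wins dimension {3}
        Yp = np.array([[0.9, 0.8, 0.1], [0.5, 0.2, 0.6]])
        votes = votes_from_activation(Yp)
        assert votes.tolist() == [2, 1]

    def test_first_index_wins_ties(self):
        Yp = np.array([[1.0, 2.0], [1.0, 2.0]])
        assert votes_from_activation(Yp).tolist() == [2, 0]

    def test_single_residue_takes_all_votes(self):
        cfg = EncoderConfig(d=5, d_in=8, dropout=0.0)
        model = PairEncoder(cfg, seed=1)
        ranked = residue_attribution(
            model, model.embedder.embed("ABBA"), model.embedder.embed("M"), k=1
        )
        assert ranked == [(1, 5)]

    def test_votes_sum_to_d_and_positions_are_one_based(self):
        cfg = EncoderConfig(d=16, d_in=8, dropout=0.0)
        model = PairEncoder(cfg, seed=2)
        ranked = residue_attribution(
            model, model.embedder.embed("ABAB"), model.embedder.embed("MKVLITAE"), k=8
        )
        assert sum(v for _, v in ranked) == 16
        assert all(1 <= pos <= 8 for pos, _ in ranked)
        votes = [v for _, v in ranked]
        assert votes == sorted(votes, reverse=True)

    def test_k_clamped_with_warning(self, caplog):
        cfg = EncoderConfig(d=4, d_in=8, dropout=0.0)
        model = PairEncoder(cfg, seed=3)
        with caplog.at_level(logging.WARNING, logger="mixdta.encoder"):
            ranked = residue_attribution(
                model, model.embedder.embed("AB"), model.embedder.embed("MKV"), k=10
            )
        assert len(ranked) == 3
        assert any("clamping" in r.message for r in caplog.records)
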