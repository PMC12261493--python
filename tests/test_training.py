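import numpy as np
import pytest

from mixdta.encoder import EncoderConfig, PairEncoder
from mixdta.gba import GBAConfig, SCENARIO_ORDER, Scenario, build_neighbor_index
from mixdta.mixup import MixupConfig
from mixdta.nn import params_checksum
from mixdta.splitting import make_folds
from mixdta.synthgen import SynthConfig, generate_dataset
from mixdta.training import (
    TrainConfig,
    TrainedEnsemble,
    extract_meta_features,
    predict,
    predict_member,
    train_meta,
    train_scenario,
    training_stream,
)

SMALL_SYNTH = SynthConfig(n_drugs=8, n_proteins=6, density=0.6, seed=0)
SMALL_ENC = EncoderConfig(d=8, d_in=8, dropout=0.0, head_layers=(16, 8, 1))


def small_setup(seed=0):
    ds, _ = generate_dataset(SynthConfig(n_drugs=8, n_proteins=6, density=0.6, seed=seed))
    fold = make_folds(ds, n_folds=1, seed=seed).folds[0]
    return ds, fold


def quick_cfg(seed=0, scenario=Scenario.NONE, epochs=10):
    return TrainConfig(
        epochs=epochs, batch_size=8, learning_rate=2e-3, patience=epochs, seed=seed, scenario=scenario
    )


class TestTrainScenario:
    def test_loss_decreases_without_augmentation(self):
        ds, fold = small_setup()
        member = train_scenario(ds, fold, quick_cfg(epochs=12), SMALL_ENC)
        assert member.history[-1]["train_mse"] < member.history[0]["train_mse"]

    def test_identical_config_reproduces_loss_trajectory(self):
        ds, fold = small_setup()
        cfg = quick_cfg(seed=3, scenario=Scenario.DRUG, epochs=6)
        a = train_scenario(ds, fold, cfg, SMALL_ENC)
        b = train_scenario(ds, fold, cfg, SMALL_ENC)
        assert [h["valid_mse"] for h in a.history] == [h["valid_mse"] for h in b.history]

    def test_training_never_touches_test_block(self):
        ds, fold = small_setup()
        for scenario in (Scenario.NONE, Scenario.PROTEIN_OR_DRUG, Scenario.COMPLEMENT):
            member = train_scenario(ds, fold, quick_cfg(scenario=scenario, epochs=4), SMALL_ENC)
            assert not member.used_pair_indices & set(fold.test.tolist())

    @pytest.mark.parametrize("aggregator", ["afa", "mha"])
    def test_loop_is_architecture_agnostic(self, aggregator):
        ds, fold = small_setup()
        enc = EncoderConfig(aggregator=aggregator, d=8, d_in=8, dropout=0.0, head_layers=(16, 8, 1))
        member = train_scenario(ds, fold, quick_cfg(scenario=Scenario.DRUG, epochs=8), enc)
        assert member.history[-1]["train_mse"] < member.history[0]["train_mse"]

    def test_empty_train_block_rejected(self):
        ds, fold = small_setup()
        from mixdta.splitting import Fold

        bad = Fold(train=np.array([], dtype=np.int64), valid=fold.valid, test=fold.test)
        with pytest.raises(ValueError):
            train_scenario(ds, bad, quick_cfg(), SMALL_ENC)


class TestTrainingStream:
    def test_none_stream_is_bitwise_plain(self):
        ds, fold = small_setup()
        rng = np.random.default_rng(0)
        plan = training_stream(fold.train, None, Scenario.NONE, MixupConfig(), GBAConfig(), rng)
        assert plan == [(int(i), None, 1.0) for i in fold.train]

    def test_augmented_stream_stays_in_train_block(self):
        ds, fold = small_setup()
        idx = build_neighbor_index(ds, fold.train, Scenario.ALL_PAIR)
        rng = np.random.default_rng(1)
        plan = training_stream(fold.train, idx, Scenario.ALL_PAIR, MixupConfig(), GBAConfig(), rng)
        train = set(fold.train.tolist())
        for i, j, lam in plan:
            assert i in train and (j is None or j in train)
            assert 0.0 <= lam <= 1.0


def make_members(ds, fold, epochs=8, seed=0):
    members = {}
    for s in SCENARIO_ORDER:
        members[s] = train_scenario(
            ds, fold, quick_cfg(seed=seed, scenario=s, epochs=epochs), SMALL_ENC
        ).model
    return members


class TestMetaStage:
    def test_members_frozen_bitwise_during_meta_training(self):
        ds, fold = small_setup()
        members = make_members(ds, fold, epochs=3)
        sums = {s: params_checksum(m.params) for s, m in members.items()}
        train_meta(members, ds, fold, quick_cfg(epochs=5), SMALL_ENC)
        assert all(params_checksum(members[s].params) == sums[s] for s in members)

    def test_fused_embedding_is_sum_of_member_representations(self):
        ds, fold = small_setup()
        model = PairEncoder(SMALL_ENC, seed=0)
        members = {s: model for s in SCENARIO_ORDER}  # six identical members
        p = ds.pairs[0]
        d_tm = model.tokenize(ds.drugs[p.drug_id])
        p_tm = model.tokenize(ds.proteins[p.protein_id])
        feat = extract_meta_features(members, d_tm, p_tm)
        single = model.encode(d_tm, p_tm).concat
        assert np.allclose(feat.fused_embedding, 6 * single, atol=1e-12)
        assert feat.fused_embedding.shape == (2 * SMALL_ENC.d,)
        assert np.allclose(feat.member_predictions, feat.member_predictions[0])

    def test_meta_tracks_the_informative_member(self):
        # one properly trained member and five untrained ones: the stacked
        # predictor must not be dragged far below the best member
        ds, fold = small_setup()
        good = train_scenario(ds, fold, quick_cfg(epochs=25), SMALL_ENC).model
        members = {s: PairEncoder(SMALL_ENC, seed=100 + k) for k, s in enumerate(SCENARIO_ORDER)}
        members[Scenario.NONE] = good
        y = ds.labels()
        member_valid = min(
            float(np.mean((predict_member(m, ds, fold.valid) - y[fold.valid]) ** 2))
            for m in members.values()
        )
        ens = train_meta(members, ds, fold, quick_cfg(epochs=150), SMALL_ENC)
        pairs = [
            (ds.drugs[ds.pairs[int(i)].drug_id], ds.proteins[ds.pairs[int(i)].protein_id])
            for i in fold.valid
        ]
        meta_valid = float(np.mean((predict(ens, pairs) - y[fold.valid]) ** 2))
        assert meta_valid <= member_valid + 0.5

    def test_identity_configured_meta_reduces_to_member_prediction(self):
        ds, fold = small_setup()
        model = train_scenario(ds, fold, quick_cfg(epochs=5), SMALL_ENC).model
        members = {s: model for s in SCENARIO_ORDER}
        ens = train_meta(members, ds, fold, quick_cfg(epochs=1), SMALL_ENC)
        # identity configuration: no learned correction
        for layer in ens.meta:
            layer["W"][...] = 0.0
            layer["b"][...] = 0.0
        p = ds.pairs[int(fold.test[0])]
        drug, protein = ds.drugs[p.drug_id], ds.proteins[p.protein_id]
        yhat = predict(ens, [(drug, protein)])[0]
        direct = model.predict_pair(model.tokenize(drug), model.tokenize(protein))
        assert yhat == pytest.approx(direct, abs=1e-9)

    def test_ensemble_requires_all_six_members(self):
        model = PairEncoder(SMALL_ENC, seed=0)
        with pytest.raises(ValueError, match="six"):
            TrainedEnsemble(
                members={Scenario.NONE: model},
                meta=[],
                encoder_cfg=SMALL_ENC,
                embedder=model.embedder,
            )

    def test_predictions_are_deterministic_and_sized(self):
        ds, fold = small_setup()
        members = make_members(ds, fold, epochs=3)
        ens = train_meta(members, ds, fold, quick_cfg(epochs=3), SMALL_ENC)
        pairs = [
            (ds.drugs[ds.pairs[int(i)].drug_id], ds.proteins[ds.pairs[int(i)].protein_id])
            for i in fold.test
        ]
        a, b = predict(ens, pairs), predict(ens, pairs)
        assert a.shape == (fold.test.size,)
        assert np.array_equal(a, b)
        assert np.all(np.isfinite(a))
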