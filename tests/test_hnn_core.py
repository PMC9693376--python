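"""Architecture contracts, training behaviour, persistence of the hybrid model."""

import dataclasses

import numpy as np
import pytest

from hnnaffinity import (
    HnnConfig,
    SyntheticSpec,
    affinity_config,
    build_model,
    denovo_config,
    generate,
    load_model,
    predict,
    save_model,
    train_model,
)
from hnnaffinity.featurize import encode_batch, labels_of

TINY = dict(L=48, M=32, D=12, fcnn_hidden=[16, 8], merge_hidden=8,
            max_epochs=4, early_stopping_patience=2, batch_size=32)


def _tiny_data(n=60, seed=0, D=12):
    spec = SyntheticSpec(n=n, seed=seed, descriptor_width=D,
                         n_active_descriptors=3, beta=(0.8, -0.6, 0.5),
                         smiles_len_range=(8, 40), seq_len_range=(8, 30))
    records, _ = generate(spec)
    batch = encode_batch(records, L=48, M=32, D=D)
    return batch, labels_of(records)


class TestConfig:
    def test_defaults_match_published_architecture(self):
        c = HnnConfig()
        assert (c.L, c.M, c.D) == (325, 150, 348)
        assert c.smiles_embed_dim == 100 and c.seq_embed_dim == 20
        assert c.kernel_size == 3

    def test_variant_helpers(self):
        assert denovo_config().use_descriptor_branch
        assert not affinity_config().use_descriptor_branch

    @pytest.mark.parametrize("field,value", [
        ("conv_filters", 64), ("dropout_rate", 0.25), ("l2_lambda", 0.5),
        ("conv_padding", "causal"), ("n_conv_layers", 3),
    ])
    def test_out_of_domain_rejected(self, field, value):
        cfg = dataclasses.replace(HnnConfig(), **{field: value})
        with pytest.raises(ValueError):
            cfg.validate()

    def test_all_branches_off_rejected(self):
        cfg = HnnConfig(use_smiles_branch=False, use_sequence_branch=False,
                        use_descriptor_branch=False)
        with pytest.raises(ValueError, match="branch"):
            cfg.validate()


class TestBuildAndShapes:
    def test_denovo_has_three_inputs(self):
        model = build_model(denovo_config(**TINY))
        assert set(model.branches) == {"smiles", "sequence", "descriptors"}

    def test_affinity_has_two_inputs(self):
        model = build_model(affinity_config(**TINY))
        assert set(model.branches) == {"smiles", "sequence"}

    @pytest.mark.parametrize("K", [0, 1, 7])
    def test_output_count_equals_K(self, K):
        model = build_model(denovo_config(**TINY))
        batch = {
            "smiles": np.zeros((K, 48), dtype=np.int32),
            "sequence": np.zeros((K, 32), dtype=np.int32),
            "descriptors": np.zeros((K, 12), dtype=np.float32),
        }
        preds = model.predict(batch)
        assert preds.shape == (K,)
        assert np.all(np.isfinite(preds))

    def test_disabled_branch_input_rejected(self):
        model = build_model(affinity_config(**TINY))
        with pytest.raises(ValueError, match="disabled"):
            model.predict({"smiles": np.zeros((2, 48), dtype=np.int32),
                           "sequence": np.zeros((2, 32), dtype=np.int32),
                           "descriptors": np.zeros((2, 12), dtype=np.float32)})

    def test_wrong_length_rejected(self):
        model = build_model(denovo_config(**TINY))
        with pytest.raises(ValueError, match="shape"):
            model.predict({"smiles": np.zeros((2, 47), dtype=np.int32),
                           "sequence": np.zeros((2, 32), dtype=np.int32),
                           "descriptors": np.zeros((2, 12), dtype=np.float32)})


class TestTraining:
    def test_loss_decreases_on_learnable_signal(self):
        batch, y = _tiny_data(n=200)
        cfg = denovo_config(**{**TINY, "max_epochs": 8}, seed=1)
        trained = train_model(build_model(cfg), batch, y)
        losses = trained.history["train_loss"]
        assert losses[-1] < losses[0]

    def test_identical_seed_identical_history_and_predictions(self):
        batch, y = _tiny_data(n=80)
        cfg = denovo_config(**TINY, seed=5)
        t1 = train_model(build_model(cfg), batch, y)
        t2 = train_model(build_model(cfg), batch, y)
        assert t1.history == t2.history
        np.testing.assert_array_equal(predict(t1, batch), predict(t2, batch))

    def test_different_seeds_differ(self):
        batch, y = _tiny_data(n=80)
        t1 = train_model(build_model(denovo_config(**TINY, seed=1)), batch, y)
        t2 = train_model(build_model(denovo_config(**TINY, seed=2)), batch, y)
        assert t1.history["train_loss"] != t2.history["train_loss"]

    def test_nonfinite_labels_rejected_before_training(self):
        batch, y = _tiny_data(n=30)
        y[3] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            train_model(build_model(denovo_config(**TINY)), batch, y)

    def test_small_dataset_clamps_batch_size_with_warning(self):
        batch, y = _tiny_data(n=20)
        cfg = denovo_config(**{**TINY, "batch_size": 64, "max_epochs": 1})
        with pytest.warns(UserWarning, match="clamped"):
            train_model(build_model(cfg), batch, y)


@pytest.fixture(scope="module")
def trained():
    batch, y = _tiny_data(n=120)
    model = train_model(build_model(denovo_config(**TINY, seed=3)), batch, y)
    return model, batch


class TestPredictContracts:

    def test_permutation_equivariance(self, trained):
        model, batch = trained
        base = predict(model, batch)
        perm = np.random.default_rng(0).permutation(batch.K)
        np.testing.assert_allclose(predict(model, batch.subset(perm)),
                                   base[perm], atol=1e-6)

    def test_duplicated_row_duplicates_prediction(self, trained):
        model, batch = trained
        dup = batch.subset([0, 0, 5])
        preds = predict(model, dup)
        assert preds[0] == pytest.approx(preds[1], abs=1e-7)


class TestRegularization:
    def test_l2_does_not_widen_generalisation_gap(self):
        """Average train/val-loss gap at l2=0.01 <= gap at l2=0.0001."""
        batch, y = _tiny_data(n=150, seed=9)
        gaps = {}
        for l2 in (0.0001, 0.01):
            gap = []
            for seed in range(3):
                cfg = denovo_config(**{**TINY, "max_epochs": 6}, seed=seed,
                                    l2_lambda=l2)
                t = train_model(build_model(cfg), batch, y)
                gap.append(t.history["val_loss"][-1]
                           - t.history["train_loss"][-1])
            gaps[l2] = np.mean(gap)
        assert gaps[0.01] <= gaps[0.0001] + 0.05


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path):
        batch, y = _tiny_data(n=60)
        trained = train_model(build_model(denovo_config(**TINY, seed=2)),
                              batch, y)
        save_model(trained, tmp_path / "m")
        loaded = load_model(tmp_path / "m")
        np.testing.assert_allclose(predict(loaded, batch),
                                   predict(trained, batch), atol=1e-6)
        assert loaded.config == trained.config
        assert loaded.provenance == trained.provenance

    def test_truncated_weights_error(self, tmp_path):
        batch, y = _tiny_data(n=40)
        trained = train_model(build_model(denovo_config(**TINY)), batch, y)
        save_model(trained, tmp_path / "m")
        weights = tmp_path / "m" / "weights.npz"
        weights.write_bytes(weights.read_bytes()[:100])
        with pytest.raises(ValueError, match="corrupt"):
            load_model(tmp_path / "m")

    def test_version_mismatch_error(self, tmp_path):
        batch, y = _tiny_data(n=40)
        trained = train_model(build_model(denovo_config(**TINY)), batch, y)
        save_model(trained, tmp_path / "m")
        prov = tmp_path / "m" / "provenance.json"
        prov.write_text(prov.read_text().replace(
            '"artifact_version": 1', '"artifact_version": 99'))
        with pytest.raises(ValueError, match="version"):
            load_model(tmp_path / "m")
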