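"""Architecture contracts, backprop correctness, and training behaviour."""

import dataclasses

import numpy as np
import pytest

from twincnn.gdsc_io import denormalize_ic50
from twincnn.model import (BranchConfig, HeadConfig, TableTensors, TrainConfig,
                           TwinCNN, branch_output_dim, load_model,
                           prepare_tensors, predict, save_model, train)
from twincnn.model import _Branch
from twincnn.splits import pair_split

SMALL_BRANCH = BranchConfig(conv_widths=(3,), conv_strides=(1,), channels=(4,),
                            pool_widths=(2,), pool_strides=(2,))
SMALL_HEAD = HeadConfig(hidden_sizes=(8,), dropout=0.0)


def _random_branch_config(rng):
    n_layers = int(rng.integers(1, 4))
    return BranchConfig(
        conv_widths=tuple(int(v) for v in rng.integers(2, 8, n_layers)),
        conv_strides=tuple(int(v) for v in rng.integers(1, 4, n_layers)),
        channels=tuple(int(v) for v in rng.integers(2, 6, n_layers)),
        pool_widths=tuple(int(v) for v in rng.integers(2, 4, n_layers)),
        pool_strides=tuple(int(v) for v in rng.integers(2, 4, n_layers)),
        padding_mode=["same", "valid"][int(rng.integers(0, 2))],
    )


class TestBranchOutputDim:
    def test_printed_embedding_widths(self):
        assert branch_output_dim(188) == 420
        assert branch_output_dim(735) == 1680

    def test_single_layer_arithmetic(self):
        cfg = BranchConfig(conv_widths=(7,), conv_strides=(1,), channels=(5,),
                           pool_widths=(3,), pool_strides=(3,))
        assert branch_output_dim(3, cfg) == 1 * 5

    def test_agrees_with_actual_forward_pass(self):
        """The dimension formula must match a real forward through the layers."""
        rng = np.random.default_rng(0)
        checked = 0
        while checked < 100:
            cfg = _random_branch_config(rng)
            input_len = int(rng.integers(4, 64))
            n_ch = int(rng.integers(1, 5))
            try:
                expected = branch_output_dim(input_len, cfg)
            except ValueError:
                continue  # stack collapses the sequence; nothing to compare
            branch = _Branch(n_ch, cfg, np.random.default_rng(1), np.float64)
            out = branch.forward(rng.standard_normal((2, n_ch, input_len)))
            assert out.shape == (2, expected)
            checked += 1

    def test_collapse_under_valid_padding_raises(self):
        cfg = dataclasses.replace(BranchConfig(), padding_mode="valid")
        with pytest.raises(ValueError):
            branch_output_dim(4, cfg)


class TestModelConstruction:
    def test_default_head_input_dimension(self):
        model = TwinCNN(72, 188, 735, seed=0)
        assert model.drug_dim + model.cell_dim == 420 + 1680
        assert model.head[0].W.value.shape[0] == 2100

    def test_forward_range_and_shape(self):
        model = TwinCNN(6, 12, 9, drug_cfg=SMALL_BRANCH, cell_cfg=SMALL_BRANCH,
                        head_cfg=SMALL_HEAD, seed=0)
        rng = np.random.default_rng(0)
        preds = model.forward((rng.random((4, 6, 12)) < 0.2).astype(np.float32),
                              (rng.random((4, 1, 9)) < 0.4).astype(np.float32))
        assert preds.shape == (4,)
        assert ((preds > 0) & (preds < 1)).all()

    def test_same_seed_same_initial_predictions(self):
        rng = np.random.default_rng(1)
        xd = rng.random((3, 6, 12)).astype(np.float32)
        xc = rng.random((3, 1, 9)).astype(np.float32)
        args = dict(drug_cfg=SMALL_BRANCH, cell_cfg=SMALL_BRANCH,
                    head_cfg=SMALL_HEAD, seed=5)
        np.testing.assert_array_equal(TwinCNN(6, 12, 9, **args).forward(xd, xc),
                                      TwinCNN(6, 12, 9, **args).forward(xd, xc))

    def test_incompatible_shapes_rejected(self):
        model = TwinCNN(6, 12, 9, drug_cfg=SMALL_BRANCH, cell_cfg=SMALL_BRANCH,
                        head_cfg=SMALL_HEAD, seed=0)
        with pytest.raises(ValueError):
            model.forward(np.zeros((2, 5, 12)), np.zeros((2, 1, 9)))
        with pytest.raises(ValueError):
            TwinCNN(0, 12, 9)


def test_backprop_matches_finite_differences():
    """Central-difference check of every parameter group, away from ReLU kinks."""
    model = TwinCNN(5, 9, 7, drug_cfg=SMALL_BRANCH, cell_cfg=SMALL_BRANCH,
                    head_cfg=SMALL_HEAD, seed=3, dtype=np.float64)
    rng = np.random.default_rng(0)
    # continuous inputs and non-zero biases keep pre-activations off 0 exactly
    for p in model.params:
        p.value += rng.normal(scale=0.05, size=p.value.shape)
    xd = rng.random((3, 5, 9)) + 0.1
    xc = rng.random((3, 1, 7)) + 0.1
    y = rng.random(3)

    def loss():
        return float(np.mean((model.forward(xd, xc) - y) ** 2))

    for p in model.params:
        p.grad[...] = 0.0
    pred = model.forward(xd, xc)
    model.backward(2.0 * (pred - y) / len(y))
    for p in model.params:
        flat, grad = p.value.reshape(-1), p.grad.reshape(-1)
        for i in rng.choice(flat.size, size=min(4, flat.size), replace=False):
            eps, orig = 1e-6, flat[i]
            flat[i] = orig + eps
            up = loss()
            flat[i] = orig - eps
            down = loss()
            flat[i] = orig
            numeric = (up - down) / (2 * eps)
            assert grad[i] == pytest.approx(numeric, rel=1e-4, abs=1e-9)


def test_channel_relabeling_equivariance():
    """Permuting vocabulary rows of inputs and first-layer weights together
    leaves predictions unchanged (the row-shuffle symmetry of the drug branch)."""
    model = TwinCNN(6, 12, 9, drug_cfg=SMALL_BRANCH, cell_cfg=SMALL_BRANCH,
                    head_cfg=SMALL_HEAD, seed=2, dtype=np.float64)
    rng = np.random.default_rng(4)
    xd = (rng.random((5, 6, 12)) < 0.25).astype(float)
    xc = (rng.random((5, 1, 9)) < 0.4).astype(float)
    base = model.forward(xd, xc)

    perm = rng.permutation(6)
    shuffled_inputs = xd[:, perm, :]  # row i of new input = row perm[i]
    conv = model.drug_branch.layers[0]
    w = conv.W.value.reshape(6, conv.width, -1)
    conv.W.value = w[perm].reshape(conv.W.value.shape)
    np.testing.assert_allclose(model.forward(shuffled_inputs, xc), base,
                               atol=1e-12)


@pytest.fixture(scope="module")
def small_setup(tiny_table, tiny_tensors):
    split = pair_split(tiny_table, seed=0)
    kwargs = dict(drug_cfg=SMALL_BRANCH, cell_cfg=SMALL_BRANCH,
                  head_cfg=HeadConfig(hidden_sizes=(16,), dropout=0.2))
    return tiny_tensors, split, kwargs


@pytest.fixture(scope="module")
def trained(tiny_table, tiny_tensors):
    split = pair_split(tiny_table, seed=0)
    model = TwinCNN(tiny_tensors.drug_onehots.shape[1],
                    tiny_tensors.drug_onehots.shape[2],
                    tiny_tensors.cell_features.shape[2],
                    drug_cfg=SMALL_BRANCH, cell_cfg=SMALL_BRANCH,
                    head_cfg=HeadConfig(hidden_sizes=(16,), dropout=0.2),
                    seed=0)
    train(model, tiny_tensors, split,
          TrainConfig(max_epochs=2, batch_size=32, learning_rate=1e-3,
                      seed=0))
    return model, tiny_tensors, split


class TestTraining:
    def test_constant_labels_are_fit_quickly(self, small_setup):
        tensors, split, kwargs = small_setup
        flat = TableTensors(
            drug_ids=tensors.drug_ids, cell_ids=tensors.cell_ids,
            drug_onehots=tensors.drug_onehots,
            cell_features=tensors.cell_features,
            values=np.full_like(tensors.values, 0.5),
            known_mask=tensors.known_mask, encoder=tensors.encoder)
        model = TwinCNN(tensors.drug_onehots.shape[1],
                        tensors.drug_onehots.shape[2],
                        tensors.cell_features.shape[2], seed=0, **kwargs)
        history = train(model, flat, split,
                        TrainConfig(max_epochs=15, batch_size=32,
                                    learning_rate=3e-3, seed=0))
        assert history.best_val_rmse < 0.01

    def test_early_stopping_restores_best_parameters(self, small_setup):
        tensors, split, kwargs = small_setup
        model = TwinCNN(tensors.drug_onehots.shape[1],
                        tensors.drug_onehots.shape[2],
                        tensors.cell_features.shape[2], seed=1, **kwargs)
        cfg = TrainConfig(max_epochs=12, patience_epochs=2, batch_size=32,
                          learning_rate=3e-3, seed=1)
        history = train(model, tensors, split, cfg)
        assert history.best_epoch == int(np.argmin(history.val_rmse))
        # restored parameters must reproduce the recorded best validation RMSE
        _, _, y_val = tensors.pair_arrays(split.val_pairs)
        val_pred = predict(model, tensors, list(split.val_pairs))
        rmse = float(np.sqrt(np.mean((val_pred - y_val) ** 2)))
        assert rmse == pytest.approx(history.best_val_rmse, abs=1e-6)
        # early stopping never runs more than patience epochs past the best
        assert len(history.val_rmse) <= history.best_epoch + cfg.patience_epochs + 1

    def test_seeded_training_is_reproducible(self, small_setup):
        tensors, split, kwargs = small_setup
        histories = []
        for _ in range(2):
            model = TwinCNN(tensors.drug_onehots.shape[1],
                            tensors.drug_onehots.shape[2],
                            tensors.cell_features.shape[2], seed=7, **kwargs)
            histories.append(train(model, tensors, split,
                                   TrainConfig(max_epochs=3, batch_size=32,
                                               learning_rate=1e-3, seed=7)))
        np.testing.assert_allclose(histories[0].val_rmse,
                                   histories[1].val_rmse, atol=1e-6)

    def test_empty_partitions_rejected(self, small_setup):
        tensors, split, kwargs = small_setup
        model = TwinCNN(tensors.drug_onehots.shape[1],
                        tensors.drug_onehots.shape[2],
                        tensors.cell_features.shape[2], seed=0, **kwargs)
        empty = dataclasses.replace(split, train_pairs=())
        with pytest.raises(ValueError):
            train(model, tensors, empty, TrainConfig(max_epochs=1))


class TestPrediction:
    def test_inference_is_deterministic(self, trained):
        model, tensors, split = trained
        pairs = list(split.test_pairs)
        np.testing.assert_array_equal(predict(model, tensors, pairs),
                                      predict(model, tensors, pairs))

    def test_batch_equals_single_pair(self, trained):
        model, tensors, split = trained
        pairs = list(split.test_pairs)[:5]
        batched = predict(model, tensors, pairs)
        singles = np.concatenate([predict(model, tensors, [p]) for p in pairs])
        np.testing.assert_allclose(batched, singles, atol=1e-6)

    def test_outputs_denormalize_to_finite_log_ic50(self, trained):
        model, tensors, split = trained
        preds = predict(model, tensors, list(split.test_pairs))
        assert np.isfinite(denormalize_ic50(preds)).all()

    def test_unknown_entity_rejected(self, trained):
        model, tensors, _ = trained
        with pytest.raises(KeyError):
            predict(model, tensors, [("no-such-drug", tensors.cell_ids[0])])

    def test_checkpoint_round_trip(self, trained, tmp_path):
        model, tensors, split = trained
        save_model(model, tmp_path / "ckpt")
        back = load_model(tmp_path / "ckpt")
        pairs = list(split.test_pairs)
        np.testing.assert_array_equal(predict(model, tensors, pairs),
                                      predict(back, tensors, pairs))


class TestEmbeddings:
    def test_embedding_widths_and_identity(self, tiny_tensors):
        from twincnn.model import embed_cells, embed_drugs
        model = TwinCNN(tiny_tensors.drug_onehots.shape[1],
                        tiny_tensors.drug_onehots.shape[2],
                        tiny_tensors.cell_features.shape[2],
                        drug_cfg=SMALL_BRANCH, cell_cfg=SMALL_BRANCH,
                        head_cfg=SMALL_HEAD, seed=0)
        zd = embed_drugs(model, tiny_tensors.drug_onehots)
        zc = embed_cells(model, tiny_tensors.cell_features)
        assert zd.shape == (len(tiny_tensors.drug_ids), model.drug_dim)
        assert zc.shape == (len(tiny_tensors.cell_ids), model.cell_dim)
        duplicated = np.stack([tiny_tensors.drug_onehots[0]] * 2)
        z = embed_drugs(model, duplicated)
        np.testing.assert_array_equal(z[0], z[1])

    def test_default_stack_gives_printed_widths(self):
        model = TwinCNN(72, 188, 735, seed=0)
        assert model.drug_dim == 420
        assert model.cell_dim == 1680


def test_prepare_tensors_never_hardcodes_dimensions(tiny_table):
    tensors = prepare_tensors(tiny_table)
    longest = max(len(t) for t in
                  (d.canonical_smiles for d in tiny_table.drugs))
    assert tensors.drug_onehots.shape[2] <= longest  # tokens, not characters
    assert (tensors.drug_onehots.sum(axis=1) == 1).all()
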