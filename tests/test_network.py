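import dataclasses

import numpy as np
import pytest

from eegrefine.montage import default_montage
from eegrefine.network import (
    ArchitectureError,
    DivergenceError,
    MultiBranchModel,
    NetworkParams,
    _elu,
    default_spec,
    output_shapes,
    train,
)
from eegrefine.representation import Tensor3DBatch


def onehot(ids, n=4):
    out = np.zeros((len(ids), n))
    out[np.arange(len(ids)), ids] = 1.0
    return out


def toy_batch(n_per_class=10, t=64, noise=0.05, seed=0):
    """Linearly separable spatial patterns on the standard grid."""
    m = default_montage()
    rng = np.random.default_rng(seed)
    cells = [m.placement[e] for e in ("C3", "C4", "Cz", "Fz")]
    data, ids = [], []
    for c in range(4):
        for _ in range(n_per_class):
            x = rng.normal(0, noise, size=(m.grid_height, m.grid_width, t))
            r, col = cells[c]
            x[r, col, :] += 1.0
            data.append(x)
            ids.append(c)
    return Tensor3DBatch(np.array(data), onehot(ids), m)


class TestSpec:
    def test_published_layer_table(self):
        spec = default_spec()
        by_name = {b.name: b for b in spec.branches}
        assert by_name["SRF"].conv_layers[0] == ((3, 3, 5), (2, 2, 4), 16)
        assert by_name["LRF"].conv_layers[2] == ((2, 2, 5), (2, 2, 4), 64)
        assert by_name["MRF"].conv_layers[1] == ((2, 2, 3), (2, 2, 2), 32)
        # first layers share the spec but not the weights
        conv1 = {b.conv_layers[0] for b in spec.branches}
        assert len(conv1) == 1

    def test_conv1_weights_unshared(self):
        model = MultiBranchModel(default_spec((6, 7, 64), seed=0))
        w = [model.branches[n].convs[0].W for n in ("SRF", "MRF", "LRF")]
        assert not np.array_equal(w[0], w[1])
        assert not np.array_equal(w[1], w[2])

    def test_output_shapes_ceil_chain(self):
        shapes = output_shapes(default_spec((6, 7, 312)))
        assert shapes["SRF"][0] == (3, 4, 78, 16)
        assert shapes["MRF"][0] == (3, 4, 78, 16)
        assert shapes["LRF"] == [(3, 4, 78, 16), (2, 2, 20, 32), (1, 1, 5, 64)]

    def test_degenerate_grid_raises(self):
        # ceil semantics keep every positive dim >= 1; only an empty input
        # dimension can collapse a conv output below 1
        with pytest.raises(ArchitectureError):
            output_shapes(default_spec((0, 7, 312)))
        with pytest.raises(ArchitectureError):
            MultiBranchModel(default_spec((0, 7, 312)))

    def test_params_json_round_trip(self):
        spec = default_spec((6, 7, 64), seed=3, epochs=5)
        back = NetworkParams.from_json(spec.to_json())
        assert back == spec


class TestForward:
    def _model_with_branch_biases(self, biases):
        """Zero all weights so each branch softmax is softmax(bias)."""
        spec = default_spec((6, 7, 16), seed=0)
        model = MultiBranchModel(spec)
        for name, bias in biases.items():
            br = model.branches[name]
            for layer in br.layers:
                layer.W[...] = 0.0
                layer.b[...] = 0.0
            br.fc2.b[...] = np.asarray(bias, dtype=br.fc2.b.dtype)
        return model

    def test_fusion_is_softmax_of_summed_softmaxes(self):
        p = [0.7, 0.1, 0.1, 0.1]
        model = self._model_with_branch_biases(
            {"SRF": np.log(p), "MRF": np.log(np.roll(p, 1)), "LRF": np.log(np.roll(p, 2))}
        )
        x = np.zeros((1, 6, 7, 16))
        fused, branch = model.forward(x)
        np.testing.assert_allclose(branch["SRF"][0], p, atol=1e-6)
        summed = sum(branch[n][0] for n in branch)
        expected = np.exp(summed) / np.exp(summed).sum()
        np.testing.assert_allclose(fused[0], expected, atol=1e-6)
        assert fused.sum() == pytest.approx(1.0, abs=1e-6)

    def test_three_distinct_winners_tie_to_lowest_class(self):
        # branches prefer classes 0, 1, 2 -> summed vector (.9,.9,.9,.3)
        p = [0.7, 0.1, 0.1, 0.1]
        model = self._model_with_branch_biases(
            {"SRF": np.log(p), "MRF": np.log(np.roll(p, 1)), "LRF": np.log(np.roll(p, 2))}
        )
        x = np.zeros((1, 6, 7, 16))
        fused, _ = model.forward(x)
        assert fused[0, 0] == pytest.approx(fused[0, 1], abs=1e-6)
        assert fused[0, 3] < fused[0, 0]
        assert model.predict(x)[0] == 0

    def test_uniform_branches_fuse_uniform_and_predict_class0(self):
        model = self._model_with_branch_biases(
            {n: np.zeros(4) for n in ("SRF", "MRF", "LRF")}
        )
        x = np.zeros((2, 6, 7, 16))
        fused, _ = model.forward(x)
        np.testing.assert_allclose(fused, 0.25, atol=1e-6)
        assert (model.predict(x) == 0).all()

    def test_probabilities_normalised_for_random_weights(self):
        model = MultiBranchModel(default_spec((6, 7, 32), seed=11))
        x = np.random.default_rng(2).normal(size=(5, 6, 7, 32))
        fused, branch = model.forward(x)
        np.testing.assert_allclose(fused.sum(axis=1), 1.0, atol=1e-6)
        for p in branch.values():
            np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_shape_mismatch_raises(self):
        model = MultiBranchModel(default_spec((6, 7, 32)))
        with pytest.raises(ValueError):
            model.forward(np.zeros((1, 6, 7, 16)))


class TestTrain:
    def test_overfits_separable_toy_set(self):
        batch = toy_batch()
        spec = default_spec((6, 7, 64), seed=1, epochs=30)
        model = train(spec, batch, None)
        assert model.history[-1]["train_accuracy"] == 1.0

    def test_zero_epochs_gives_initialised_model_empty_history(self):
        batch = toy_batch(n_per_class=2)
        model = train(default_spec((6, 7, 64), seed=1, epochs=0), batch, None)
        assert model.history == []

    def test_same_seed_bitwise_identical_history(self):
        batch = toy_batch(n_per_class=4)
        spec = default_spec((6, 7, 64), seed=9, epochs=3)
        h1 = train(spec, batch, batch).history
        h2 = train(spec, batch, batch).history
        assert h1 == h2

    def test_divergence_raises_with_epoch_number(self):
        batch = toy_batch(n_per_class=4)
        spec = default_spec((6, 7, 64), seed=1, epochs=5, learning_rate=1e12)
        with pytest.raises(DivergenceError, match="epoch"):
            train(spec, batch, None)

    def test_history_records_validation(self):
        batch = toy_batch(n_per_class=3)
        model = train(default_spec((6, 7, 64), seed=2, epochs=2), batch, batch)
        assert len(model.history) == 2
        assert {"val_loss", "val_accuracy"} <= set(model.history[0])


class TestGradientTap:
    def test_matches_central_finite_difference(self):
        spec = default_spec((6, 7, 32), seed=5, dtype="float64")
        model = MultiBranchModel(spec)
        x = np.random.default_rng(3).normal(size=(1, 6, 7, 32))
        for name in ("SRF", "LRF"):
            a3, grad, _ = model.conv_tap(x, name, target_class=2)
            br = model.branches[name]

            def head(a3_flat):
                h1 = a3_flat @ br.fc1.W + br.fc1.b
                return (_elu(h1) @ br.fc2.W + br.fc2.b)[2]

            flat = a3.reshape(-1).copy()
            eps = 1e-5
            idx = np.random.default_rng(0).choice(flat.size, size=50, replace=False)
            for i in idx:
                fp, fm = flat.copy(), flat.copy()
                fp[i] += eps
                fm[i] -= eps
                fd = (head(fp) - head(fm)) / (2 * eps)
                assert grad.reshape(-1)[i] == pytest.approx(fd, rel=1e-3, abs=1e-8)


class TestPersistence:
    def test_checkpoint_round_trip(self, tmp_path):
        batch = toy_batch(n_per_class=3)
        model = train(default_spec((6, 7, 64), seed=4, epochs=2), batch, batch)
        model.save(tmp_path / "ckpt")
        back = MultiBranchModel.load(tmp_path / "ckpt")
        np.testing.assert_array_equal(model.predict(batch.data), back.predict(batch.data))
        f1, _ = model.forward(batch.data)
        f2, _ = back.forward(batch.data)
        np.testing.assert_array_equal(f1, f2)
        assert (tmp_path / "ckpt" / "history.csv").exists()
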