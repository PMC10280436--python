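import numpy as np
import pytest

from tsskit.dataset import DatasetSplit, LabeledDataset, split_by_chromosome
from tsskit.encoding import encode_batch
from tsskit.errors import ConfigurationError
from tsskit.metrics import auc_roc
from tsskit.nn import (
    ARCHITECTURE_NAMES,
    TrainingConfig,
    build_architecture,
    predict_proba,
    stopped_epoch_from_trace,
    train,
)
from tsskit.nn.core import (
    LSTM,
    Bidirectional,
    Conv1D,
    Dense,
    Flatten,
    MaxPool1D,
    Network,
    bce_with_logits,
)
from tsskit.nn.training import train_arrays


def layer_kinds(spec, kind):
    return [layer for layer in spec.layers if layer["kind"] == kind]


class TestArchitectureSpecs:
    def test_cnn_layer_list(self):
        spec, _ = build_architecture("cnn")
        convs = layer_kinds(spec, "conv1d")
        assert len(convs) == 3
        assert all(c["filters"] == 32 and c["width"] == 5 and c["stride"] == 1 for c in convs)
        assert len(layer_kinds(spec, "maxpool")) == 3
        dense = layer_kinds(spec, "dense")
        assert [d["units"] for d in dense] == [1024, 512, 128, 1]
        dropouts = layer_kinds(spec, "dropout")
        assert [d["rate"] for d in dropouts] == [0.2, 0.2, 0.2]
        assert spec.layers[-1] == {"kind": "dense", "units": 1, "activation": "sigmoid"}

    def test_lstm_and_blstm_layer_lists(self):
        for name in ("lstm", "blstm"):
            spec, _ = build_architecture(name, input_length=30)
            assert spec.layers[0]["units"] == 128
            assert spec.layers[0]["kind"] == ("blstm" if name == "blstm" else "lstm")
            assert [d["units"] for d in layer_kinds(spec, "dense")] == [64, 1]
            assert [d["rate"] for d in layer_kinds(spec, "dropout")] == [0.5]

    def test_hybrid_dropout_schedule(self):
        for name in ("cnn_lstm", "cnn_blstm"):
            spec, _ = build_architecture(name, input_length=30)
            assert [d["rate"] for d in layer_kinds(spec, "dropout")] == [0.25, 0.8]
            conv = layer_kinds(spec, "conv1d")[0]
            assert conv["filters"] == 64 and conv["width"] == 3
            assert layer_kinds(spec, "maxpool")[0]["size"] == 3
            recurrent = spec.layers[3]
            assert recurrent["units"] == 64

    def test_unknown_name_rejected(self):
        with pytest.raises(ConfigurationError):
            build_architecture("transformer")

    def test_too_short_input_rejected(self):
        with pytest.raises(ConfigurationError):
            build_architecture("cnn", input_length=40)

    @pytest.mark.parametrize("name", ARCHITECTURE_NAMES)
    def test_forward_pass_probabilities(self, name):
        length = 1003 if name == "cnn" else 30
        _, net = build_architecture(name, input_length=length, seed=0)
        x = encode_batch(["".join(c) for c in np.random.default_rng(0).choice(
            list("ACGT"), size=(2, length))])
        proba = net.predict_proba(x)
        assert proba.shape == (2,)
        assert np.all((proba > 0) & (proba < 1))

    def test_blstm_concatenates_directions(self):
        _, net = build_architecture("blstm", input_length=12, seed=0)
        layer = net.layers[0]
        assert isinstance(layer, Bidirectional)
        assert layer.fwd.units == layer.bwd.units == 128


class TestGradients:
    def _gradcheck(self, layers, x_shape, eps=1e-6, n_checks=4, tol=1e-5):
        net = Network(layers)
        x = np.random.default_rng(1).normal(size=x_shape)
        y = np.random.default_rng(2).integers(0, 2, x_shape[0]).astype(float)
        _, grad = bce_with_logits(net.forward_logits(x, train=False), y)
        net.backward(grad)
        analytic = [g.copy() for g in net.grads]
        rng = np.random.default_rng(3)
        for pi, p in enumerate(net.params):
            flat = p.reshape(-1)
            for idx in rng.choice(flat.size, size=min(n_checks, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                up, _ = bce_with_logits(net.forward_logits(x, train=False), y)
                flat[idx] = orig - eps
                down, _ = bce_with_logits(net.forward_logits(x, train=False), y)
                flat[idx] = orig
                numeric = (up - down) / (2 * eps)
                a = analytic[pi].reshape(-1)[idx]
                assert abs(numeric - a) <= tol * max(1.0, abs(numeric), abs(a))

    def test_dense_stack_gradients(self):
        rng = np.random.default_rng(0)
        self._gradcheck([Dense(6, 4, rng, "relu"), Dense(4, 1, rng)], (3, 6))

    def test_conv_pool_gradients(self):
        rng = np.random.default_rng(0)
        self._gradcheck(
            [Conv1D(4, 8, 3, rng), MaxPool1D(2), Flatten(), Dense(40, 1, rng)], (3, 12, 4)
        )

    def test_lstm_gradients(self):
        rng = np.random.default_rng(0)
        self._gradcheck([LSTM(4, 6, rng), Dense(6, 1, rng)], (3, 10, 4))

    def test_blstm_gradients(self):
        rng = np.random.default_rng(0)
        self._gradcheck([Bidirectional(4, 5, rng), Dense(10, 1, rng)], (3, 10, 4))


class TestEarlyStopping:
    def test_plateau_from_epoch_three_stops_at_thirteen(self):
        trace = [1.0, 0.8, 0.6] + [0.6] * 20
        assert stopped_epoch_from_trace(trace, patience=10) == 13

    def test_never_exhausted_runs_full_trace(self):
        trace = list(np.linspace(1.0, 0.1, 30))
        assert stopped_epoch_from_trace(trace, patience=10) == 30

    def test_immediate_plateau(self):
        assert stopped_epoch_from_trace([0.5] * 20, patience=3) == 4


@pytest.fixture(scope="module")
def tiny_split(small_dataset):
    return split_by_chromosome(small_dataset, {"3"}, set())


class TestTraining:
    def test_training_beats_uninformative_baseline(self, tiny_split):
        """On the planted-motif fixture the final train loss must fall below
        ln 2, the loss of predicting 0.5 everywhere."""
        _, net = build_architecture("cnn_lstm", 20, seed=0)
        history = train(net, tiny_split, TrainingConfig(max_epochs=12, seed=0))
        assert history.train_loss[-1] < np.log(2)
        assert history.best_epoch <= history.stopped_epoch <= 12

    def test_same_seed_reproduces_first_epoch(self, tiny_split):
        losses = []
        for _ in range(2):
            _, net = build_architecture("lstm", 20, seed=5)
            history = train(net, tiny_split, TrainingConfig(max_epochs=2, patience=1, seed=5))
            losses.append(history.train_loss[0])
        assert losses[0] == losses[1]

    def test_empty_partition_rejected(self, tiny_split):
        _, net = build_architecture("lstm", 20, seed=0)
        empty_split = DatasetSplit(
            train=tiny_split.train,
            validation=LabeledDataset([]),
            test=LabeledDataset([]),
            validation_chromosomes=frozenset(),
            test_chromosomes=frozenset(),
        )
        with pytest.raises(ConfigurationError):
            train(net, empty_split, TrainingConfig())

    def test_trained_model_separates_classes(self, tiny_split):
        """Mean predicted probability for positives exceeds negatives."""
        _, net = build_architecture("lstm", 20, seed=1)
        train(net, tiny_split, TrainingConfig(max_epochs=25, seed=1))
        proba = predict_proba(net, tiny_split.validation.sequences())
        y = tiny_split.validation.labels()
        assert proba[y == 1].mean() > proba[y == 0].mean()
        assert auc_roc(y, proba) > 0.7

    def test_early_stopping_restores_best_weights(self):
        """Validation loss of the returned model equals the best epoch's."""
        rng = np.random.default_rng(0)
        X = rng.normal(size=(64, 8))
        y = rng.integers(0, 2, 64).astype(float)
        Xv = rng.normal(size=(32, 8))
        yv = rng.integers(0, 2, 32).astype(float)
        net = Network([Dense(8, 4, rng, "relu"), Dense(4, 1, rng)])
        history = train_arrays(net, X, y, Xv, yv, TrainingConfig(max_epochs=40, patience=5, seed=0))
        logits = net.forward_logits(Xv, train=False)
        final_loss, _ = bce_with_logits(logits, yv)
        assert final_loss == pytest.approx(min(history.val_loss), abs=1e-9)


class TestPredictProba:
    def test_empty_input(self):
        _, net = build_architecture("lstm", 20, seed=0)
        assert predict_proba(net, []).shape == (0,)

    def test_order_preserved_and_range(self, tiny_split):
        _, net = build_architecture("lstm", 20, seed=0)
        seqs = tiny_split.train.sequences()[:7]
        proba = predict_proba(net, seqs)
        assert proba.shape == (7,)
        assert np.all((proba > 0) & (proba < 1))
        flipped = predict_proba(net, seqs[::-1])
        assert np.allclose(flipped, proba[::-1])
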