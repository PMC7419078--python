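"""CVAE training and encoding behaviour on controlled datasets."""

import numpy as np
import pytest

from ugtshape.contacts import ContactDataset, ResidueSelection, build_dataset
from ugtshape.cvae import (
    Conv,
    ConvTranspose,
    CvaeConfig,
    Dense,
    TrainedCVAE,
    encode,
    train,
)
from ugtshape.errors import EmptyInputError


def _constant_dataset(n=60, size=12):
    matrices = np.ones((n, size, size), dtype=np.uint8)
    labels = [("v", "s", k) for k in range(n)]
    train_idx = np.arange(int(0.8 * n))
    val_idx = np.arange(int(0.8 * n), n)
    return ContactDataset(matrices, labels, train_idx, val_idx, split_seed=0)


def _num_grad(f, x, eps=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = f()
        x[i] = orig - eps
        fm = f()
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
    return g


class TestLayerGradients:
    """Analytic backward passes agree with central finite differences."""

    def test_conv_gradients(self):
        rng = np.random.default_rng(0)
        layer = Conv(2, 3, 3, 2, 1, rng, dtype=np.float64)
        x = rng.normal(size=(2, 2, 7, 7))
        w = rng.normal(size=layer.forward(x).shape)
        loss = lambda: float((layer.forward(x) * w).sum())
        loss()
        dx = layer.backward(w)
        assert np.abs(dx - _num_grad(loss, x)).max() < 1e-6
        assert np.abs(layer.grads[0] - _num_grad(loss, layer.W)).max() < 1e-6
        assert np.abs(layer.grads[1] - _num_grad(loss, layer.b)).max() < 1e-6

    @pytest.mark.parametrize("out_size", [7, 8])  # odd and even upsampling
    def test_conv_transpose_gradients(self, out_size):
        rng = np.random.default_rng(1)
        layer = ConvTranspose(3, 2, 3, 2, 1, in_size=4, out_size=out_size,
                              rng=rng, dtype=np.float64)
        x = rng.normal(size=(2, 3, 4, 4))
        w = rng.normal(size=layer.forward(x).shape)
        loss = lambda: float((layer.forward(x) * w).sum())
        loss()
        dx = layer.backward(w)
        assert np.abs(dx - _num_grad(loss, x)).max() < 1e-6
        assert np.abs(layer.grads[0] - _num_grad(loss, layer.W)).max() < 1e-6

    def test_dense_gradients(self):
        rng = np.random.default_rng(2)
        layer = Dense(5, 4, rng, dtype=np.float64)
        x = rng.normal(size=(3, 5))
        w = rng.normal(size=(3, 4))
        loss = lambda: float((layer.forward(x) * w).sum())
        loss()
        dx = layer.backward(w)
        assert np.abs(dx - _num_grad(loss, x)).max() < 1e-6


class TestTraining:
    def test_constant_data_memorized(self):
        # all-contact matrices: reconstruction must reach < 1e-2 per element
        ds = _constant_dataset()
        config = CvaeConfig(input_size=12, seed=0, max_epochs=150,
                            batch_size=16, latent_dim=2)
        model = train(ds, config)
        per_element = model.history[-1]["reconstruction_term"] / (12 * 12)
        assert per_element < 1e-2

    def test_same_seed_identical_history(self, two_state_dataset):
        config = CvaeConfig(input_size=two_state_dataset.size, seed=5, max_epochs=8)
        h1 = train(two_state_dataset, config).history
        h2 = train(two_state_dataset, config).history
        assert h1 == h2

    def test_kl_term_nonnegative_every_epoch(self, small_trained_model):
        assert all(row["kl_term"] >= 0 for row in small_trained_model.history)

    def test_converges_before_max_epochs_on_two_state_data(self, small_trained_model):
        assert small_trained_model.history  # trained at all
        assert small_trained_model.converged_epoch <= small_trained_model.config.max_epochs

    def test_smoothed_training_loss_nonincreasing_on_constant_data(self):
        ds = _constant_dataset()
        config = CvaeConfig(input_size=12, seed=1, max_epochs=60,
                            batch_size=16, latent_dim=2)
        model = train(ds, config)
        losses = np.array([row["train_loss"] for row in model.history])
        window = np.convolve(losses, np.ones(5) / 5, mode="valid")
        # monotone through the descent phase; once memorization is reached
        # (per-matrix loss < 1) the loss sits at its noise floor
        floor = np.argmax(window < 1.0) if (window < 1.0).any() else window.size
        descent = window[: floor + 1]
        assert (np.diff(descent) < 1e-3 * np.abs(descent[:-1]) + 1e-6).all()

    def test_empty_train_split_rejected(self):
        ds = _constant_dataset(n=10)
        empty = ContactDataset(ds.matrices, ds.labels,
                               np.array([], dtype=int), np.arange(10), split_seed=0)
        with pytest.raises(EmptyInputError):
            train(empty, CvaeConfig(input_size=12, seed=0))

    def test_size_mismatch_rejected(self, two_state_dataset):
        with pytest.raises(ValueError, match="input_size"):
            train(two_state_dataset, CvaeConfig(input_size=10, seed=0))


class TestEncode:
    def test_encoding_is_deterministic(self, small_trained_model, two_state_dataset):
        e1 = encode(small_trained_model, two_state_dataset)
        e2 = encode(small_trained_model, two_state_dataset)
        np.testing.assert_array_equal(e1.codes, e2.codes)

    def test_one_code_per_matrix_with_labels(self, small_trained_model,
                                             two_state_dataset):
        emb = encode(small_trained_model, two_state_dataset)
        assert emb.codes.shape == (two_state_dataset.n,
                                   small_trained_model.config.latent_dim)
        assert emb.labels == two_state_dataset.labels

    def test_permutation_of_inputs_permutes_codes(self, small_trained_model,
                                                  two_state_dataset):
        ds = two_state_dataset
        rng = np.random.default_rng(0)
        perm = rng.permutation(ds.n)
        permuted = ContactDataset(
            ds.matrices[perm], [ds.labels[k] for k in perm],
            np.arange(int(0.8 * ds.n)), np.arange(int(0.8 * ds.n), ds.n),
            split_seed=0,
        )
        base = encode(small_trained_model, ds).codes
        shuffled = encode(small_trained_model, permuted).codes
        np.testing.assert_allclose(shuffled, base[perm], rtol=0, atol=1e-5)

    def test_hidden_states_linearly_separable_in_latent(
            self, small_trained_model, two_state_dataset, two_state_ensemble):
        # the generator's hidden state labels are recoverable from the codes
        from sklearn.linear_model import LogisticRegression
        from sklearn.model_selection import train_test_split

        emb = encode(small_trained_model, two_state_dataset)
        y = (two_state_ensemble.state_labels == "open").astype(int)
        x_tr, x_te, y_tr, y_te = train_test_split(
            emb.codes, y, test_size=0.3, random_state=0, stratify=y)
        probe = LogisticRegression(max_iter=1000).fit(x_tr, y_tr)
        assert probe.score(x_te, y_te) >= 0.95


class TestCheckpoint:
    def test_save_load_round_trip(self, small_trained_model, two_state_dataset,
                                  tmp_path):
        path = tmp_path / "model.npz"
        small_trained_model.save(path)
        loaded = TrainedCVAE.load(path)
        assert loaded.config == small_trained_model.config
        assert loaded.history == small_trained_model.history
        np.testing.assert_array_equal(
            encode(loaded, two_state_dataset).codes,
            encode(small_trained_model, two_state_dataset).codes,
        )
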