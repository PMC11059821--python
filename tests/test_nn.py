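"""Neural encoders: gradient correctness, training sanity, cross-batch."""

import numpy as np
import pytest

from xformscan import depth_scaled_scenario, simulate_counts
from xformscan.nn import (
    DownstreamConfig,
    EncoderSpec,
    evaluate_cross_batch,
    proto_query_accuracy,
    train_autoencoder,
    train_prototypical,
    train_vae,
)
from xformscan.nn.encoders import kl_standard_normal
from xformscan.nn.layers import BatchNorm, Dense, ReLU, Sequential


def separable_classes(n=100, dim=30, gap=4.0, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0, 1, (n, dim)), rng.normal(gap, 1, (n, dim))])
    y = np.array([0] * n + [1] * n)
    return X, y


class TestBackprop:
    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        net = Sequential(Dense(4, 6, rng), BatchNorm(6), ReLU(), Dense(6, 3, rng))
        x = rng.normal(size=(8, 4))
        y = rng.normal(size=(8, 3))

        def loss():
            return np.mean((net.forward(x, train=True) - y) ** 2)

        for layer, name in net.parameters():
            layer.grads[name][...] = 0.0
        out = net.forward(x, train=True)
        net.backward(2.0 * (out - y) / y.size)
        eps = 1e-6
        for layer, name in net.parameters():
            P, G = layer.params[name], layer.grads[name]
            flat = P.ravel()
            for ix in range(0, flat.size, max(1, flat.size // 5)):
                old = flat[ix]
                flat[ix] = old + eps
                lp = loss()
                flat[ix] = old - eps
                lm = loss()
                flat[ix] = old
                num = (lp - lm) / (2 * eps)
                assert G.ravel()[ix] == pytest.approx(num, rel=1e-4, abs=1e-8)


class TestAutoencoder:
    def spec(self, **kw):
        base = dict(n_genes=30, latent_size=2, hidden_sizes=(32,), epochs=30, seed=0)
        base.update(kw)
        return EncoderSpec(**base)

    def test_loss_decreases(self):
        X, _ = separable_classes()
        enc = train_autoencoder(X, self.spec())
        assert enc.final_loss < enc.loss_history[0]

    def test_same_seed_same_final_loss(self):
        X, _ = separable_classes(seed=1)
        e1 = train_autoencoder(X, self.spec())
        e2 = train_autoencoder(X, self.spec())
        assert e1.final_loss == e2.final_loss

    def test_rank2_data_near_pca_error(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=(200, 2)) * [4, 2]
        basis = np.linalg.qr(rng.normal(size=(20, 2)))[0].T
        X = scores @ basis
        enc = train_autoencoder(X, self.spec(n_genes=20, epochs=200, hidden_sizes=(64,)))
        latent = enc.encode(X)
        recon = enc.decoder.forward(latent, train=False)
        ae_err = np.mean((recon - X) ** 2)
        # PCA-2 reconstructs rank-2 data exactly; allow the nonlinear model 2x
        # of the residual variance left by a rank-2 linear fit (here ~0), so
        # compare against total variance shrunk to a small fraction instead
        assert ae_err < 0.1 * np.mean(X**2)

    def test_finite_outputs(self):
        X, _ = separable_classes(seed=3)
        enc = train_autoencoder(X, self.spec(epochs=5))
        assert np.all(np.isfinite(enc.encode(X)))

    def test_wrong_spec_rejected(self):
        with pytest.raises(ValueError):
            train_autoencoder(np.zeros((10, 30)), self.spec(variational=True))


class TestVAE:
    def spec(self, **kw):
        base = dict(
            n_genes=30, latent_size=4, hidden_sizes=(32, 16), variational=True,
            epochs=30, seed=0,
        )
        base.update(kw)
        return EncoderSpec(**base)

    def test_loss_decreases(self):
        X, _ = separable_classes(seed=4)
        enc = train_vae(X, self.spec())
        assert enc.final_loss < enc.loss_history[0]

    def test_kl_of_standard_normal_is_zero(self):
        mu = np.zeros((10, 4))
        sigma = np.ones((10, 4))
        assert kl_standard_normal(mu, sigma) == pytest.approx(0.0)

    def test_kl_positive_otherwise(self):
        rng = np.random.default_rng(5)
        assert kl_standard_normal(rng.normal(size=(6, 3)), np.full((6, 3), 0.5)) > 0

    def test_encode_deterministic_and_sigma_positive(self):
        X, _ = separable_classes(seed=6)
        enc = train_vae(X, self.spec(epochs=5))
        mu1, s1 = enc.encode_distribution(X)
        mu2, s2 = enc.encode_distribution(X)
        np.testing.assert_array_equal(mu1, mu2)
        np.testing.assert_array_equal(s1, s2)
        assert np.all(s1 > 0)


class TestPrototypical:
    def spec(self, **kw):
        base = dict(
            n_genes=30, latent_size=4, hidden_sizes=(32,), prototypical=True,
            epochs=20, seed=0,
        )
        base.update(kw)
        return EncoderSpec(**base)

    def test_separable_classes_high_query_accuracy(self):
        X, y = separable_classes(seed=7)
        enc = train_prototypical(X, y, self.spec())
        assert proto_query_accuracy(enc, X, y, seed=1) >= 0.95

    def test_variational_variant_trains(self):
        X, y = separable_classes(seed=8)
        enc = train_prototypical(
            X, y, self.spec(variational=True, hidden_sizes=(32, 16))
        )
        assert proto_query_accuracy(enc, X, y, seed=1) >= 0.95
        assert np.all(np.isfinite(enc.encode(X)))

    def test_single_class_rejected(self):
        X = np.random.default_rng(9).normal(size=(40, 30))
        with pytest.raises(ValueError, match="at least 2 classes"):
            train_prototypical(X, np.zeros(40, dtype=int), self.spec())

    def test_class_too_small_named_in_error(self):
        X, y = separable_classes(n=30, seed=10)
        y = np.array([f"cls{v}" for v in y], dtype=object)
        y[:3] = "rare"
        with pytest.raises(ValueError, match="rare"):
            train_prototypical(X, y, self.spec())

    def test_loss_decreases(self):
        X, y = separable_classes(gap=2.0, seed=11)
        enc = train_prototypical(X, y, self.spec())
        assert enc.final_loss < enc.loss_history[0]


@pytest.fixture(scope="module")
def cross_batch_data():
    return simulate_counts(
        depth_scaled_scenario(
            n_types=3, n_batches=2, cells_per_type_per_batch=50, n_genes=100, seed=2
        )
    )


def tiny_spec(**kw):
    base = dict(n_genes=100, latent_size=8, hidden_sizes=(64,), epochs=25, n_runs=3, seed=0)
    base.update(kw)
    return EncoderSpec(**base)


class TestCrossBatch:
    def test_total_beats_raw_for_autoencoder(self, cross_batch_data):
        raw = evaluate_cross_batch(tiny_spec(), cross_batch_data, "batch0", "raw")
        tot = evaluate_cross_batch(tiny_spec(), cross_batch_data, "batch0", "total")
        med = lambda r: np.median([p.ari for p in r.per_run])
        assert med(tot) > med(raw)
        assert tot.best.ari >= raw.best.ari

    def test_total_beats_raw_for_prototypical(self, cross_batch_data):
        raw = evaluate_cross_batch(
            tiny_spec(prototypical=True), cross_batch_data, "batch0", "raw"
        )
        tot = evaluate_cross_batch(
            tiny_spec(prototypical=True), cross_batch_data, "batch0", "total"
        )
        assert np.median([p.ari for p in tot.per_run]) > np.median(
            [p.ari for p in raw.per_run]
        )

    def test_single_run_reproducible(self, cross_batch_data):
        r1 = evaluate_cross_batch(tiny_spec(n_runs=1, epochs=5), cross_batch_data, "batch0", "total")
        r2 = evaluate_cross_batch(tiny_spec(n_runs=1, epochs=5), cross_batch_data, "batch0", "total")
        assert r1.best.ari == r2.best.ari

    def test_absent_train_batch_rejected(self, cross_batch_data):
        with pytest.raises(ValueError, match="not present"):
            evaluate_cross_batch(tiny_spec(), cross_batch_data, "nope", "total")

    def test_per_run_count_matches_spec(self, cross_batch_data):
        r = evaluate_cross_batch(
            tiny_spec(n_runs=2, epochs=5), cross_batch_data, "batch0", "total",
            DownstreamConfig(seed=1),
        )
        assert len(r.per_run) == 2
        assert r.chain_name == "total" and r.model_name == "ae"
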