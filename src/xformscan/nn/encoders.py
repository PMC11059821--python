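"""Feature encoders: autoencoder, variational autoencoder, and
prototypical networks (plain and variational).

All four share the same building block — fully connected layer, batch
normalization, rectifier — and small default stacks: the autoencoder
has one hidden layer of 1024 units with a mirrored decoder; the
variational models use a [1024, 128] trunk with separate heads for the
latent mean and (softplus-positive) scale. Reconstruction loss is mean
squared error; the variational loss adds beta * KL(q || N(0, I)); the
prototypical loss is softmax cross-entropy over negative squared
euclidean distances between query embeddings and class prototypes (mean
support embeddings), trained episodically.

The cross-batch protocol trains on a single batch and encodes all
batches, so downstream clustering quality measures how well the chosen
data transformation removed batch effects before encoding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from ..clustering import ari_scorer, cluster, silhouette_scorer
from ..datamodel import ExpressionMatrix
from ..embedding import embed
from ..metrics import MetricsRecord, compute_metrics
from ..transforms import TransformChain, apply_chain
from .layers import Adam, BatchNorm, Dense, ReLU, Sequential, softplus, softplus_grad

__all__ = [
    "EncoderSpec",
    "TrainedEncoder",
    "train_autoencoder",
    "train_vae",
    "train_prototypical",
    "train_encoder",
    "DownstreamConfig",
    "evaluate_cross_batch",
    "CrossBatchResult",
]

_LATENT_SIZES = (2, 4, 8, 16, 32, 64, 128, 256)


@dataclass
class EncoderSpec:
    """Architecture and training hyper-parameters for one encoder."""

    n_genes: int
    latent_size: int = 8
    hidden_sizes: tuple[int, ...] | None = None  # default depends on variational
    variational: bool = False
    prototypical: bool = False
    seed: int = 0
    epochs: int = 100
    learning_rate: float = 1e-3
    batch_size: int = 128
    beta: float = 1.0  # KL weight (variational only)
    n_support: int = 5  # episodic composition (prototypical only)
    n_query: int = 5
    n_runs: int = 10

    def __post_init__(self):
        if self.latent_size < 2:
            raise ValueError("latent_size must be >= 2")
        if self.hidden_sizes is None:
            self.hidden_sizes = (1024, 128) if self.variational else (1024,)
        self.hidden_sizes = tuple(int(h) for h in self.hidden_sizes)
        if any(h <= 0 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must be positive")

    @property
    def model_name(self) -> str:
        if self.prototypical:
            return "vproto" if self.variational else "proto"
        return "vae" if self.variational else "ae"


def _mlp(sizes: list[int], rng: np.random.Generator, final_linear: int | None = None) -> Sequential:
    """Stack of Dense -> BatchNorm -> ReLU blocks, plus a linear head."""
    layers: list = []
    for n_in, n_out in zip(sizes[:-1], sizes[1:]):
        layers += [Dense(n_in, n_out, rng), BatchNorm(n_out), ReLU()]
    if final_linear is not None:
        layers.append(Dense(sizes[-1], final_linear, rng))
    return Sequential(*layers)


@dataclass
class TrainedEncoder:
    """A trained encoder with its loss history and encode() interface."""

    spec: EncoderSpec
    trunk: Sequential
    mu_head: Dense | None = None
    sigma_head: Dense | None = None
    decoder: Sequential | None = None
    loss_history: list[float] = field(default_factory=list)

    @property
    def final_loss(self) -> float:
        return self.loss_history[-1]

    def encode(self, X) -> np.ndarray:
        """Deterministic latent representation (mu for variational)."""
        V = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=float)
        h = self.trunk.forward(V, train=False)
        if self.mu_head is not None:
            return self.mu_head.forward(h, train=False)
        return h

    def encode_distribution(self, X) -> tuple[np.ndarray, np.ndarray]:
        if self.mu_head is None or self.sigma_head is None:
            raise ValueError("not a variational encoder")
        V = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=float)
        h = self.trunk.forward(V, train=False)
        mu = self.mu_head.forward(h, train=False)
        sigma = softplus(self.sigma_head.forward(h, train=False))
        return mu, sigma


def _check_finite(loss: float, context: str) -> None:
    if not np.isfinite(loss):
        raise FloatingPointError(f"non-finite loss during {context}: {loss}")


def _minibatches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        idx = order[start : start + batch_size]
        if idx.size >= 2:  # batchnorm needs >= 2 rows
            yield idx


def train_autoencoder(X, spec: EncoderSpec) -> TrainedEncoder:
    """Train a plain autoencoder with MSE reconstruction loss."""
    if spec.variational or spec.prototypical:
        raise ValueError("spec requests a different model; use train_vae/train_prototypical")
    V = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=float)
    rng = np.random.default_rng(spec.seed)
    sizes = [spec.n_genes, *spec.hidden_sizes]
    encoder = _mlp(sizes, rng, final_linear=spec.latent_size)
    decoder = _mlp([spec.latent_size, *reversed(spec.hidden_sizes)], rng, final_linear=spec.n_genes)
    model = Sequential(encoder, decoder)
    opt = Adam(model.parameters(), lr=spec.learning_rate)
    history: list[float] = []
    for _ in range(spec.epochs):
        losses = []
        for idx in _minibatches(V.shape[0], spec.batch_size, rng):
            xb = V[idx]
            opt.zero_grad()
            xhat = model.forward(xb, train=True)
            diff = xhat - xb
            loss = float(np.mean(diff**2))
            _check_finite(loss, "autoencoder training")
            model.backward(2.0 * diff / diff.size)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return TrainedEncoder(spec=spec, trunk=encoder, decoder=decoder, loss_history=history)


def kl_standard_normal(mu: np.ndarray, sigma: np.ndarray) -> float:
    """Mean-per-sample KL(N(mu, sigma^2) || N(0, I))."""
    return float(np.mean(np.sum(0.5 * (sigma**2 + mu**2 - 1.0) - np.log(sigma), axis=1)))


def train_vae(X, spec: EncoderSpec) -> TrainedEncoder:
    """Train a variational autoencoder (MSE reconstruction + beta KL)."""
    if not spec.variational or spec.prototypical:
        raise ValueError("spec does not request a VAE")
    V = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=float)
    rng = np.random.default_rng(spec.seed)
    trunk = _mlp([spec.n_genes, *spec.hidden_sizes], rng)
    mu_head = Dense(spec.hidden_sizes[-1], spec.latent_size, rng)
    sigma_head = Dense(spec.hidden_sizes[-1], spec.latent_size, rng)
    decoder = _mlp([spec.latent_size, *reversed(spec.hidden_sizes)], rng, final_linear=spec.n_genes)
    handles = list(trunk.parameters()) + list(mu_head.parameters()) + list(
        sigma_head.parameters()
    ) + list(decoder.parameters())
    opt = Adam(handles, lr=spec.learning_rate)
    history: list[float] = []
    n_batch = None
    for _ in range(spec.epochs):
        losses = []
        for idx in _minibatches(V.shape[0], spec.batch_size, rng):
            xb = V[idx]
            n_batch = xb.shape[0]
            opt.zero_grad()
            h = trunk.forward(xb, train=True)
            mu = mu_head.forward(h, train=True)
            raw = sigma_head.forward(h, train=True)
            sigma = softplus(raw)
            eps = rng.standard_normal(mu.shape)
            z = mu + sigma * eps
            xhat = decoder.forward(z, train=True)
            diff = xhat - xb
            recon = float(np.mean(diff**2))
            kl = kl_standard_normal(mu, sigma)
            loss = recon + spec.beta * kl
            _check_finite(loss, "VAE training")
            dz = decoder.backward(2.0 * diff / diff.size)
            dmu = dz + spec.beta * mu / n_batch
            dsigma = dz * eps + spec.beta * (sigma - 1.0 / sigma) / n_batch
            draw = dsigma * softplus_grad(raw)
            dh = mu_head.backward(dmu) + sigma_head.backward(draw)
            trunk.backward(dh)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return TrainedEncoder(
        spec=spec, trunk=trunk, mu_head=mu_head, sigma_head=sigma_head, decoder=decoder,
        loss_history=history,
    )


def _proto_loss_and_grads(
    z_support: np.ndarray, z_query: np.ndarray, n_way: int, n_support: int, n_query: int
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Prototypical softmax cross-entropy on squared euclidean distances.

    Returns (loss, accuracy, d_z_support, d_z_query). Support rows are
    grouped by class (class c occupies rows c*n_support:(c+1)*n_support),
    queries likewise.
    """
    protos = z_support.reshape(n_way, n_support, -1).mean(axis=1)
    diff = z_query[:, None, :] - protos[None, :, :]  # (Nq, way, d)
    logits = -np.sum(diff**2, axis=2)
    logits -= logits.max(axis=1, keepdims=True)
    p = np.exp(logits)
    p /= p.sum(axis=1, keepdims=True)
    targets = np.repeat(np.arange(n_way), n_query)
    nq = z_query.shape[0]
    loss = float(-np.mean(np.log(p[np.arange(nq), targets] + 1e-12)))
    acc = float(np.mean(p.argmax(axis=1) == targets))
    dlogits = p.copy()
    dlogits[np.arange(nq), targets] -= 1.0
    dlogits /= nq
    dzq = np.einsum("qc,qcd->qd", dlogits, -2.0 * diff)
    dproto = np.einsum("qc,qcd->cd", dlogits, 2.0 * diff)
    dzs = np.repeat(dproto / n_support, n_support, axis=0)
    return loss, acc, dzs, dzq


def train_prototypical(X, labels, spec: EncoderSpec) -> TrainedEncoder:
    """Episodic training of a (variational) prototypical network.

    Every episode samples ``n_support + n_query`` cells per class, embeds
    them, and pulls queries toward their own class prototype. The
    variational form draws the latent by reparametrization before the
    prototypical loss.
    """
    if not spec.prototypical:
        raise ValueError("spec does not request a prototypical model")
    V = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    need = spec.n_support + spec.n_query
    too_small = classes[counts < need]
    if classes.size < 2:
        raise ValueError("prototypical training needs at least 2 classes")
    if too_small.size:
        raise ValueError(
            f"classes with fewer than support+query={need} cells: {too_small.tolist()}"
        )
    rng = np.random.default_rng(spec.seed)
    trunk = _mlp([spec.n_genes, *spec.hidden_sizes], rng)
    if spec.variational:
        mu_head = Dense(spec.hidden_sizes[-1], spec.latent_size, rng)
        sigma_head = Dense(spec.hidden_sizes[-1], spec.latent_size, rng)
        handles = (
            list(trunk.parameters()) + list(mu_head.parameters()) + list(sigma_head.parameters())
        )
    else:
        head = Dense(spec.hidden_sizes[-1], spec.latent_size, rng)
        encoder = Sequential(trunk, head)
        mu_head = sigma_head = None
        handles = encoder.parameters()
    opt = Adam(handles, lr=spec.learning_rate)
    class_idx = {c: np.flatnonzero(labels == c) for c in classes}
    episodes_per_epoch = max(1, V.shape[0] // (classes.size * need))
    n_way, ns, nq = classes.size, spec.n_support, spec.n_query
    history: list[float] = []
    for _ in range(spec.epochs):
        losses = []
        for _ in range(episodes_per_epoch):
            sup_rows, qry_rows = [], []
            for c in classes:
                pick = rng.choice(class_idx[c], size=need, replace=False)
                sup_rows.append(pick[:ns])
                qry_rows.append(pick[ns:])
            batch = V[np.concatenate(sup_rows + qry_rows)]
            opt.zero_grad()
            if spec.variational:
                h = trunk.forward(batch, train=True)
                mu = mu_head.forward(h, train=True)
                raw = sigma_head.forward(h, train=True)
                sigma = softplus(raw)
                eps = rng.standard_normal(mu.shape)
                z = mu + sigma * eps
            else:
                z = encoder.forward(batch, train=True)
            n_sup = n_way * ns
            loss, _, dzs, dzq = _proto_loss_and_grads(z[:n_sup], z[n_sup:], n_way, ns, nq)
            _check_finite(loss, "prototypical training")
            dz = np.vstack([dzs, dzq])
            if spec.variational:
                draw = (dz * eps) * softplus_grad(raw)
                dh = mu_head.backward(dz) + sigma_head.backward(draw)
                trunk.backward(dh)
            else:
                encoder.backward(dz)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    if spec.variational:
        return TrainedEncoder(
            spec=spec, trunk=trunk, mu_head=mu_head, sigma_head=sigma_head, loss_history=history
        )
    return TrainedEncoder(spec=spec, trunk=encoder, loss_history=history)


def proto_query_accuracy(encoder: TrainedEncoder, X, labels, seed: int = 0, n_episodes: int = 20) -> float:
    """Held-out episodic accuracy: fraction of queries nearest their own prototype."""
    V = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    spec = encoder.spec
    need = spec.n_support + spec.n_query
    rng = np.random.default_rng(seed)
    accs = []
    z_all = encoder.encode(V)
    class_idx = {c: np.flatnonzero(labels == c) for c in classes}
    for _ in range(n_episodes):
        zs, zq = [], []
        for c in classes:
            pick = rng.choice(class_idx[c], size=need, replace=False)
            zs.append(z_all[pick[: spec.n_support]])
            zq.append(z_all[pick[spec.n_support :]])
        _, acc, _, _ = _proto_loss_and_grads(
            np.vstack(zs), np.vstack(zq), classes.size, spec.n_support, spec.n_query
        )
        accs.append(acc)
    return float(np.mean(accs))


def train_encoder(X, spec: EncoderSpec, labels=None) -> TrainedEncoder:
    """Dispatch to the right trainer for the spec's model."""
    if spec.prototypical:
        if labels is None:
            raise ValueError("prototypical training requires labels")
        return train_prototypical(X, labels, spec)
    if spec.variational:
        return train_vae(X, spec)
    return train_autoencoder(X, spec)


# ---------------------------------------------------------------------------
# cross-batch evaluation protocol
# ---------------------------------------------------------------------------


@dataclass
class DownstreamConfig:
    """Embedding + clustering applied to the encoded cells."""

    embed_method: str = "pca2"
    cluster_algorithm: str = "kmeans"
    seed: int = 0


@dataclass
class CrossBatchResult:
    best: MetricsRecord
    per_run: list[MetricsRecord]
    train_batch: str
    chain_name: str
    model_name: str


def evaluate_cross_batch(
    spec: EncoderSpec,
    X_all: ExpressionMatrix,
    train_batch: str,
    chain: TransformChain | str,
    downstream: DownstreamConfig | None = None,
) -> CrossBatchResult:
    """Train on one batch, encode every batch, score the joint clustering.

    The transform chain is applied to all cells first; ``spec.n_runs``
    encoders are trained on the training batch alone with distinct
    seeds; each encodes the full dataset, which is embedded, clustered
    and scored. The best run by ARI (silhouette when no cell-type labels
    exist) is reported alongside all per-run records.
    """
    downstream = downstream or DownstreamConfig()
    if isinstance(chain, str):
        chain = TransformChain.from_name(chain)
    batches = X_all.batches.to_numpy()
    if train_batch not in set(batches):
        raise ValueError(f"train batch {train_batch!r} not present in metadata")
    Xt = apply_chain(X_all, chain)
    train_mask = batches == train_batch
    labels_all = X_all.labels("cell_type")
    labels_all = None if labels_all is None else labels_all.to_numpy()
    train_labels = None if labels_all is None else labels_all[train_mask]

    per_run: list[MetricsRecord] = []
    best: MetricsRecord | None = None
    for run in range(spec.n_runs):
        run_spec = replace(spec, seed=spec.seed + run)
        enc = train_encoder(Xt.values[train_mask], run_spec, labels=train_labels)
        latent = enc.encode(Xt.values)
        d = min(2, latent.shape[1])
        emb = (
            embed(latent, downstream.embed_method, seed=downstream.seed)
            if latent.shape[1] > 2
            else embed(latent, f"pca{d}", seed=downstream.seed)
        )
        if labels_all is not None:
            score_fn = ari_scorer(labels_all)
            n_ref = len(np.unique(labels_all))
        else:
            score_fn = silhouette_scorer()
            n_ref = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = cluster(
                emb,
                downstream.cluster_algorithm,
                score_fn,
                n_reference_labels=n_ref,
                seed=downstream.seed,
            )
        rec = compute_metrics(emb.coords, res.labels, batch_ids=batches, true_labels=labels_all)
        per_run.append(rec)
        key = rec.ari if rec.ari is not None else rec.silhouette
        best_key = None if best is None else (best.ari if best.ari is not None else best.silhouette)
        if best is None or (key is not None and key > best_key):
            best = rec
    return CrossBatchResult(
        best=best,
        per_run=per_run,
        train_batch=train_batch,
        chain_name=chain.name,
        model_name=spec.model_name,
    )
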