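"""Beta-annealed variational autoencoder for 64x64x3 cell crops.

The encoder is five stride-2 3x3 convolutions with 32, 64, 128, 256 and
512 filters (64 -> 2 spatial), flattened into a 64-dimensional Gaussian
posterior; the decoder mirrors it with five stride-2 transposed
convolutions.  Training minimizes

    L = ||x - x_hat||^2_sum / batch  +  beta * KL(q(z|x) || N(0, I)) / batch

with Adam (default learning rate 5e-4, batch size 16) and a per-batch
linear KL-weight ramp: beta starts at 0.001 and grows by 0.001 every
batch until it saturates at 2.0 for the rest of training.  Early stopping
watches the validation loss.  All randomness (init, shuffling, posterior
sampling) derives from the config seed, so identical runs are identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ..errors import ConfigError, DataError, NumericError
from .crops import CROP_SIZE, Crop, crops_to_array
from .nn import Adam, Conv2D, ConvTranspose2D, Dense, ReLU, zero_grads


@dataclass
class BetaSchedule:
    """Linear per-batch KL-weight ramp, clamped at ``beta_max``."""

    beta_start: float = 0.001
    beta_step: float = 0.001
    beta_max: float = 2.0

    def __post_init__(self) -> None:
        if not 0 < self.beta_start <= self.beta_max:
            raise ConfigError("require 0 < beta_start <= beta_max")
        if self.beta_step <= 0:
            raise ConfigError("beta_step must be positive")


def beta_at(batch_index: int, schedule: BetaSchedule = BetaSchedule()) -> float:
    """KL weight used for batch ``batch_index`` (0-based).

    Batch 0 trains at ``beta_start``; each later batch adds ``beta_step``
    until the ramp saturates at ``beta_max``.
    """
    if batch_index < 0:
        raise ConfigError("batch_index must be nonnegative")
    return min(schedule.beta_max, schedule.beta_start + batch_index * schedule.beta_step)


@dataclass
class VAEConfig:
    encoder_filters: tuple[int, ...] = (32, 64, 128, 256, 512)
    latent_dim: int = 64
    batch_size: int = 16
    learning_rate: float = 5e-4
    max_epochs: int = 100
    patience: int = 10
    min_delta: float = 0.0
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim < 1:
            raise ConfigError("latent_dim must be >= 1")
        if not self.encoder_filters:
            raise ConfigError("encoder_filters must be nonempty")
        if not 0 < self.validation_fraction < 0.5:
            raise ConfigError("validation_fraction must lie in (0, 0.5)")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ConfigError("batch_size and max_epochs must be positive")
        if (CROP_SIZE >> len(self.encoder_filters)) < 1:
            raise ConfigError("too many encoder layers for a 64-px crop")


@dataclass
class EmbeddingSet:
    """Posterior-mean embeddings with aligned annotations."""

    matrix: np.ndarray  # (n, latent_dim)
    labels: list[str]
    provenance: list[tuple[str, int]]
    umap_coords: np.ndarray | None = None
    feature_table: object | None = None  # pandas.DataFrame when populated

    def __post_init__(self) -> None:
        if len(self.labels) != self.matrix.shape[0]:
            raise DataError("labels not aligned with embedding matrix")
        if len(self.provenance) != self.matrix.shape[0]:
            raise DataError("provenance not aligned with embedding matrix")


class BetaVAE:
    """The convolutional encoder/decoder pair with explicit training step."""

    def __init__(self, config: VAEConfig, rng: np.random.Generator | None = None) -> None:
        self.config = config
        #: divisor applied to inputs before encoding; set by train_vae so
        #: crops enter the network at unit variance (keeps the
        #: reconstruction and KL terms on commensurate scales, letting the
        #: beta ramp actually prune nuisance latent dimensions)
        self.input_scale = 1.0
        rng = rng or np.random.default_rng(config.seed)
        filters = config.encoder_filters
        self.enc_layers: list = []
        cin = 3
        for cout in filters:
            self.enc_layers.append(Conv2D(rng, cin, cout, stride=2))
            self.enc_layers.append(ReLU())
            cin = cout
        self.spatial = CROP_SIZE >> len(filters)
        self.flat = self.spatial * self.spatial * filters[-1]
        self.fc_mu = Dense(rng, self.flat, config.latent_dim)
        self.fc_logvar = Dense(rng, self.flat, config.latent_dim)
        self.fc_dec = Dense(rng, config.latent_dim, self.flat)
        self.dec_relu = ReLU()
        self.dec_layers: list = []
        rev = list(filters[::-1][1:]) + [3]
        cin = filters[-1]
        for i, cout in enumerate(rev):
            self.dec_layers.append(ConvTranspose2D(rng, cin, cout, stride=2))
            if i < len(rev) - 1:
                self.dec_layers.append(ReLU())
            cin = cout

    # -- plumbing -----------------------------------------------------------
    def _all_layers(self) -> list:
        return (
            self.enc_layers
            + [self.fc_mu, self.fc_logvar, self.fc_dec, self.dec_relu]
            + self.dec_layers
        )

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self._all_layers() for p in layer.params()]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self._all_layers() for g in layer.grads()]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        for p, w in zip(self.parameters(), weights):
            p[...] = w

    # -- forward / backward -------------------------------------------------
    def encode_params(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        h = x
        for layer in self.enc_layers:
            h = layer.forward(h)
        h = h.reshape(h.shape[0], self.flat)
        return self.fc_mu.forward(h), self.fc_logvar.forward(h)

    def decode(self, z: np.ndarray) -> np.ndarray:
        h = self.dec_relu.forward(self.fc_dec.forward(z))
        n = z.shape[0]
        h = h.reshape(n, self.spatial, self.spatial, -1)
        for layer in self.dec_layers:
            h = layer.forward(h)
        return h

    def loss_and_grad(
        self, x: np.ndarray, beta: float, rng: np.random.Generator | None
    ) -> dict[str, float]:
        """One forward/backward pass; gradients accumulate on the layers.

        ``rng=None`` disables posterior sampling (z = mu), used for
        validation passes.
        """
        n = x.shape[0]
        mu, logvar = self.encode_params(x)
        logvar = np.clip(logvar, -15.0, 15.0)
        std = np.exp(0.5 * logvar)
        eps = (
            rng.standard_normal(mu.shape).astype(np.float32)
            if rng is not None
            else np.zeros_like(mu)
        )
        z = mu + std * eps
        xhat = self.decode(z)

        diff = xhat - x
        recon = float((diff**2).sum()) / n
        kl = float((-0.5 * (1.0 + logvar - mu**2 - np.exp(logvar))).sum()) / n
        losses = {"recon": recon, "kl": kl, "total": recon + beta * kl}
        if not np.isfinite(losses["total"]):
            raise NumericError("non-finite training loss; lower the learning rate")

        if rng is None:
            return losses  # evaluation only

        dxhat = (2.0 / n) * diff
        # grads through the decoder first, to recover dz
        dh = dxhat
        for layer in reversed(self.dec_layers):
            dh = layer.backward(dh)
        dh = dh.reshape(n, self.flat)
        dz = self.fc_dec.backward(self.dec_relu.backward(dh))

        dmu = dz + (beta / n) * mu
        dlogvar = dz * eps * 0.5 * std + (beta / n) * 0.5 * (np.exp(logvar) - 1.0)
        dflat = self.fc_mu.backward(dmu) + self.fc_logvar.backward(dlogvar)
        dh = dflat.reshape(n, self.spatial, self.spatial, -1)
        for layer in reversed(self.enc_layers):
            dh = layer.backward(dh)
        return losses


def train_vae(
    crops: Sequence[Crop],
    config: VAEConfig | None = None,
    schedule: BetaSchedule | None = None,
) -> tuple[BetaVAE, list[dict]]:
    """Train the autoencoder on a crop set; returns (model, history).

    History holds one record per epoch: train/validation reconstruction,
    KL and total losses plus the beta in force at the epoch's last batch.
    Early stopping restores the best-validation weights.
    """
    config = config or VAEConfig()
    schedule = schedule or BetaSchedule()
    x = crops_to_array(list(crops))
    n = x.shape[0]
    if n < 2 * config.batch_size:
        raise DataError(
            f"need at least {2 * config.batch_size} crops to train, got {n}"
        )

    rng = np.random.default_rng(config.seed)
    scale = float(x.std())
    if scale > 0:
        x = x / scale
    else:
        scale = 1.0
    order = rng.permutation(n)
    n_val = max(config.batch_size, int(round(n * config.validation_fraction)))
    val_x = x[order[:n_val]]
    train_x = x[order[n_val:]]
    n_train = train_x.shape[0]
    if n_train < config.batch_size:
        raise DataError("validation split leaves fewer than one training batch")

    model = BetaVAE(config, rng=np.random.default_rng(rng.integers(2**31)))
    model.input_scale = scale
    optimizer = Adam(model.parameters(), lr=config.learning_rate)

    history: list[dict] = []
    best_val = np.inf
    best_weights = model.get_weights()
    stale = 0
    batch_index = 0
    n_batches = n_train // config.batch_size

    for epoch in range(config.max_epochs):
        perm = rng.permutation(n_train)
        tr = {"recon": 0.0, "kl": 0.0, "total": 0.0}
        beta = beta_at(batch_index, schedule)
        for b in range(n_batches):
            idx = perm[b * config.batch_size : (b + 1) * config.batch_size]
            beta = beta_at(batch_index, schedule)
            zero_grads(model._all_layers())
            losses = model.loss_and_grad(train_x[idx], beta, rng)
            optimizer.step(model.gradients())
            batch_index += 1
            for key in tr:
                tr[key] += losses[key]
        for key in tr:
            tr[key] /= n_batches

        val = model.loss_and_grad(val_x, beta, rng=None)
        history.append(
            {
                "epoch": epoch,
                "beta": beta,
                "train_recon": tr["recon"],
                "train_kl": tr["kl"],
                "train_loss": tr["total"],
                "val_recon": val["recon"],
                "val_kl": val["kl"],
                "val_loss": val["total"],
            }
        )
        if val["total"] < best_val - config.min_delta:
            best_val = val["total"]
            best_weights = model.get_weights()
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break

    model.set_weights(best_weights)
    return model, history


def encode(
    model: BetaVAE,
    crops: Sequence[Crop],
    feature_table: object | None = None,
    batch: int = 64,
) -> EmbeddingSet:
    """Posterior-mean embeddings for a crop sequence, rows in crop order."""
    crops = list(crops)
    x = crops_to_array(crops) / getattr(model, "input_scale", 1.0)
    mats = []
    for i in range(0, x.shape[0], batch):
        mu, _ = model.encode_params(x[i : i + batch])
        mats.append(mu)
    return EmbeddingSet(
        matrix=np.concatenate(mats, axis=0),
        labels=[c.phase for c in crops],
        provenance=[c.provenance for c in crops],
        feature_table=feature_table,
    )
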