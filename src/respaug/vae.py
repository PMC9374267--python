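"""Three variational autoencoders over normalized log-mel spectrograms.

* ``mlp`` — dense encoder/decoder (two ReLU hidden layers of
  ``intermediate_dim`` each side, sigmoid output), Adam.
* ``cnn`` — two stride-2 convolutions (16, 32 filters, kernel 3) and a
  dense bottleneck in the encoder; dense + reshape + three stride-2
  transposed convolutions (32, 16, 1) in the decoder, sigmoid output,
  RMSprop.  The encoder downsamples x4 while the decoder upsamples x8 from
  its reshape grid; the dense bottleneck reconciles the factors.
* ``conditional`` — the cnn topology trained on all minority classes
  jointly, with the one-hot class label broadcast as constant channels at
  the encoder input and concatenated to the latent code at the decoder.

All variants use a 2-dimensional latent space and are trained by
minimizing the negative evidence lower bound: a sum-over-pixels squared
reconstruction error plus ``beta`` times the KL divergence of the encoder
posterior from the standard-normal prior (``beta = 1`` by default).

A desk-scale mode average-pools spectrograms (e.g. 128x256 -> 64x64)
before training and upsamples generated samples back, trading resolution
for speed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor
from .features import MelSpec, MelSpecParams
from .io import MINORITY_LABELS

VARIANTS = ("mlp", "cnn", "conditional")
_DEFAULT_OPTIMIZERS = {"mlp": "adam", "cnn": "rmsprop",
                       "conditional": "rmsprop"}


@dataclass
class VAEConfig:
    variant: str
    latent_dim: int = 2
    intermediate_dim: int = 512
    conv_filters: tuple[int, int] = (16, 32)
    bottleneck_dim: int = 128
    spec_shape: tuple[int, int] = (128, 256)
    pool: tuple[int, int] = (1, 1)  # average-pool factor before training
    optimizer: str | None = None
    learning_rate: float = 1e-3
    beta: float = 1.0
    epochs: int = 100
    batch_size: int = 32
    seed: int = 0
    n_classes: int = len(MINORITY_LABELS)
    class_labels: tuple[str, ...] = MINORITY_LABELS

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(
                f"unknown VAE variant {self.variant!r}; expected one of "
                f"{VARIANTS}"
            )
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.optimizer is None:
            self.optimizer = _DEFAULT_OPTIMIZERS[self.variant]
        h, w = self.model_shape
        if self.variant != "mlp" and (h % 8 or w % 8):
            raise ValueError(
                f"convolutional variants need spectrogram dimensions "
                f"divisible by 8 after pooling, got {h}x{w}"
            )

    @property
    def model_shape(self) -> tuple[int, int]:
        return (self.spec_shape[0] // self.pool[0],
                self.spec_shape[1] // self.pool[1])


@dataclass
class EncoderOutput:
    mu: np.ndarray
    logvar: np.ndarray


def reparameterize(enc: EncoderOutput, rng: np.random.Generator) -> np.ndarray:
    """z = mu + exp(logvar/2) * eps with eps ~ N(0, I)."""
    eps = rng.standard_normal(np.shape(enc.mu))
    return enc.mu + np.exp(0.5 * np.asarray(enc.logvar)) * eps


def kl_divergence(enc: EncoderOutput) -> float:
    """KL(N(mu, diag exp(logvar)) || N(0, I)); >= 0, zero iff standard normal.

    For batched inputs the KL is summed over the latent axis and averaged
    over the batch.
    """
    mu, lv = np.atleast_2d(enc.mu), np.atleast_2d(enc.logvar)
    per = 0.5 * (mu ** 2 + np.exp(lv) - 1.0 - lv).sum(axis=-1)
    # exp(x)-1-x >= 0 analytically; clamp the float rounding at tiny |x|
    return max(float(per.mean()), 0.0)


def vae_loss(x: np.ndarray, x_hat: np.ndarray, enc: EncoderOutput,
             beta: float = 1.0) -> float:
    """Negative ELBO: sum-over-pixels squared error + beta * KL."""
    x, x_hat = np.asarray(x), np.asarray(x_hat)
    if x.shape != x_hat.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {x_hat.shape}")
    flat = (x - x_hat).reshape(x.shape[0], -1) if x.ndim > 2 else \
        (x - x_hat).reshape(1, -1)
    recon = float((flat ** 2).sum(axis=-1).mean())
    return recon + beta * kl_divergence(enc)


# -- model definitions -------------------------------------------------------

class _MLPVAE(nn.Module):
    def __init__(self, config: VAEConfig, rng):
        h, w = config.model_shape
        d, inter, z = h * w, config.intermediate_dim, config.latent_dim
        self.enc1 = nn.Dense(d, inter, rng, activation="relu")
        self.enc2 = nn.Dense(inter, inter, rng, activation="relu")
        self.mu_head = nn.Dense(inter, z, rng)
        self.lv_head = nn.Dense(inter, z, rng)
        self.dec1 = nn.Dense(z, inter, rng, activation="relu")
        self.dec2 = nn.Dense(inter, inter, rng, activation="relu")
        self.out = nn.Dense(inter, d, rng, activation="sigmoid")
        self.shape = (h, w)

    def encode(self, x: Tensor):
        hdn = self.enc2(self.enc1(x.reshape(x.shape[0], -1)))
        return self.mu_head(hdn), self.lv_head(hdn)

    def decode(self, z: Tensor) -> Tensor:
        h, w = self.shape
        out = self.out(self.dec2(self.dec1(z)))
        return out.reshape(out.shape[0], h, w)


class _CNNVAE(nn.Module):
    conditional = False

    def __init__(self, config: VAEConfig, rng):
        h, w = config.model_shape
        f1, f2 = config.conv_filters
        z = config.latent_dim
        in_c = 1 + (config.n_classes if self.conditional else 0)
        self.conv1 = nn.Conv2D(in_c, f1, 3, 2, rng, activation="relu")
        self.conv2 = nn.Conv2D(f1, f2, 3, 2, rng, activation="relu")
        flat = f2 * (h // 4) * (w // 4)
        self.enc_dense = nn.Dense(flat, config.bottleneck_dim, rng,
                                  activation="relu")
        self.mu_head = nn.Dense(config.bottleneck_dim, z, rng)
        self.lv_head = nn.Dense(config.bottleneck_dim, z, rng)
        self.grid = (32, h // 8, w // 8)
        z_in = z + (config.n_classes if self.conditional else 0)
        self.dec_dense = nn.Dense(z_in, int(np.prod(self.grid)), rng,
                                  activation="relu")
        self.deconv1 = nn.ConvTranspose2D(32, 32, rng, activation="relu")
        self.deconv2 = nn.ConvTranspose2D(32, 16, rng, activation="relu")
        self.deconv3 = nn.ConvTranspose2D(16, 1, rng, activation="sigmoid")
        self.shape = (h, w)

    def encode(self, x: Tensor, onehot: np.ndarray | None = None):
        n = x.shape[0]
        h, w = self.shape
        img = x.reshape(n, 1, h, w)
        if self.conditional:
            chans = np.broadcast_to(
                onehot[:, :, None, None], (n, onehot.shape[1], h, w)
            )
            img = nn.concat([img, Tensor(chans)], axis=1)
        hdn = self.enc_dense(
            self.conv2(self.conv1(img)).reshape(n, -1)
        )
        return self.mu_head(hdn), self.lv_head(hdn)

    def decode(self, z: Tensor, onehot: np.ndarray | None = None) -> Tensor:
        if self.conditional:
            z = nn.concat([z, Tensor(onehot)], axis=1)
        g = self.dec_dense(z).reshape(z.shape[0], *self.grid)
        out = self.deconv3(self.deconv2(self.deconv1(g)))
        return out.reshape(out.shape[0], *self.shape)


class _ConditionalVAE(_CNNVAE):
    conditional = True


def build_vae(config: VAEConfig) -> nn.Module:
    """Construct an untrained VAE of the configured variant."""
    rng = np.random.default_rng(config.seed)
    if config.variant == "mlp":
        return _MLPVAE(config, rng)
    if config.variant == "cnn":
        return _CNNVAE(config, rng)
    return _ConditionalVAE(config, rng)


# -- training ----------------------------------------------------------------

@dataclass
class TrainedVAE:
    config: VAEConfig
    model: nn.Module
    loss_history: list[float]
    class_label: str | None  # None for the conditional variant
    mel_params: MelSpecParams = None

    def state_dict(self):
        return self.model.state_dict()


def _pool(values: np.ndarray, pool: tuple[int, int]) -> np.ndarray:
    ph, pw = pool
    if ph == 1 and pw == 1:
        return values
    h, w = values.shape[-2:]
    return values.reshape(*values.shape[:-2], h // ph, ph, w // pw, pw
                          ).mean(axis=(-3, -1))


def _unpool(values: np.ndarray, pool: tuple[int, int]) -> np.ndarray:
    if pool == (1, 1):
        return values
    return np.kron(values, np.ones(pool))


def _onehot(labels, class_labels) -> np.ndarray:
    index = {c: i for i, c in enumerate(class_labels)}
    out = np.zeros((len(labels), len(class_labels)))
    for i, lab in enumerate(labels):
        out[i, index[lab]] = 1.0
    return out


def train_vae(model: nn.Module, specs: list[MelSpec],
              config: VAEConfig) -> TrainedVAE:
    """Train a VAE on normalized mel spectrograms.

    Unconditional variants require every spectrogram to carry the same
    minority-class label (a per-class model must never see another class,
    and COPD, the majority class, is never augmented).  The conditional
    variant expects all minority classes.
    """
    if not specs:
        raise ValueError("empty training set")
    labels = [s.label for s in specs]
    classes = sorted(set(labels))
    if config.variant in ("mlp", "cnn"):
        if len(classes) != 1:
            raise ValueError(
                f"unconditional VAE must be trained on exactly one class, "
                f"got {classes}"
            )
        if classes[0] == "COPD":
            raise ValueError(
                "unconditional VAEs augment minority classes; refusing to "
                "train on the majority class COPD"
            )
        class_label = classes[0]
        onehots = None
    else:
        if len(classes) == 1:
            warnings.warn(
                "conditional VAE trained on a single class; conditioning "
                "will carry no information",
                stacklevel=2,
            )
        class_label = None
        onehots = _onehot(labels, config.class_labels)

    X = _pool(np.stack([s.values for s in specs]), config.pool)
    rng = np.random.default_rng(config.seed)
    params = model.parameters()
    opt = nn.make_optimizer(config.optimizer, params, config.learning_rate)
    n = len(specs)
    history = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb = Tensor(X[idx])
            hot = onehots[idx] if onehots is not None else None
            mu, lv = (model.encode(xb, hot) if hot is not None
                      else model.encode(xb))
            eps = rng.standard_normal(mu.shape)
            z = mu + (lv * 0.5).exp() * Tensor(eps)
            xh = model.decode(z, hot) if hot is not None else model.decode(z)
            diff = (xh - xb).reshape(len(idx), -1)
            recon = (diff * diff).sum(axis=1).mean()
            kl = ((mu * mu + lv.exp() - 1.0 - lv).sum(axis=1) * 0.5).mean()
            loss = recon + config.beta * kl
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        history.append(epoch_loss / n_batches)
    return TrainedVAE(config, model, history, class_label,
                      mel_params=specs[0].params)


def generate_samples(vae: TrainedVAE, n: int,
                     class_label: str | None = None,
                     rng: np.random.Generator | None = None
                     ) -> list[MelSpec]:
    """Sample ``n`` spectrograms by decoding standard-normal latent draws."""
    if n <= 0:
        raise ValueError("n must be positive")
    cfg = vae.config
    if cfg.variant == "conditional":
        if class_label is None:
            raise ValueError("conditional VAE needs a class_label to sample")
        label = class_label
    else:
        if class_label is not None and class_label != vae.class_label:
            raise ValueError(
                f"this VAE instance generates {vae.class_label!r}, "
                f"not {class_label!r}"
            )
        label = vae.class_label
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    out = []
    model = vae.model
    batch = 64
    with nn.no_grad():
        for start in range(0, n, batch):
            k = min(batch, n - start)
            z = Tensor(rng.standard_normal((k, cfg.latent_dim)))
            if cfg.variant == "conditional":
                hot = _onehot([label] * k, cfg.class_labels)
                values = model.decode(z, hot).data
            else:
                values = model.decode(z).data
            values = _unpool(values, cfg.pool)
            for v in values:
                out.append(MelSpec(np.clip(v, 0.0, 1.0), vae.mel_params,
                                   label))
    return out
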