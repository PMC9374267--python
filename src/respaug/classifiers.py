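"""Five MFCC-based lung-sound classifiers: MLP, CNN, LSTM, and compact
ResNet-style / EfficientNet-style convolutional backbones with dense heads.

All models consume a 13 x 130 MFCC matrix (6 s segment at 22050 Hz) and
emit 7 class probabilities through a softmax layer.  They are trained with
categorical cross-entropy, Adam, learning rate 1e-4, and standardized
inputs (per-coefficient mean/std fitted on the training set).

The two backbone models are randomly initialised, scaled-down analogues of
their namesakes (no pretrained weights are used); the EfficientNet-style
backbone reduces the (13, 130) input by five stride-2 stages to a
(1, 5, 1280) map, so its flattened width is 6400 in the full preset.

A ``desk`` preset shrinks widths and epochs for laptop-scale experiments;
the ``paper`` preset uses the full layer widths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor
from .io import CLASS_LABELS

ARCHS = ("mlp", "cnn", "lstm", "resnet50", "efficientnetb0")

_PRESETS = {
    "paper": {
        "mlp_widths": (512, 512, 512, 1024, 512, 512, 512),
        "mlp_dropout": (0.1, 0.15, 0.2, 0.25, 0.3, 0.35, 0.4),
        "cnn_filters": 32,
        "cnn_dense": (64, 128, 128, 64),
        "lstm_units": (64, 128),
        "lstm_dense": (64, 256, 128),
        "lstm_time_stride": 1,
        "resnet_stem": 32,
        "resnet_blocks": (64, 128, 256),
        "resnet_dense": (256, 128, 64, 512, 512, 512),
        "resnet_dropout": (0.1, 0.15, 0.2, 0.25, 0.3, 0.3),
        "effnet_channels": (32, 16, 24, 40, 80),
        "effnet_head_channels": 1280,
        "effnet_dense": (256, 128, 64),
        "effnet_dropout": 0.5,
    },
    "desk": {
        "mlp_widths": (64, 64, 128, 64),
        "mlp_dropout": (0.1, 0.1, 0.2, 0.1),
        "cnn_filters": 8,
        "cnn_dense": (32, 32),
        "lstm_units": (16, 24),
        "lstm_dense": (32,),
        "lstm_time_stride": 4,
        "resnet_stem": 8,
        "resnet_blocks": (16,),
        "resnet_dense": (32, 32),
        "resnet_dropout": (0.1, 0.1),
        "effnet_channels": (8, 8, 16, 16, 32),
        "effnet_head_channels": 64,
        "effnet_dense": (32, 32),
        "effnet_dropout": 0.3,
    },
}

INPUT_SHAPE = (13, 130)


@dataclass
class ClfConfig:
    arch: str
    n_classes: int = 7
    learning_rate: float = 1e-4
    optimizer: str = "adam"
    epochs: int = 100
    batch_size: int = 32
    n_trials: int = 3
    seed: int = 0
    preset: str = "paper"
    class_labels: tuple[str, ...] = CLASS_LABELS

    def __post_init__(self):
        if self.arch not in ARCHS:
            raise ValueError(f"unknown arch {self.arch!r}; expected {ARCHS}")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.preset not in _PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")

    @property
    def hyper(self) -> dict:
        return _PRESETS[self.preset]


class _MLP(nn.Module):
    def __init__(self, cfg: ClfConfig, rng):
        h = cfg.hyper
        dims = [INPUT_SHAPE[0] * INPUT_SHAPE[1], *h["mlp_widths"]]
        self.layers = [
            nn.Dense(a, b, rng, activation="relu")
            for a, b in zip(dims[:-1], dims[1:])
        ]
        self.drops = [nn.Dropout(r, rng) for r in h["mlp_dropout"]]
        self.head = nn.Dense(dims[-1], cfg.n_classes, rng)

    def forward(self, x: Tensor) -> Tensor:
        out = x.reshape(x.shape[0], -1)
        for layer, drop in zip(self.layers, self.drops):
            out = drop(layer(out))
        return self.head(out)


class _CNN(nn.Module):
    def __init__(self, cfg: ClfConfig, rng):
        h = cfg.hyper
        f = h["cnn_filters"]
        self.conv1 = nn.Conv2D(1, f, 3, 1, rng, activation="relu")
        self.conv2 = nn.Conv2D(f, f, 2, 1, rng, padding="valid",
                               activation="relu")
        mh, mw = INPUT_SHAPE[0] // 2, INPUT_SHAPE[1] // 2  # after pool 1
        mh, mw = (mh - 1) // 2, (mw - 1) // 2  # conv2 'valid' + pool 2
        dims = [f * mh * mw, *h["cnn_dense"]]
        self.dense = [
            nn.Dense(a, b, rng, activation="relu")
            for a, b in zip(dims[:-1], dims[1:])
        ]
        self.head = nn.Dense(dims[-1], cfg.n_classes, rng)

    def forward(self, x: Tensor) -> Tensor:
        out = nn.max_pool2d(self.conv1(x))
        out = nn.max_pool2d(self.conv2(out))
        out = out.reshape(out.shape[0], -1)
        for layer in self.dense:
            out = layer(out)
        return self.head(out)


class _LSTMClf(nn.Module):
    def __init__(self, cfg: ClfConfig, rng):
        h = cfg.hyper
        u1, u2 = h["lstm_units"]
        self.stride = h["lstm_time_stride"]
        self.lstm1 = nn.LSTM(INPUT_SHAPE[0], u1, rng)
        self.lstm2 = nn.LSTM(u1, u2, rng)
        dims = [u2, *h["lstm_dense"]]
        self.dense = [
            nn.Dense(a, b, rng, activation="relu")
            for a, b in zip(dims[:-1], dims[1:])
        ]
        self.head = nn.Dense(dims[-1], cfg.n_classes, rng)

    def forward(self, x: Tensor) -> Tensor:
        # (N, 1, 13, T) -> sequence (N, T', 13)
        n = x.shape[0]
        seq = x.reshape(n, *INPUT_SHAPE).transpose((0, 2, 1))
        if self.stride > 1:
            seq = seq[:, ::self.stride, :]
        out = self.lstm2(self.lstm1(seq))
        out = out[:, -1, :]
        for layer in self.dense:
            out = layer(out)
        return self.head(out)


class _ResBlock(nn.Module):
    def __init__(self, in_c, out_c, rng):
        self.conv1 = nn.Conv2D(in_c, out_c, 3, 2, rng)
        self.bn1 = nn.BatchNorm(out_c, axis=1)
        self.conv2 = nn.Conv2D(out_c, out_c, 3, 1, rng)
        self.bn2 = nn.BatchNorm(out_c, axis=1)
        self.proj = nn.Conv2D(in_c, out_c, 1, 2, rng)

    def forward(self, x: Tensor) -> Tensor:
        out = self.bn1(self.conv1(x)).relu()
        out = self.bn2(self.conv2(out))
        return (out + self.proj(x)).relu()


class _ResNetStyle(nn.Module):
    def __init__(self, cfg: ClfConfig, rng):
        h = cfg.hyper
        stem = h["resnet_stem"]
        self.stem = nn.Conv2D(1, stem, 3, 2, rng, activation="relu")
        chans = [stem, *h["resnet_blocks"]]
        self.blocks = [
            _ResBlock(a, b, rng) for a, b in zip(chans[:-1], chans[1:])
        ]
        sh, sw = INPUT_SHAPE
        for _ in range(1 + len(self.blocks)):
            sh, sw = (sh + 1) // 2, (sw + 1) // 2
        flat = chans[-1] * sh * sw
        self.bn = nn.BatchNorm(flat)
        dims = [flat, *h["resnet_dense"]]
        self.dense = [
            nn.Dense(a, b, rng, activation="relu")
            for a, b in zip(dims[:-1], dims[1:])
        ]
        self.drops = [nn.Dropout(r, rng) for r in h["resnet_dropout"]]
        self.head = nn.Dense(dims[-1], cfg.n_classes, rng)

    def forward(self, x: Tensor) -> Tensor:
        out = self.stem(x)
        for block in self.blocks:
            out = block(out)
        out = self.bn(out.reshape(out.shape[0], -1))
        for layer, drop in zip(self.dense, self.drops):
            out = drop(layer(out))
        return self.head(out)


class _EffNetStyle(nn.Module):
    def __init__(self, cfg: ClfConfig, rng):
        h = cfg.hyper
        chans = h["effnet_channels"]
        self.convs = []
        in_c = 1
        for c in chans:
            self.convs.append(nn.Conv2D(in_c, c, 3, 2, rng,
                                        activation="relu"))
            in_c = c
        self.pointwise = nn.Conv2D(in_c, h["effnet_head_channels"], 1, 1,
                                   rng, activation="relu")
        sh, sw = INPUT_SHAPE
        for _ in chans:
            sh, sw = (sh + 1) // 2, (sw + 1) // 2
        self.flat_width = h["effnet_head_channels"] * sh * sw
        self.bn = nn.BatchNorm(self.flat_width)
        self.drop = nn.Dropout(h["effnet_dropout"], rng)
        dims = [self.flat_width, *h["effnet_dense"]]
        self.dense = [
            nn.Dense(a, b, rng, activation="relu")
            for a, b in zip(dims[:-1], dims[1:])
        ]
        self.head = nn.Dense(dims[-1], cfg.n_classes, rng)

    def forward(self, x: Tensor) -> Tensor:
        out = x
        for conv in self.convs:
            out = conv(out)
        out = self.pointwise(out)
        out = self.drop(self.bn(out.reshape(out.shape[0], -1)))
        for layer in self.dense:
            out = layer(out)
        return self.head(out)


_BUILDERS = {
    "mlp": _MLP,
    "cnn": _CNN,
    "lstm": _LSTMClf,
    "resnet50": _ResNetStyle,
    "efficientnetb0": _EffNetStyle,
}


def build_classifier(config: ClfConfig,
                     seed: int | None = None) -> nn.Module:
    rng = np.random.default_rng(config.seed if seed is None else seed)
    return _BUILDERS[config.arch](config, rng)


@dataclass
class TrainedClassifier:
    config: ClfConfig
    models: list[nn.Module]
    histories: list[list[float]]
    scaler_mean: np.ndarray = None
    scaler_std: np.ndarray = None


def _standardize_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # per-MFCC-coefficient statistics over samples and frames
    mean = X.mean(axis=(0, 2), keepdims=True)
    std = X.std(axis=(0, 2), keepdims=True)
    return mean, np.maximum(std, 1e-8)


def param_count(model: nn.Module) -> int:
    return int(sum(p.data.size for p in model.parameters()))


def train_classifier(train_set: list[tuple[np.ndarray, str]],
                     config: ClfConfig,
                     model: nn.Module | None = None) -> TrainedClassifier:
    """Run ``n_trials`` independent trainings (seeds seed+trial).

    ``train_set`` holds (13 x 130 MFCC matrix, class label) pairs; every
    class in the config's vocabulary must be present.  A caller-supplied
    ``model`` is used for the first trial; later trials are re-initialised.
    """
    labels = [lab for _, lab in train_set]
    present = set(labels)
    for c in config.class_labels:
        if c not in present:
            raise ValueError(f"class {c!r} absent from training data")
    X = np.stack([m for m, _ in train_set]).astype(np.float64)
    index = {c: i for i, c in enumerate(config.class_labels)}
    onehot = np.eye(config.n_classes)[[index[lab] for lab in labels]]
    mean, std = _standardize_fit(X)
    Xs = ((X - mean) / std)[:, None, :, :]  # NCHW

    models, histories = [], []
    for trial in range(config.n_trials):
        trial_seed = config.seed + trial
        net = (model if model is not None and trial == 0
               else build_classifier(config, seed=trial_seed))
        rng = np.random.default_rng(trial_seed)
        net.set_training(True)
        opt = nn.make_optimizer(config.optimizer, net.parameters(),
                                config.learning_rate)
        history = []
        n = len(train_set)
        for _ in range(config.epochs):
            order = rng.permutation(n)
            epoch_loss, n_batches = 0.0, 0
            for start in range(0, n, config.batch_size):
                idx = order[start:start + config.batch_size]
                logits = net(Tensor(Xs[idx]))
                loss = nn.softmax_cross_entropy(logits, onehot[idx])
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_loss += float(loss.data)
                n_batches += 1
            history.append(epoch_loss / n_batches)
        net.set_training(False)
        models.append(net)
        histories.append(history)
    return TrainedClassifier(config, models, histories,
                             scaler_mean=mean, scaler_std=std)


def predict(clf: TrainedClassifier, mfccs: list[np.ndarray],
            trial: int = 0) -> tuple[np.ndarray, list[str]]:
    """Class probabilities and argmax labels for a batch of MFCC matrices."""
    X = np.stack(mfccs).astype(np.float64)
    if X.shape[1:] != INPUT_SHAPE:
        raise ValueError(
            f"expected MFCC matrices of shape {INPUT_SHAPE}, got "
            f"{X.shape[1:]}"
        )
    Xs = ((X - clf.scaler_mean) / clf.scaler_std)[:, None, :, :]
    net = clf.models[trial]
    net.set_training(False)
    probs_all = []
    with nn.no_grad():
        for start in range(0, len(Xs), 256):
            logits = net(Tensor(Xs[start:start + 256]))
            probs_all.append(nn.softmax(logits.data))
    probs = np.concatenate(probs_all)
    labels = [clf.config.class_labels[i] for i in probs.argmax(axis=1)]
    return probs, labels
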