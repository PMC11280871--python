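"""Encoder-decoder networks for representative-beat segmentation.

Four variants share one symmetric geometry: a three-block convolutional
encoder (feature-map lengths 512 -> 256 -> 128 -> 64) and a mirrored
three-block decoder (64 -> 128 -> 256 -> 512) followed by an output
convolution with sigmoid activation producing three per-sample probability
maps (P-wave, QRS-complex, QT-interval).  Every convolution is stride-1
with "same" zero padding; encoder blocks end in max-pooling (size 2) and
decoder blocks in upsampling by value repetition (size 2).

variant "cednet"
    The plain network: convolutions C1..C7 only.
variant "lstm"
    One full-sequence LSTM layer (one memory cell per channel, Ch6 units)
    inserted after the third decoder upsampling, before C7.
variant "unet"
    Symmetric encoder maps are concatenated onto the decoder maps
    ([Ch4,Ch3], [Ch5,Ch2], [Ch6,Ch1]), so C5, C6 and C7 see doubled input
    width.
variant "resnet"
    C2..C6 are wrapped into residual blocks: y = ReLU(W2*ReLU(W1*x+b1)+b2+x),
    one extra convolution per block; pooling/upsampling applies to the
    block output.

The trainable-parameter total of each built model equals the closed-form
layer-wise sum ``count_trainable`` -- each convolution contributes
``Ch_i * (K_i * Ch_{i-1} + 1)``; the input standardization has no
trainable parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from ._nn import LSTM, Conv1D, Dropout, MaxPool, ReLU, Upsample, sigmoid
from .beat_model import N_SAMPLES, RepresentativeBeat, ValidationError

__all__ = ["VARIANTS", "ModelConfig", "InputTensor", "NetworkModel",
           "make_input", "build", "count_trainable"]

VARIANTS = ("cednet", "lstm", "unet", "resnet")


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters: variant, widths Ch1..Ch6, kernels K1..K7."""

    variant: str = "cednet"
    ch: tuple[int, ...] = (24,) * 6
    k: tuple[int, ...] = (8,) * 7
    ch_in: int = 13
    ch_out: int = 3
    pool_size: int = 2
    upsample_size: int = 2
    dropout_rate: float = 0.1

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValidationError(f"unknown variant {self.variant!r}")
        ch = tuple(int(c) for c in self.ch)
        k = tuple(int(x) for x in self.k)
        if len(ch) != 6 or len(k) != 7:
            raise ValidationError("need six channel widths and seven kernels")
        if min(ch) < 1 or min(k) < 1 or self.ch_in < 1 or self.ch_out < 1:
            raise ValidationError("widths and kernels must be >= 1")
        if self.variant == "resnet":
            # identity addition needs matching input/output widths on C2..C6
            ins = (ch[0], ch[1], ch[2], ch[3], ch[4])
            if tuple(ch[1:]) != ins:
                raise ValidationError(
                    "resnet requires Ch2..Ch6 to equal their block input width")
        object.__setattr__(self, "ch", ch)
        object.__setattr__(self, "k", k)

    def to_dict(self) -> dict:
        return {"variant": self.variant, "ch": list(self.ch),
                "k": list(self.k), "ch_in": self.ch_in,
                "ch_out": self.ch_out, "pool_size": self.pool_size,
                "upsample_size": self.upsample_size,
                "dropout_rate": self.dropout_rate}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(variant=d["variant"], ch=tuple(d["ch"]), k=tuple(d["k"]),
                   ch_in=d["ch_in"], ch_out=d["ch_out"],
                   pool_size=d["pool_size"],
                   upsample_size=d["upsample_size"],
                   dropout_rate=d["dropout_rate"])


@dataclass(frozen=True)
class InputTensor:
    """512x13 network input: 12 lead channels (uV) + time channel 1..512."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.shape != (N_SAMPLES, 13):
            raise ValidationError(f"input must be {N_SAMPLES}x13, got {v.shape}")
        object.__setattr__(self, "values", v)


def make_input(beat: RepresentativeBeat) -> InputTensor:
    """Stack the 12 leads with the linear time channel t = 1..512."""
    v = np.empty((N_SAMPLES, 13))
    v[:, :12] = beat.samples
    v[:, 12] = np.arange(1, N_SAMPLES + 1)
    return InputTensor(v)


def count_trainable(config: ModelConfig) -> int:
    """Closed-form trainable-parameter total of the configured network.

    Plain convolutions contribute ``Ch_i*(K_i*Ch_{i-1}+1)``; the unet
    concatenations double the input width of C5..C7; the lstm variant adds
    the recurrent gate parameters ``4*((Ch6+Ch6)*Ch6+Ch6)``; each residual
    block adds one extra convolution.  Input standardization contributes 0.
    """
    chs = [config.ch_in, *config.ch, config.ch_out]
    total = 0
    for i in range(7):
        cin = chs[i]
        if config.variant == "unet" and i >= 4:      # C5, C6, C7
            cin *= 2
        total += chs[i + 1] * (config.k[i] * cin + 1)
    if config.variant == "lstm":
        u = config.ch[5]
        total += 4 * ((u + u) * u + u)
    if config.variant == "resnet":
        for i in range(1, 6):                        # C2..C6
            total += chs[i + 1] * (config.k[i] * chs[i + 1] + 1)
    return total


class _PlainBlock:
    """conv -> ReLU -> dropout."""

    def __init__(self, cin, cout, k, rate, rng):
        self.conv = Conv1D(cin, cout, k, rng)
        self.relu = ReLU()
        self.drop = Dropout(rate)
        self.layers = [self.conv]

    def forward(self, x, train=False):
        return self.drop.forward(self.relu.forward(
            self.conv.forward(x, train), train), train)

    def backward(self, d):
        return self.conv.backward(self.relu.backward(self.drop.backward(d)))


class _ResidualBlock:
    """y = dropout(ReLU(conv_b(dropout(ReLU(conv_a(x)))) + x))."""

    def __init__(self, cin, cout, k, rate, rng):
        self.conv_a = Conv1D(cin, cout, k, rng)
        self.relu_a = ReLU()
        self.drop_a = Dropout(rate)
        self.conv_b = Conv1D(cout, cout, k, rng)
        self.relu_b = ReLU()
        self.drop_b = Dropout(rate)
        self.layers = [self.conv_a, self.conv_b]

    def forward(self, x, train=False):
        h = self.drop_a.forward(self.relu_a.forward(
            self.conv_a.forward(x, train), train), train)
        return self.drop_b.forward(self.relu_b.forward(
            self.conv_b.forward(h, train) + x, train), train)

    def backward(self, d):
        d = self.relu_b.backward(self.drop_b.backward(d))
        dh = self.conv_b.backward(d)
        dx = self.conv_a.backward(self.relu_a.backward(
            self.drop_a.backward(dh)))
        return dx + d          # identity skip


class NetworkModel:
    """A built network: config, parameter store, input standardization.

    The standardization statistics (per-channel mean/std over all 13 input
    channels, the time channel included) are fit once on training data via
    :meth:`fit_normalizer` and are not trainable, so the parameter total
    equals :func:`count_trainable`.
    """

    def __init__(self, config: ModelConfig, seed: int = 0) -> None:
        self.config = config
        rng = np.random.default_rng(seed)
        ch, k, rate = config.ch, config.k, config.dropout_rate
        unet = config.variant == "unet"
        res = config.variant == "resnet"
        Block = _ResidualBlock if res else _PlainBlock

        self.b1 = _PlainBlock(config.ch_in, ch[0], k[0], rate, rng)
        self.b2 = Block(ch[0], ch[1], k[1], rate, rng)
        self.b3 = Block(ch[1], ch[2], k[2], rate, rng)
        self.b4 = Block(ch[2], ch[3], k[3], rate, rng)
        self.b5 = Block(ch[3] * (2 if unet else 1), ch[4], k[4], rate, rng)
        self.b6 = Block(ch[4] * (2 if unet else 1), ch[5], k[5], rate, rng)
        self.lstm = LSTM(ch[5], ch[5], rng) if config.variant == "lstm" else None
        self.conv7 = Conv1D(ch[5] * (2 if unet else 1), config.ch_out,
                            k[6], rng)
        self.pools = [MaxPool(config.pool_size) for _ in range(3)]
        self.ups = [Upsample(config.upsample_size) for _ in range(3)]

        self.mu = np.zeros(config.ch_in)
        self.sd = np.ones(config.ch_in)

    # -- parameter plumbing -------------------------------------------------

    @property
    def blocks(self):
        return [self.b1, self.b2, self.b3, self.b4, self.b5, self.b6]

    def _param_layers(self):
        layers = [ly for blk in self.blocks for ly in blk.layers]
        if self.lstm is not None:
            layers.append(self.lstm)
        layers.append(self.conv7)
        return layers

    @property
    def n_params(self) -> int:
        return sum(ly.n_params for ly in self._param_layers())

    def parameters(self):
        return [p for ly in self._param_layers() for p in ly.params]

    def gradients(self):
        return [g for ly in self._param_layers() for g in ly.grads]

    def zero_grads(self) -> None:
        for ly in self._param_layers():
            ly.zero_grads()

    def set_dropout_rng(self, rng: np.random.Generator) -> None:
        for blk in self.blocks:
            for attr in ("drop", "drop_a", "drop_b"):
                layer = getattr(blk, attr, None)
                if layer is not None:
                    layer.rng = rng

    # -- normalization ------------------------------------------------------

    def fit_normalizer(self, inputs: np.ndarray) -> None:
        """Fit per-channel standardization on ``(N, 512, 13)`` raw inputs."""
        flat = inputs.reshape(-1, inputs.shape[-1])
        self.mu = flat.mean(axis=0)
        sd = flat.std(axis=0)
        self.sd = np.where(sd > 0, sd, 1.0)

    # -- forward / backward -------------------------------------------------

    def forward_batch(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Map ``(N, 512, 13)`` raw inputs to ``(N, 512, 3)`` probabilities."""
        unet = self.config.variant == "unet"
        h = (x - self.mu) / self.sd
        e1 = self.b1.forward(h, train)
        h = self.pools[0].forward(e1, train)
        e2 = self.b2.forward(h, train)
        h = self.pools[1].forward(e2, train)
        e3 = self.b3.forward(h, train)
        h = self.pools[2].forward(e3, train)
        h = self.ups[0].forward(self.b4.forward(h, train), train)
        if unet:
            h = np.concatenate([h, e3], axis=2)
        h = self.ups[1].forward(self.b5.forward(h, train), train)
        if unet:
            h = np.concatenate([h, e2], axis=2)
        h = self.ups[2].forward(self.b6.forward(h, train), train)
        if self.lstm is not None:
            h = self.lstm.forward(h, train)
        if unet:
            h = np.concatenate([h, e1], axis=2)
        z = self.conv7.forward(h, train)
        return sigmoid(z)

    def backward_from_logits(self, dz: np.ndarray) -> None:
        """Backpropagate a gradient w.r.t. the pre-sigmoid output.

        For the binary cross-entropy loss the combined sigmoid+loss
        gradient is ``(prob - target) / n_entries``, which callers pass
        here directly for numerical stability.
        """
        unet = self.config.variant == "unet"
        ch = self.config.ch
        d = self.conv7.backward(dz)
        dskips = []
        if unet:
            d, ds = d[..., :ch[5]], d[..., ch[5]:]
            dskips.append(ds)          # -> e1
        if self.lstm is not None:
            d = self.lstm.backward(d)
        d = self.b6.backward(self.ups[2].backward(d))
        if unet:
            d, ds = d[..., :ch[4]], d[..., ch[4]:]
            dskips.append(ds)          # -> e2
        d = self.b5.backward(self.ups[1].backward(d))
        if unet:
            d, ds = d[..., :ch[3]], d[..., ch[3]:]
            dskips.append(ds)          # -> e3
        d = self.b4.backward(self.ups[0].backward(d))
        d = self.pools[2].backward(d)
        if unet:
            d = d + dskips[2]
        d = self.b3.backward(d)
        d = self.pools[1].backward(d)
        if unet:
            d = d + dskips[1]
        d = self.b2.backward(d)
        d = self.pools[0].backward(d)
        if unet:
            d = d + dskips[0]
        self.b1.backward(d)

    def forward_batched(self, x: np.ndarray, chunk: int = 64) -> np.ndarray:
        """Chunked inference over many inputs (bounds peak memory)."""
        return np.concatenate([self.forward_batch(x[i:i + chunk])
                               for i in range(0, len(x), chunk)])

    def forward(self, x: InputTensor) -> np.ndarray:
        """Inference on one input; returns a 512x3 probability map."""
        return self.forward_batch(x.values[None])[0]

    # -- serialization ------------------------------------------------------

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_state(self, state) -> None:
        for p, s in zip(self.parameters(), state):
            p[...] = s

    def save(self, path) -> None:
        arrays = {f"p{i}": p for i, p in enumerate(self.parameters())}
        np.savez(path, config=json.dumps(self.config.to_dict()),
                 mu=self.mu, sd=self.sd, **arrays)

    @classmethod
    def load(cls, path) -> "NetworkModel":
        with np.load(path, allow_pickle=False) as data:
            config = ModelConfig.from_dict(json.loads(str(data["config"])))
            model = cls(config)
            model.mu = data["mu"]
            model.sd = data["sd"]
            model.set_state([data[f"p{i}"]
                             for i in range(len(model.parameters()))])
        return model


def build(config: ModelConfig, seed: int = 0) -> NetworkModel:
    """Instantiate a network with seeded uniform fan-in initialization."""
    return NetworkModel(config, seed=seed)
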