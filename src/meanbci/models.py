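"""Network architectures for attention-level classification.

The centerpiece is the multifeature enhancement attention network (MEAN):

1. *Channel attention* (squeeze-and-excitation): per-sensor squeeze is the
   average of mean- and max-pooling over the 93 feature columns; excitation
   is an FC-ReLU-FC bottleneck with sigmoid gating, multiplied back onto the
   sensor rows.
2. *Spatial attention*: the channel x frequency plane is gated position-wise
   by a sigmoid over a 7x7 convolution of its stacked average/max statistics.
3. The gated map is flattened, the two time-domain scalars (SpO2, HR) are
   concatenated, and four *mapping blocks* apply the star operation: the
   element-wise product of a linear 1-D convolution branch and a ReLU6
   convolution branch, combined with the input by learnable residual weights.
   Algebraically one star operation of a d-dimensional (augmented) input
   spans the (d+2)(d+1)/2 pairwise monomials, an implicit high-dimensional
   polynomial mapping.
4. A small convolutional head (also used standalone as the CNN baseline)
   performs the three-class readout.

RNN and LSTM baselines consume the sensor x feature map as a 15-step
sequence of 93-vectors (two stacked layers, 128 hidden units), with the
scalars appended to the final hidden state.
"""
from __future__ import annotations

import numpy as np

from .core import ConfigError
from .nn import Conv1d, Conv2d, Dropout, Linear, Module, Tensor, concat
from .nn.layers import maxpool1d

__all__ = [
    "star_term_count",
    "ChannelAttention",
    "SpatialAttention",
    "MappingBlock",
    "ConvHead",
    "MeanNetwork",
    "CnnBaseline",
    "RecurrentBaseline",
    "build_network",
]


def star_term_count(d: int) -> int:
    """Number of distinct monomials spanned by one star operation on a
    d-dimensional input (with augmented bias coordinate): (d+2)(d+1)/2."""
    if d < 1:
        raise ConfigError("input dimension must be >= 1")
    return (d + 2) * (d + 1) // 2


class ChannelAttention(Module):
    """Squeeze-excitation gate along the sensor dimension."""

    def __init__(self, n_channels: int, rng: np.random.Generator, reduction: int = 3):
        super().__init__()
        hidden = max(n_channels // reduction, 1)
        self.fc1 = Linear(n_channels, hidden, rng)
        self.fc2 = Linear(hidden, n_channels, rng)
        self.last_weights: np.ndarray | None = None

    def __call__(self, x: Tensor) -> Tensor:
        # x: (B, C, F); squeeze = (mean + max)/2 over features
        s = (x.mean(axis=2) + x.max(axis=2)) * 0.5  # (B, C)
        w = self.fc2(self.fc1(s).relu()).sigmoid()  # (B, C)
        self.last_weights = w.data.copy()
        b, c = w.shape
        return x * w.reshape(b, c, 1)


class SpatialAttention(Module):
    """Position-wise sigmoid gate over the channel-frequency plane."""

    def __init__(self, rng: np.random.Generator, kernel: int = 7):
        super().__init__()
        self.conv = Conv2d(2, 1, kernel, rng, padding=kernel // 2)

    def __call__(self, x: Tensor) -> Tensor:
        b, c, f = x.shape
        plane = x.reshape(b, 1, c, f)
        stats = concat([plane, plane], axis=1)  # stacked average/max statistics
        gate = self.conv(stats).sigmoid()  # (B, 1, C, F)
        return x * gate.reshape(b, c, f)


class MappingBlock(Module):
    """Star-operation block: conv branch x ReLU6 conv branch, weighted residual."""

    def __init__(self, rng: np.random.Generator, kernel: int = 3):
        super().__init__()
        self.conv_lin = Conv1d(1, 1, kernel, rng, padding=kernel // 2)
        self.conv_nl = Conv1d(1, 1, kernel, rng, padding=kernel // 2)
        self.w_latent = Tensor(np.array(0.5), requires_grad=True)
        self.w_orig = Tensor(np.array(0.5), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        fused = self.conv_lin(x) * self.conv_nl(x).relu6()
        return self.w_latent * fused + self.w_orig * x


class ConvHead(Module):
    """Convolutional three-class readout over a length-L feature vector.

    Shared verbatim with the standalone CNN baseline so the baseline doubles
    as an ablation of the attention and mapping stages.
    """

    def __init__(self, rng: np.random.Generator, n_classes: int = 3, dropout: float = 0.3):
        super().__init__()
        self.conv1 = Conv1d(1, 8, 7, rng, stride=2)
        self.conv2 = Conv1d(8, 16, 5, rng, stride=2)
        self.fc1 = Linear(16, 64, rng)
        self.drop = Dropout(dropout, rng)
        self.fc2 = Linear(64, n_classes, rng)

    def __call__(self, x: Tensor) -> Tensor:
        h = maxpool1d(self.conv1(x).relu(), 2)
        h = self.conv2(h).relu()
        h = h.mean(axis=2)  # global average over length -> (B, 16)
        h = self.drop(self.fc1(h).relu())
        return self.fc2(h)

    def architecture_hash(self) -> str:
        return "conv1x8k7s2-maxpool2-conv8x16k5s2-gap-fc16x64-drop-fc64x3"


class MeanNetwork(Module):
    """Full MEAN forward path on (freq_map, scalars) instances."""

    def __init__(self, n_channels: int, n_cols: int, n_scalars: int,
                 rng: np.random.Generator, n_blocks: int = 4):
        super().__init__()
        self.n_channels = n_channels
        self.n_cols = n_cols
        self.n_scalars = n_scalars
        self.channel_att = ChannelAttention(n_channels, rng)
        self.spatial_att = SpatialAttention(rng)
        self.blocks = [MappingBlock(rng) for _ in range(n_blocks)]
        self.head = ConvHead(rng)

    @property
    def flat_width(self) -> int:
        return self.n_channels * self.n_cols + self.n_scalars

    def __call__(self, freq: Tensor, scalars: Tensor) -> Tensor:
        b = freq.shape[0]
        h = self.channel_att(freq)
        h = self.spatial_att(h)
        h = h.reshape(b, self.n_channels * self.n_cols)
        if self.n_scalars:
            h = concat([h, scalars], axis=1)
        h = h.reshape(b, 1, self.flat_width)
        for block in self.blocks:
            h = block(h)
        return self.head(h)


class CnnBaseline(Module):
    """The MEAN head alone, consuming the flattened fused vector."""

    def __init__(self, n_channels: int, n_cols: int, n_scalars: int,
                 rng: np.random.Generator):
        super().__init__()
        self.n_channels = n_channels
        self.n_cols = n_cols
        self.n_scalars = n_scalars
        self.head = ConvHead(rng)

    def __call__(self, freq: Tensor, scalars: Tensor) -> Tensor:
        b = freq.shape[0]
        h = freq.reshape(b, self.n_channels * self.n_cols)
        if self.n_scalars:
            h = concat([h, scalars], axis=1)
        return self.head(h.reshape(b, 1, -1))


class _LstmLayer(Module):
    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.hidden = hidden
        self.gates = [Linear(n_in + hidden, hidden, rng) for _ in range(4)]  # i, f, g, o

    def __call__(self, xs: list[Tensor]) -> list[Tensor]:
        b = xs[0].shape[0]
        h = Tensor(np.zeros((b, self.hidden)))
        c = Tensor(np.zeros((b, self.hidden)))
        out = []
        for x in xs:
            xh = concat([x, h], axis=1)
            i = self.gates[0](xh).sigmoid()
            f = self.gates[1](xh).sigmoid()
            g = self.gates[2](xh).tanh()
            o = self.gates[3](xh).sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            out.append(h)
        return out


class _RnnLayer(Module):
    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.hidden = hidden
        self.cell = Linear(n_in + hidden, hidden, rng)

    def __call__(self, xs: list[Tensor]) -> list[Tensor]:
        b = xs[0].shape[0]
        h = Tensor(np.zeros((b, self.hidden)))
        out = []
        for x in xs:
            h = self.cell(concat([x, h], axis=1)).tanh()
            out.append(h)
        return out


class RecurrentBaseline(Module):
    """Two stacked RNN/LSTM layers (128 hidden units) over the sensor axis."""

    def __init__(self, n_channels: int, n_cols: int, n_scalars: int,
                 rng: np.random.Generator, cell: str = "lstm",
                 hidden: int = 128, n_layers: int = 2):
        super().__init__()
        self.n_channels = n_channels
        self.hidden = hidden
        layer_cls = _LstmLayer if cell == "lstm" else _RnnLayer
        self.layers = [
            layer_cls(n_cols if i == 0 else hidden, hidden, rng) for i in range(n_layers)
        ]
        self.out = Linear(hidden + n_scalars, 3, rng)
        self.n_scalars = n_scalars

    def __call__(self, freq: Tensor, scalars: Tensor) -> Tensor:
        b, c, f = freq.shape
        steps: list[Tensor] = []
        for t in range(c):
            steps.append(Tensor(freq.data[:, t, :]) if not freq.requires_grad
                         else _row(freq, t))
        for layer in self.layers:
            steps = layer(steps)
        final = steps[-1]
        if self.n_scalars:
            final = concat([final, scalars], axis=1)
        return self.out(final)


def _row(x: Tensor, t: int) -> Tensor:
    """Differentiable slice x[:, t, :] of a (B, C, F) tensor."""

    def bwd(g):
        if x.requires_grad:
            grad = np.zeros_like(x.data)
            grad[:, t, :] = g
            x._accum(grad)

    return Tensor._make(x.data[:, t, :], (x,), bwd)


def build_network(arch: str, n_channels: int, n_cols: int, n_scalars: int,
                  rng: np.random.Generator) -> Module:
    if arch == "mean":
        return MeanNetwork(n_channels, n_cols, n_scalars, rng)
    if arch == "cnn":
        return CnnBaseline(n_channels, n_cols, n_scalars, rng)
    if arch in ("rnn", "lstm"):
        return RecurrentBaseline(n_channels, n_cols, n_scalars, rng, cell=arch)
    raise ConfigError(f"unknown architecture {arch!r}; expected mean/cnn/rnn/lstm")
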