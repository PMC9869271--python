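"""Interpolation-first, pooling-second encoder-decoder ("Ipp Net").

The architecture inverts the classic U-Net: the input tile is first
*enlarged* twice by nearest-neighbour interpolation (so that glands only a
few pixels across are never collapsed onto single feature-map pixels), then
reduced back by max-pooling, with concatenation skip connections joining
each up-sampling stage to the pooling stage at the same resolution. All
convolutions are 3x3 "same" (stride 1), each followed by batch
normalisation and ReLU. A final 1x1 convolution with a ReLU produces one
non-negative response map per tile, which is thresholded into the binary
gland mask.

With the default 120-px tile and two up/down stages, the spatial trace is
120 -> 240 -> 480 -> 240 -> 120 and the channel schedule is
16/16/16 on the enlarging path, then 32 after each skip-concatenation.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, asdict, field

import numpy as np

from ._nn import (
    AdamOptimizer,
    BatchNorm2D,
    Conv2D,
    MaxPool2x2,
    ReLU,
    UpsampleNearest2x,
)

__all__ = ["NetworkSpec", "IppNet", "build_network", "binarize"]


@dataclass(frozen=True)
class NetworkSpec:
    """Layer schedule of the network.

    ``base_channels`` is the width of the enlarging path; every block after
    a skip-concatenation carries ``2 * base_channels``. ``binarize_threshold``
    is the default response threshold: the literal rule maps every strictly
    positive rectified response to foreground (threshold 0); 0.5 is the
    robust choice when training against {0,1} targets with a squared-error
    loss, and is what the training loop uses for validation metrics.
    """

    input_size: int = 120
    input_channels: int = 3
    base_channels: int = 16
    up_blocks: int = 2
    down_blocks: int = 2
    kernel: int = 3
    binarize_threshold: float = 0.0

    def __post_init__(self):
        if self.up_blocks != self.down_blocks:
            raise ValueError("up_blocks must equal down_blocks")
        if self.up_blocks < 1:
            raise ValueError("need at least one up/down stage")
        if self.kernel % 2 == 0:
            raise ValueError("kernel must be odd (same-convolution)")
        if self.input_size < 2 ** self.up_blocks:
            raise ValueError(
                f"input_size {self.input_size} too small for "
                f"{self.up_blocks} pooling stages")
        if self.input_channels < 1 or self.base_channels < 1:
            raise ValueError("channel counts must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        return cls(**d)


class _ConvBlock:
    """conv3x3 -> BN -> ReLU, twice."""

    def __init__(self, rng, in_ch: int, out_ch: int, kernel: int):
        self.layers = []
        for cin, cout in ((in_ch, out_ch), (out_ch, out_ch)):
            self.layers += [Conv2D(rng, cin, cout, kernel),
                            BatchNorm2D(cout), ReLU()]

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self):
        out = []
        for layer in self.layers:
            out += layer.parameters()
        return out

    def stateful(self):
        return [l for l in self.layers if hasattr(l, "state")]


class IppNet:
    """The network and its parameters (build with :func:`build_network`)."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(seed)
        c = spec.base_channels
        k = spec.kernel
        self.up_path = []     # (block, upsample) per stage
        in_ch = spec.input_channels
        for _ in range(spec.up_blocks):
            self.up_path.append((_ConvBlock(rng, in_ch, c, k), UpsampleNearest2x()))
            in_ch = c
        self.bottom = _ConvBlock(rng, c, c, k)
        self.down_path = []   # (pool, block) per stage; concat before block
        in_ch = c
        for _ in range(spec.down_blocks):
            self.down_path.append((MaxPool2x2(), _ConvBlock(rng, in_ch + c, 2 * c, k)))
            in_ch = 2 * c
        self.head = Conv2D(rng, in_ch, 1, kernel=1)
        self.head_relu = ReLU()
        self._concat_splits: list | None = None

    # -- forward / backward -------------------------------------------------

    def forward(self, batch: np.ndarray, train: bool = False) -> np.ndarray:
        """Map a batch of RGB tiles to non-negative single-channel responses.

        ``batch`` is (N, H, W, 3) with values in [0, 1] (an (N, 3, H, W)
        float array is also accepted). Returns (N, H, W) float32 >= 0.
        """
        x = self._to_nchw(batch)
        skips = []
        splits = []
        for block, up in self.up_path:
            x = block.forward(x, train=train)
            skips.append(x)
            x = up.forward(x, train=train)
        x = self.bottom.forward(x, train=train)
        for (pool, block), skip in zip(self.down_path, reversed(skips)):
            x = pool.forward(x, train=train)
            splits.append(x.shape[1])
            x = np.concatenate([x, skip], axis=1)
            x = block.forward(x, train=train)
        x = self.head.forward(x, train=train)
        x = self.head_relu.forward(x, train=train)
        if train:
            self._concat_splits = splits
        return x[:, 0]

    def backward(self, grad: np.ndarray) -> None:
        """Backpropagate d(loss)/d(output); grad is (N, H, W)."""
        g = self.head.backward(self.head_relu.backward(grad[:, None]))
        skip_grads = []
        for (pool, block), split in zip(reversed(self.down_path),
                                        reversed(self._concat_splits)):
            g = block.backward(g)
            g, g_skip = g[:, :split], g[:, split:]
            skip_grads.append(g_skip)
            g = pool.backward(g)
        g = self.bottom.backward(g)
        for (block, up), g_skip in zip(reversed(self.up_path),
                                       reversed(skip_grads)):
            g = up.backward(g)
            g = block.backward(g + g_skip)
        self._concat_splits = None

    def _to_nchw(self, batch: np.ndarray) -> np.ndarray:
        batch = np.asarray(batch, dtype=np.float32)
        if batch.ndim != 4:
            raise ValueError("expected a 4-d batch of tiles")
        c = self.spec.input_channels
        if batch.shape[-1] == c and batch.shape[1] != c:
            batch = batch.transpose(0, 3, 1, 2)
        if batch.shape[1] != c:
            raise ValueError(f"expected {c} channels, got shape {batch.shape}")
        n, _, h, w = batch.shape
        s = self.spec.input_size
        if h != s or w != s:
            raise ValueError(f"expected {s}x{s} tiles, got {h}x{w}")
        return np.ascontiguousarray(batch)

    # -- bookkeeping ---------------------------------------------------------

    def _blocks(self):
        out = [b for b, _ in self.up_path] + [self.bottom] + \
              [b for _, b in self.down_path]
        return out

    def parameters(self):
        params = []
        for block in self._blocks():
            params += block.parameters()
        params += self.head.parameters()
        return params

    def n_parameters(self) -> int:
        return int(sum(p.size for p, _ in self.parameters()))

    def make_optimizer(self, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        return AdamOptimizer(self.parameters(), lr=lr, beta1=beta1,
                             beta2=beta2, eps=eps)

    def _stateful(self):
        out = []
        for block in self._blocks():
            out += block.stateful()
        out.append(self.head)
        return out

    def state_dict(self) -> dict:
        return {f"layer{i}_{k}": v.copy()
                for i, layer in enumerate(self._stateful())
                for k, v in layer.state().items()}

    def load_state_dict(self, state: dict) -> None:
        for i, layer in enumerate(self._stateful()):
            layer.load({k: state[f"layer{i}_{k}"] for k in layer.state()})

    # -- checkpoint i/o ------------------------------------------------------

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            np.savez(fh, __spec__=json.dumps(self.spec.to_dict()),
                     __seed__=self.seed, **self.state_dict())

    @classmethod
    def from_file(cls, path) -> "IppNet":
        with np.load(path, allow_pickle=False) as data:
            spec = NetworkSpec.from_dict(json.loads(str(data["__spec__"])))
            net = cls(spec, seed=int(data["__seed__"]))
            net.load_state_dict({k: data[k] for k in data.files
                                 if not k.startswith("__")})
        return net


def build_network(spec: NetworkSpec | None = None, seed: int = 0) -> IppNet:
    """Build an initialised network (He-uniform kernels, zero biases)."""
    return IppNet(spec or NetworkSpec(), seed=seed)


def binarize(response: np.ndarray, threshold: float = 0.0) -> np.ndarray:
    """Threshold a response map into a {0,1} uint8 mask (foreground iff
    value > threshold)."""
    response = np.asarray(response)
    if np.isnan(response).any():
        raise ValueError("response map contains NaN")
    return (response > threshold).astype(np.uint8)
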