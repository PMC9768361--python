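"""SE-ResNet-34 U-Net for three-class mucosal segmentation.

The encoder is the ResNet-34 layout — a 7x7/2 stem, 3x3/2 max pool, then
four stages of basic residual blocks (3, 4, 6, 3) whose outputs at strides
4, 8, 16 and 32 feed the skip connections.  The decoder mirrors it with
2x nearest-neighbor upsampling + 3x3 convolutions, concatenating the
matching skip at each stage; a squeeze-and-excitation block recalibrates
the channels of each decoder stage output (placement configurable, and
``"none"`` yields the plain U-Net used as the comparison baseline).  A final
1x1 convolution and per-pixel softmax produce a 3-channel probability map
at input resolution, so the total downsampling factor of 32 requires input
sizes divisible by 32.

Weights are initialized with seeded He-normal draws; there is no external
pretrained-weight dependency.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .nn.layers import (
    Conv2d,
    ConvBNReLU,
    Layer,
    MaxPool2d,
    Param,
    ResidualBlock,
    SEBlock,
    Sequential,
    UpsampleNearest2x,
)

#: product of the encoder's stride-2 stages (stem, pool, stages 2-4)
DOWNSAMPLING_FACTOR = 32

RESNET34_BLOCKS = (3, 4, 6, 3)


@dataclass
class NetworkConfig:
    """Architecture hyper-parameters.

    ``base_width`` is the stem channel count (64 in the full-size network;
    smaller values give proportionally narrower encoders/decoders for
    desk-scale experiments).  ``se_placement`` is ``"decoder"`` (an SE block
    on every decoder stage output) or ``"none"`` (plain U-Net baseline).
    """

    num_classes: int = 3
    input_size: int = 512
    base_width: int = 64
    encoder_blocks: tuple = RESNET34_BLOCKS
    se_reduction: int = 16
    se_placement: str = "decoder"
    seed: int = 0

    def __post_init__(self):
        if self.input_size % DOWNSAMPLING_FACTOR != 0:
            raise ValueError(
                f"input_size must be divisible by {DOWNSAMPLING_FACTOR}, "
                f"got {self.input_size}"
            )
        if self.se_placement not in ("decoder", "none"):
            raise ValueError("se_placement must be 'decoder' or 'none'")
        if self.se_placement != "none":
            for ch in self.decoder_channels:
                if ch % self.se_reduction != 0:
                    raise ValueError(
                        f"se_reduction {self.se_reduction} does not divide "
                        f"decoder channel count {ch}"
                    )

    @property
    def decoder_channels(self) -> tuple:
        # full-width tail: confident per-pixel margins need head fan-in
        w = self.base_width
        return (4 * w, 2 * w, w, w, 2 * w)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["encoder_blocks"] = list(self.encoder_blocks)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        if "encoder_blocks" in d:
            d["encoder_blocks"] = tuple(d["encoder_blocks"])
        return cls(**d)


class _DecoderStage(Layer):
    """Upsample, concatenate the encoder skip, two conv-BN-ReLU, optional SE."""

    def __init__(self, in_ch, skip_ch, out_ch, se_reduction, use_se, rng):
        self.up = UpsampleNearest2x()
        self.skip_ch = skip_ch
        self.conv1 = ConvBNReLU(in_ch + skip_ch, out_ch, rng=rng)
        self.conv2 = ConvBNReLU(out_ch, out_ch, rng=rng)
        self.se = SEBlock(out_ch, se_reduction, rng) if use_se else None

    def params(self):
        ps = self.conv1.params() + self.conv2.params()
        if self.se is not None:
            ps += self.se.params()
        return ps

    def forward(self, x, skip, train=True):
        u = self.up(x, train)
        h = u if skip is None else np.concatenate([u, skip], axis=1)
        self._in_ch = u.shape[1]
        h = self.conv2(self.conv1(h, train), train)
        if self.se is not None:
            h = self.se(h, train)
        return h

    def backward(self, g):
        if self.se is not None:
            g = self.se.backward(g)
        g = self.conv1.backward(self.conv2.backward(g))
        gu, gskip = g[:, : self._in_ch], g[:, self._in_ch :]
        return self.up.backward(gu), (gskip if self.skip_ch else None)


class SegNetwork:
    """Encoder-decoder segmentation network with softmax output.

    ``forward`` returns per-pixel class probabilities of shape
    (B, num_classes, H, W); ``backward`` takes the loss gradient with
    respect to those probabilities and chains it through the softmax and
    every layer.
    """

    def __init__(self, cfg: NetworkConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        w = cfg.base_width
        self.stem = ConvBNReLU(3, w, kernel=7, stride=2, rng=rng)
        self.pool = MaxPool2d(3, 2, 1)

        def stage(in_ch, out_ch, n_blocks, stride):
            blocks = [ResidualBlock(in_ch, out_ch, stride, rng)]
            blocks += [ResidualBlock(out_ch, out_ch, 1, rng) for _ in range(n_blocks - 1)]
            return Sequential(*blocks)

        n1, n2, n3, n4 = cfg.encoder_blocks
        self.layer1 = stage(w, w, n1, 1)
        self.layer2 = stage(w, 2 * w, n2, 2)
        self.layer3 = stage(2 * w, 4 * w, n3, 2)
        self.layer4 = stage(4 * w, 8 * w, n4, 2)

        use_se = cfg.se_placement == "decoder"
        d = cfg.decoder_channels
        r = cfg.se_reduction
        self.dec4 = _DecoderStage(8 * w, 4 * w, d[0], r, use_se, rng)
        self.dec3 = _DecoderStage(d[0], 2 * w, d[1], r, use_se, rng)
        self.dec2 = _DecoderStage(d[1], w, d[2], r, use_se, rng)
        self.dec1 = _DecoderStage(d[2], w, d[3], r, use_se, rng)
        self.dec0 = _DecoderStage(d[3], 0, d[4], r, use_se, rng)
        self.head = Conv2d(d[4], cfg.num_classes, 1, pad=0, bias=True, rng=rng)

        self._modules = [
            self.stem, self.layer1, self.layer2, self.layer3, self.layer4,
            self.dec4, self.dec3, self.dec2, self.dec1, self.dec0, self.head,
        ]

    # -- parameters ---------------------------------------------------------

    def parameters(self) -> list[Param]:
        return [p for m in self._modules for p in m.params()]

    def _batchnorms(self):
        out = []

        def walk(obj):
            from .nn.layers import BatchNorm2d

            if isinstance(obj, BatchNorm2d):
                out.append(obj)
            for v in vars(obj).values() if hasattr(obj, "__dict__") else []:
                if isinstance(v, Layer) or isinstance(v, Sequential):
                    walk(v)
                elif isinstance(v, list):
                    for item in v:
                        if isinstance(item, Layer):
                            walk(item)

        for m in self._modules:
            walk(m)
        return out

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """x: (B, 3, H, W) float32 in [0, 1]; returns (B, K, H, W) probs."""
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError("expected (B, 3, H, W) input")
        if x.shape[2] % DOWNSAMPLING_FACTOR or x.shape[3] % DOWNSAMPLING_FACTOR:
            raise ValueError(
                f"spatial size must be divisible by {DOWNSAMPLING_FACTOR}"
            )
        c1 = self.stem(x, train)                   # stride 2
        c2 = self.layer1(self.pool(c1, train), train)  # stride 4
        c3 = self.layer2(c2, train)                # stride 8
        c4 = self.layer3(c3, train)                # stride 16
        c5 = self.layer4(c4, train)                # stride 32
        h = self.dec4.forward(c5, c4, train)
        h = self.dec3.forward(h, c3, train)
        h = self.dec2.forward(h, c2, train)
        h = self.dec1.forward(h, c1, train)
        h = self.dec0.forward(h, None, train)
        z = self.head(h, train)
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        probs = e / e.sum(axis=1, keepdims=True)
        if train:
            self._probs = probs
        return probs

    def backward(self, gprobs: np.ndarray) -> None:
        """Backpropagate d(loss)/d(probs) through softmax and all layers."""
        p = self._probs
        gz = p * (gprobs - (gprobs * p).sum(axis=1, keepdims=True))
        g = self.head.backward(gz.astype(np.float32))
        g, _ = self.dec0.backward(g)
        g, gc1 = self.dec1.backward(g)
        g, gc2 = self.dec2.backward(g)
        g, gc3 = self.dec3.backward(g)
        g, gc4 = self.dec4.backward(g)
        g = self.layer4.backward(g) + gc4
        g = self.layer3.backward(g) + gc3
        g = self.layer2.backward(g) + gc2
        # layer1's input is the pooled stem output; c1's skip grad joins after
        g = self.pool.backward(self.layer1.backward(g))
        g = g + gc1
        self.stem.backward(g)

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Single-file checkpoint: weights, BN running stats, config."""
        arrays = {f"p{i}": p.data for i, p in enumerate(self.parameters())}
        for i, bn in enumerate(self._batchnorms()):
            arrays[f"rm{i}"] = bn.running_mean
            arrays[f"rv{i}"] = bn.running_var
        np.savez(path, config=json.dumps(self.cfg.to_dict()), **arrays)

    @classmethod
    def load(cls, path) -> "SegNetwork":
        with np.load(path, allow_pickle=False) as z:
            cfg = NetworkConfig.from_dict(json.loads(str(z["config"])))
            net = cls(cfg)
            for i, p in enumerate(net.parameters()):
                p.data[...] = z[f"p{i}"]
            for i, bn in enumerate(net._batchnorms()):
                bn.running_mean[...] = z[f"rm{i}"]
                bn.running_var[...] = z[f"rv{i}"]
        return net


def build_network(cfg: NetworkConfig) -> SegNetwork:
    """Construct the segmentation network from its configuration."""
    return SegNetwork(cfg)
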