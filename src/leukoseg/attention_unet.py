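"""U-net with a VGG16-style encoder and CBAM-gated skip connections.

The contracting path is the VGG16 convolution stack (block widths
64-128-256-512-512, 2-2-3-3-3 conv layers, 2x2 max pooling between
blocks).  Each of the four pre-pool encoder feature maps passes through
its own convolutional block attention module (CBAM) — a channel-attention
gate followed by a spatial-attention gate — before being concatenated
with the matching decoder stage.  The expanding path uses bilinear x2
upsampling followed by two 3x3 convolutions per stage, and a 1x1
convolution head with per-pixel softmax over the class set (background
plus five leukocyte types by default).

Channel attention squeezes space with global average and max pooling,
pushes both through one shared two-layer MLP (bottleneck C/r), sums and
applies a sigmoid — one weight in (0, 1) per channel.  Spatial attention
squeezes channels with per-pixel mean and max, stacks the two maps and
convolves them to a single sigmoid-gated map — one weight per location.
Both gates multiply the feature map element-wise, so CBAM can only
attenuate, never amplify.

``base_width`` scales all block widths together, giving reduced models
for CPU-scale experiments while keeping the architecture identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Module, Conv2d, Linear, relu, sigmoid, concat

__all__ = [
    "ModelConfig",
    "ChannelAttention",
    "SpatialAttention",
    "CBAM",
    "CBAMUNet",
    "build_model",
    "channel_attention",
    "spatial_attention",
    "cbam",
    "predict_mask",
]


@dataclass
class ModelConfig:
    """Architecture parameters.

    num_classes: per-pixel classes (background + 5 leukocyte types).
    input_size: (H, W) the network is sized for; must be divisible by 16.
    reduction_ratio: channel-attention MLP bottleneck divisor r.
    sam_kernel_size: spatial-attention convolution size (odd).
    base_width: width of the first encoder block; VGG16 uses 64.
    decoder_channels: widths of the four decoder stages (deep to shallow);
        None mirrors the encoder.
    upsample: "bilinear" (default; followed by convolutions).
    pretrained: load encoder weights from ``pretrained_path`` (npz).
    """

    num_classes: int = 6
    input_size: tuple = (512, 512)
    reduction_ratio: int = 16
    sam_kernel_size: int = 7
    encoder: str = "vgg16"
    base_width: int = 64
    decoder_channels: tuple | None = None
    upsample: str = "bilinear"
    pretrained: bool = False
    pretrained_path: str | None = None

    def __post_init__(self):
        if self.num_classes < 2:
            raise ValueError("num_classes must be at least 2")
        if self.input_size[0] % 16 or self.input_size[1] % 16:
            raise ValueError(
                f"input_size {self.input_size} must be divisible by 16 "
                "(four 2x2 pooling stages)")
        if self.sam_kernel_size % 2 == 0:
            raise ValueError("sam_kernel_size must be odd")
        if self.encoder != "vgg16":
            raise ValueError(f"unknown encoder '{self.encoder}'")

    @property
    def encoder_widths(self) -> tuple:
        w = self.base_width
        return (w, 2 * w, 4 * w, 8 * w, 8 * w)

    def decoder_widths(self) -> tuple:
        if self.decoder_channels is not None:
            return tuple(self.decoder_channels)
        w = self.base_width
        return (8 * w, 4 * w, 2 * w, w)


class ChannelAttention(Module):
    """Global avg+max pooling -> shared MLP -> sigmoid channel gate."""

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        hidden = max(1, channels // reduction)
        self.fc1 = Linear(channels, hidden, rng)
        self.fc2 = Linear(hidden, channels, rng)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        n, c, h, w = x.shape
        flat = x.reshape((n, c, h * w))
        avg = flat.mean(axis=2)
        mx = flat.max(axis=2)
        gate = sigmoid(self.fc2(relu(self.fc1(avg))) + self.fc2(relu(self.fc1(mx))))
        return gate.reshape((n, c, 1, 1))


class SpatialAttention(Module):
    """Channel mean+max maps -> KxK convolution -> sigmoid spatial gate."""

    def __init__(self, kernel_size: int, rng: np.random.Generator):
        self.conv = Conv2d(2, 1, kernel_size, rng)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        avg = x.mean(axis=1, keepdims=True)
        mx = x.max(axis=1, keepdims=True)
        return sigmoid(self.conv(concat([avg, mx], axis=1)))


class CBAM(Module):
    """Channel attention then spatial attention, applied in series."""

    def __init__(self, channels: int, reduction: int, sam_kernel: int,
                 rng: np.random.Generator):
        self.ca = ChannelAttention(channels, reduction, rng)
        self.sa = SpatialAttention(sam_kernel, rng)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        y = x * self.ca(x)
        return y * self.sa(y)


def _conv_block(cin: int, cout: int, n_convs: int, rng) -> list:
    convs = []
    for i in range(n_convs):
        convs.append(Conv2d(cin if i == 0 else cout, cout, 3, rng))
    return convs


def _run_block(convs, x):
    for conv in convs:
        x = relu(conv(x))
    return x


class CBAMUNet(Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.cfg = cfg
        w1, w2, w3, w4, w5 = cfg.encoder_widths
        d4, d3, d2, d1 = cfg.decoder_widths()
        # contracting path (VGG16 layout)
        self.enc1 = _conv_block(3, w1, 2, rng)
        self.enc2 = _conv_block(w1, w2, 2, rng)
        self.enc3 = _conv_block(w2, w3, 3, rng)
        self.enc4 = _conv_block(w3, w4, 3, rng)
        self.enc5 = _conv_block(w4, w5, 3, rng)
        # one CBAM per skip connection
        self.cbam1 = CBAM(w1, cfg.reduction_ratio, cfg.sam_kernel_size, rng)
        self.cbam2 = CBAM(w2, cfg.reduction_ratio, cfg.sam_kernel_size, rng)
        self.cbam3 = CBAM(w3, cfg.reduction_ratio, cfg.sam_kernel_size, rng)
        self.cbam4 = CBAM(w4, cfg.reduction_ratio, cfg.sam_kernel_size, rng)
        # expanding path
        self.dec4 = _conv_block(w5 + w4, d4, 2, rng)
        self.dec3 = _conv_block(d4 + w3, d3, 2, rng)
        self.dec2 = _conv_block(d3 + w2, d2, 2, rng)
        self.dec1 = _conv_block(d2 + w1, d1, 2, rng)
        self.head = Conv2d(d1, cfg.num_classes, 1, rng)

    def encoder_parameters(self) -> list:
        params = []
        for block in (self.enc1, self.enc2, self.enc3, self.enc4, self.enc5):
            for conv in block:
                params.extend(conv.parameters())
        return params

    def forward(self, x) -> nn.Tensor:
        """x: (N, 3, H, W) in [0, 1] -> per-pixel class probabilities
        (N, K, H, W), softmax-normalized over the class axis."""
        x = nn.as_tensor(x)
        s1 = _run_block(self.enc1, x)
        s2 = _run_block(self.enc2, nn.maxpool2d(s1))
        s3 = _run_block(self.enc3, nn.maxpool2d(s2))
        s4 = _run_block(self.enc4, nn.maxpool2d(s3))
        bottom = _run_block(self.enc5, nn.maxpool2d(s4))
        d = _run_block(self.dec4,
                       concat([nn.upsample_bilinear(bottom), self.cbam4(s4)], axis=1))
        d = _run_block(self.dec3,
                       concat([nn.upsample_bilinear(d), self.cbam3(s3)], axis=1))
        d = _run_block(self.dec2,
                       concat([nn.upsample_bilinear(d), self.cbam2(s2)], axis=1))
        d = _run_block(self.dec1,
                       concat([nn.upsample_bilinear(d), self.cbam1(s1)], axis=1))
        return nn.softmax(self.head(d), axis=1)


def build_model(cfg: ModelConfig | None = None, seed: int = 0) -> CBAMUNet:
    """Construct a CBAM U-net with He-initialized weights.

    With ``cfg.pretrained`` set, encoder weights are loaded from
    ``cfg.pretrained_path`` (an .npz archive keyed like ``state_dict``);
    random initialization is the default so no download is ever needed.
    """
    cfg = cfg or ModelConfig()
    net = CBAMUNet(cfg, np.random.default_rng(seed))
    if cfg.pretrained:
        if not cfg.pretrained_path:
            raise ValueError("pretrained=True requires pretrained_path")
        with np.load(cfg.pretrained_path) as arc:
            state = net.state_dict()
            for name in arc.files:
                if name not in state:
                    raise ValueError(f"unexpected weight '{name}' in pretrained file")
                state[name] = arc[name]
            net.load_state_dict(state)
    return net


# -- functional views of the spec operations (channels-last numpy) --------

def channel_attention(feature_hwc: np.ndarray, module: ChannelAttention) -> np.ndarray:
    """Channel gate of an (H, W, C) map -> (1, 1, C) weights in (0, 1)."""
    x = _to_nchw(feature_hwc)
    with nn.no_grad():
        gate = module(x)
    return gate.data[0].transpose(1, 2, 0)


def spatial_attention(feature_hwc: np.ndarray, module: SpatialAttention) -> np.ndarray:
    """Spatial gate of an (H, W, C) map -> (H, W, 1) weights in (0, 1)."""
    x = _to_nchw(feature_hwc)
    with nn.no_grad():
        gate = module(x)
    return gate.data[0].transpose(1, 2, 0)


def cbam(feature_hwc: np.ndarray, module: CBAM) -> np.ndarray:
    """Apply CBAM to an (H, W, C) map; output has the same shape."""
    x = _to_nchw(feature_hwc)
    with nn.no_grad():
        out = module(x)
    return out.data[0].transpose(1, 2, 0)


def _to_nchw(feature_hwc: np.ndarray) -> nn.Tensor:
    arr = np.asarray(feature_hwc, dtype=np.float64)
    if arr.ndim != 3:
        raise ValueError("expected an (H, W, C) feature map")
    return nn.Tensor(arr.transpose(2, 0, 1)[None])


def predict_mask(net: CBAMUNet, img: np.ndarray) -> np.ndarray:
    """Segment an 8-bit RGB (H, W, 3) image -> integer label mask (H, W).

    Intensities are scaled to [0, 1]; the per-pixel argmax breaks ties
    toward the lower class index (numpy argmax convention).
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 RGB image, got {img.shape}")
    x = img.astype(np.float64).transpose(2, 0, 1)[None] / 255.0
    with nn.no_grad():
        probs = net(x)
    return np.argmax(probs.data[0], axis=0).astype(np.int64)
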