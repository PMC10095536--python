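"""AHE-Retinex enhancement for stained blood-smear images.

Blood-cell images come off the microscope with uneven background colour and
brightness, which washes out the chromatin and granule detail that separates
the five leukocyte types.  The correction applied here has two stages:

1. contrast-limited adaptive histogram equalization (CLAHE) on the value
   channel of the HSV representation, which restores local contrast without
   blowing out the stain colours; and
2. multiscale retinex with color restoration (MSRCR) on the resulting RGB
   channels, which removes the smooth illumination field (estimated by
   Gaussian surrounds at three scales) and corrects the colour shift that
   plain multiscale retinex introduces.

The single-scale retinex (SSR) of a channel I is the log-domain difference
``log(I) - log(F_sigma * I)`` between the image and its Gaussian-blurred
illumination estimate; MSR averages SSR over three surround scales; MSRCR
multiplies the MSR reflectance by the colour-restoration gain
``c_i = alpha * log(beta * S_i / sum_j S_j)`` and linearly stretches the
result back into 8-bit range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import convolve1d
from skimage import color, exposure

__all__ = [
    "RetinexConfig",
    "rgb_to_hsv",
    "hsv_to_rgb",
    "adaptive_hist_eq",
    "gaussian_surround",
    "ssr",
    "msr",
    "color_restoration",
    "msrcr",
    "ahe_retinex",
]

#: added to 8-bit intensities before taking logs, guards log(0)
LOG_EPS = 1.0
#: relative guard inside the colour-restoration ratio
_CR_EPS = 1e-6


@dataclass
class RetinexConfig:
    """Parameters of the AHE-Retinex pipeline.

    scales
        Standard deviations (pixels) of the three Gaussian surrounds.  Small
        scales preserve detail, large scales preserve colour constancy.
    scale_weights
        Convex weights combining the three SSR maps into the MSR map.
    alpha, beta
        Gain and offset of the colour-restoration function; the customary
        values are 46 and 125.
    stretch_low_pct, stretch_high_pct
        Percentile clip bounds of the final per-channel linear stretch.
    ahe_clip_limit
        Normalized CLAHE clip limit in [0, 1] (scikit-image convention).
    ahe_tile_grid
        Number of CLAHE tiles along (rows, cols).
    """

    scales: tuple = (15.0, 80.0, 250.0)
    scale_weights: tuple = (1 / 3, 1 / 3, 1 / 3)
    alpha: float = 46.0
    beta: float = 125.0
    stretch_low_pct: float = 1.0
    stretch_high_pct: float = 99.0
    ahe_clip_limit: float = 0.01
    ahe_tile_grid: tuple = (8, 8)

    def __post_init__(self):
        if len(self.scales) != 3:
            raise ValueError("exactly three surround scales are required")
        if any(s <= 0 for s in self.scales):
            raise ValueError("surround scales must be positive")
        if len(self.scale_weights) != 3 or any(w < 0 for w in self.scale_weights):
            raise ValueError("scale_weights must be three nonnegative reals")
        if abs(sum(self.scale_weights) - 1.0) > 1e-9:
            raise ValueError("scale_weights must sum to 1")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")


def _check_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 RGB image, got shape {img.shape}")
    return img


def rgb_to_hsv(img: np.ndarray) -> np.ndarray:
    """8-bit RGB -> float HSV with H, S, V all in [0, 1] (H = hue/360)."""
    img = _check_rgb(img)
    return color.rgb2hsv(img.astype(np.float64) / 255.0)


def hsv_to_rgb(hsv: np.ndarray) -> np.ndarray:
    """Float HSV (all channels in [0, 1]) -> 8-bit RGB."""
    hsv = _check_rgb(hsv)
    rgb = color.hsv2rgb(hsv)
    return np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8)


def adaptive_hist_eq(v_channel: np.ndarray, clip_limit: float = 0.01,
                     tile_grid: tuple = (8, 8)) -> np.ndarray:
    """CLAHE on a single 8-bit channel; returns an 8-bit channel."""
    v = np.asarray(v_channel)
    if v.ndim != 2:
        raise ValueError("adaptive_hist_eq expects a single-channel image")
    ty, tx = tile_grid
    if ty > v.shape[0] or tx > v.shape[1] or ty < 1 or tx < 1:
        raise ValueError(
            f"tile grid {tile_grid} invalid for image of shape {v.shape}")
    if v.max() == v.min():
        return v.astype(np.uint8).copy()  # degenerate histogram: nothing to do
    kernel = (max(1, v.shape[0] // ty), max(1, v.shape[1] // tx))
    out = exposure.equalize_adapthist(v.astype(np.uint8), kernel_size=kernel,
                                      clip_limit=clip_limit)
    return np.clip(np.rint(out * 255.0), 0, 255).astype(np.uint8)


def gaussian_surround(scale: float, kernel_size: int) -> np.ndarray:
    """Isotropic 2-D Gaussian surround kernel normalized to sum 1."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    if kernel_size < 1 or kernel_size % 2 == 0:
        raise ValueError("kernel_size must be a positive odd integer")
    g = _gaussian_1d(scale, kernel_size)
    return np.outer(g, g)


def _gaussian_1d(scale: float, kernel_size: int) -> np.ndarray:
    r = kernel_size // 2
    x = np.arange(-r, r + 1, dtype=np.float64)
    g = np.exp(-(x ** 2) / (2.0 * scale ** 2))
    return g / g.sum()


def _default_ksize(scale: float) -> int:
    return 2 * int(np.ceil(3.0 * scale)) + 1


def ssr(channel: np.ndarray, scale: float, kernel_size: int | None = None) -> np.ndarray:
    """Single-scale retinex reflectance of one channel (log domain).

    ``R = log(I + LOG_EPS) - log(F_scale * I + LOG_EPS)`` where ``F_scale``
    is the normalized Gaussian surround and the convolution uses reflective
    border handling (the separable passes are exactly equivalent to a full
    2-D convolution with the outer-product kernel).
    """
    ch = np.asarray(channel, dtype=np.float64)
    if ch.ndim != 2:
        raise ValueError("ssr expects a single-channel image")
    if np.any(ch < 0):
        raise ValueError("channel values must be nonnegative")
    if kernel_size is None:
        kernel_size = _default_ksize(scale)
    g = _gaussian_1d(scale, kernel_size)
    blur = convolve1d(ch, g, axis=0, mode="reflect")
    blur = convolve1d(blur, g, axis=1, mode="reflect")
    return np.log(ch + LOG_EPS) - np.log(blur + LOG_EPS)


def msr(channel: np.ndarray, cfg: RetinexConfig) -> np.ndarray:
    """Multiscale retinex: weighted combination of SSR maps."""
    out = np.zeros(np.asarray(channel).shape, dtype=np.float64)
    for w, s in zip(cfg.scale_weights, cfg.scales):
        if w == 0.0:
            continue
        out += w * ssr(channel, s)
    return out


def color_restoration(img3: np.ndarray, alpha: float = 46.0,
                      beta: float = 125.0) -> np.ndarray:
    """Per-pixel colour-restoration gain ``alpha*log(beta*S_i/sum_j S_j)``.

    A small relative epsilon keeps the ratio finite at all-zero pixels while
    leaving the equal-channel case exact: for a pixel (s, s, s) every channel
    gets exactly ``alpha * log(beta / 3)``.
    """
    img3 = _check_rgb(img3).astype(np.float64)
    if np.any(img3 < 0):
        raise ValueError("channel values must be nonnegative")
    s = img3 + _CR_EPS
    total = s.sum(axis=2, keepdims=True)
    return alpha * np.log(beta * s / total)


def _linear_stretch(x: np.ndarray, low_pct: float, high_pct: float) -> np.ndarray:
    """Per-channel percentile stretch into 8-bit range."""
    out = np.empty(x.shape, dtype=np.float64)
    for c in range(x.shape[2]):
        ch = x[:, :, c]
        lo, hi = np.percentile(ch, [low_pct, high_pct])
        if hi - lo < 1e-12:
            out[:, :, c] = 127.5  # constant channel: mid-gray
        else:
            out[:, :, c] = (np.clip(ch, lo, hi) - lo) / (hi - lo) * 255.0
    return out


def msrcr(img3: np.ndarray, cfg: RetinexConfig | None = None) -> np.ndarray:
    """MSRCR: colour-restored multiscale retinex, stretched to 8-bit RGB."""
    cfg = cfg or RetinexConfig()
    img3 = _check_rgb(img3).astype(np.float64)
    refl = np.stack([msr(img3[:, :, c], cfg) for c in range(3)], axis=2)
    restored = color_restoration(img3, cfg.alpha, cfg.beta) * refl
    stretched = _linear_stretch(restored, cfg.stretch_low_pct, cfg.stretch_high_pct)
    return np.clip(np.rint(stretched), 0, 255).astype(np.uint8)


def ahe_retinex(img: np.ndarray, cfg: RetinexConfig | None = None) -> np.ndarray:
    """Full correction: CLAHE on HSV value channel, then MSRCR in RGB.

    Deterministic for fixed configuration; output is 8-bit RGB of the same
    shape as the input.
    """
    cfg = cfg or RetinexConfig()
    img = _check_rgb(img)
    hsv = rgb_to_hsv(img)
    v8 = np.clip(np.rint(hsv[:, :, 2] * 255.0), 0, 255).astype(np.uint8)
    v_eq = adaptive_hist_eq(v8, cfg.ahe_clip_limit, cfg.ahe_tile_grid)
    hsv[:, :, 2] = v_eq.astype(np.float64) / 255.0
    rgb_eq = hsv_to_rgb(hsv)
    return msrcr(rgb_eq, cfg)
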