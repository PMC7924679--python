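"""Texture descriptors on distance-matrix images.

Implements the local binary pattern (LBP) transform and its 256-bin
histogram, the uniform-pattern 59-bin histogram, Gabor filtering, and two
block filters applied before uniform LBP:

* separate-row multiplication (SRM): each non-overlapping 3x3 block B is
  replaced by ``(B @ B) // 100`` clamped to 255 — row i of the new block is
  row i of B multiplied by B;
* neighbor-block subtraction (NBS): each block is subtracted from its
  right-hand neighbor block (centres one column apart), negatives clamped
  to zero, which collapses to ``out(x, y) = max(0, in(x, y) - in(x, y+1))``
  with the last column zero.

LBP convention: the eight 3x3 neighbors are read clockwise starting from
the top-left, the first-visited neighbor being the most significant bit;
a bit is 0 when the centre is strictly greater than that neighbor, 1
otherwise (ties give 1). Borders are zero-padded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "NEIGHBOR_OFFSETS",
    "lbp_code",
    "lbp_transform",
    "histogram_256",
    "circular_transitions",
    "is_uniform",
    "uniform_codes",
    "uniform_histogram_59",
    "GaborParams",
    "gabor_kernel",
    "gabor_filter_image",
    "srm_filter",
    "nbs_filter",
]

# (row, col) offsets clockwise from top-left; index 0 is the MSB.
NEIGHBOR_OFFSETS = ((-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1))


def lbp_code(window: np.ndarray) -> int:
    """LBP code of a single 3x3 window."""
    window = np.asarray(window, dtype=float)
    if window.shape != (3, 3):
        raise ValueError(f"expected a 3x3 window, got {window.shape}")
    if not np.all(np.isfinite(window)):
        raise ValueError("non-finite intensity in window")
    center = window[1, 1]
    code = 0
    for bit, (dr, dc) in enumerate(NEIGHBOR_OFFSETS):
        if window[1 + dr, 1 + dc] >= center:
            code |= 1 << (7 - bit)
    return code


def lbp_transform(image: np.ndarray) -> np.ndarray:
    """Per-pixel LBP codes of a zero-padded image; same shape, dtype uint8."""
    image = np.asarray(image)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("expected a non-empty 2D image")
    a = image.astype(np.int64)
    h, w = a.shape
    padded = np.pad(a, 1, mode="constant", constant_values=0)
    out = np.zeros((h, w), dtype=np.uint8)
    for bit, (dr, dc) in enumerate(NEIGHBOR_OFFSETS):
        neighbor = padded[1 + dr : 1 + dr + h, 1 + dc : 1 + dc + w]
        out |= (neighbor >= a).astype(np.uint8) << (7 - bit)
    return out


def histogram_256(lbp_image: np.ndarray) -> np.ndarray:
    """256-bin histogram of LBP codes; bins sum to the pixel count."""
    flat = np.asarray(lbp_image).ravel()
    if flat.min() < 0 or flat.max() > 255:
        raise ValueError("LBP image pixels must lie in [0, 255]")
    return np.bincount(flat.astype(np.intp), minlength=256)[:256]


def circular_transitions(code: int) -> int:
    """Number of 0-1 / 1-0 changes around the circular 8-bit pattern."""
    if not 0 <= code <= 255:
        raise ValueError(f"code must be in [0, 255], got {code}")
    rotated = ((code << 1) | (code >> 7)) & 0xFF
    return int(bin(code ^ rotated).count("1"))


def is_uniform(code: int) -> bool:
    """True when the circular pattern has at most two transitions."""
    return circular_transitions(code) <= 2


def uniform_codes() -> np.ndarray:
    """The 58 uniform codes in ascending numeric order."""
    return np.array([c for c in range(256) if is_uniform(c)], dtype=np.intp)


# bin index per code: uniform codes (ascending) -> 0..57, non-uniform -> 58
_UNIFORM_BIN = np.full(256, 58, dtype=np.intp)
_UNIFORM_BIN[[c for c in range(256) if bin(c ^ (((c << 1) | (c >> 7)) & 0xFF)).count("1") <= 2]] = np.arange(58)


def uniform_histogram_59(lbp_image: np.ndarray) -> np.ndarray:
    """59-bin histogram: one bin per uniform code plus one catch-all bin."""
    flat = np.asarray(lbp_image).ravel()
    if flat.min() < 0 or flat.max() > 255:
        raise ValueError("LBP image pixels must lie in [0, 255]")
    return np.bincount(_UNIFORM_BIN[flat.astype(np.intp)], minlength=59)[:59]


@dataclass(frozen=True)
class GaborParams:
    """Real Gabor kernel parameters.

    Defaults are the working values of the feature pipeline: wavelength 10,
    orientation 0, phase 0, aspect ratio 0.02 (a strongly elongated
    envelope), Gaussian std 5. ``kernel_side`` defaults to 31 ≈ 6σ + 1.
    """

    wavelength: float = 10.0
    theta: float = 0.0
    phase: float = 0.0
    gamma: float = 0.02
    sigma: float = 5.0
    kernel_side: int = 31

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.wavelength <= 0:
            raise ValueError("sigma and wavelength must be positive")
        if self.kernel_side < 3 or self.kernel_side % 2 == 0:
            raise ValueError("kernel_side must be odd and >= 3")


def gabor_kernel(params: GaborParams = GaborParams()) -> np.ndarray:
    """Real-valued Gabor kernel.

    Entry at offset (x, y) from the centre is
    ``exp(-(x'^2 + gamma^2 y'^2) / (2 sigma^2)) * cos(2 pi x'/lambda + phase)``
    with rotated coordinates ``x' = x cos(theta) + y sin(theta)`` and
    ``y' = -x sin(theta) + y cos(theta)``.
    """
    half = params.kernel_side // 2
    y, x = np.mgrid[-half : half + 1, -half : half + 1].astype(float)
    xr = x * np.cos(params.theta) + y * np.sin(params.theta)
    yr = -x * np.sin(params.theta) + y * np.cos(params.theta)
    envelope = np.exp(-(xr**2 + params.gamma**2 * yr**2) / (2.0 * params.sigma**2))
    carrier = np.cos(2.0 * np.pi * xr / params.wavelength + params.phase)
    return envelope * carrier


def gabor_filter_image(
    image: np.ndarray, params: GaborParams = GaborParams(), normalize: str = "minmax"
) -> np.ndarray:
    """Convolve with the real Gabor kernel and map back to 8-bit grayscale.

    Borders are zero-padded. The raw response is mapped to [0, 255] either by
    per-image min-max stretch (default) or by clipping (``normalize="clip"``)
    so the LBP stage always sees valid intensities.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2D image")
    response = ndimage.convolve(image, gabor_kernel(params), mode="constant", cval=0.0)
    if normalize == "minmax":
        lo, hi = response.min(), response.max()
        if hi == lo:
            return np.zeros(image.shape, dtype=np.uint8)
        out = 255.0 * (response - lo) / (hi - lo)
    elif normalize == "clip":
        out = response
    else:
        raise ValueError(f"unknown normalization {normalize!r}")
    return np.rint(out).clip(0, 255).astype(np.uint8)


def srm_filter(image: np.ndarray) -> np.ndarray:
    """Separate-row-multiplication filter on non-overlapping 3x3 blocks.

    Rows or columns not covered by a complete block (image side mod 3) pass
    through unchanged.
    """
    image = np.asarray(image)
    if image.ndim != 2 or image.shape[0] < 3 or image.shape[1] < 3:
        raise ValueError("srm_filter needs an image of at least 3x3")
    a = image.astype(np.int64)
    h, w = a.shape
    hh, ww = h - h % 3, w - w % 3
    out = a.copy()
    blocks = a[:hh, :ww].reshape(hh // 3, 3, ww // 3, 3).transpose(0, 2, 1, 3)
    products = np.clip(np.matmul(blocks, blocks) // 100, 0, 255)
    out[:hh, :ww] = products.transpose(0, 2, 1, 3).reshape(hh, ww)
    return np.clip(out, 0, 255).astype(np.uint8)


def nbs_filter(image: np.ndarray) -> np.ndarray:
    """Neighbor-block-subtraction filter.

    Every pixel becomes its difference from the pixel one column to the
    right (computed on the original image), negatives clamped to zero; the
    last column, having no right neighbor, is zero.
    """
    image = np.asarray(image)
    if image.ndim != 2 or image.shape[0] < 3 or image.shape[1] < 3:
        raise ValueError("nbs_filter needs an image of at least 3x3")
    a = image.astype(np.int64)
    out = np.zeros_like(a)
    out[:, :-1] = np.maximum(a[:, :-1] - a[:, 1:], 0)
    return out.astype(np.uint8)
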