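"""Distance-matrix images.

A structure's pairwise Euclidean distance matrix is treated as a grayscale
image: distances are mapped linearly onto [0, 255] per image (min-max) and
rescaled to a common 128x128 size by bicubic interpolation so structures of
different lengths become comparable texture images.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, squareform
from skimage.transform import resize

__all__ = [
    "SingleAtomImageError",
    "pairwise_distance_matrix",
    "matrix_to_image",
    "rescale_image",
    "save_png",
    "DEFAULT_IMAGE_SIDE",
]

DEFAULT_IMAGE_SIDE = 128


class SingleAtomImageError(ValueError):
    """A 1x1 image (single-atom structure) carries no texture; excluded."""


def pairwise_distance_matrix(coords: np.ndarray) -> np.ndarray:
    """All-pairs Euclidean distance matrix (Å), symmetric with zero diagonal."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 1:
        raise ValueError(f"expected (n, 3) coordinates, got shape {coords.shape}")
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinate in input")
    return squareform(pdist(coords, metric="euclidean"), checks=False)


def matrix_to_image(matrix: np.ndarray, mode: str = "minmax", cap: float | None = None) -> np.ndarray:
    """Map a non-negative matrix to 8-bit grayscale.

    ``minmax`` (default) stretches each image's own range onto [0, 255],
    ``pixel = round(255 * (v - min) / (max - min))``; a constant matrix maps
    to all zeros. ``clamp`` instead divides by a fixed distance cap so that
    intensities are comparable across images: ``round(255 * min(v, cap)/cap)``.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValueError(f"expected a 2D matrix, got ndim={matrix.ndim}")
    if mode == "minmax":
        lo, hi = matrix.min(), matrix.max()
        if hi == lo:
            return np.zeros(matrix.shape, dtype=np.uint8)
        scaled = 255.0 * (matrix - lo) / (hi - lo)
    elif mode == "clamp":
        if cap is None or cap <= 0:
            raise ValueError("clamp mode requires a positive cap")
        scaled = 255.0 * np.minimum(matrix, cap) / cap
    else:
        raise ValueError(f"unknown intensity mapping {mode!r}")
    return np.rint(scaled).clip(0, 255).astype(np.uint8)


def rescale_image(image: np.ndarray, side: int = DEFAULT_IMAGE_SIDE) -> np.ndarray:
    """Bicubic rescale to ``side`` x ``side``, values rounded back to [0, 255].

    1x1 inputs are rejected: a single-atom structure has no texture to
    interpolate (such ligands are excluded upstream).
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"expected a 2D image, got ndim={image.ndim}")
    if min(image.shape) < 2:
        raise SingleAtomImageError(f"cannot rescale a {image.shape[0]}x{image.shape[1]} image")
    if side < 1:
        raise ValueError("side must be positive")
    out = resize(
        image.astype(float),
        (side, side),
        order=3,  # bicubic
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return np.rint(out).clip(0, 255).astype(np.uint8)


def save_png(image: np.ndarray, path) -> None:
    """Write an 8-bit grayscale PNG (inspection helper)."""
    from PIL import Image

    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="L").save(path)
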