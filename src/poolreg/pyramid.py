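"""Pyramid average-pooling descriptor, feature-magnitude map, keypoint selection.

The descriptor of a pixel is computed over the W x W *working window* centred
on it. Layer ``l`` (1-based) partitions the window into ``2**(l-1)`` equal-area
blocks and records each block's mean intensity. All layer values are
concatenated (layers ascending, blocks row-major within a layer); the single
layer-1 (whole-window) mean is then removed from the vector and subtracted
from every remaining entry, which makes the descriptor exactly invariant to a
constant intensity offset. The resulting length is ``2**L - 2``.

Block geometry: splits alternate axes as depth grows -- layer 2 halves the
window into left/right columns, layer 3 yields the 2 x 2 quadrants, layer 4
splits each quadrant into left/right again (2 rows x 4 cols), and so on.
Block edges for non-divisible window sizes are placed by rounding equal
fractions, so blocks may differ by one pixel in extent. The grid rule lives in
:func:`layer_grid` so it can be swapped without touching callers.

The *feature magnitude map* assigns every interior pixel the Euclidean norm of
its descriptor: bright regions mark high local intensity variation and are
preferred keypoint sites. Selection is greedy by descending magnitude under a
minimum-distance constraint D (every accepted keypoint is farther than D from
all previously accepted ones), implemented by masking a disc of radius D
around each acceptance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .exceptions import ValidationError
from .image_prep import as_image

__all__ = [
    "PyramidConfig",
    "KeyPoint",
    "MagnitudeMap",
    "layer_grid",
    "descriptor_at",
    "dense_descriptors",
    "magnitude_map",
    "select_keypoints",
]


@dataclass(frozen=True)
class PyramidConfig:
    """Descriptor and keypoint-selection parameters.

    Parameters
    ----------
    window:
        Side W of the square working window, in pixels.
    layers:
        Number of pooling layers L; descriptor length is ``2**L - 2``.
    min_distance:
        Distance-regulation threshold D in pixels; accepted keypoints are
        pairwise farther apart than D. Defaults to ``window / 2``.
    max_features:
        Cap N on the number of selected keypoints.
    stride:
        Evaluation stride of the dense magnitude map (1 = every pixel).
    """

    window: int = 32
    layers: int = 4
    min_distance: float | None = None
    max_features: int = 500
    stride: int = 1

    def __post_init__(self) -> None:
        if self.window < 2:
            raise ValidationError(f"window must be >= 2, got {self.window}")
        if self.layers < 2:
            raise ValidationError(f"layers must be >= 2, got {self.layers}")
        if self.min_distance is None:
            object.__setattr__(self, "min_distance", self.window / 2)
        if self.min_distance <= 0:
            raise ValidationError(f"min_distance must be > 0, got {self.min_distance}")
        if self.max_features < 3:
            raise ValidationError(
                f"max_features must be >= 3 (an affine needs 3 pairs), got {self.max_features}"
            )
        if self.stride < 1:
            raise ValidationError(f"stride must be >= 1, got {self.stride}")

    @property
    def descriptor_length(self) -> int:
        return 2 ** self.layers - 2

    @property
    def border(self) -> int:
        """Half-window exclusion border: keypoints keep this distance from edges."""
        return math.ceil(self.window / 2)


@dataclass
class KeyPoint:
    """A selected feature: pixel location, pooled descriptor, and its norm.

    ``loc`` is ``(u, v)`` = (column, row), matching the x/y convention used by
    the affine transform stage.
    """

    loc: tuple[int, int]
    descriptor: np.ndarray
    magnitude: float


@dataclass
class MagnitudeMap:
    """Dense per-pixel descriptor norms with an invalid half-window border."""

    values: np.ndarray
    border_width: int
    config: PyramidConfig


def layer_grid(layer: int) -> tuple[int, int]:
    """(n_rows, n_cols) of the pooling grid at 1-based ``layer``.

    Columns double on even layers, rows on odd layers > 1, so the block count
    is ``2**(layer-1)`` with aspect ratio never worse than 2:1.
    """
    if layer < 1:
        raise ValidationError(f"layer index must be >= 1, got {layer}")
    n_cols = 2 ** math.ceil((layer - 1) / 2)
    n_rows = 2 ** math.floor((layer - 1) / 2)
    return n_rows, n_cols


def _edges(n_blocks: int, size: int) -> np.ndarray:
    """Integer block edges splitting ``size`` pixels into ``n_blocks`` parts."""
    return np.round(np.linspace(0.0, size, n_blocks + 1)).astype(int)


def _iter_blocks(config: PyramidConfig) -> Iterator[tuple[int, int, int, int]]:
    """Yield (r0, r1, c0, c1) window-relative spans of every pooling block,
    layers ascending, row-major within a layer. The first block is the whole
    window (the "top layer")."""
    w = config.window
    for layer in range(1, config.layers + 1):
        n_rows, n_cols = layer_grid(layer)
        re = _edges(n_rows, w)
        ce = _edges(n_cols, w)
        for i in range(n_rows):
            for j in range(n_cols):
                yield re[i], re[i + 1], ce[j], ce[j + 1]


def descriptor_at(
    image: np.ndarray, center: tuple[int, int], config: PyramidConfig
) -> np.ndarray:
    """Pooled pyramid descriptor of the window centred at ``center`` = (u, v).

    Raises
    ------
    ValidationError
        If the working window does not lie fully inside the image.
    """
    image = as_image(image)
    u, v = int(center[0]), int(center[1])
    w = config.window
    h = w // 2
    r0, c0 = v - h, u - h
    if r0 < 0 or c0 < 0 or r0 + w > image.shape[0] or c0 + w > image.shape[1]:
        raise ValidationError(
            f"window of size {w} at (u={u}, v={v}) exceeds image bounds {image.shape}"
        )
    win = image[r0 : r0 + w, c0 : c0 + w]
    vals = np.array(
        [win[a:b, c:d].mean() for a, b, c, d in _iter_blocks(config)]
    )
    return vals[1:] - vals[0]


def dense_descriptors(image: np.ndarray, config: PyramidConfig) -> tuple[np.ndarray, int]:
    """Descriptors at every valid interior pixel, computed via an integral image.

    Returns ``(desc, border)`` where ``desc`` has shape
    ``(descriptor_length, n_rows, n_cols)`` covering image pixels
    ``[border : H - border : stride, border : W - border : stride]``, and
    ``desc[:, i, j]`` equals :func:`descriptor_at` at the corresponding pixel
    (up to summation-order rounding). One integral image makes the dense
    evaluation a few array operations per pooling block instead of per pixel.
    """
    image = as_image(image)
    bw = config.border
    hgt, wid = image.shape
    stride = config.stride
    n_r = hgt - 2 * bw
    n_c = wid - 2 * bw
    if n_r < 1 or n_c < 1:
        raise ValidationError(
            f"image {image.shape} too small for window {config.window} "
            f"(needs > {2 * bw} pixels per side)"
        )
    # integral image with zero padding: S[i, j] = sum of image[:i, :j]
    s = np.zeros((hgt + 1, wid + 1))
    np.cumsum(np.cumsum(image, axis=0), axis=1, out=s[1:, 1:])

    half = config.window // 2
    # top-left corner of the window for centres in the valid region
    r_base = bw - half
    c_base = bw - half
    blocks = list(_iter_blocks(config))
    n_rs = len(range(0, n_r, stride))
    n_cs = len(range(0, n_c, stride))
    means = np.empty((len(blocks), n_rs, n_cs))
    for k, (a, b, c, d) in enumerate(blocks):
        ra, rb = r_base + a, r_base + b
        ca, cb = c_base + c, c_base + d
        block_sum = (
            s[rb : rb + n_r : stride, cb : cb + n_c : stride]
            - s[rb : rb + n_r : stride, ca : ca + n_c : stride]
            - s[ra : ra + n_r : stride, cb : cb + n_c : stride]
            + s[ra : ra + n_r : stride, ca : ca + n_c : stride]
        )
        means[k] = block_sum / ((b - a) * (d - c))
    return means[1:] - means[0], bw


def magnitude_map(image: np.ndarray, config: PyramidConfig) -> MagnitudeMap:
    """Dense feature-magnitude map: descriptor norm at every interior pixel.

    Entries inside the half-window border are zero and marked invalid.
    """
    image = as_image(image)
    desc, bw = dense_descriptors(image, config)
    norms = np.sqrt(np.einsum("kij,kij->ij", desc, desc))
    values = np.zeros(image.shape)
    stride = config.stride
    n_r, n_c = image.shape[0] - 2 * bw, image.shape[1] - 2 * bw
    values[bw : bw + n_r : stride, bw : bw + n_c : stride] = norms
    return MagnitudeMap(values=values, border_width=bw, config=config)


def select_keypoints(
    mag: MagnitudeMap, image: np.ndarray, config: PyramidConfig
) -> list[KeyPoint]:
    """Greedy distance-regulated keypoint selection.

    Candidates are visited in descending magnitude (ties broken in row-major
    scan order for reproducibility); a candidate is accepted only if it is
    farther than D from every previously accepted keypoint, enforced by
    masking a disc of radius D around each acceptance. Stops at
    ``max_features`` accepted points or when candidates are exhausted.
    Zero-magnitude pixels are never selected.
    """
    image = as_image(image)
    d = float(config.min_distance)
    values = mag.values
    rows, cols = np.nonzero(values > 0)
    if rows.size == 0:
        return []
    mags = values[rows, cols]
    # descending magnitude; ties in row-major order (row, then column)
    order = np.lexsort((cols, rows, -mags))
    rows, cols, mags = rows[order], cols[order], mags[order]

    # disc stencil of radius D (inclusive: dist <= D is masked, so accepted
    # points are pairwise *strictly* farther than D apart)
    rad = int(math.floor(d))
    dy, dx = np.mgrid[-rad : rad + 1, -rad : rad + 1]
    disc = dy * dy + dx * dx <= d * d

    masked = np.zeros(values.shape, dtype=bool)
    hgt, wid = values.shape
    out: list[KeyPoint] = []
    for r, c, m in zip(rows, cols, mags):
        if masked[r, c]:
            continue
        out.append(
            KeyPoint(
                loc=(int(c), int(r)),
                descriptor=descriptor_at(image, (int(c), int(r)), config),
                magnitude=float(m),
            )
        )
        if len(out) >= config.max_features:
            break
        r0, r1 = max(0, r - rad), min(hgt, r + rad + 1)
        c0, c1 = max(0, c - rad), min(wid, c + rad + 1)
        masked[r0:r1, c0:c1] |= disc[
            r0 - (r - rad) : r1 - (r - rad), c0 - (c - rad) : c1 - (c - rad)
        ]
    return out
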