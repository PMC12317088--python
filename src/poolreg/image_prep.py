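"""Image loading and preconditioning.

Single-channel 2D images are represented as plain ``float64`` numpy arrays
(rows = image height, columns = width); :func:`as_image` is the validating
entry point every stage uses. Multichannel acquisitions (e.g. per-ion mass
spectrometry images) are carried as a :class:`ChannelStack` and collapsed to
one registration channel by :func:`collapse_channels`.

Preprocessing follows the order hotspot clip -> intensity normalisation; the
optional quarter-turn pre-rotation handles modality pairs acquired 90 degrees
apart.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .exceptions import ConfigurationError, ValidationError

__all__ = [
    "ChannelStack",
    "as_image",
    "load_image",
    "load_stack",
    "save_image",
    "hotspot_clip",
    "rotate90",
    "collapse_channels",
    "normalize_intensity",
    "register_embedding",
]

#: luminance weights for RGB -> gray (ITU-R BT.709, as used by scikit-image)
_LUMA = np.array([0.2125, 0.7154, 0.0721])


def as_image(pixels: np.ndarray) -> np.ndarray:
    """Validate and coerce ``pixels`` into the canonical 2D float image form.

    Non-finite values (possible in raw MS rasters) are replaced by zero with
    a warning so every downstream stage can assume finite intensities.
    """
    arr = np.asarray(pixels, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValidationError(f"expected a non-empty 2D image, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        warnings.warn("non-finite intensities replaced with 0", stacklevel=2)
        arr = np.nan_to_num(arr, nan=0.0, posinf=0.0, neginf=0.0)
    return arr


@dataclass
class ChannelStack:
    """A stack of co-registered single-channel rasters (n_channels, H, W)."""

    channels: np.ndarray
    channel_labels: list[str] | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.channels, dtype=np.float64)
        if arr.ndim != 3 or arr.shape[0] < 1:
            raise ValidationError(
                f"channel stack must be (n_channels, H, W), got shape {arr.shape}"
            )
        self.channels = np.stack([as_image(c) for c in arr])
        if self.channel_labels is not None and len(self.channel_labels) != len(arr):
            raise ValidationError("channel_labels length does not match n_channels")

    @property
    def n_channels(self) -> int:
        return self.channels.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels.shape[1:]


def load_image(path: str | Path, convert_gray: bool = True) -> np.ndarray:
    """Load a TIFF/PNG (or ``.npy`` raw array) file as a 2D float image.

    Color input is collapsed to luminance when ``convert_gray`` is set; an
    alpha channel, if present, is dropped first.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if path.suffix.lower() == ".npy":
        arr = np.load(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        arr = arr[..., :3]
        if convert_gray:
            arr = arr @ _LUMA
    if arr.ndim != 2:
        raise ValidationError(
            f"{path} is not a single-channel 2D image (shape {arr.shape}); "
            "use load_stack for multichannel TIFFs"
        )
    if arr.size == 0:
        raise ValidationError(f"{path} is a zero-sized image")
    return as_image(arr)


def load_stack(path: str | Path, channel_labels: Sequence[str] | None = None) -> ChannelStack:
    """Load a multi-page TIFF (or 3D ``.npy``) as a ChannelStack."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if path.suffix.lower() == ".npy":
        arr = np.load(path)
    else:
        import tifffile

        arr = tifffile.imread(path)
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[None]
    return ChannelStack(arr, list(channel_labels) if channel_labels else None)


def save_image(path: str | Path, image: np.ndarray, dtype=np.float32) -> None:
    """Write an image losslessly: TIFF via tifffile, PNG via imageio, or .npy."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".npy":
        np.save(path, np.asarray(image))
    elif suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, np.asarray(image, dtype=dtype))
    else:
        import imageio.v3 as iio

        iio.imwrite(path, np.asarray(image))


def hotspot_clip(image: np.ndarray, quantile: float = 0.99) -> np.ndarray:
    """Clip intensities above the ``quantile`` level down to that level.

    Tames the extreme single-pixel outliers ("hotspots") typical of laser
    ablation MS rasters. The level is the lower order statistic at the
    requested quantile (``numpy`` method ``"lower"``); unlike interpolating
    estimators this makes clipping a true projection — applying it twice
    with the same quantile equals applying it once.
    """
    image = as_image(image)
    if not 0.0 < quantile <= 1.0:
        raise ValidationError(f"quantile must be in (0, 1], got {quantile}")
    level = np.quantile(image, quantile, method="lower")
    return np.minimum(image, level)


def rotate90(image: np.ndarray, k: int = 1) -> np.ndarray:
    """Rotate by ``k`` quarter turns (positive = counter-clockwise)."""
    return np.ascontiguousarray(np.rot90(as_image(image), k))


def normalize_intensity(image: np.ndarray) -> np.ndarray:
    """Affinely rescale intensities to [0, 1]; a constant image maps to zeros."""
    image = as_image(image)
    lo, hi = image.min(), image.max()
    if hi == lo:
        return np.zeros_like(image)
    return (image - lo) / (hi - lo)


# --- channel-collapse (embedding) registry ----------------------------------


def _collapse_mean(stack: ChannelStack, seed: int | None) -> np.ndarray:
    return stack.channels.mean(axis=0)


def _collapse_pca(stack: ChannelStack, seed: int | None) -> np.ndarray:
    """Score of the first principal direction across channels, per pixel.

    Sign is fixed so the component correlates positively with the channel
    mean, making the output deterministic.
    """
    c, h, w = stack.channels.shape
    x = stack.channels.reshape(c, -1).T  # pixels x channels
    x = x - x.mean(axis=0)
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    scores = x @ vt[0]
    mean_img = x.sum(axis=1)
    if np.dot(scores, mean_img) < 0:
        scores = -scores
    return scores.reshape(h, w)


def _collapse_tsne(stack: ChannelStack, seed: int | None) -> np.ndarray:
    """1D t-SNE embedding of the per-pixel channel vectors.

    Stochastic; reproducible for a fixed seed. Intended for small rasters --
    cost is quadratic-ish in pixel count.
    """
    from sklearn.manifold import TSNE

    c, h, w = stack.channels.shape
    x = stack.channels.reshape(c, -1).T
    n = x.shape[0]
    emb = TSNE(
        n_components=1,
        perplexity=min(30.0, max(2.0, (n - 1) / 3.0)),
        random_state=0 if seed is None else seed,
        init="pca" if c > 1 else "random",
    ).fit_transform(x)
    return emb[:, 0].reshape(h, w)


_EMBEDDINGS: dict[str, Callable[[ChannelStack, int | None], np.ndarray]] = {
    "mean": _collapse_mean,
    "pca": _collapse_pca,
    "tsne": _collapse_tsne,
}


def register_embedding(
    name: str, fn: Callable[[ChannelStack, int | None], np.ndarray]
) -> None:
    """Register a custom channel-collapse method under ``name``."""
    _EMBEDDINGS[name] = fn


def collapse_channels(
    stack: ChannelStack, method: str = "mean", seed: int | None = None
) -> np.ndarray:
    """Collapse a multichannel stack to one registration channel.

    The default ``"mean"`` is deterministic; ``"pca"`` takes the first
    principal direction; ``"tsne"`` is a seeded stochastic embedding.
    """
    if method not in _EMBEDDINGS:
        raise ConfigurationError(
            f"unknown embedding method {method!r}; known: {sorted(_EMBEDDINGS)}"
        )
    return as_image(_EMBEDDINGS[method](stack, seed))
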