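"""Registration-quality metrics: Dice, Hausdorff distance, mutual information.

Dice and Hausdorff compare binary annotation masks in the fixed frame;
mutual information compares intensity images directly via their joint
histogram. Mutual information is reported in nats (natural log). Hausdorff
distances are in pixels unless a pixel size (micrometres per pixel) is
supplied.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass

import numpy as np
from scipy.spatial.distance import directed_hausdorff

from .exceptions import ValidationError
from .image_prep import as_image

__all__ = ["EvaluationReport", "as_mask", "dice", "hausdorff", "mutual_information", "evaluate"]


@dataclass
class EvaluationReport:
    """The three registration-quality numbers plus the MI histogram size."""

    dice: float
    hausdorff: float
    mutual_information: float | None
    bins: int
    pixel_size: float = 1.0

    def to_dict(self) -> dict:
        return asdict(self)


def as_mask(pixels: np.ndarray) -> np.ndarray:
    """Coerce to a 2D boolean mask (nonzero = foreground)."""
    arr = np.asarray(pixels)
    if arr.ndim != 2 or arr.size == 0:
        raise ValidationError(f"mask must be a non-empty 2D array, got shape {arr.shape}")
    return arr.astype(bool)


def _check_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a, b = as_mask(a), as_mask(b)
    if a.shape != b.shape:
        raise ValidationError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return a, b


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|); 1 means perfect overlap."""
    a, b = _check_pair(a, b)
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        raise ValidationError("Dice of two empty masks is undefined")
    return 2.0 * int((a & b).sum()) / (na + nb)


def hausdorff(a: np.ndarray, b: np.ndarray, pixel_size: float = 1.0) -> float:
    """Symmetric Hausdorff distance between mask foregrounds.

    max of the two directed max-min Euclidean distances over foreground
    pixel coordinates, scaled by ``pixel_size`` (micrometres per pixel when
    known; otherwise the result is in pixels).
    """
    a, b = _check_pair(a, b)
    pa, pb = np.argwhere(a), np.argwhere(b)
    if len(pa) == 0 or len(pb) == 0:
        raise ValidationError("Hausdorff distance needs non-empty masks")
    d = max(directed_hausdorff(pa, pb)[0], directed_hausdorff(pb, pa)[0])
    return float(d * pixel_size)


def mutual_information(a: np.ndarray, b: np.ndarray, bins: int = 32) -> float:
    """Mutual information (nats) of the joint intensity histogram.

    Equal-width bins over each image's own min-max range. A constant image
    has zero marginal entropy; MI is then 0 (with a warning).
    """
    a, b = as_image(a), as_image(b)
    if a.shape != b.shape:
        raise ValidationError(f"image shapes differ: {a.shape} vs {b.shape}")
    if bins < 2:
        raise ValidationError(f"bins must be >= 2, got {bins}")
    if a.min() == a.max() or b.min() == b.max():
        warnings.warn("constant image: mutual information is 0", stacklevel=2)
        return 0.0
    joint, _, _ = np.histogram2d(a.ravel(), b.ravel(), bins=bins)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))


def evaluate(
    fixed_mask: np.ndarray,
    registered_mask: np.ndarray,
    fixed_image: np.ndarray | None = None,
    registered_image: np.ndarray | None = None,
    bins: int = 32,
    pixel_size: float = 1.0,
) -> EvaluationReport:
    """Bundle the three metrics into one report.

    MI is computed only when both intensity images are given (masks alone do
    not carry enough intensity structure for a meaningful histogram).
    """
    mi = None
    if fixed_image is not None and registered_image is not None:
        mi = mutual_information(fixed_image, registered_image, bins=bins)
    return EvaluationReport(
        dice=dice(fixed_mask, registered_mask),
        hausdorff=hausdorff(fixed_mask, registered_mask, pixel_size=pixel_size),
        mutual_information=mi,
        bins=bins,
        pixel_size=pixel_size,
    )
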