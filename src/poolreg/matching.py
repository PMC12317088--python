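"""Descriptor matching, geometric consistency filtering, affine estimation.

Matching is nearest-neighbour in descriptor space with Lowe's ratio test:
for each moving keypoint the best fixed match is accepted only if its
distance is at most ``ratio`` (default 0.75) times the second-best distance,
with equality counting as acceptance. Because the test is row-wise, several
moving points can claim the same fixed point; only the closest claimant is
kept.

Surviving pairs are filtered by perspective consistency: since the two image
planes are views of the same tissue section, matched locations must be
related by a plane-to-plane projective map. A seeded RANSAC consensus fit
(scikit-image) discards pairs whose reprojection error exceeds a pixel
threshold. The final 2D affine transform is then the least-squares minimiser
of the summed projection error over the inlier pairs, solved by orthogonal
decomposition (no normal equations) for stability on near-collinear sets.

Coordinates are (u, v) = (x, y) = (column, row) throughout; the affine acts
on homogeneous column vectors, ``p_fixed = M @ p_moving``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist
from skimage import transform as sktf
from skimage.measure import ransac as _sk_ransac

from .exceptions import (
    DegenerateGeometryError,
    InsufficientMatchesError,
    ValidationError,
)
from .image_prep import as_image
from .pyramid import KeyPoint

__all__ = [
    "MatchSet",
    "AffineTransform",
    "correlation_matrix",
    "ratio_test_match",
    "geometry_filter",
    "estimate_affine",
    "projection_error",
    "warp_image",
]

STAGES = ("raw", "ratio_filtered", "geometry_filtered")


@dataclass
class MatchSet:
    """Correspondences between moving and fixed keypoints.

    ``moving_idx``/``fixed_idx`` index into the keypoint lists the set was
    built from; ``distance`` is the descriptor-space Euclidean distance.
    """

    moving_idx: np.ndarray
    fixed_idx: np.ndarray
    distance: np.ndarray
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.moving_idx = np.asarray(self.moving_idx, dtype=int)
        self.fixed_idx = np.asarray(self.fixed_idx, dtype=int)
        self.distance = np.asarray(self.distance, dtype=float)
        if self.stage not in STAGES:
            raise ValidationError(f"unknown match stage {self.stage!r}")
        if len({a.shape for a in (self.moving_idx, self.fixed_idx, self.distance)}) != 1:
            raise ValidationError("match arrays must have equal length")
        if len(np.unique(self.moving_idx)) != len(self.moving_idx):
            raise ValidationError("each moving index may appear at most once")

    def __len__(self) -> int:
        return len(self.moving_idx)

    def pairs(self) -> list[tuple[int, int, float]]:
        return list(zip(self.moving_idx.tolist(), self.fixed_idx.tolist(), self.distance.tolist()))


@dataclass
class AffineTransform:
    """2D affine map as a 3x3 homogeneous matrix with last row (0, 0, 1)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValidationError(f"affine matrix must be 3x3, got {m.shape}")
        if not np.allclose(m[2], [0.0, 0.0, 1.0]):
            raise ValidationError(f"last row must be (0, 0, 1), got {m[2]}")
        m[2] = (0.0, 0.0, 1.0)
        self.matrix = m

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(3))

    @classmethod
    def from_params(
        cls,
        rotation_deg: float = 0.0,
        scale: float | tuple[float, float] = 1.0,
        translation: tuple[float, float] = (0.0, 0.0),
        shear: float = 0.0,
        center: tuple[float, float] = (0.0, 0.0),
    ) -> "AffineTransform":
        """Compose scale -> shear -> rotation about ``center``, then translate.

        ``shear`` is the off-diagonal x-shear coefficient. ``center`` is in
        (x, y) pixels; rotation is counter-clockwise in image (x right,
        y down) coordinates.
        """
        sx, sy = (scale, scale) if np.isscalar(scale) else scale
        if sx == 0 or sy == 0:
            raise ValidationError("scale factors must be nonzero")
        th = np.deg2rad(rotation_deg)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        sh = np.array([[1.0, shear], [0.0, 1.0]])
        sc = np.diag([sx, sy])
        lin = rot @ sh @ sc
        cx, cy = center
        t = np.asarray(translation, dtype=float) + np.array([cx, cy]) - lin @ [cx, cy]
        m = np.eye(3)
        m[:2, :2] = lin
        m[:2, 2] = t
        return cls(m)

    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:2, :2]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:2, 2]

    def is_invertible(self) -> bool:
        return abs(np.linalg.det(self.linear)) > 1e-12

    def inverse(self) -> "AffineTransform":
        if not self.is_invertible():
            raise ValidationError("transform is singular")
        return AffineTransform(np.linalg.inv(self.matrix))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map an (n, 2) array of (x, y) points into the fixed frame."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.linear.T + self.translation

    def to_json(self, **extra) -> str:
        payload = {"matrix": self.matrix.tolist(), **extra}
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "AffineTransform":
        return cls(np.asarray(json.loads(text)["matrix"], dtype=float))


def _locs(points: Sequence[KeyPoint], idx: np.ndarray | None = None) -> np.ndarray:
    arr = np.array([p.loc for p in points], dtype=float)
    return arr if idx is None else arr[idx]


def _unit_rows(x: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(x, axis=-1, keepdims=True)
    return x / np.maximum(n, 1e-300)


def correlation_matrix(
    moving: Sequence[KeyPoint], fixed: Sequence[KeyPoint], normalize: bool = False
) -> np.ndarray:
    """Pairwise descriptor distances, shape (n_moving, n_fixed).

    Entry (i, j) is the Euclidean distance between moving descriptor i and
    fixed descriptor j. With ``normalize`` the descriptors are scaled to
    unit length first: a monotone intensity remap acts locally like a gain
    on the pooled descriptor, and unit-scaling cancels that gain, which
    makes cross-modality matching far more reliable (an intensity inversion
    remains a sign flip, handled by the pipeline's polarity trial).
    """
    if len(moving) == 0 or len(fixed) == 0:
        raise ValidationError("keypoint lists must be non-empty")
    dm = np.array([p.descriptor for p in moving], dtype=float)
    df = np.array([p.descriptor for p in fixed], dtype=float)
    if dm.shape[1] != df.shape[1]:
        raise ValidationError(
            f"descriptor lengths differ: {dm.shape[1]} vs {df.shape[1]}"
        )
    if normalize:
        dm, df = _unit_rows(dm), _unit_rows(df)
    return cdist(dm, df)


def ratio_test_match(
    h_cor: np.ndarray, ratio: float = 0.75, unique_fixed: bool = True
) -> MatchSet:
    """Lowe ratio-test matching on a correlation (distance) matrix.

    A row's best match is accepted iff ``best <= ratio * second_best``;
    equality at the printed threshold counts as a match (implemented with a
    tiny relative tolerance so decimal boundary cases behave as printed).
    With ``unique_fixed`` (default), when several moving rows accept the
    same fixed column only the pair with the smallest distance survives, so
    matches are one-to-one; the plain row-wise rule (for which acceptance
    shrinks monotonically as the ratio decreases) is kept available with
    ``unique_fixed=False``.
    """
    h = np.asarray(h_cor, dtype=float)
    if h.ndim != 2 or h.shape[0] < 1:
        raise ValidationError(f"correlation matrix must be 2D, got shape {h.shape}")
    if h.shape[1] < 2:
        raise ValidationError("ratio test needs at least two fixed features")
    if not 0 < ratio:
        raise ValidationError(f"ratio must be positive, got {ratio}")
    part = np.partition(h, 1, axis=1)
    best, second = part[:, 0], part[:, 1]
    accept = best <= ratio * second * (1.0 + 1e-9)
    mov = np.nonzero(accept)[0]
    fix = np.argmin(h[mov], axis=1) if mov.size else np.empty(0, dtype=int)
    dist = best[mov]
    if unique_fixed:
        # one-to-one: keep the closest claimant per fixed index
        keep = {}
        for i, j, d in zip(mov, fix, dist):
            if j not in keep or d < keep[j][1]:
                keep[j] = (i, d)
        items = sorted((i, j, d) for j, (i, d) in keep.items())
        if items:
            mov, fix, dist = map(np.asarray, zip(*items))
        else:
            mov = fix = np.empty(0, dtype=int)
            dist = np.empty(0)
    return MatchSet(mov, fix, dist, stage="ratio_filtered")


def geometry_filter(
    matches: MatchSet,
    moving: Sequence[KeyPoint],
    fixed: Sequence[KeyPoint],
    residual_threshold: float = 3.0,
    max_trials: int = 2000,
    seed: int = 0,
    stop_probability: float = 0.9999,
) -> MatchSet:
    """Perspective-consistency filtering of ratio-test matches.

    Fits a projective (plane-to-plane) transform by seeded RANSAC and keeps
    only pairs whose reprojection error is within ``residual_threshold``
    pixels. Assumes the two images are views of one planar section, so any
    affine relation is a special case of the fitted model.

    Raises
    ------
    InsufficientMatchesError
        Fewer than 4 input pairs (the projective minimal sample).
    DegenerateGeometryError
        Consensus failed or found fewer than 3 inliers.
    """
    if len(matches) < 4:
        raise InsufficientMatchesError(
            f"geometry filter needs >= 4 pairs, got {len(matches)}"
        )
    src = _locs(moving, matches.moving_idx)
    dst = _locs(fixed, matches.fixed_idx)
    try:
        model, inliers = _sk_ransac(
            (src, dst),
            sktf.ProjectiveTransform,
            min_samples=4,
            residual_threshold=residual_threshold,
            max_trials=max_trials,
            stop_probability=stop_probability,
            rng=seed,
        )
    except Exception as exc:  # rank-deficient samples raise inside skimage
        raise DegenerateGeometryError(f"consensus fit failed: {exc}") from exc
    if model is None or inliers is None or int(inliers.sum()) < 3:
        raise DegenerateGeometryError(
            "perspective consensus found fewer than 3 inliers"
        )
    return MatchSet(
        matches.moving_idx[inliers],
        matches.fixed_idx[inliers],
        matches.distance[inliers],
        stage="geometry_filtered",
    )


def estimate_affine(
    matches: MatchSet,
    moving: Sequence[KeyPoint],
    fixed: Sequence[KeyPoint],
) -> tuple[AffineTransform, float]:
    """Least-squares affine from matched keypoint locations.

    Minimises the summed Euclidean projection error between fixed locations
    and affine-mapped moving locations; returns the transform together with
    the residual projection error at the optimum. Solved via ``lstsq``
    (orthogonal decomposition), never normal equations.

    Raises
    ------
    DegenerateGeometryError
        Fewer than 3 pairs, or all pairs (near-)collinear.
    """
    if len(matches) < 3:
        raise DegenerateGeometryError(
            f"affine estimation needs >= 3 pairs, got {len(matches)}"
        )
    src = _locs(moving, matches.moving_idx)
    dst = _locs(fixed, matches.fixed_idx)
    a = np.column_stack([src, np.ones(len(src))])
    if np.linalg.matrix_rank(a, tol=1e-8 * max(1.0, np.abs(a).max())) < 3:
        raise DegenerateGeometryError("matched moving points are collinear")
    theta, *_ = np.linalg.lstsq(a, dst, rcond=None)
    m = np.eye(3)
    m[0, :] = theta[:, 0]
    m[1, :] = theta[:, 1]
    transform = AffineTransform(m)
    return transform, projection_error(transform, matches, moving, fixed)


def projection_error(
    transform: AffineTransform,
    matches: MatchSet,
    moving: Sequence[KeyPoint],
    fixed: Sequence[KeyPoint],
) -> float:
    """Sum of Euclidean residuals between fixed points and mapped moving points."""
    if len(matches) == 0:
        raise ValidationError("projection error of an empty match set is undefined")
    src = _locs(moving, matches.moving_idx)
    dst = _locs(fixed, matches.fixed_idx)
    res = dst - transform.apply(src)
    return float(np.linalg.norm(res, axis=1).sum())


def warp_image(
    moving: np.ndarray,
    transform: AffineTransform,
    out_shape: tuple[int, int] | None = None,
    order: int = 1,
    cval: float = 0.0,
) -> np.ndarray:
    """Resample ``moving`` into the fixed frame by inverse mapping.

    ``order=1`` is bilinear (images); ``order=0`` nearest-neighbour (use for
    masks to preserve binarity). Out-of-source pixels are filled with
    ``cval``.
    """
    moving = as_image(moving)
    if not transform.is_invertible():
        raise ValidationError("cannot warp by a singular transform")
    inv = sktf.AffineTransform(matrix=transform.inverse().matrix)
    return sktf.warp(
        moving,
        inverse_map=inv,
        output_shape=out_shape or moving.shape,
        order=order,
        cval=cval,
        preserve_range=True,
    )
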