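"""End-to-end registration pipeline.

Three phases: (1) detect — dense pyramid-pooling descriptors, magnitude map,
distance-regulated keypoint selection on both images; (2) match — ratio-test
nearest-neighbour matching in descriptor space followed by perspective
consensus filtering; (3) estimate — least-squares affine from the inlier
pairs, then warping of the moving image into the fixed frame.

Two practical robustness layers wrap the core method:

* **Intensity representation.** The pooled descriptor is linear in
  intensity, so a contrast inversion (absorbance histology vs.
  emission-style ion maps) negates it, and a non-affine monotone remap
  distorts it. Matching is therefore tried on three moving-image
  candidates — the image as-is (with a descriptor-sign polarity trial,
  exact for affinely related intensities) and the image and its complement
  histogram-matched onto the fixed image (which undoes any monotone
  increasing remap) — and the winner is picked by an alignment score.
  Keypoint *locations* are identical across polarity flips because the
  magnitude map is a norm.

* **Coarse-to-fine geometry.** The descriptor is not rotation-invariant;
  beyond ~10 degrees of relative rotation direct matching degrades. The
  pipeline therefore (a) searches a small set of candidate pre-rotations
  of the moving image, (b) refines globally by warping the moving image
  with the current estimate and re-matching, and (c) polishes with a
  *local descriptor search*: for every fixed keypoint, the best-matching
  descriptor within a radius in the dense descriptor field of the warped
  moving image is taken as its correspondence, and the correction is
  re-estimated from those near-exact pairs (again under RANSAC), with the
  radii cycling coarse-to-fine.

Every refinement step must improve a ground-truth-free alignment score
(median best local descriptor distance at the fixed keypoints), which
keeps noise-biased corrections from degrading a good estimate.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
from skimage import transform as sktf
from skimage.measure import ransac as _sk_ransac

from . import image_prep, matching, pyramid
from .exceptions import PoolregError
from .matching import AffineTransform, MatchSet
from .pyramid import KeyPoint, PyramidConfig

__all__ = ["RegistrationConfig", "RegistrationResult", "preprocess", "register"]


@dataclass
class RegistrationConfig:
    """Everything needed to reproduce a registration run.

    ``rotation_search`` lists candidate pre-rotations (degrees) of the
    moving image tried in order; the search stops early once a candidate
    reaches ``early_exit_inliers`` geometry-filter inliers.
    ``local_refine_radii`` are the search radii (pixels) the local
    descriptor-search refinement cycles through (coarse to fine), up to
    ``local_refine_max_iter`` guarded iterations in total.
    """

    pyramid: PyramidConfig = field(default_factory=PyramidConfig)
    ratio: float = 0.75
    residual_threshold: float = 3.0
    max_trials: int = 2000
    seed: int = 0
    hotspot_quantile: float | None = 0.99
    normalize: bool = True
    pre_rotation: int = 0  # quarter turns applied to the moving image first
    try_polarity_inversion: bool = True
    normalize_descriptors: bool = True
    histogram_match: bool = True
    smooth_sigma: float = 1.0
    rotation_search: tuple[float, ...] = (0.0, 10.0, -10.0, 20.0, -20.0, 30.0, -30.0)
    early_exit_inliers: int = 30
    refine_iterations: int = 2
    local_refine_radii: tuple[int, ...] = (16, 8, 4)
    local_refine_max_iter: int = 15

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pyramid"] = asdict(self.pyramid)
        return d


@dataclass
class RegistrationResult:
    """Recovered transform plus per-stage provenance.

    ``matches``, ``moving_keypoints`` and ``fixed_keypoints`` come from the
    winning global matching pass (useful for visualisation);
    ``projection_error`` is the residual of the final refinement fit, i.e.
    the remaining summed misalignment over its correspondences.
    """

    transform: AffineTransform
    projection_error: float
    matches: MatchSet
    moving_keypoints: list[KeyPoint]
    fixed_keypoints: list[KeyPoint]
    n_ratio_matches: int
    polarity: int
    pre_rotation_deg: float
    warped: np.ndarray | None
    config: RegistrationConfig

    @property
    def mean_residual(self) -> float:
        return self.projection_error / max(len(self.matches), 1)

    def counts(self) -> dict:
        return {
            "keypoints_moving": len(self.moving_keypoints),
            "keypoints_fixed": len(self.fixed_keypoints),
            "ratio_filtered": self.n_ratio_matches,
            "geometry_filtered": len(self.matches),
        }


def preprocess(
    image: np.ndarray, config: RegistrationConfig, rotate: bool = False
) -> np.ndarray:
    """Hotspot clip, normalise to [0, 1], mild Gaussian smoothing.

    The optional quarter-turn pre-rotation (``rotate=True``) is applied
    first; smoothing (``smooth_sigma`` pixels) suppresses pixel noise before
    any descriptor is computed.
    """
    out = image_prep.as_image(image)
    if rotate and config.pre_rotation:
        out = image_prep.rotate90(out, config.pre_rotation)
    if config.hotspot_quantile is not None:
        out = image_prep.hotspot_clip(out, config.hotspot_quantile)
    if config.normalize:
        out = image_prep.normalize_intensity(out)
    if config.smooth_sigma > 0:
        from scipy.ndimage import gaussian_filter

        out = gaussian_filter(out, config.smooth_sigma)
    return out


def _negate(points: list[KeyPoint]) -> list[KeyPoint]:
    return [
        KeyPoint(loc=p.loc, descriptor=-p.descriptor, magnitude=p.magnitude)
        for p in points
    ]


def _match_pass(
    fixed_kp: list[KeyPoint],
    moving_p: np.ndarray,
    config: RegistrationConfig,
    polarities: tuple[int, ...] = (1,),
) -> tuple:
    """One detect→match→filter→estimate pass against precomputed fixed keypoints.

    Returns (transform, d_proj, inliers, n_ratio, polarity, moving_kp).
    Raises a PoolregError when no polarity yields a consensus.
    """
    cfg = config.pyramid
    moving_kp = pyramid.select_keypoints(
        pyramid.magnitude_map(moving_p, cfg), moving_p, cfg
    )
    best: tuple | None = None
    first_error: PoolregError | None = None
    for pol in polarities:
        mov = moving_kp if pol == 1 else _negate(moving_kp)
        try:
            h = matching.correlation_matrix(
                mov, fixed_kp, normalize=config.normalize_descriptors
            )
            ratio_matches = matching.ratio_test_match(h, config.ratio)
            inliers = matching.geometry_filter(
                ratio_matches,
                mov,
                fixed_kp,
                residual_threshold=config.residual_threshold,
                max_trials=config.max_trials,
                seed=config.seed,
            )
            transform, d_proj = matching.estimate_affine(inliers, mov, fixed_kp)
        except PoolregError as exc:
            if first_error is None:
                first_error = exc
            continue
        mean_res = d_proj / max(len(inliers), 1)
        key = (len(inliers), -mean_res)
        if best is None or key > best[0]:
            best = (key, transform, d_proj, inliers, len(ratio_matches), pol)
    if best is None:
        assert first_error is not None
        raise first_error
    return best[1:] + (moving_kp,)


def _local_refine(
    fixed_kp: list[KeyPoint],
    warped_p: np.ndarray,
    polarity: int,
    radius: int,
    config: RegistrationConfig,
) -> tuple[AffineTransform, float] | None:
    """Correction transform from a local descriptor search around each keypoint.

    For each fixed keypoint, finds the pixel within ``radius`` (in the dense
    descriptor field of the nearly aligned warped moving image) whose
    descriptor is closest to the keypoint's, pairs them, and fits the
    residual affine under the same RANSAC consensus. Returns None when the
    configuration is too weak to refine.
    """
    desc, bw = pyramid.dense_descriptors(warped_p, config.pyramid)
    if config.normalize_descriptors:
        desc = desc / np.maximum(
            np.sqrt(np.einsum("kij,kij->ij", desc, desc))[None], 1e-300
        )
    n_r, n_c = desc.shape[1:]
    src, dst = [], []
    for p in fixed_kp:
        u, v = p.loc
        rr, cc = v - bw, u - bw  # valid-region coordinates
        r0, r1 = max(0, rr - radius), min(n_r, rr + radius + 1)
        c0, c1 = max(0, cc - radius), min(n_c, cc + radius + 1)
        if r0 >= r1 or c0 >= c1:
            continue
        ref = polarity * p.descriptor
        if config.normalize_descriptors:
            ref = ref / max(np.linalg.norm(ref), 1e-300)
        patch = desc[:, r0:r1, c0:c1] - ref[:, None, None]
        dist2 = np.einsum("kij,kij->ij", patch, patch)
        dv, du = np.unravel_index(np.argmin(dist2), dist2.shape)
        # sub-pixel offset: 1D parabola through the distance surface per axis
        sv = su = 0.0
        if 0 < dv < dist2.shape[0] - 1:
            a, b, c2 = dist2[dv - 1, du], dist2[dv, du], dist2[dv + 1, du]
            den = a - 2 * b + c2
            if den > 0:
                sv = float(np.clip(0.5 * (a - c2) / den, -0.5, 0.5))
        if 0 < du < dist2.shape[1] - 1:
            a, b, c2 = dist2[dv, du - 1], dist2[dv, du], dist2[dv, du + 1]
            den = a - 2 * b + c2
            if den > 0:
                su = float(np.clip(0.5 * (a - c2) / den, -0.5, 0.5))
        src.append((c0 + du + bw + su, r0 + dv + bw + sv))
        dst.append(p.loc)
    if len(src) < 8:
        return None
    src_a = np.asarray(src, dtype=float)
    dst_a = np.asarray(dst, dtype=float)
    try:
        model, inl = _sk_ransac(
            (src_a, dst_a),
            sktf.ProjectiveTransform,
            min_samples=4,
            residual_threshold=config.residual_threshold,
            max_trials=config.max_trials,
            rng=config.seed,
        )
    except Exception:
        return None
    if model is None or inl is None or int(inl.sum()) < 8:
        return None
    s, d = src_a[inl], dst_a[inl]
    a = np.column_stack([s, np.ones(len(s))])
    if np.linalg.matrix_rank(a) < 3:
        return None
    theta, *_ = np.linalg.lstsq(a, d, rcond=None)
    m = np.eye(3)
    m[0, :] = theta[:, 0]
    m[1, :] = theta[:, 1]
    delta = AffineTransform(m)
    res = float(np.linalg.norm(d - delta.apply(s), axis=1).sum())
    return delta, res


def _alignment_score(
    fixed_kp: list[KeyPoint],
    moving_img: np.ndarray,
    transform: AffineTransform,
    polarity: int,
    config: RegistrationConfig,
    radius: int = 2,
) -> float:
    """Median best local descriptor distance under ``transform`` (lower = better).

    Warps the moving image by the candidate transform and, at every fixed
    keypoint, takes the smallest (unit-normalised) descriptor distance
    within ``radius`` pixels. Used to accept or reject refinement steps
    without any ground truth.
    """
    warped = matching.warp_image(moving_img, transform, out_shape=moving_img.shape)
    desc, bw = pyramid.dense_descriptors(warped, config.pyramid)
    if config.normalize_descriptors:
        desc = desc / np.maximum(
            np.sqrt(np.einsum("kij,kij->ij", desc, desc))[None], 1e-300
        )
    n_r, n_c = desc.shape[1:]
    dists = []
    for p in fixed_kp:
        u, v = p.loc
        rr, cc = v - bw, u - bw
        r0, r1 = max(0, rr - radius), min(n_r, rr + radius + 1)
        c0, c1 = max(0, cc - radius), min(n_c, cc + radius + 1)
        if r0 >= r1 or c0 >= c1:
            continue
        ref = polarity * p.descriptor
        if config.normalize_descriptors:
            ref = ref / max(np.linalg.norm(ref), 1e-300)
        patch = desc[:, r0:r1, c0:c1] - ref[:, None, None]
        dists.append(np.sqrt(np.einsum("kij,kij->ij", patch, patch).min()))
    return float(np.median(dists)) if dists else np.inf


def _rotation_about_center(deg: float, shape: tuple[int, int]) -> AffineTransform:
    h, w = shape
    return AffineTransform.from_params(
        rotation_deg=deg, center=((w - 1) / 2.0, (h - 1) / 2.0)
    )


def register(
    fixed: np.ndarray,
    moving: np.ndarray,
    config: RegistrationConfig | None = None,
    warp: bool = True,
) -> RegistrationResult:
    """Register ``moving`` onto ``fixed``; returns the affine and provenance.

    The returned transform maps moving-image (x, y) coordinates into the
    fixed frame (after any configured quarter-turn pre-rotation of the
    moving image). Raises :class:`InsufficientMatchesError` or
    :class:`DegenerateGeometryError` when no rotation candidate yields a
    usable geometric consensus.
    """
    config = config or RegistrationConfig()
    fixed_p = preprocess(fixed, config)
    moving_p = preprocess(moving, config, rotate=True)

    cfg = config.pyramid
    fixed_kp = pyramid.select_keypoints(
        pyramid.magnitude_map(fixed_p, cfg), fixed_p, cfg
    )

    # Moving-image candidates. The raw image (with a descriptor-sign
    # polarity trial) is exact when the modalities share an affine intensity
    # relation; the histogram-matched variants map the moving intensity
    # distribution onto the fixed one, which undoes any monotone increasing
    # modality remap, with ``1 - moving`` covering contrast inversion at the
    # image level. Consensus strength picks the representation.
    raw_pols = (1, -1) if config.try_polarity_inversion else (1,)
    variants: list[tuple[int, np.ndarray, tuple[int, ...]]] = [
        (1, moving_p, raw_pols)
    ]
    if config.histogram_match:
        from skimage.exposure import match_histograms

        variants.append((1, match_histograms(moving_p, fixed_p), (1,)))
        if config.try_polarity_inversion:
            inv = 1.0 - moving_p if config.normalize else -moving_p
            variants.append((-1, match_histograms(inv, fixed_p), (1,)))

    # --- phase A: coarse rotation search with global matching ---
    angles = list(dict.fromkeys(config.rotation_search)) or [0.0]
    best: tuple | None = None
    first_error: PoolregError | None = None
    strong_consensus = False
    for deg in angles:
        for variant_pol, var_img, var_desc_pols in variants:
            if deg == 0.0:
                mov_img, rot = var_img, AffineTransform.identity()
            else:
                rot = _rotation_about_center(deg, var_img.shape)
                mov_img = matching.warp_image(var_img, rot, out_shape=fixed_p.shape)
            try:
                transform, d_proj, inliers, n_ratio, pol, mov_kp = _match_pass(
                    fixed_kp, mov_img, config, var_desc_pols
                )
            except PoolregError as exc:
                if first_error is None:
                    first_error = exc
                continue
            total = AffineTransform(transform.matrix @ rot.matrix)
            # candidates are ranked by the ground-truth-free alignment
            # score: inlier counts are not comparable across image variants
            score = _alignment_score(fixed_kp, var_img, total, pol, config)
            if best is None or score < best[0]:
                best = (
                    score, total, d_proj, inliers, n_ratio,
                    pol * variant_pol, var_img, var_desc_pols, pol, mov_kp, deg,
                )
            if len(inliers) >= config.early_exit_inliers:
                strong_consensus = True
                break
        if strong_consensus:
            break
    if best is None:
        assert first_error is not None
        raise first_error
    (
        score, transform, d_proj, inliers, n_ratio, pol,
        active_img, active_desc_pols, desc_pol, mov_kp, search_deg,
    ) = best

    # Refinement steps are only accepted when they improve the alignment
    # score, which keeps a noise-biased correction from degrading a good
    # estimate.

    # --- phase B: global refinement on the warped pair ---
    for _ in range(config.refine_iterations):
        warped_p = matching.warp_image(active_img, transform, out_shape=fixed_p.shape)
        try:
            delta, d_proj_b, *_ = _match_pass(
                fixed_kp, warped_p, config, active_desc_pols
            )
        except PoolregError:
            break  # keep the last good estimate
        candidate = AffineTransform(delta.matrix @ transform.matrix)
        cand_score = _alignment_score(fixed_kp, active_img, candidate, desc_pol, config)
        if cand_score >= score:
            break
        transform, score, d_proj = candidate, cand_score, d_proj_b

    # --- phase C: local descriptor-search refinement, iterated to a score
    # fixed point. The search radii cycle coarse-to-fine (a coarse pass
    # catches corner displacements a fine pass cannot see); iteration stops
    # once a full cycle brings no accepted improvement, since rejected
    # steps recompute identically ---
    radii = config.local_refine_radii
    rejected_in_row = 0
    for i in range(config.local_refine_max_iter):
        radius = radii[i % len(radii)]
        warped_p = matching.warp_image(active_img, transform, out_shape=fixed_p.shape)
        refined = _local_refine(fixed_kp, warped_p, desc_pol, radius, config)
        if refined is None:
            break
        delta, d_proj_c = refined
        candidate = AffineTransform(delta.matrix @ transform.matrix)
        cand_score = _alignment_score(fixed_kp, active_img, candidate, desc_pol, config)
        if cand_score >= score:
            rejected_in_row += 1
            if rejected_in_row >= len(radii):
                break
            continue
        rejected_in_row = 0
        transform, score, d_proj = candidate, cand_score, d_proj_c

    warped = (
        matching.warp_image(moving_p, transform, out_shape=fixed_p.shape)
        if warp
        else None
    )
    return RegistrationResult(
        transform=transform,
        projection_error=d_proj,
        matches=inliers,
        moving_keypoints=mov_kp,
        fixed_keypoints=fixed_kp,
        n_ratio_matches=n_ratio,
        polarity=pol,
        pre_rotation_deg=search_deg,
        warped=warped,
        config=config,
    )
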