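"""Synthetic modality-shifted image pairs with known ground-truth affines.

The generator draws a smooth "tissue" on the fixed frame — a handful of
anisotropic Gaussian blobs plus band-limited texture at two spatial scales —
and produces the moving image by resampling that content through the inverse
of a known affine, applying a monotone intensity remap (the modality change:
gamma curve, contrast inversion, or a piecewise-linear tone curve), adding
Gaussian noise, and optionally a sprinkle of saturated hotspot pixels
mimicking laser-ablation MS outliers. Masks are thresholded from the blob
field and carried through the same geometry, so registration quality can be
scored by Dice / Hausdorff against ground truth.

Monotone remaps preserve the ordering of intensities, hence image structure,
while changing absolute values — the situation the pooled descriptor is
designed for. What the generator does *not* emulate: non-rigid tissue
deformation, section-to-section content differences, and structured
(non-i.i.d.) noise.

The transform composition order is scale -> shear -> rotation about the
frame centre, then translation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .exceptions import ConfigurationError, ValidationError
from .matching import AffineTransform, warp_image
from .metrics import dice
from .pipeline import RegistrationConfig, register

__all__ = [
    "TransformParams",
    "FixtureConfig",
    "FixturePair",
    "generate_pair",
    "corner_displacement",
    "recovery_suite",
]


@dataclass(frozen=True)
class TransformParams:
    rotation_deg: float = 0.0
    scale: float = 1.0
    translation: tuple[float, float] = (0.0, 0.0)
    shear: float = 0.0


@dataclass(frozen=True)
class FixtureConfig:
    """Study conditions for one synthetic pair.

    ``noise_sigma`` is the Gaussian noise level as a fraction of the image
    dynamic range; ``hotspot_fraction`` the share of pixels replaced by
    saturated outliers (exercises hotspot clipping).
    """

    seed: int = 0
    shape: tuple[int, int] = (256, 256)
    n_blobs: int = 6
    texture_scale: float = 0.25
    transform: TransformParams = field(default_factory=TransformParams)
    intensity_remap: str = "identity"
    noise_sigma: float = 0.0
    hotspot_fraction: float = 0.0
    mask: bool = True
    mask_level: float = 0.3

    def __post_init__(self) -> None:
        if min(self.shape) < 64:
            raise ValidationError(f"fixture frames must be >= 64x64, got {self.shape}")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        if self.transform.scale <= 0:
            raise ValidationError("scale factor must be > 0")


@dataclass
class FixturePair:
    fixed: np.ndarray
    moving: np.ndarray
    truth: AffineTransform
    fixed_mask: np.ndarray | None
    moving_mask: np.ndarray | None
    config: FixtureConfig


def _remap_identity(x: np.ndarray) -> np.ndarray:
    return x


def _remap_gamma(x: np.ndarray) -> np.ndarray:
    return np.clip(x, 0.0, None) ** 0.7


def _remap_inverted(x: np.ndarray) -> np.ndarray:
    return 1.0 - x


def _remap_piecewise(x: np.ndarray) -> np.ndarray:
    # 3-segment monotone tone curve: compresses shadows/highlights
    return np.interp(x, [0.0, 0.3, 0.7, 1.0], [0.0, 0.15, 0.85, 1.0])


REMAPS = {
    "identity": _remap_identity,
    "gamma": _remap_gamma,
    "inverted": _remap_inverted,
    "piecewise": _remap_piecewise,
}


def _tissue(config: FixtureConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Blob field (for masks) and full textured fixed image, both in [0, 1]."""
    h, w = config.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    blob = np.zeros((h, w))
    for _ in range(config.n_blobs):
        cy = rng.uniform(0.25 * h, 0.75 * h)
        cx = rng.uniform(0.25 * w, 0.75 * w)
        sy = rng.uniform(h / 16, h / 7)
        sx = rng.uniform(w / 16, w / 7)
        th = rng.uniform(0, np.pi)
        amp = rng.uniform(0.5, 1.0)
        dy, dx = yy - cy, xx - cx
        ry = dy * np.cos(th) - dx * np.sin(th)
        rx = dy * np.sin(th) + dx * np.cos(th)
        blob += amp * np.exp(-0.5 * ((ry / sy) ** 2 + (rx / sx) ** 2))
    blob /= blob.max()
    tex = gaussian_filter(rng.standard_normal((h, w)), sigma=4.0)
    tex += 0.5 * gaussian_filter(rng.standard_normal((h, w)), sigma=10.0)
    tex /= max(np.abs(tex).max(), 1e-12)
    img = blob + config.texture_scale * tex * blob  # texture modulated by tissue
    img -= img.min()
    img /= max(img.max(), 1e-12)
    return blob, img


def generate_pair(config: FixtureConfig | None = None) -> FixturePair:
    """Deterministically generate one fixed/moving pair for a seed."""
    config = config or FixtureConfig()
    if config.intensity_remap not in REMAPS:
        raise ConfigurationError(
            f"unknown intensity remap {config.intensity_remap!r}; known: {sorted(REMAPS)}"
        )
    rng = np.random.default_rng(config.seed)
    h, w = config.shape
    blob, fixed = _tissue(config, rng)

    tp = config.transform
    truth = AffineTransform.from_params(
        rotation_deg=tp.rotation_deg,
        scale=tp.scale,
        translation=tp.translation,
        shear=tp.shear,
        center=((w - 1) / 2.0, (h - 1) / 2.0),
    )
    # moving(p) = fixed_content(truth @ p): warp_image inverse-maps by its
    # argument's inverse, so pass truth.inverse()
    moving = warp_image(fixed, truth.inverse(), out_shape=(h, w))
    moving = REMAPS[config.intensity_remap](moving)
    if config.noise_sigma > 0:
        moving = moving + rng.normal(0.0, config.noise_sigma, size=moving.shape)
    if config.hotspot_fraction > 0:
        n_hot = max(1, int(config.hotspot_fraction * moving.size))
        idx = rng.choice(moving.size, size=n_hot, replace=False)
        flat = moving.ravel()
        flat[idx] = moving.max() * rng.uniform(3.0, 10.0, size=n_hot)
        moving = flat.reshape(moving.shape)

    fixed_mask = moving_mask = None
    if config.mask:
        fixed_mask = blob > config.mask_level
        moving_mask = (
            warp_image(fixed_mask.astype(float), truth.inverse(), out_shape=(h, w), order=0)
            > 0.5
        )
    return FixturePair(fixed, moving, truth, fixed_mask, moving_mask, config)


def corner_displacement(
    estimated: AffineTransform, truth: AffineTransform, shape: tuple[int, int]
) -> tuple[float, float]:
    """(mean, max) displacement between the two maps over the frame corners."""
    h, w = shape
    corners = np.array(
        [[0.0, 0.0], [w - 1.0, 0.0], [0.0, h - 1.0], [w - 1.0, h - 1.0]]
    )
    d = np.linalg.norm(estimated.apply(corners) - truth.apply(corners), axis=1)
    return float(d.mean()), float(d.max())


def _suite_cases(n_cases: int, seed: int, shape: tuple[int, int]) -> list[FixtureConfig]:
    """Case grid: remaps and noise levels cycled, geometry drawn per case.

    Rotations within +/-30 degrees, scales 0.9–1.1, translations up to 15%
    of the frame, mild shear.
    """
    rng = np.random.default_rng(seed)
    remaps = list(REMAPS)
    noises = [0.0, 0.02, 0.05]
    h, w = shape
    cases = []
    for i in range(n_cases):
        tp = TransformParams(
            rotation_deg=float(rng.uniform(-30, 30)),
            scale=float(rng.uniform(0.9, 1.1)),
            translation=(
                float(rng.uniform(-0.15, 0.15) * w),
                float(rng.uniform(-0.15, 0.15) * h),
            ),
            shear=float(rng.uniform(-0.05, 0.05)),
        )
        cases.append(
            FixtureConfig(
                seed=int(rng.integers(0, 2**31 - 1)),
                shape=shape,
                transform=tp,
                intensity_remap=remaps[i % len(remaps)],
                noise_sigma=noises[i % len(noises)],
            )
        )
    return cases


def recovery_suite(
    n_cases: int = 20,
    seed: int = 0,
    shape: tuple[int, int] = (256, 256),
    registration_config: RegistrationConfig | None = None,
) -> pd.DataFrame:
    """Run the full pipeline over a seeded battery of fixture pairs.

    Returns one row per case with the drawn conditions, the corner
    displacement error of the recovered affine against ground truth, mask
    Dice before/after registration, and the per-stage match counts.
    """
    if n_cases < 1:
        raise ValidationError("n_cases must be >= 1")
    rows = []
    for i, fc in enumerate(_suite_cases(n_cases, seed, shape)):
        pair = generate_pair(fc)
        reg_cfg = registration_config or RegistrationConfig(seed=seed)
        row = {
            "case": i,
            "rotation_deg": fc.transform.rotation_deg,
            "scale": fc.transform.scale,
            "tx": fc.transform.translation[0],
            "ty": fc.transform.translation[1],
            "remap": fc.intensity_remap,
            "noise_sigma": fc.noise_sigma,
            "dice_before": dice(pair.fixed_mask, pair.moving_mask),
        }
        try:
            result = register(pair.fixed, pair.moving, reg_cfg, warp=False)
        except Exception as exc:  # a failed case is reported, not fatal
            row.update(
                error=type(exc).__name__,
                corner_err_mean=np.nan,
                corner_err_max=np.nan,
                dice_after=np.nan,
            )
            rows.append(row)
            continue
        mean_err, max_err = corner_displacement(result.transform, pair.truth, shape)
        warped_mask = (
            warp_image(
                pair.moving_mask.astype(float),
                result.transform,
                out_shape=shape,
                order=0,
            )
            > 0.5
        )
        row.update(
            error="",
            corner_err_mean=mean_err,
            corner_err_max=max_err,
            dice_after=dice(pair.fixed_mask, warped_mask),
            polarity=result.polarity,
            **result.counts(),
        )
        rows.append(row)
    return pd.DataFrame(rows)
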