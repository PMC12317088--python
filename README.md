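# poolreg

Feature-based registration of multi-modal 2D biomedical images — histology
(H&E) against mass-spectrometry imaging (MALDI-MSI, LA-ICP-MSI) ion maps,
or any pair of single-channel rasters of the same section whose intensities
are related by an unknown monotone mapping.

Classical detectors (SIFT, ORB) key on modality-specific gradients and
break down across imaging modalities. `poolreg` instead describes each
pixel by hierarchical average pooling over its W×W working window: layer
*l* of *L* splits the window into 2^(l−1) equal blocks and records each
block's mean intensity; the whole-window mean is subtracted, giving a
fixed-length (2^L − 2) descriptor that is exactly invariant to intensity
offsets and damps pixel noise by averaging. Keypoints are the peaks of the
descriptor-norm ("feature magnitude") map, selected greedily under a
minimum-distance constraint D. Matching is nearest-neighbour in descriptor
space under Lowe's ratio test (accept iff `H[0] ≤ 0.75·H[1]`), followed by
a RANSAC perspective-consistency filter, and the final 2D affine **M**
minimising the summed projection error `Σᵢ ‖P_F^i − M·P_M^i‖` is fit by
least squares to the inlier pairs. Registration quality is scored by Dice
overlap, Hausdorff distance, and mutual information.

No external data is needed: a synthetic fixture generator produces
modality-shifted image pairs with known ground-truth affines and masks, so
the whole pipeline is testable end-to-end. See `docs/methods.md` for the
model, parameter defaults, and design choices.

## Worked example

```python
import poolreg

# a synthetic cross-modality pair: rotated 12°, scaled 1.05, translated,
# gamma-remapped intensities, 2% noise — ground truth known
fc = poolreg.FixtureConfig(
    seed=3,
    transform=poolreg.TransformParams(
        rotation_deg=12, scale=1.05, translation=(10, -8)),
    intensity_remap="gamma",
    noise_sigma=0.02,
)
pair = poolreg.generate_pair(fc)

result = poolreg.register(pair.fixed, pair.moving)
print(result.counts())
mean_err, max_err = poolreg.corner_displacement(
    result.transform, pair.truth, fc.shape)
print(f"corner error: mean {mean_err:.2f} px, max {max_err:.2f} px")

warped_mask = poolreg.warp_image(
    pair.moving_mask.astype(float), result.transform,
    out_shape=fc.shape, order=0) > 0.5
print(f"dice after registration: {poolreg.dice(pair.fixed_mask, warped_mask):.3f}")
```

prints

```
{'keypoints_moving': 197, 'keypoints_fixed': 198, 'ratio_filtered': 86, 'geometry_filtered': 52}
corner error: mean 1.21 px, max 1.92 px
dice after registration: 0.994
```

i.e. out of ~200 keypoints per image, 86 moving keypoints survive the
ratio test and 52 the perspective-consistency filter; the affine estimated
from those pairs reproduces the ground-truth transform to within two
pixels at the image corners despite the modality gap and noise, and the
tissue masks overlap almost perfectly after warping.

The same pipeline from the shell:

```sh
poolreg fixtures generate -o fx/ --n-cases 1
poolreg register fx/case_000_fixed.tif fx/case_000_moving.tif -o out/ \
    --fixed-mask fx/case_000_fixed_mask.png --moving-mask fx/case_000_moving_mask.png
```

`register` writes `warped.tif`, `transform.json` (3×3 matrix plus a full
provenance block: effective config, seed, match counts per stage), and
`matches.csv`. Exit codes distinguish validation/I-O failures (2),
insufficient matches (3), and degenerate geometry (4). `features detect`
and `matches show` expose the intermediate magnitude map, keypoints, and
match visualisation for debugging.

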