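# chronolux

Colorimetric image statistics and perceived time-of-day modeling for
outdoor-scene images.

Daylight changes predictably over the course of a day: solar elevation
drives illuminance, spectral shape (correlated color temperature, CCT),
diffuseness, and haze. Paintings and photographs of outdoor scenes inherit
these regularities, and human viewers exploit them when judging the
depicted time of day. `chronolux` implements that analysis chain for
vision scientists and computational-aesthetics researchers:

1. **Colorimetry** — decode gamma-encoded RGB (`I = v^γ`, γ = 2.2) to
   CIE XYZ under a configurable display white point; derive CIELAB,
   chroma/hue/saturation, CIE 1960 (u, v), CCT and the signed locus
   distance D_uv (positive above the Planckian locus, toward green), and
   CIEDE2000 (ΔE00) color differences.
2. **Photoreceptor activations** — reconstruct a per-pixel spectrum from
   linear RGB with fitted primary spectra and integrate against L/M/S
   cone, rod (scotopic), and melanopic sensitivity curves.
3. **Image statistics** — a canonical, fixed-order vector of 30 per-image
   statistics (luminance moments, luma, receptor means, RMS contrasts,
   chromatic summaries, CCT-based measures, luminance-weighted CCT, the
   ΔE00 between brightest and darkest pixels, and luminance–chromaticity
   correlations and distances), plus a dark-channel-prior airlight
   (haze color) estimate per image.
4. **Perception model** — score observer ratings on 7-point, 4-point
   merged, or binary morning/evening chronological scales (with catch-trial
   observer exclusion); PCA on z-scored statistics retaining eigenvalues
   greater than 1; forward regression with AIC model selection; covariance
   ellipses enclosing a target fraction (default 68%) of each category's
   images in PC space. The published two-component model

   ```
   mean time-of-day rating = 0.583 + 0.034·PC1 + 0.017·PC2
   ```

   ships as a frozen asset for prediction without refitting.
5. **Synthetic studies** — seeded generators for outdoor scenes with
   controlled illuminant CCT/D_uv, luminance, contrast, haze density and
   airlight color, plus noisy-observer ratings from a latent time-of-day
   score, so the entire pipeline is testable without image downloads.

## Worked example

Generate a 24-image synthetic study (latent scores from 0 = morning pole
to 1 = evening pole) and run the full pipeline:

```bash
chronolux simulate --n-images 24 --n-obs 15 --noise-sd 0.1 --seed 7 -o demo/study
chronolux extract-stats demo/study/images -o demo/out --ratings demo/study/ratings.csv
```

Selected statistics for the two extreme images:

```
          mean_luminance  mean_image_cct  rms_contrast_luminance  mean_bstar
img0000            0.597        7617.947                   0.213      -8.373
img0023            0.300        3700.451                   0.598      22.997
```

The morning-pole image (`img0000`) is bright and cool (CCT ≈ 7600 K,
negative b* = bluish); the evening-pole image is dim and warm (≈ 3700 K,
strongly positive b* = yellowish). Forward-AIC selection on the PCA of all
30 statistics reports:

```
selected: ['PC1', 'PC2']  intercept 0.511  coefs [0.0567, 0.0165]  R2 0.988
```

and per-image predictions track the observed normalized mean scores:

```
            PC1    PC2  observed  predicted
img0000  -5.934 -2.867     0.143      0.127
img0012  -0.691  2.422     0.600      0.512
img0023   9.422 -2.772     0.962      1.000
```

Observed scores are mean ratings on the 4-point merged scale divided by 7,
so 0.14 ≈ morning/sunrise and 0.96 ≈ night-leaning evening. The same
objects are available from Python (`chronolux.generate_study`,
`chronolux.extract_statistics`, `chronolux.fit_pca`,
`chronolux.forward_aic_regression`, `chronolux.predict_time_of_day`).

## Documentation

See `docs/methods.md` for the model and procedure details, parameter
defaults and units, what the synthetic generator does and does not
emulate, numerical conventions, and known limitations.
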