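# nirvein

Enhancement and segmentation of near-infrared (NIR) hand-vein images.

Locating a vein for venipuncture is hard when the vessel is not visible
through the skin. NIR imaging helps because deoxygenated hemoglobin
absorbs near-infrared light strongly: veins image as dark tubular dips on
a brighter tissue background. Raw NIR frames, however, carry sensor
noise, illumination inhomogeneity, fine skin texture, and foreign objects
(hairs, wounds) whose intensity resembles veins, so a segmentation run
directly on the raw frame reports vein-like structure everywhere.

`nirvein` implements a preprocessing-and-segmentation pipeline built
around **relative-total-variation (RTV) smoothing**, together with the
classical baselines it is compared against, a synthetic phantom generator
standing in for real acquisitions, and the evaluation metrics used to
compare the methods.

## The method

The pipeline runs, in order:

1. **Smoothing** — one of
   * *RTV* (the proposed method): find S minimizing

     ```
     E(S) = Σ_p (S(p) − I(p))²
          + λ Σ_p [ D_x(p)/(L_x(p) + ε) + D_y(p)/(L_y(p) + ε) ]
     ```

     where, with a Gaussian window ρ of scale h,
     `D_x(p) = Σ_q ρ(p,q) |∂_x S(q)|` is the windowed *total* variation and
     `L_x(p) = |Σ_q ρ(p,q) ∂_x S(q)|` the windowed *inherent* variation.
     On oscillatory texture the signed gradients cancel (L ≈ 0, D large
     — heavily penalized, flattened); on a salient edge L ≈ D (cheap,
     preserved). Veins survive; texture, noise and hairs do not.
     The minimizer is approximated by iteratively reweighted least
     squares: 4 sparse SPD solves with data-dependent edge weights.
   * *median filter* (3×3) or *local adaptive Wiener filter* (5×5),
     `S = μ + (σ²−η²)⁺/σ² (I−μ)`, as baselines; or *none*.
2. **CLAHE** — contrast-limited adaptive histogram equalization: per-tile
   clipped histogram equalization (excess redistributed over all bins,
   iterated) with bilinear interpolation between tile mappings.
3. **k-means (k = 3)** — intensity clustering into background, tissue and
   vein classes; the vein mask is the darkest cluster.
4. **Blend** — optional overlay of the mask onto a co-registered optical
   (RGB) image for display.

Evaluation follows two instruments: the **coefficient of variation**
(COV = 100·σ/mean) of vein-free regions of the segmentation image, which
meters residual noise and foreign-object signal, and **line-intensity
profiles** across known veins (response counting and full width at half
maximum, which gauges smoothing-induced blur).

Because no public NIR acquisitions accompany this problem, the package
generates **phantoms**: synthetic NIR scenes with spline-centerline veins
of Gaussian cross-section, hairs, multiplicative illumination fields,
band-limited texture and sensor noise — with exact ground truth.

## Worked example

```sh
# 1. generate a two-vein phantom suite (NIR + RGB + truth masks)
nirvein phantom --n 2 --seed 0 --out phantoms

# 2. run the proposed pipeline on the first scene
nirvein run --input phantoms/nir_00.tiff --optical phantoms/rgb_00.png \
            --out run_rtv --method rtv

# 3. compare all four methods with four vein-free ROIs and a midline profile
nirvein evaluate --input phantoms/nir_00.tiff --out eval \
    --rois "8,8,32,32;8,224,32,248;120,8,144,32;224,120,248,144" \
    --profile "128,0,128,255"
```

which prints

```
  mean COV       none:   26.941%
  mean COV     median:   17.547%
  mean COV     wiener:    9.565%
  mean COV  rtv_clahe:    4.071%
```

and `eval/summary.json` records the midline response counts
`{"none": 18, "median": 4, "wiener": 4, "rtv_clahe": 2}`: the scene
contains exactly two veins, and only the RTV+CLAHE pipeline reports
exactly two vein crossings along the midline — the baselines leave
residual structure that segments as spurious "veins", which is also what
their larger COV values measure. `run_rtv/` holds the smoothed and
enhanced images (16-bit TIFF), the vein mask and segmentation (PNG), the
green-on-skin blended overlay, and a `provenance.json` sufficient to
reproduce the run.

The same functionality is available as a library:

```python
from nirvein import PhantomSpec, make_phantom, process, PipelineParams

nir, rgb, truth = make_phantom(PhantomSpec(seed=0))
result = process(nir, PipelineParams(method="rtv"))
result.vein.mask          # boolean vein mask
result.clusters.centroids # the three intensity classes
```

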