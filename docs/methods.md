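# Methods

This note documents the models, parameter choices, numerics and known
limitations of `nirvein`. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## The RTV smoothing model

The smoother minimizes

    E(S) = Σ_p (S(p) − I(p))² + λ Σ_p [ D_x(p)/(L_x(p)+ε) + D_y(p)/(L_y(p)+ε) ]

over images S, with forward-difference partials (replicate boundary: the
last row/column gradient is zero) and a Gaussian window
ρ(p,q) = exp(−‖p−q‖²/2h²) truncated at radius ⌈3h⌉ and used
**unnormalized** — the windowed sums D and L carry the window's mass
(≈ 2πh² ≈ 39 at h = 2.5). The ratio D/(L+ε) is the texture detector:
both D and L scale with local gradient magnitude, so on a coherent edge
the ratio saturates near 1 regardless of contrast, while on oscillatory
texture the signed sum L cancels and the ratio grows like D/ε.

Parameters, units, defaults:

| name      | meaning                                   | default | basis |
|-----------|-------------------------------------------|---------|-------|
| `h`       | window scale, pixels                      | 2.5     | standard setting for dorsal-vein NIR frames |
| `eps` (ε) | stabilizer in the penalty denominator     | 1e-5    | standard setting; assumes intensities normalized to [0,1] |
| `lam` (λ) | fidelity/penalty balance                  | 2.5e-4  | see below |
| `eps_s`   | solver-side gradient stabilizer           | 1e-3    | bounds the IRLS point weight 1/(|∂S|+eps_s) |
| `n_iters` | IRLS reweighting iterations               | 4       | energy trace is flat afterwards (logged per run) |

**Why λ = 2.5e-4.** No canonical λ exists for the unnormalized-window
form of the objective. The customary default of 0.01 presumes a
unit-mass window; with the window mass ≈ 39 at h = 2.5 folded into D and
L, the equivalent balance is 0.01/39 ≈ 2.5e-4. The distinction matters:
with ε = 1e-5, the penalty per unit residual gradient in flat regions is
of order 1/ε, and λ = 0.01 under this parametrization flattens soft
tubular structures (the veins themselves), not just texture. λ remains
exposed (`--rtv-lambda`, `rtv.lambda`).

**Solver.** The standard IRLS linearization: at iteration t the penalty
is replaced by Σ w_x (∂_x S)² with w_x = u_x·v_x, where
u_x = ρ ⊛ 1/(L_x(S_t)+ε) and v_x = 1/(|∂_x S_t|+eps_s) (symmetrically in
y), giving the sparse SPD system (Id + λ G'WG) S_{t+1} = I over 5-point
difference operators. Systems up to 512² pixels are solved by direct
sparse factorization, larger ones by Jacobi-preconditioned conjugate
gradient (rtol 1e-10, failure raised, never silent). The direct path
additionally checks the relative residual against 1e-6 — the IRLS
weights span ~6 decades, so a correctly solved system still shows
~1e-8 rounding-level residual. S_0 = I; no clipping inside the solver,
which preserves exact gray-shift equivariance.

## Baselines

Median (3×3) and local adaptive Wiener (5×5, population-variance
plug-in, negative variance excess clamped to zero, η² estimated as the
mean local variance in "auto" mode) with replicate padding, matching the
gradient convention. Window sizes are the smallest standard choices; no
authoritative values exist for this comparison.

## CLAHE

Own implementation of the clip-and-redistribute variant: per-tile
256-bin histograms over the global [0,1] range, clip at
max(clip_limit·N_tile, N_tile/n_bins), excess pooled and spread
uniformly over **all** bins, iterated until no bin exceeds clip+1 (total
count conserved exactly, integer remainders to the lowest-index bins);
tile mapping is the rescaled CDF; pixels interpolate bilinearly between
the four surrounding tile-center mappings. Defaults: 8×8 tiles, clip
0.01, 256 bins.

Two documented consequences of this construction: (i) redistribution
over all bins (including empty ones) adds a global ramp to each tile's
CDF, so at clip 0.01 the dynamic-range expansion of a low-contrast scene
is bounded near 2× (the clip is doing its job; clip 0.02 releases > 3×,
and expansion is monotone in the clip — asserted in tests);
(ii) CLAHE operates on the smoothed image renormalized to [0,1] by
min-max stretch, a choice made because the RTV output's range varies
with λ.

## Segmentation

1-D k-means (k = 3: background, tissue, vein) on pixel intensities only
— the clustering model is over values, and spatial k-means would change
the method. Lloyd's alternation with k-means++ seeding from a fixed
seed; emptied clusters reseed at the worst-fit point; the within-cluster
sum of squares is recorded per iteration and is non-increasing. The vein
class is the cluster of **rank** darkest centroid (robust to label
permutation); exact centroid ties are rejected rather than broken
arbitrarily. No morphological cleanup is applied between k-means and
the metrics — any cleanup would silently alter the COV comparison.

## The phantom generator

Emulates a dorsal-hand NIR acquisition:

    nir = clip( T · illum · (1 − Σ vein dips − Σ hair dips) + texture + noise, 0, 1 )

* veins: cubic splines through 4–6 gently jittered control points
  crossing the frame, Gaussian cross-section of depth `vein_contrast`
  and width σ ∈ [2.5, 4.5] px; truth mask = pixels within 2σ of a
  centerline;
* hairs: slowly-turning random-walk strands, σ ≈ 0.5–0.8 px, contrast
  comparable to veins (the designed confounder);
* illumination: smooth random cosine field, ±12% multiplicative;
* texture: band-limited (Gaussian-smoothed) noise added before sensor
  noise so texture suppression and denoising are exercised separately;
* noise: additive Gaussian, σ = 0.05 in the standard suite;
* RGB: the same scene without the vein dips (veins are invisible in
  visible light), skin-toned.

Defaults (256², 3 veins, contrast 0.45, tissue level 0.55, 4 hairs,
hair contrast 0.35, texture 0.02) were fixed once as a plausible
dorsal-hand scene and define the package's study conditions. The
standard suite pins member 0 to a two-parallel-vein scene whose
horizontal midline crosses exactly two vein runs (the profile-analysis
target). All randomness flows from a single integer seed;
identical spec ⇒ bit-identical arrays.

What the phantoms do **not** model: anatomy (vein branching, depth
variation), Poisson/shot noise, optics (defocus, specular highlights),
motion, and real skin texture statistics. Passing on phantoms shows the
pipeline's behavior under its stated assumptions, not clinical
performance.

## Evaluation metrics

* **COV** = 100·σ/mean (population σ) over a rectangular ROI of the
  *segmentation image rendered at cluster-centroid intensities*. ROIs
  are placed on vein-free tissue by a deterministic grid scan keeping a
  6-px margin from the true vein mask; hairs are deliberately not
  excluded — they are part of the residual signal being metered. The
  centroid rendering (rather than a 0/1 mask) is what makes COV a
  *noise meter*: for misclassification fraction p in a tissue ROI, a
  binary rendering would give COV = 100·√((1−p)/p), which *decreases*
  in p and would rank a noisier method better; against the tissue-class
  level, COV instead grows with residual misclassification. An all-clean
  ROI (σ = 0) reports COV 0 by convention.
* **Line profiles**: bilinear samples at n equally spaced points
  (default: segment length rounded up, plus one). Response counting
  uses maximal runs below max − threshold·range (dark polarity).
* **FWHM** of a dip: half-depth crossings located by linear sub-sample
  interpolation around the minimum; auto baseline = median of the outer
  20% of samples.

## Problem sizes and determinism

The evaluation harness uses 20 suite seeds at 256², four methods each —
the scale at which the cross-method comparisons stabilize while a full
run stays in the minutes range on one CPU. The RTV solver-optimality
check runs at 16² against a dense-matrix multi-start descent oracle.
Every stochastic component (phantoms, k-means seeding) is seeded;
pipeline reruns are byte-identical on disk.

## Known limitations

* The IRLS scheme guarantees neither monotone energy descent nor a
  global minimum; in practice the energy drops by orders of magnitude in
  the first iteration and an independent descent method cannot improve
  the returned solution by more than a few percent (asserted in tests).
* COV on a centroid-rendered segmentation is scale-free but depends on
  the tissue centroid being well away from zero; scenes that are almost
  entirely vein would break the background/tissue/vein class model
  anyway.
* The k = 3 class model assumes no region darker than veins; a dark
  frame border (outside-hand background) would capture the darkest
  cluster. The phantoms model the in-hand field of view accordingly.
* `vein_contrast` = 1 is rejected only when it would zero the centerline
  exactly; deep-contrast scenes close to that limit clip at 0 and the
  generative closed form no longer holds there.
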