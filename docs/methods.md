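# Methods

`visfeat` detects and matches vascular bifurcations in endoscopic
(minimally-invasive-surgery) still images. Vessels are the dominant
texture in the lumen, but they are dark, low-contrast, tubular structures
on smoothly varying tissue, framed by a black field-of-view annulus and
peppered with saturated specular highlights — conditions under which
generic corner detectors are unreliable. The pipeline therefore enhances
tubular structure explicitly, reduces it to a single-pixel centerline,
and treats centerline bifurcations as the interest points.

## Pipeline model

For an input frame `I` (green channel of an RGB endoscopic image, float
in [0, 1]):

1. **Field-of-view masking.** Per pixel, a window mean/median threshold
   `T = k·mean − (1−k)·median` (default 31×31 window, `k = 0.5`) marks
   foreground; the raw mask is cleaned by keeping the largest component
   and filling interior holes. The defaults make the black sensor
   surround (intensity ≈ 0) background and tissue foreground.
2. **Highlight inpainting.** Pixels exceeding both a local-variance
   threshold `T = k_var·var + C` and a global saturation floor (default
   0.9 — specular highlights are saturated, merely bright tissue is not)
   are treated as holes and filled by Telea-style fast-marching
   inpainting: hole pixels are visited in increasing arrival time of a
   first-order eikonal front started at the hole boundary, and each is
   the weighted mean of first-order estimates `I(q) + ∇I(q)·(p−q)` over
   known pixels `q` in a ball of radius 5, with weights
   `dir·dst·lev` (front-normal alignment, inverse squared distance,
   arrival-time proximity; `d0 = T0 = 1`). Gradients at `q` use central
   differences where both neighbors are known and one-sided differences
   otherwise, so the fill is exact for affine intensity fields.
3. **Dual-branch enhancement.** Both branches share the scale-normalized
   Hessian `σ²·H(G_σ * I)` over the grid σ ∈ {1, 1.5, 2, 3, 4, 6} px
   (covering vessel widths of roughly 1–8 px), with eigenvalues ordered
   by magnitude (|λ₁| ≤ |λ₂|; λ₂'s eigenvector points across the
   vessel).
   - **Frangi branch:** `V = exp(−R_B²/2β²)·(1 − exp(−S²/2c²))` with
     `R_B = |λ₁|/|λ₂|` (≈ 0 on tubes, ≈ 1 on blobs),
     `S = √(λ₁²+λ₂²)`, zero where λ₂ ≤ 0 (dark-vessel polarity);
     `β = 0.5`, `c` defaults to half the per-scale maximum of `S`.
     The multiscale map is the per-pixel maximum over σ.
   - **MFAT branch:** eigenvalues are polarity-normalized so vessels
     carry positive sign; the dominant eigenvalue (duplicated as the
     auxiliary λ₃) is regularized by an upper cutoff
     (`λ_ρ = λ₃` above `τ·max λ₃`, clamped to `τ·max λ₃` for
     `0 < λ₃ ≤ τ·max λ₃`, else 0; τ₁ = 0.5, τ₂ = 0.25) and a
     three-case response is formed: 0 where the sign guard fails or the
     normalized anisotropy gap `(λ_ρ − λ₂)/max(λ_ρ − λ₂)` (maximum taken
     over the sign-valid domain) exceeds a guard fraction (0.5 — these
     are pixels whose regularized value was clamped far above their
     actual eigenvalue, i.e. noise); 1 where the gap attains its
     minimum (solid vessels); `1 − accumulated response` otherwise.
     Scales accumulate as `acc += σ·tanh(R − σ)`, clamped at zero from
     below (for σ ≥ 1 the increment is never positive, so the final map
     is effectively the multiscale maximum of R; an unclamped verbatim
     mode is available via `clamp_accumulator=False`), the final map is
     the per-pixel maximum of accumulator and response over scales,
     values below 10⁻² are pruned, and the map is rescaled to [0, 1].
     The fractional-anisotropy measure
     `FAT = √(3/2)·√(Σ(λᵢ−D̄)²/Σλᵢ²)` with `D̄ = Σλᵢ/2` (a
     `fat_mean="standard"` option divides by 3) is computed and exposed
     but does not enter the response. The Frangi measure dips at
     bifurcations, where the local structure is blob-like; the MFAT
     response is by construction uniform across centerlines including
     junctions (its coefficient of variation along synthetic centerlines
     is ≈ 0 versus ≈ 0.2 for Frangi), which is the reason the second
     branch exists.
4. **Gaussian-weighted fusion with SSIM-selected μ.** Both branch maps
   are rescaled to [0, 1] so their residuals against `I` are
   commensurate, then fused per pixel as the convex combination with
   weights `w₁ = exp(−(I−F)²/2μ²)`, `w₂ = 1 − exp(−(I−M)²/2μ²)`.
   The shape parameter μ is chosen per image by exhaustive search over
   [2, 4] in steps of 0.1: each candidate's fused map is thinned to a
   centerline and scored by *global* SSIM (whole-image means, variances,
   covariance; `C₁ = 0.01²`, `C₂ = 0.03²`) between `I` and the
   centerline rendered in image intensity convention (dark line on a
   bright field, so structure correlates positively); the argmax wins,
   ties going to the smallest μ. SSIM is computed against the
   preprocessed green channel, which is the pipeline's `I`.
5. **Single-pixel ridge.** Centerline candidates are pixels containing a
   zero crossing of the cross-vessel directional derivative: with
   `d = ∇(G_σ*I)·V₂` and second directional derivative `λ₂` (in image
   units), the crossing offset is `t* = −d/λ₂` and a pixel fires when
   `|t*·V₂|` stays within half the pixel width (ε/2 with ε = 1).
   The test runs per scale with that scale's own smoothed gradient and
   cross-direction, OR-ed over the grid — near a junction a thin arm's
   valley is only a shoulder of the thick arm's basin at fine smoothing,
   and its crossing reappears at coarser scales; the pixelization of the
   continuous valley curves is then connected wherever the response is.
   The local-maximum selection that thins the candidate band to one
   pixel is realized as response-ordered removal: visiting candidates
   from weakest to strongest, a pixel is removed when a stronger
   candidate is 8-adjacent and its removal does not disconnect its
   neighborhood (checked in the 3×3 neighborhood, and within a 17×17
   window to collapse the two-strand loops that slightly offset
   per-scale crossings can form). Endpoints are never removed; dangling
   stubs of ≤ 3 px attached to a junction pixel and fragments of < 5 px
   are pruned as scale-union residue. The result is single-pixel wide
   (no solid 2×2 block survives) with the candidate band's connectivity.
6. **Branch-point detection (dual-circle test).** Candidates are ridge
   pixels with ≥ 3 skeleton neighbors. Around each, discrete circles of
   radius 5 and then 7 are walked; a crossing is a maximal run of
   on-pixels along the circumference (wrapping across the start), and a
   candidate is accepted when any circle sees ≥ 3 crossings — the
   second, larger circle recovers junctions whose arms have not yet
   separated at radius 5. Two robustness choices: the circle raster is
   the midpoint circle thickened to 4-connectivity (an 8-connected 1-px
   line can pass between two diagonal pixels of an 8-connected circle
   without touching it), and only runs connected to the candidate
   through ridge pixels inside the circle's disk are counted (a branch
   point has three or more segments *centered on it*; unrelated vessels
   grazing the circle do not qualify). Each accepted point is scored by
   the circumference off-pixel mass `Σ max(|I_x − I_p| − ε_d, 0)`
   summed over all accepting circles, so centers confirmed by both
   circles outrank single-circle satellites. Suppression is greedy in
   decreasing score with a per-point Chebyshev window
   `max(nms_radius, radius_hit + 2)` (a detection first accepted at
   radius r localizes its junction only to within r), and each survivor
   is finally moved to the rounded score-weighted centroid of the raw
   detections within 5 px — the candidate cloud surrounds the junction
   from every arm, so its centroid is far more stable across viewpoints
   than any single maximum-score member (mean localization error
   ≈ 0.9 px on synthetic trees).
7. **ZSSD matching and evaluation.** For each frame-I point P, the
   ground-truth homography predicts Q in frame J; frame-J detections
   within a circle of radius width/20 around Q are compared by zero-mean
   SSD over 21×21 blocks (each block's own mean subtracted, sum of
   squared differences divided by the pixel count so the acceptance
   threshold 0.02 is size-independent), with P's block warped into
   frame-J geometry through the local affine Jacobian of the homography.
   The minimal-ZSSD candidate below 0.02 is the match (ties: nearest to
   Q, then topmost-leftmost); a match is correct within 3.5 px of Q.
   Reported metrics: per-frame branch-point counts; repeatability (the
   fraction of frame-I points whose prediction lands inside frame J and
   has a frame-J detection within 3.5 px); average error (mean distance
   of matched points to their predictions); correctness (fraction of
   correct matches); and variance, read as the mean per-axis variance of
   matched point positions normalized by the squared image diagonal — a
   spread measure, flagged as this package's own definition in reports.

## Synthetic scenes

The generator (`visfeat.synth`) emulates the luminal features the
pipeline must cope with: dark vessels of Gaussian cross-profile and
width 1.5–6 px at 50% contrast on a smooth bright background
(0.55–0.85), grown as self-avoiding random-walk trees (distinct branches
keep a 9 px margin, so recorded bifurcations are exactly the junctions
present; every bifurcation has three arms of ≥ 12 px and bifurcations
are ≥ 16 px apart), a black circular field-of-view surround, three
saturated highlight blobs placed off-vessel (≥ 10 px from centerlines —
specularities on wet tissue between vessels), and additive Gaussian
noise of σ = 0.01 inside the field of view. Bifurcation coordinates are
recorded at the raster divergence point (where child pixels stop
coinciding with the parent's), which is where any detector can localize
them. Frame pairs render the same tree through a similarity homography
with the background resampled through the same map, widths scaled,
transformed polylines resampled to unit arclength (so rasters stay
8-connected), per-frame independent noise and highlights, and frame-J
bifurcations recomputed from frame J's own raster.

What the generator does **not** emulate: real tissue texture and
three-dimensional shading, non-rigid deformation, motion blur and smoke,
interlacing/compression artifacts, bleeding regions, and vessels
appearing or disappearing with depth. Passing tests therefore
demonstrate the internal consistency and geometric correctness of the
method under its own model assumptions, not clinical performance.

## Numerical choices

- Gaussian-derivative kernels are truncated at 8σ: at 4σ the truncated
  second-derivative kernels carry a residual moment of ≈ exp(−8) that
  breaks the constant-image-gives-zero invariant.
- Symmetric 2×2 eigen-decomposition is closed-form; |λ₁| = |λ₂| ties
  keep λ₁ as the algebraically smaller value; isotropic pixels default
  to the axis-aligned eigenvector pair.
- Thresholds are strict (`>`) in both the adaptive and highlight masks.
- The ridge direction field passed to extraction comes from the stronger
  branch per pixel (`direction_source: stronger`; `frangi` available),
  and extraction regularizes it through a response-weighted orientation
  tensor where a smoothed normal is needed.
- All coordinates are 0-based (row, col); homographies act on
  (x, y) = (col, row) homogeneous coordinates and are stored as
  plain-text 3×3 matrices normalized to a unit bottom-right entry.
- Degenerate inputs: empty hole masks are identity; holes touching the
  image border or covering ≥ 30% of the image are rejected; λ₂ = 0
  pixels have zero vesselness rather than a division error; fusion
  weights summing to zero yield zero; SSIM of constant pairs is
  stabilized by C₁/C₂; evaluation with zero detections reports explicit
  nulls, never NaN.

## Cross-section width measurement

"Single-pixel wide" is measured on truth-centerline normals sampled on
branch interiors (≥ 6 px from bifurcations and branch ends, where a
single cross-vessel direction exists). The cross-section is the
8-connected cluster of ridge pixels nearest the sample inside a ±3 px
corridor along the normal; it has width 1 when it spans < 2 px along the
normal and contains no solid 2×2 block. L-shaped corners of a digital
curve are width 1 under this definition; genuine thickening is not.

## Problem sizes

Tests and the acceptance script run on 256×256 scenes: 20 trees for
detector recovery, 10 trees for ridge quality and branch-uniformity
comparisons, 10 homography pairs (rotation ≤ 15°, translation ≤ 10 px,
scale 0.95–1.05) for matching, and 5 full-pipeline runs including the
exhaustive μ search. A full single-frame run takes about 2 s at this
size.

## Known limitations

- The fusion weights as specified keep `w₂ ≤ 1 − exp(−1/(2μ²)) ≈ 0.06`
  for μ ∈ [2, 4] on [0, 1] data, so the fused map is Frangi-dominated
  and the MFAT branch acts as a small corrective term; the junction
  robustness of the final ridge comes mostly from the multiscale
  zero-crossing candidates.
- Global SSIM between an image and a sparse centerline is small in
  absolute terms (≈ 0.01–0.02 here); only its ordering over μ matters.
- Branch-point localization is integer-pixel; sub-pixel refinement is
  out of scope.
- The detector's resolving distance is bounded below by the suppression
  window: junctions closer than ~2 circle radii merge into one
  detection.
- Full-pipeline detection on rendered scenes is noisier than detection
  on ground-truth centerlines (extracted ridges can place a junction a
  few pixels from the true meeting point); both figures are reported by
  the acceptance script.
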