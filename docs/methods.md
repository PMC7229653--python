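# Methods

This note documents the models, numerical choices, and limits of the
package. It covers what each stage computes, the tunable parameters and
their defaults, what the synthetic generators emulate (and do not), and
the design decisions that were genuinely open.

## Traction force microscopy

### Model

The substrate is a linear-elastic half-space with Young's modulus `E`
(Pa) and Poisson ratio `ν ∈ [0, 0.5)`. Surface tractions `T(x)` and
surface displacements `u(x)` are related by convolution with the
Boussinesq (tangential point-force) Green's function; in the frequency
domain the relation is diagonal per wavevector `k`:

    û(k) = G̑(k) T̂(k),
    G̑(k) = 2(1+ν)/(E k³) [ (1−ν)k² + ν k_y²,  −ν k_x k_y
                            −ν k_x k_y,        (1−ν)k² + ν k_x² ]

`ν = 0.5` is rejected everywhere: the kernel diverges for an
incompressible solid. The zero-frequency mode is undefined (a rigid
translation of the half-space); it is pinned to zero, which is exact
for balanced (zero-net-force) fields.

The inverse problem is Tikhonov-regularized per wavevector,
`T̂ = (G̑*G̑ + λ²I)⁻¹ G̑* û`. When no `λ` is supplied, a data-free
heuristic `λ² = 10⁻³ × mean diag(G̑*G̑)` is used; it suppresses the
noise-dominated high-`k` modes without visibly biasing smooth fields.
`Σ|T|` is non-increasing in `λ` (tested), so reported tractions are
conservative with respect to regularization.

Strain energy is the discrete work integral `U = ½ Σ (T·u) ΔA`, with
Pa·µm³ = 10⁻⁶ pJ. For time series, each time point is inverted
independently; the default frame interval is 30 min (typical for
overnight sprouting acquisitions) and configurable.

### Numerical choices

* **Forward model padding.** The forward convolution zero-pads the
  traction grid 4× before the FFT. Tractions in the synthetic truths
  are compactly supported, so zero padding is exact there, and the
  periodic images of the slowly decaying displacement field are pushed
  far enough away that wrap-around stays below a percent near the
  traction support (verified against real-space quadrature).
* **Inversion padding.** Displacement fields do *not* vanish at the
  field edge, so a hard zero pad would inject a step discontinuity and
  spectral leakage. The inversion therefore extends the grid 2× by
  continuing the edge values and tapering them to zero with a raised
  cosine. On noiseless forward-generated fields this brings the
  round-trip traction error from ~5–7% (hard zero pad) to ~0.3%.
* **Mean subtraction.** `u` is mean-subtracted before inversion; the
  mean is unobservable (k = 0) and carries no traction information.
* **Coordinates.** Pixel origin top-left, `x` = column, `y` = row,
  0-based; physical position = pixel × `pixel_size_um`. All
  displacements are µm, tractions Pa.

### Bead tracking

Bead localization uses local maxima above an intensity percentile
(default 99th — bead pixels are a small fraction of the field; a
looser cut admits noise maxima) refined by a background-subtracted
intensity-weighted centroid in a window of ~2 bead diameters, accurate
to ~0.01 px on clean spots. Detections closer than one bead radius
collapse to the brighter. Frame-to-frame matching minimizes total
squared displacement via optimal assignment (Hungarian algorithm),
with pairings beyond `max_displacement_um` forbidden; for ≤ 7 beads
the result equals brute-force enumeration (tested). Tracking errors
are removed by the normalized-median test: a vector is discarded when
its residual to the median of its `k = 8` nearest neighbours exceeds
`threshold = 2` times the median neighbour residual plus a floor
(0.05 µm) that guards the all-zero field.

PTV has an intrinsic validity regime: displacements must be small
compared with the bead spacing (else assignments become ambiguous) and
the displacement field must vary on scales coarser than the spacing
(else interpolation to the grid under-resolves it). The synthetic
bead-image defaults respect this regime; the sharper patch defaults
used for grid-level round-trip tests deliberately do not, and are
analysed on the grid directly.

## Nuclear decorrelation

For each nucleus, a fixed mask (taken on the first frame) selects the
pixel list; each later frame is first rigidly registered to frame 0 by
phase cross-correlation (10× upsampling) so whole-nucleus translation
is not mistaken for internal reorganization. A warning is raised when
the mask-edge intensity gradient is high after registration, since
residual motion then biases the statistic.

`PCC(L)` is the mean over *all* frame pairs `(t, t+L)` of the Pearson
correlation between the two pixel lists — using every pair reduces the
variance of the curve at the cost of correlated averaging, which the
across-cell confidence interval absorbs. Lag 0 is excluded (it is
identically 1); zero-variance frames are skipped. Pearson correlation
is invariant to affine intensity rescaling, so acquisition gain drifts
do not move the curve (tested).

The decay model `y(t) = (1 − α) + α e^{−t/τ} − η` is fitted to the
condition-mean curve by bounded trust-region least squares with
`α ∈ [0, 1]`, `τ ∈ (0, 10·max lag]`, `η ∈ [0, 0.5]`, from three
perturbed initializations (`α₀ = 1 − min y`, `τ₀ = max lag / 3`,
`η₀ = clip(1 − y(first lag))`), keeping the best residual. When the
curve is flat, `τ` is unidentifiable; the fit then returns `α ≈ 0`
with `τ` near its initialization and the convergence flag reports the
optimizer status. Per-cell fits are also available for dispersion
analysis, but the headline parameters come from the mean curve.

### Generative model for synthetic nuclei

Per-pixel intensity is `I_t = S + D_t + ε_t`: a static Gaussian
texture `S` with variance `(1 − α)σ²`, a stationary AR(1) process
`D_t` with variance `ασ²` and autocorrelation `exp(−kΔt/τ)` (AR(1) is
used precisely because its autocorrelation is exactly exponential,
making the fit model the correct generative family), and white noise
of SD `noise_sd·σ`. The expected PCC is
`[(1 − α) + α e^{−t/τ}] / (1 + noise_sd²)` — the model family with the
lag-independent noise deficit absorbed by `η`. The generator does
*not* emulate nucleus deformation, photobleaching trends, or focus
drift; recovery results on it validate the estimator under the model's
own assumptions, not robustness to those artefacts.

Defaults follow the acquisition they emulate: 1-min frame interval,
33 frames (lags up to 32 min), ~300-pixel nuclei.

## Morphometry

* **Nucleus segmentation**: Otsu threshold → hole filling → watershed
  of the Euclidean distance transform seeded at its local maxima
  (footprint default 7 px) → regions below `min_area_px = 50`
  discarded. The watershed split is preserved through the size filter
  (regions are renumbered, not re-labelled by connectivity).
* **Foci counting**: Laplacian-of-Gaussian band-pass at the expected
  spot scale (scale-normalized), local maxima with prominence above
  `prominence_factor = 7` × the nucleus-local MAD, counted inside the
  mask. The factor sits above the expected extreme of filtered noise
  over a nucleus-sized area (~5 MAD for thousands of correlated
  samples) while real foci exceed it by an order of magnitude. Two
  spots closer than ~1.5 σ merge into one maximum — the stated
  resolution limit. The band-pass removes constant offsets, so counts
  are invariant to background shifts (tested).
* **Sprout length**: threshold → largest component → the spheroid core
  is isolated by a Euclidean opening (erosion/dilation via two
  distance transforms, fast at large radii) → the remainder is
  skeletonized → each skeleton tip is traced back to the core along
  the skeleton graph. Step weights are Kulpa-corrected (0.948 axial,
  1.340 diagonal) because raw 1/√2 chain steps overestimate digitized
  straight lines by up to ~8%; the junction gap to the core and the
  tip retraction (local half-width from the distance transform) are
  added back. One length is reported per tip, so sprouts that touch
  mid-field remain separate. Stubs below 5 µm are treated as debris.
* **Gel contraction**: per frame, Otsu threshold → largest component →
  hole fill → pixel count; areas are normalized to frame 0 and percent
  contraction is `100(1 − normalized)`. A gel below 1% of the frame is
  flagged as unreliable.
* **EdU fraction**: per-nucleus mean intensity, positive above an Otsu
  split of the means (needs ≥ 2 nuclei; a fixed threshold overrides).
* **Cell shape**: area from pixel count; aspect ratio from the
  second-moment ellipse (major/minor axis).
* **Intensity normalization** (e.g. LaminA): values divided by the
  control-condition mean — the natural reference when a control group
  is present; per-image background normalization was the alternative
  and is not implemented.
* Pixel calibration defaults: 0.42 or 0.21 µm/px (20×/63× confocal),
  z-step 1–5 µm; all configurable.

## Statistics

Pooled-variance (Student's) unpaired two-tailed t test is the default,
matching the named test; Welch is available via a flag. Degenerate
zero-variance inputs: equal means give p = 1, unequal means raise.
Bonferroni is `min(1, p·m)`. ΔΔCt uses per-replicate
`ΔCt = Ct_gene − Ct_ref`, condition means, and `fold = 2^(−ΔΔCt)`;
plate shifts cancel exactly. Box summaries use linear-interpolation
quantiles with whiskers at the most extreme points within 1.5 IQR.
Significance stars: * p < 0.05, ** p < 0.01, *** p < 0.001.

## Synthetic truth fields for traction

Balanced truths are sums of Gaussian *dipoles* (opposed patch pairs,
like contractile cells), placed in the central part of the field so
the displacement decays toward the boundary — the regime the
inversion and real fields of view both assume. Building balance into
the construction avoids the alternative (subtracting the mean of a
random field), which injects a constant background traction that is
physically non-local; the residual numerical net force is still
removed by mean subtraction, then a vanishing correction. The truth
object carries its analytic patch description so off-grid values are
available to independent quadrature checks.

## Problem sizes used in the test suite

Round-trip and oracle checks run on 32×32 and 64×64 grids at 2 µm
spacing; decorrelation recovery uses 9 parameter combinations × 200
nuclei of ~300 px × 33 frames; foci exactness uses ~216 nuclei with
0–12 foci; sprout recovery uses 50 spheroids × 5 sprouts; these sizes
give Monte-Carlo errors well inside the asserted tolerances while the
whole suite remains desk-scale.

## Known limitations

* The half-space inversion is planar. Bead displacements measured
  around cells in 3-D fibrous collagen can be analysed per-plane, but
  collagen is nonlinear and fibrous; the recovered "tractions" are
  then effective quantities, not true surface stresses. A fibrous
  finite-element inversion is out of scope.
* The stress-free reference state must be supplied explicitly; the
  package does not decide between a drug-relaxed and a first-frame
  reference, and results depend on that choice.
* One centroid localizer serves both large (µm) beads and
  diffraction-limited spots; the window size is configurable but the
  method is not PSF-fitting, so localization accuracy saturates around
  0.01–0.1 px depending on noise and crowding.
* Whether the PCC should use one pair per lag or all pairs is an open
  convention; all pairs is implemented (documented above), and the two
  differ only in curve variance, not expectation.
* The morphometric segmentations are intensity-threshold based and
  assume reasonably uniform illumination; no flat-field correction is
  included.
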