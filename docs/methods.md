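# Methods

## Image model and stain separation

Brightfield H-DAB images are modelled with the Beer–Lambert law. For stain
concentrations `c_s` and unit stain vectors `v_s` in RGB optical-density
space, transmitted intensity per channel is `I = 255 · 10^(−Σ_s c_s v_s)`.
Optical density is computed as `OD = −log10(max(I, 1)/255)` (the intensity
floor of 1 avoids log 0), and concentrations are recovered by multiplying
with the inverse of the 3×3 stain matrix; negative solutions are clamped to
zero. When only hematoxylin and DAB vectors are supplied the third column
is completed with their normalised cross product, the standard practice in
colour deconvolution. The default vectors are the published H-DAB pair,
hematoxylin ≈ (0.65, 0.70, 0.29) and DAB ≈ (0.27, 0.57, 0.78) after
normalisation; in real workflows deconvolution vectors are set per staining
batch, so they are a parameter, not a constant.

Under 8-bit quantisation the deconvolution error is bounded by the
per-channel rounding error `0.5/(I·ln 10)` amplified by the inverse-matrix
row norms (max ℓ1 row norm ≈ 2.81 for the default vectors). The synthetic
renderer's default OD levels (nucleus hematoxylin 0.55, DAB 0.45, artefact
specks 0.9) keep the worst-case absolute round-trip error below 0.01 OD,
which is what the round-trip tests assert at zero noise.

## Masks and compartments

The tissue mask thresholds total OD (sum of the three channel ODs; default
threshold 0.05, chosen against the synthetic renderer since real scanners
differ), fills holes and drops components below 0.001 mm². The epithelium
mask comes either from GeoJSON polygon annotations — rasterised with the
half-open pixel-centre rule (a pixel is inside iff the polygon covers its
centre), holes honoured, overlaps unioned — or from a trainable per-pixel
classifier.

That classifier is a seeded random forest over hand-crafted local features
(stain ODs, grayscale intensity, and their Gaussian means and local
standard deviations at 1, 3 and 6 μm scales). It deliberately replaces a
deep segmentation network: the subject of this package is the
quantification pipeline and its statistics, and a classical pixel
classifier reproduces the same mask contract deterministically at desk
scale, trainable in seconds. Predictions are post-processed (hole filling,
minimum component area 0.0002 mm²) and intersected with the tissue mask.

Compartments are defined in physical units. The subepithelial band is the
set of tissue pixels within 5 μm Euclidean distance of the epithelium and
not in it; the distance transform is thresholded at `5/mpp` pixels without
rounding, so the band width is resolution independent. Where the 5 μm
expansion would leave tissue (biopsy edge, lumen) it is clipped to tissue —
only mucosal cells are counted, and the clipping preserves the exact
partition `epithelium ∪ band ∪ lamina propria = tissue`. Euclidean (disk)
dilation is used rather than chessboard or taxicab, reading "expand by
5 μm" as a geometric distance.

## Cell detection and classification

Detection runs on the hematoxylin OD channel: Gaussian smoothing (default
σ = 1.5 μm), local maxima at a minimum separation of 4 μm inside the
foreground mask (smoothed OD > 0.3), and marker-based watershed on the
inverted OD landscape. This is a deterministic re-creation of the contract
of a pretrained star-convex nucleus detector; the detector's published
settings map onto it as follows. The requested pixel size (0.225 μm/px)
fixes the *reference scale* at which nucleus areas are evaluated
(`area_ref = area_px · (mpp/0.225)²`), so the inclusive 125–3,000 px²
inclusion bounds always mean 6.33–151.9 μm² regardless of native
resolution. The probability threshold (0.01) becomes a minimum
absorbed-light fraction `1 − 10^(−OD)` at a peak; it is deliberately
permissive, with the foreground OD threshold doing the operative
separation — the mapping between a learned objectness probability and any
classical score is a calibration choice, not an equivalence. Bounds are
inclusive: excluding areas "above and below" the limits keeps the limits
themselves.

Each retained nucleus is expanded by 1.5 μm; overlapping expansions are
split by the nearest-nucleus (Voronoi) rule so cell regions are disjoint.
The feature vector per cell is: mean/max DAB OD in nucleus and cell, mean
hematoxylin OD in nucleus, nucleus area (μm²), eccentricity, solidity. A
seeded three-class random forest (positive / negative / artefact) is
trained on labelled detections; artefacts are excluded from every
downstream count.

## Quantification

Compartment membership is by the nucleus centroid's label in the
compartment map — a single deterministic label per cell, so the subtraction
identities hold exactly: subepithelial count = (expanded-epithelium count) −
(epithelium count), lamina propria = whole mucosa − expanded, and the three
compartments always sum to the whole-mucosa count. Intraepithelial and
subepithelial positives are reported per 100 epithelial cells (positives +
negatives labelled epithelium), lamina propria positives per mm² of mucosa.
A zero denominator marks the measure missing rather than zero. γδ/CD3
ratios are computed per biopsy from the matching normalised measures of
parallel sections (raw-count ratios would conflate section areas), then
modelled like any other measure.

## Statistical model

Counts are right-skewed and biopsies are nested in subjects, so inference
uses a random-intercept linear mixed model on natural-log measures:

    log(y_ij) = x_ij' β + b_i + e_ij,  b_i ~ N(0, σ_b²),  e_ij ~ N(0, σ_e²)

with group (diagnosis × activity) and colon location fixed and subject
random. Natural log is used throughout (fold changes are base-invariant;
offsets and residual SDs are reported in natural-log units). Zero counts
are handled by adding 0.5 to the count before normalising and logging; the
offset is a parameter and +1 is the documented sensitivity setting.

Estimation is REML. With a single random intercept the problem profiles to
one dimension in λ = σ_b²/σ_e²: per subject `V_i⁻¹` and `log|V_i|` have
closed forms, and the profiled −2·REML criterion is minimised by bounded
scalar search over log λ (tolerance 1e-10) with the boundary λ = 0 checked
explicitly. This makes every fit deterministic and ~milliseconds, which the
replicate-based calibration checks rely on. Fixed-effect covariances are
`σ̂_e²(X'V₀⁻¹X)⁻¹`; at λ = 0 the estimator reduces exactly to OLS with the
unbiased residual variance, which is one of the test oracles.

Group comparisons are differences of estimated marginal means (averages of
the design row over the observed covariate distribution with the group
forced to each level), reported back-transformed: `FC = exp(Δ)` with CI
`exp(Δ ± t_q·SE)`. Degrees of freedom use a Satterthwaite-style
approximation — `df = 2·V_c²/Var(V_c)` with `Var(V_c)` from the delta
method and the numeric REML information matrix — falling back to the
residual df `n − p` at the λ = 0 boundary and to the normal quantile if the
numerics fail. Post hoc pairwise tests are least-significant-difference:
unadjusted, deliberately without multiplicity correction. Whether LSD is
applied to estimated marginal means or observed means was an open design
choice; estimated marginal means were chosen because they respect the
location covariate. Group summaries report both the model-based geometric
mean and the sample median, labelled, since back-transformed "medians" are
ambiguous between the two.

The ICC is σ_b²/(σ_b² + σ_e²). Blood–mucosa ratio association uses
Spearman rank correlation (mid-ranks for ties) per compartment within each
group subset; proximal-vs-distal comparisons in histologically inactive
mucosa use the tie-corrected Kruskal–Wallis test. Both delegate to scipy
and are verified against brute-force rank formulas exhaustively on small
inputs. Covariate analyses (oral corticosteroids, age, gender, disease
duration) are separate refits with the covariate added, as in the source
workflow; interaction checks are Wald chi-squared tests on the
group × location product block.

## Synthetic data: what it emulates and what it does not

The tile generator emulates the geometry and photometry that the pipeline
depends on: a calibrated raster (default 512² px at 0.5 μm/px), crypt-like
sinusoidal epithelial ribbons with a stronger hematoxylin wash (0.16 vs
0.06 OD), elliptical nuclei with Gaussian edge blur (σ 0.5 μm), planted
classes and compartments, and artefacts on both sides of the area filter
(specks < 1 μm radius, smears > 8 μm). Default densities (4,000 /mm² in
epithelium, 3,000 /mm² elsewhere, ~200 cells per tile) and nucleus radii
(2.3–3.8 μm) are of the order of colonic mucosa at these magnifications; a
7.5 μm minimum centre separation keeps planted nuclei resolvable, which
real crowded epithelium does not guarantee. It does not attempt
photorealism: no scanner noise model beyond additive Gaussian, no staining
gradients, no ulceration, no lymphoid aggregates, no overlapping nuclei.
Passing tests therefore demonstrate the correctness of the geometry,
arithmetic and inference — not that the detector or segmenter would reach
the same accuracy on scanned slides.

The cohort generator draws `count = round(exp(μ + b_subject + ε))` with the
planted log fold changes, a proximal location multiplier (default 1.3), an
oral-steroid multiplier on γδ counts (default 0.6), and log-normal
denominators. Counts are rounded, not truncated, and zeros are allowed so
the log-offset path is exercised. Default group sizes (41/39/35/44/22 for
HC, inactive UC, inactive CD, active UC, active CD), baseline measures
(e.g. 2.8 CD3 and 0.6 γδ IELs per 100 epithelial cells, ~700 CD3/mm²
lamina propria) and the planted fold-change pattern mirror the magnitudes
reported for colonic IBD cohorts; between-subject and residual SDs default
to 0.5 each on the log scale (ICC 0.5, "moderate" within-subject
correlation).

## Problem sizes and numerical choices in the checks

The replicate-based checks size their simulations for sharpness: the
fold-change recovery and CI coverage check uses 500 replicates of 50
subjects/group × 2 biopsies (planted FC 2.0, σ_b 0.3, σ_e 0.4); null
calibration pools 2,040 LSD contrasts from 34 independent null cohorts of
30 subjects/group, with the oral-steroid multiplier disabled as well —
group steroid prevalence differs by design, so leaving it on would plant a
real γδ group difference and the check would not be a null; the directional-pattern check scales the cohort to 120
subjects/group so that, by a pre-hoc power calculation (SE of a log FC
≈ 0.61·√(2/120) ≈ 0.079), every planted direction is recovered with high
probability while the planted-constant contrasts stay inside [0.8, 1.25].
Detection quality is measured on 10–20 tiles (~200 cells each) with
one-to-one optimal matching at 2 px.

## Known limitations

* The epithelium segmenter is a pixel classifier; on real WSIs a modern
  segmentation network will outperform it, and the package treats the mask
  source as pluggable (polygon annotations are a first-class alternative).
* Detection assumes nuclei are hematoxylin-dense blobs separable at ~4 μm;
  heavily overlapping nuclei are merged.
* The mixed model supports a single random intercept (subject). Crossed or
  nested random effects (e.g. slide within subject) are out of scope.
* Surface vs crypt epithelium is not distinguished, and lymphoid
  aggregates are not detected or excluded.
* γδ/CD3 ratios are computed per biopsy and then modelled; modelling the
  two stains jointly and forming ratios of modelled means is a possible
  sensitivity analysis the package does not automate.
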