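# Methods

This note records the models, parameter choices, and numerical
decisions behind `stretchplate`, and what the synthetic-data tests do
and do not demonstrate.

## Strain mechanics

The membrane strain of a well is measured from a stamped fiducial dot
(default diameter 1.5 mm). Indentation of a silicone membrane by a
cylindrical post produces a spatially homogeneous, equibiaxial strain
field with negligible shear, so the uniaxial Green–Lagrange form is
used per axis:

    E_axial = u/X + ½(u/X)²,   u = x − X,

with X the pre-stretch dimension and x the dimension at peak stretch.
E_xx comes from dot widths, E_yy from heights, and the well strain E is
their mean. Replicates (default 5 per well) are aggregated by averaging
replicate *strains*, not dimensions — the replicates are independent
stretch events on different plates, so strain is the natural replicate-
level quantity. Standard deviations are sample (n−1) throughout; the
convention is not externally fixed, so the more conservative estimator
was chosen.

The forward generator is the exact inverse: post = pre · √(1 + 2E) on
both axes. Strains at or below −0.5 have no real stretch ratio and are
rejected and resampled (logged). With zero replicate noise the analysis
round trip is exact to floating-point precision, which the tests assert
at 1e-10.

The displacement–strain relationship is an ordinary least-squares line;
levels with strain below 0.02 (configurable) are flagged as negligible
rather than fitted around, because at the smallest stage amplitudes the
membrane barely engages the posts and the measured strain sits off the
linear trend.

## Dose–response model

Each injury metric y is modeled as a four-parameter logistic in strain:

    y(E) = y_f + (y_0 − y_f) / (1 + exp(k (E − E_t)))

- **y₀** (metric units): zero-strain plateau. Strictly, y(0) → y₀ only
  when k·E_t ≫ 1; that holds for every default parameter set (k·E_t ≈
  4.8–8.8), so the plateau interpretation is sound.
- **y_f** (metric units): high-strain asymptote.
- **k** (dimensionless, > 0): transition sharpness.
- **E_t** (strain, > 0): transition point; y(E_t) = (y₀ + y_f)/2
  exactly.

Fitting is unweighted Levenberg–Marquardt least squares
(`scipy.optimize.curve_fit`, method `"lm"`, up to 20,000 function
evaluations). Auto-initialization replaces by-eye starting values: y₀
from the lowest-strain tertile mean, y_f from the highest-strain
tertile mean, E_t from the strain whose response is nearest the
midpoint, k = 15 (the middle of the range typical for these metrics).
95% confidence intervals are asymptotic: ±t₀.₉₇₅,(n−4) × √(diag Σ) with
Σ the Jacobian-based covariance. R² = 1 − SS_res/SS_tot. Fits that fail
to converge, or land on k ≤ 0 or E_t ≤ 0, are returned flagged
(`converged=False`) with a message instead of raising, so batch fitting
over nine metrics never aborts; flagged fits are excluded from the E_t
range summary.

Cross-checks: the LM minimum is tested against an independent coarse
grid over (k, E_t) — with the asymptotes solved linearly at each grid
node — followed by a Nelder–Mead polish, and agrees to 1e-4 relative in
sum of squared residuals.

## Simulated dose–response experiments

The generator's default parameter sets for the nine metrics are the
published estimates for this assay (e.g. neurite length/cell: y₀ = 141
µm, y_f = 31.55 µm, k = 14.43, E_t = 0.339, R² = 0.834), used as ground
truth for parameter-recovery validation.

**Design.** One experiment is 152 injured wells (five plates) plus 8
unstretched controls at strain 0. Injured wells are split evenly over
five stage-displacement amplitudes with level-mean strains (0.02, 0.19,
0.37, 0.55, 0.71): the lowest amplitude produces negligible strain and
the rest rise linearly with displacement. Within a level, wells scatter
with sd 0.09 (the deliberate post-array misalignment spreads strain
across the plate, filling the gaps between levels), clipped at zero.
A uniform-strain design was considered and rejected: it under-weights
the near-zero-strain anchor that the real five-level protocol provides
and correspondingly inflates the variance of ŷ₀.

**Noise.** Per-well Gaussian noise with sd² = SS_tot·(1 − R²)/n, where
SS_tot is taken over the noise-free curve values at the drawn strains
and R² is the metric's published fit quality. This reproduces the
observed signal-to-noise share per metric (simulated R² comes out
within a few hundredths of the target; the approximation ignores the
small inflation of SS_tot by the noise itself).

Under these conditions the pipeline recovers E_t within the published
confidence interval in ≳95% of seeded runs for the best-determined
metrics, and the across-metric min/max of Ê_t reproduces the reported
0.305–0.361 spread within ±0.03.

## Synthetic culture scenes

A scene is a parametric field of view at 0.33 µm/px (default
384×384 px ≈ 127 µm, the central region of a 10× field). Defaults: 6
cells (the seeding density of 33,750 cells/cm² implies ~5.4 cells per
field), soma radii 16–22 px (~11–15 µm diameter), nuclear radii
9–12 px, 2–4 primary neurites per cell of 200–340 px (66–112 µm) with
60% branch probability, thickness 3.2 px (~1 µm).

Control geometry is drawn from the seed alone; the injury level in
[0, 1] is then a deterministic transform:

- neurite paths keep the leading (1 − 0.7·injury) fraction of their arc
  length; thickness falls by 1.4·injury px (floor 1.6 px);
- beads (radius 4–6 px) appear along neurites at 1.7·injury per 100 px
  — bead size/frequency are free parameters, as no distribution is
  published; values were set so beads are clearly sub-somatic yet
  survive candidate detection;
- a nested prefix of a seed-fixed random cell order dies:
  round(0.6·injury·n) cells keep their nucleus but lose calcein signal
  and neurites (calcein-AM logic: dead cells do not retain the dye).

Because the geometry never depends on the injury level, ground-truth
neurite length is non-increasing in injury for a fixed seed — a
property the tests exercise directly.

Rendering stamps disks and round-capped strokes, applies a Gaussian PSF
(σ = 1 px; widefield), adds Gaussian noise (sd 0.01) and an optional
linear background ramp, and clips to [0, 1]. Background levels are 0.03
for live channels and 0.20 for the MAP2 channel (immunofluorescence
background is substantially higher; this also places the Background-
method threshold, 2× mode, at the half-maximum of neurite edges, where
an area measurement is unbiased). Neurite paths steer away from other
cells' centers and terminate at the field margin, keeping scenes
separable so that count-exactness is a meaningful test.

**What the generator does not emulate:** photobleaching, camera shot
noise, debris, overlapping cell clusters, out-of-focus light, or
genuinely ambiguous dead/alive morphology. Passing the ground-truth
tests therefore shows the algorithms are correct on clean, resolvable
cultures; it does not bound their error on crowded or low-SNR real
images.

## Live-cell segmentation

1. **Preprocessing**: 3×3 median filter; background estimated by a
   separable large-window median (two 1-D passes, window 101 px)
   refined by a robust quadratic surface fit to background pixels, then
   subtracted and clipped at 0. The surface refinement exists because
   windowed estimators are biased at the borders of a tilted field.
2. **Nuclei**: Otsu threshold, minimum area 20 µm², watershed
   declumping from distance-transform peaks (min peak separation
   12 px).
3. **Cell bodies**: the viability channel is thresholded at
   median + 0.3·(p99.5 − median) — a background-referenced cut chosen
   because the histogram is background-dominated (bimodal criteria sit
   far too high and drop injury-thinned neurites) while a cut too near
   background inflates a blur halo that merges neighboring strands.
   Candidates are the connected components of a radius-4 opening (small
   enough to keep beads detectable); a candidate is a viable cell iff
   it overlaps ≥1 nucleus and its area is ≥ 60 µm². Failures are
   recorded as rejected beads with reasons. Accepted somata are
   restricted to a radius-7 opening so the soma mask hugs the cell body
   rather than the wedges where neurites enter. A nucleus is dead if
   under half its area lies on calcein signal.
4. **Neurites**: viability mask minus the (1-px-dilated) somata is
   skeletonized; fragments under 6 px are dropped and terminal spurs
   ≤ 7 px hanging off junctions are pruned (artifacts of skeletonizing
   lumpy strokes). The skeleton becomes a junction/endpoint graph whose
   edges carry polyline arc length, measured on every-5th-pixel chords:
   raw per-pixel (1, √2) step weights overestimate digital lines by up
   to ~8% at unfavorable angles, subsampled chords by well under 1%.
   Two endpoint corrections counter skeleton end-retraction: free tips
   gain the local mask radius (distance transform, capped at 5 px) and
   soma-rim roots gain their distance to the halo-corrected (2-px
   eroded) soma surface (capped at 8 px).
5. **Metrics**: a process is a connected cluster of skeleton pixels in
   a soma's contact rim; a branch is a cluster of degree-≥3 skeleton
   pixels outside soma rims. Fragments touching no soma count toward
   totals but no cell's per-cell value (severed fragments are a real
   injury outcome). Per-cell values divide by the viable count;
   viability% requires a user-supplied reference count (its definition
   is assay-specific and not derivable from one image).

On 40 rendered scenes (20 seeds × two injury levels) viable and dead
counts are exact, and total neurite length is recovered with ≈ −2%
mean error (worst case ≈ −7%, from genuinely merged parallel strands
at crossings). Process and branch counts are exact on clean fixtures
but only approximate on dense scenes, where neurite crossings create
junctions indistinguishable from branches — an inherent limitation of
skeleton topology, shared with the instrument-vendor pipelines this
module stands in for.

## Synaptophysin compartments

All immunofluorescence channels get a 2×2 median prefilter; since a
2×2 window has an even sample count, the median is the mean of the two
middle order statistics (either middle alone shifts object edges by a
pixel). The MAP2 cell mask uses the Background method: threshold = 2 ×
the mode of a 256-bin histogram over the observed range, foreground
strictly above. The soma mask is a grayscale-free binary erosion of the
cell mask (disk, default radius 4 px — it must exceed half the maximal
neurite thickness; exposed in config because no value is published).
The neurite mask is cell minus the soma dilated by 3 px (disk, chosen
for isotropy), which guarantees soma ∩ neurite = ∅ with a guard band.
Note the soma domain is deliberately the *eroded* image, exactly as the
procedure defines it, not a reconstruction of the full cell body.

Maximum-correlation thresholding: after 1-px Gaussian smoothing,
in-mask intensities are quantized to 256 levels and the threshold
maximizing the Pearson correlation between intensity and the
foreground indicator is selected; the criterion is evaluated for every
candidate level in closed form from cumulative sums, and ties take the
lowest threshold. Equivalence with an exhaustive per-candidate search
is asserted on random images. Constant in-mask input has no valid
threshold and raises a degenerate-input error; the density wrapper
maps that case to ratio 1 (uniformly bright) or 0 (blank), and empty
domains report NaN.

Group comparison uses Welch's unequal-variance t-test (the variant is
not externally specified; Welch is the safer default) at significance
level 0.05/3 for the three domain comparisons. Puncta are *not* counted
per neurite length anywhere: injury-induced beading makes uniform
stain look punctate, so area fraction is the only density measure
offered.

## Problem sizes and determinism

Validation runs use 50-repetition recovery simulations (160 wells per
fit), 20 rendered 384² scenes, 100 random 32² threshold images, and
1,000 random compartment masks; the full suite and the acceptance
script each complete in well under five minutes on one core. Every
stochastic component takes a `numpy` `Generator` or integer seed;
derived streams (death order, beads, puncta, render noise) use fixed
offsets from the scene seed so that ground-truth geometry is identical
across injury levels of the same seed.

## Known limitations

- Segmentation accuracy claims are relative to the synthetic renderer;
  no claim of equivalence with any proprietary instrument pipeline.
- Neurite length degrades gracefully but measurably (to ≈ −7%) on
  fields with many crossings; branch counts on such fields conflate
  crossings with true branch points.
- The logistic CIs are asymptotic; no bootstrap option.
- The strain module assumes no shear and exact equibiaxiality; it
  cannot detect a violation from dot width/height alone.
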