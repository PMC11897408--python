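# Methods

This note documents the models and procedures implemented in
`decondenseq`, the defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the numerical conventions shared
by all modules.

## Conventions

Images are 2D arrays indexed (row, col), origin top-left, 0-based, pixel
identified with its center. Rasterization is pixel-center-in-region.
Filters use reflect padding (avoids dark rims that would bias histogram
thresholds). Foreground connectivity is 8-connected, background
4-connected — the standard dual that keeps hole filling topologically
consistent. Areas are reported in px² and, via the configured pixel size,
µm². No pixel size is intrinsic to the synthetic data; the default
1 µm/px is a placeholder, and a 60× confocal acquisition would typically
use ~0.11 µm/px.

## Synthetic generator

The generator is first-class, tested code: it defines the conditions
under which every downstream guarantee is verified.

**Chromatin mass.** The boundary is drawn in polar form
r(θ) = R·(1 + a·Σⱼ cⱼ·cos(jθ + φⱼ)), j = 1..m, with seeded weights
normalized to Σ|cⱼ| = 1, so the roughness amplitude `a` is exactly the
maximal fractional radial excursion — a single interpretable
"condensation" knob (a = 0 is a perfect disk). Harmonics start at j = 1
(lobed shapes allowed). The default m = 12 places the boundary
wavelength 2πR/m at ~26 px for the reference R = 50 px object, the scale
of chromosome arms in a condensed cluster. The analytic area of the
shape, πR²(1 + a²Σcⱼ²/2), is used to back-solve R when a target area is
requested. The intensity field (background + foreground) is blurred with
a Gaussian PSF surrogate, then Gaussian noise is added and the result is
clipped at 0 — shot-noise-on-PSF ordering without modelling either.
Defaults: foreground 200, background 10, so a noise sd of 38 gives a
contrast-to-noise ratio (SNR) of 5.

**Mitotic time-lapse.** One condensed mass of area A₀ (default
1000 px², standing at 30 % of the interphase reference area) until the
onset frame; from onset, two daughter masses — one boundary draw and its
mirror image — separate symmetrically while their summed analytic area
follows A(t) = A₀·(1 + k·t), optionally clipped. Daughters are smooth
disks by default (decondensing chromatin is smooth; roughness, if any,
belongs to the pre-onset mass). The generator guarantees two non-touching
masses at every post-onset frame and raises otherwise. The default
separation speed is 2.0 px/frame: an integer speed keeps the daughters'
subpixel phase constant so a non-growing daughter's rasterized area is
exactly conserved; non-integer speeds add ~2 % frame-to-frame
rasterization jitter, which is a property of pixel grids, not of the
biology being emulated. Ground-truth phase labels default to: metaphase
before onset, anaphase for 2 frames from onset, telophase until a
daughter's analytic area reaches 80 % of the interphase reference, then
interphase.

**Two-channel cell.** The marker channel is rim_intensity on the
perichromatin rim (dilation of the chromatin mask by rim_width = 4 px,
minus the mask), cytoplasm_intensity inside the cell disk, and — on the
chromatin body itself — rim_intensity by default, because a
perichromatin marker read over the chromatin mask should report the
coat's level; this makes the background-corrected intensity exactly
rim − cytoplasm on noise-free cells. Foci are disks rejection-sampled
into the cytoplasm, pairwise ≥ 4 focus radii apart, re-drawn up to a
retry cap if they would hit chromatin, rim, or another focus.

**What the generator does not emulate:** real PSFs, camera noise
statistics (only additive Gaussian), intensity inhomogeneity,
out-of-focus light, touching cells, chromosome bridges or lagging
chromosomes, 3D structure, or any physics of chromatin. Passing tests
demonstrate the *algorithms* recover what they are defined to recover
under these idealized conditions; they do not certify performance on
real microscopy, where segmentation error is the dominant unknown.

## Segmentation

Two recipes, used verbatim by the pipelines:

* in-vitro: median denoise (default 3 px — the smallest effective
  window; configurable) → optional 8-bit rescale (on by default; fixed
  substrate images are interchanged as 8-bit TIFF) → Otsu → hole fill.
* live-cell: Gaussian blur, default σ = 1.5 px → Otsu → hole fill
  (8-bit conversion off by default).

Otsu maximizes the between-class variance over a 256-bin histogram
(uint8 levels used directly; other dtypes binned uniformly over
[min, max]); ties break toward the smallest maximizing level, and the
mask is strictly `frame > t`. A constant image has no threshold and
raises a degenerate-input error; callers may opt into an empty mask.
Both recipes are translation-equivariant and, with 8-bit rescaling,
invariant to positive affine intensity maps up to quantization. One
threshold family is used everywhere, including for the intensity-mask
workflow where ISODATA-style "default" thresholding is sometimes used
elsewhere; standardizing on Otsu keeps the whole package testable
against a single exhaustive-sweep oracle.

## Border smoothness

soft(M) is a binary median filter: foreground iff more than half of the
k×k window is foreground (odd k, no ties possible). The score is
s = |M ∩ soft(M)| / |M ∪ soft(M)|. Scoring is per object (each connected
component is a substrate, the experimental unit), not per image. The
default kernel is 15 px, calibrated to the ~50 px-radius reference
object (≈ 0.3·R): large enough to erase chromosome-scale roughness, small
enough that a digital disk scores ≥ 0.99. The kernel sets the roughness
scale being measured and should be rescaled with object size; s is
non-increasing in the kernel on rough masks. An empty mask has no score
(error); a mask softened to nothing scores 0 with a warning.

## Time-course analysis

Objects (≤ 2 per frame; more is an ambiguity error) are linked by
nearest centroids, with the two-object assignment chosen to minimize the
summed displacement. Anaphase onset is the first frame with exactly two
objects, each ≥ 20 % of the last single-mass area, persisting for ≥ 2
consecutive frames — the persistence rule makes the "first frame where
two daughters are segmentable" robust to one-frame spurious splits from
segmentation noise. Trajectories without a qualifying split are
discarded, and every discard is logged with its reason.

Normalized area is the summed daughter area divided by the area at
onset, so the curve equals 1 at t = 0 exactly; pre-onset frames are
reported at negative time with the same denominator. The expansion rate
is the least-squares slope of (normalized − 1) vs t through the origin —
anchored, because the t = 0 value is exact by construction.

Phase classification is an explicit size rule (trained morphology
classifiers are out of scope): with reference area I (interphase
nucleus; estimated as the median single-object area of the first 5
frames when the clip starts in interphase, otherwise user-supplied), a
single mass ≥ 0.8·I is interphase, < 0.4·I is metaphase, and in between
prophase; two masses are anaphase for 2 frames from onset, then
telophase until a daughter reaches 0.8·I, then interphase. All four
cut-offs are configuration, calibrated on synthetic fixtures only.
Dwell time is frames-in-phase × interval; curve aggregation reports
per-timepoint mean and s.e.m. = sd/√n over available cells (n = 1
reports s.e.m. 0, flagged by the n column).

## Intensity and foci

Mean marker intensity over the chromatin mask, background-corrected by
the mean in a circular ROI (default radius 10 px) rejection-sampled
uniformly over the cytoplasm (cell minus the chromatin mask dilated by a
configurable exclusion band, default 5 px, which keeps the ROI off the
perichromatin rim). Negative corrected values are allowed and flagged.
Line scans take exactly 200 samples, endpoints inclusive, bilinear
interpolation. Foci detection is an explicit algorithmic surrogate for
visual scoring: cytoplasmic pixels ≥ 3× the cytoplasm median, 8-connected
components ≥ 4 px² are foci, and "big" foci require ≥ 25 px² at that
intensity; every threshold is in the config and echoed in the output.

## Statistics

Each sample is tested for normality with Shapiro-Wilk (delegated to
scipy; the *gate* is the tested behavior). Both samples pass at α (default
0.05) → two-tailed Welch t (Welch–Satterthwaite df; two constant samples
with equal means give t = 0, p = 1, with unequal means the statistic is
undefined and raises). Otherwise → two-tailed Mann-Whitney U: exact by
full enumeration of all C(nₐ+n_b, nₐ) group assignments of the pooled
mid-ranks when nₐ+n_b ≤ 12 (two-tailed mass: assignments whose U is at
least as far into either tail as observed), else the normal approximation
with tie and continuity corrections. Fisher's exact test uses the
probability-mass two-sided rule (sum of hypergeometric probabilities of
tables no more probable than observed). No multiple-testing correction is
applied; comparisons are reported one at a time. Hierarchical summaries
emit per-experiment means plus overall mean ± s.e.m. on *both* bases
(across experiments and across units), since the two answer different
questions and published ± values do not always declare their basis.

A constant sample is routed to the rank branch (Shapiro-Wilk is
undefined on zero variance; a point mass is not Gaussian).

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` use cohorts sized so that the
guarantees are meaningful yet fast: 100 masks for the IoU oracle, 30
masks per amplitude for monotonicity, 2 experiments × 25 substrates per
condition for the contrast, 20–50 cells for onset/dwell/rate recovery,
1000 replicates per null for type-I calibration. All randomness flows
from explicit seeds (the acceptance script derives every sub-seed from
its single `--seed`), and both pipelines are deterministic given config
+ seed, verified at byte level on their CSV outputs.

## Known limitations

* The size-rule phase classifier ignores morphology and texture; it
  cannot distinguish prophase from early prometaphase and will mislabel
  cells whose interphase reference is wrong.
* Object linking assumes ≤ 2 relevant objects; crowded fields need
  upstream cropping.
* The smoothness score conflates boundary roughness with topology
  (holes touching the boundary); on real data the soft-kernel size must
  be chosen relative to object scale.
* The background ROI is a single draw per cell, as in common practice;
  its variance contribution is not propagated.
* The normal-approximation Mann-Whitney branch is approximate near
  n = 13–20; exact enumeration is used only up to pooled n = 12.
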