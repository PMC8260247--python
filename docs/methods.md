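# Methods

## The analysis in one paragraph

`connsel` asks whether the voxels of a category-preferring visual region
that are most strongly functionally connected to distal same-category
regions carry more multivoxel category information than the least
connected voxels do.  Per subject, runs of a blocked visual task are fit
with a first-level GLM; a duplicate of the data is task-regressed and
band-passed to obtain pseudo-resting-state residuals; each target-region
voxel is scored by its mean Fisher-z correlation to distal seed voxels;
the 100 most and 100 least connected voxels (and, for comparison, the
100 most activated) are selected on one data split and decoded on the
remaining splits with split-half correlation decoding; group inference
uses within-subject ANOVAs and paired t tests.  Controls include
activation-matched voxel-set permutations, temporal-SNR comparison, and
a whole-grid "good seed" searchlight with sign-flip TFCE group maps.

## Task design and GLM

Each run is a 176 s block design (88 volumes at TR = 2 s): 16 s fixation
lead-in/out, then twelve 6 s stimulus blocks each followed by 6 s
fixation — two blocks per intact category (tools, faces, places,
animals) and one per phase-scrambled variant, order randomized per run.
Six runs per subject.

Condition boxcars are convolved with the canonical double-gamma HRF
(response peak 6 s shape parameter, peaking near 5 s; undershoot delay
16 s, ratio 1/6; 32 s kernel; no derivatives) on a 0.1 s microtime grid
and resampled at the TR.  The run-wise design holds one regressor per
condition, six motion regressors, one intercept, and a discrete-cosine
drift basis.  Estimation is ordinary least squares; contrast t maps use
t = c'b / sqrt(sigma^2 c'(X'X)^-1 c).  Category preference contrasts
weight the preferred category 1 and the other three intact categories
-1/3 (scrambled conditions 0); comparison-specific selection uses
simple +1/-1 pairwise contrasts.

Two deliberate simplifications:

* **OLS instead of AR(1) prewhitening.**  The synthetic noise is white
  by construction, and the quantities of interest (selection orderings,
  split-half correlations) are invariant to the mild efficiency loss.
* **Drift basis definition.**  The basis holds DCT components with
  period in (`hp_cutoff`, run length]; the k = 1 half-cycle component
  (period 2T = 352 s) is excluded as inseparable from a within-run
  trend.  With the default 256 s cutoff and 176 s runs the basis is
  empty, so the intercept alone detrends — the simulated data carry no
  drift.  Absorbing drift in the design is the same projection as
  pre-filtering, with simpler provenance.

## Connectivity estimation

The denoising regression removes, per run: the task regressors, six
motion series plus their first-order temporal derivatives, one combined
global-signal proxy (the mean over non-gray voxels, standing in for
white matter/CSF), and the intercept.  Residuals are band-pass filtered
to 0.01-0.1 Hz and runs of a data split are concatenated.

The band-pass is a zero-phase frequency-domain filter with
raised-cosine rolloffs (half-width 25% of each edge).  An IIR filter
was rejected: on 88-sample runs, `filtfilt` edge transients inflated a
passband sinusoid by tens of percent and left the stopband essentially
unattenuated, while the spectral filter meets the gain contract
(passband within 10% of unity, gain < 0.1 at twice the upper edge, DC
removed) exactly and is a cached 88x88 linear operator, applied with
one BLAS call per run.

Connectivity is the Pearson correlation of each target voxel with every
same-category seed voxel over the split's concatenated residuals,
Fisher transformed with |r| clipped at 1 - 1e-7 to keep z finite; a
voxel's selection score is its mean z over all seed voxels.
Zero-variance voxels are flagged ineligible.  Seed voxels are the 100
most activated voxels (by the seed region's own preference contrast,
estimated from the selection split) within each other same-category
region.

## Split scheme, selection and decoding

The six runs are partitioned at random into three two-run splits.  Each
fold selects voxels on one split and decodes on the other two, so
selection and decoding data never mix.  Selection returns exactly k
(default 100) voxels; ties break by ascending voxel index; most- and
least-connected sets are disjoint by construction when 2k does not
exceed the eligible count.

Decoding restricts the run-averaged condition beta patterns of the two
decoding splits to the voxel set, correlates each condition pattern
across the halves (2x2 matrix), and reports mean within-condition minus
mean between-condition correlation — positive when patterns are more
similar to themselves than to the other condition.  Patterns are raw
betas: no voxelwise normalization or mean-pattern subtraction.  Fold
accuracies are averaged per subject x region x comparison x mode before
group inference.

The matched-activation control median-splits the target region by mean
connectivity z, repeatedly (default 10,000 draws) samples one random
k-subset from each half, and keeps only pairs whose activation t values
do not differ by a pooled two-sample t test: liberal (two-tailed
p > 0.10), intermediate (|t| <= 0.5), or strict (-0.5 <= t <= 0, the
strongly connected set at most as activated).  Decoding accuracy is
averaged over retained pairs; a subject/region with no retained pair
drops out of that analysis, as happens with real data when connectivity
and activation are too entangled.  The degenerate all-equal case is
defined as t = 0 (pass).  The matching t uses the comparison-specific
contrast for every region — the stricter, comparison-aligned control.

## Group statistics

Paired t tests are two-tailed with listwise deletion; Bonferroni
correction divides alpha by the number of post hoc comparisons.
Repeated-measures ANOVAs (statsmodels `AnovaRM`) report uncorrected
degrees of freedom and partial eta squared = F*dfn/(F*dfn + dfd); no
sphericity correction is applied.  A constant response is defined as
F = 0 everywhere.

The searchlight group analysis enhances the per-subject most-minus-least
difference maps' group t map (mean/SE) with TFCE (E = 0.5, H = 2,
dh = max/100 by default; 6-connectivity), builds a null distribution of
the maximum enhanced statistic under random per-subject sign flips, and
converts family-wise p values to z, thresholded at Z > 1.65 (one-tailed
most > least).  Permutation p values live in [1/(n_perm+1), 1].

## Good-seed searchlight

For each gray-matter center outside the target region, the seed is the
mean residual time course of the 100 nearest gray voxels (ties by
index), with target-region voxels excluded from the averaging so the
target cannot seed itself.  Selection uses the full six-run residuals
and decoding a single odd/even-run fold; this reuse is benign here
because both selection modes share it and no activation comparison is
involved.  The planted "good seed" ground truth used by tests is the
set of centers whose searchlight can reach coupled voxels: the seed
region dilated by the ~2.9-voxel radius of a 100-voxel sphere.  TFCE
deliberately spreads enhancement across contiguous suprathreshold
voxels, so detection is evaluated by coverage of the true seed region,
the majority of suprathreshold mass falling in that support, and the
group-mean difference peaking inside it — not by exact containment,
which no TFCE map with a real effect can satisfy.

## The synthetic cohort generator

Subjects are simulated on an isotropic unit-spacing grid (no physical
mm, no spatial normalization; a one-voxel border shell is non-gray and
supplies the global-signal proxy).  The default layout mirrors the
six-region study geometry: per category, two radius-5 target spheres
(515 voxels, satisfying the >300-voxel requirement) plus one radius-3
distal seed sphere; each target is seeded from every other same-category
region.  Reduced layouts (single category; radius-4.5 targets of 389
voxels; single-target searchlight grids) support replicate-heavy
calibration studies.

Per voxel, the signal is

    baseline (100)
    + activation_gain * act_v * pref(condition) convolved responses
    + pattern contribution (see below)
    + band-limited (0.01-0.1 Hz) component of SD coupling_strength
    + white noise filling the remainder of noise_sd^2.

`act_v` is a heterogeneous per-voxel amplitude (|N(1, 0.35)|), with
pref = 1 for the region's category, 0.3 for other intact categories,
0.15 for scrambled.  Condition-specific patterns are i.i.d. Gaussian
across voxels scaled by `pattern_snr`, mean-centered across the region
so they shape multivoxel geometry without shifting regional mean
response, and by default carried only by the "informative" fraction
(`frac_informative`, default 0.5) of target voxels.

Connectivity is planted by *sharing*: coupled voxels (all seed-region
voxels plus the informative target voxels of that category) share their
category's band-limited latent, while every other voxel receives a
private band-limited series of the same amplitude.  All latents are
orthogonalized against the full first-level design span (conditions,
motion, intercept).  Two properties follow, and both matter:

* Planting connectivity never changes a voxel's marginal variance,
  spectrum, or GLM residual behavior — only cross-correlation
  structure.  Without this (naive additive injection), coupled voxels
  had inflated residual variance, hence systematically lower t values,
  and the "activation independent of connectivity" premise of the
  matched-activation control silently failed.
* Orthogonalizing against the full design span (not just the task
  regressors) prevents the shared latent from leaking into condition
  betas through partialling with motion.

Defaults (the study conditions everywhere): coupling_strength 0.5
(giving informative-voxel target-seed correlations around 0.2-0.3 after
denoising), frac_informative 0.5, noise_sd 1, activation_gain 1,
pattern_snr 0.1.  The pattern amplitude was fixed by a pre-build
calibration sweep at single-subject fold-averaged most-connected
accuracy ≈ 0.29 with least-connected ≈ 0 and most-activated ≈ 0.27 —
moderate accuracies with the most-connected ≥ most-activated ordering
the analysis is designed to detect.  Motion series are smooth random
walks that carry no signal; they exist to exercise the nuisance
interface.  Truth records (informative indices, patterns, latents) are
stored for tests only; no analysis stage reads them.

What the generator does **not** emulate: physiological (cardiac or
respiratory) noise, motion artifacts in the image domain, scanner
drift, field inhomogeneity, spatial autocorrelation of noise, and
anatomical variability.  Passing tests therefore demonstrate that the
pipeline recovers the statistical structure it assumes, with calibrated
error rates under its noise model — not that the method is robust to
every nuisance present in real fMRI.

## Numerical and procedural choices

* Fisher z clipping at |r| = 1 - 1e-7; ordering impact negligible.
* All RNG streams derive from one master seed via `SeedSequence`
  spawning; identical configuration + seed reproduces every table bit
  for bit.  The searchlight module draws no random numbers.
* Matched-draw subsets are sampled by ranking i.i.d. uniforms
  (vectorized, uniform over k-subsets), with an RNG stream independent
  of the simulation stream.
* Degenerate inputs: zero-variance voxels are flagged and excluded from
  selection; zero-variance patterns make that accuracy cell missing
  (propagated as subject dropout, never imputed); an all-equal matching
  pool passes (t = 0); rank-deficient designs raise with the collinear
  columns named.
* Problem sizes in tests and the acceptance script are scaled to the
  smallest geometry that preserves the contract under test (reduced
  grids, 100 null cohorts of n = 10, 1000 sign flips with dh = max/50
  for calibration loops); the full-size defaults (k = 100, 10,000 draws
  and permutations, 20 subjects) remain the package defaults.

## Known limitations

* The ANOVA reports uncorrected df; sphericity corrections
  (Greenhouse-Geisser and kin) are not applied.
* The searchlight's use of all runs for both selection and decoding is
  deliberate (both modes share it symmetrically), but it would bias
  comparisons against activation-based selection if one were added
  there.
* The matched-activation control's retention rate equals its nominal
  value only on average over subjects; individual subjects with chance
  activation-connectivity imbalance retain fewer pairs (and genuinely
  entangled subjects drop out, mirroring the real-data behavior).
* With coupling_strength > noise_sd the white-noise floor is zero and
  the marginal-variance-preservation property no longer holds (the
  band-limited component then exceeds the nominal noise budget).
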