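# Methods

This note documents the models and numerical choices behind the
package: what each feature is, how the synthetic cohort is generated,
how effects are calibrated, and what the tests do and do not establish
about real data.

## Pixel features

Each photograph is an 8-bit RGB raster; alpha channels are dropped,
palettes expanded, and grayscale promoted to R=G=B on load.  Per photo
we compute population (divide-by-N) means and variances of the R, G and
B channels, and of saturation and value from the hexcone HSV model
(V = max(R,G,B); S = 0 if V = 0, else 255·(V−min)/V).  Population
variance is used because the variance here measures within-photo
contrast, a property of the photo's pixel population, and it is defined
even for one-pixel images.

Hue is computed in continuous degrees by the max-channel piecewise rule
and stored in half-degrees in [0, 180), the convention of 8-bit imaging
pipelines.  The six color intervals are left-closed/right-open with
boundaries [7, 23, 35, 90, 130, 169]: orange [7,23), yellow [23,35),
green [35,90), blue [90,130), violet [130,169), and red wrapping across
zero (h < 7 or h ≥ 169) — the only tiling consistent with six
boundaries, six colors and red's position on the hue circle.
Classification uses the continuous hue (no pre-rounding).  Achromatic
pixels (R=G=B) carry the h = 0 convention and therefore count as red;
desaturated pixels are not excluded from hue classification.  Color
shares are exact pixel-count fractions, so they always sum to 1.

Per-user aggregation is the unweighted mean over the user's photos:
photos weigh equally regardless of resolution.

Implementation notes: the single-image extractor works in float64 with
integer-exact moment sums; the batch extractor adds a fused
single-pass numba kernel for uint8 stacks and a float32 hue path in the
numpy fallback.  Boundary-exact hues are integer ratios that
correctly-rounded float division reproduces exactly, so all paths
classify identically; tests compare them directly and against a
per-pixel double-loop oracle.

## Content and face features

Content sub-categories arrive as an annotation table (the interface
that replaces live vision-API calls).  Recoding to the 15 top
categories (abstract, animal, building, dark, drink, food, indoor,
others, outdoor, people, plant, object, sky, text, transportation) is a
data-driven mapping: an explicit per-label table wins; otherwise the
token before the first underscore, resolved through an alias table
(e.g. `trans` → transportation); anything unresolved falls back to
"others".  The category distribution's Gini coefficient is the
normalised mean absolute difference G = Σᵢⱼ|pᵢ−pⱼ|/(2nΣp), computed via
the O(n log n) sorted-rank identity and verified against the pairwise
oracle.

Face features: average faces per photo, share of photos with exactly
one face, and the mean emotion vector pooled over *faces* (a three-face
photo contributes three faces), matching the definition of a per-face
average.  Users with no detected faces carry missing emotion features;
the correlation screen handles them by pairwise deletion and the
predictor by training-fold mean imputation.

## Instrument scoring

All instruments are scored as item means on the 1–5 scale (not sums),
so every trait and every RMSE lives on the same scale.  Reverse-keyed
items map v → 6−v.  The scoring key (item counts and reverse-key
indices) is external configuration; the defaults use the published item
counts (9 SD3-narcissism items, 5 SWLS items, 5 SELSA-S items per
sub-factor), no reverse-keyed SWLS items (true of the instrument), and
a fixed editable convention for the SD3/SELSA-S reverse sets, whose
exact published assignments are not reproduced here.  Total loneliness
is the mean of the three sub-factor scores.

## Cohort assembly

Users with fewer than `min_photos` (default 30) manifest rows are
excluded — the study's activity criterion.  Real crawls are ragged, so
each feature family uses its own denominator: photos lacking an
annotation row still count toward pixel averages and vice versa.  The
per-user table has a fixed 45-column order (id, photo count, 15
category shares, Gini, 2 face statistics, 8 emotion means, 17 pixel
features); identical inputs reproduce it byte-identically.

## Correlation screen and prediction

The screen computes Pearson r for every trait × feature pair with the
two-sided p from t = r√((n−2)/(1−r²)), flags p < 0.05, and applies no
multiple-testing correction — matching the bare significance-star
convention of exploratory tables in this literature.  Pearson (rather
than Spearman) is the default convention for such tables and supports
the t-based p-value.  Zero-variance features are reported as missing
with a reason rather than failing the screen.

Prediction uses all 43 numeric user features (including the photo
count).  Folds are a seeded uniform shuffle into 10 near-equal parts,
no stratification; within each fold, missing cells are imputed with
training-fold means and features standardised by training-fold
mean/sd before fitting, so held-out rows never leak into
preprocessing.  Models: ordinary least squares, and a random forest
with 500 trees, p/3 candidate features per split (the regression
convention) and no depth limit, seeded.  The reported RMSE is the
unweighted mean of the 10 fold RMSEs.

## Synthetic cohort model

The generator emulates the study conditions: 179 users, each with a
uniform 30–60 photos (the ≥30 inclusion rule built in), correlated
latent traits, and photo features that drift linearly with traits.

**Traits.**  Latents are multivariate normal on the 1–5 scale, clipped
to [1,5].  Default means (2.8, 3.2, 2.2, 2.4, 2.8) and sds (0.65,
0.80, 0.75, 0.70, 0.95) give realistic Likert-scale dispersion;
the default correlation structure has life satisfaction negatively
related to the loneliness sub-factors (−0.25…−0.35), loneliness
sub-factors inter-correlated (+0.40…+0.45) and narcissism nearly
independent.  Likert items are latent + N(0, 0.7) discretised to 1..5,
stored inverted for reverse-keyed items, so instrument scoring recovers
the latents up to measurement error (reliability ≈ 0.87 for 5-item
scales at these sds).

**Effects.**  Each feature channel g (people share, animal share,
one-faced share, multi-face mass, happiness, warm share, value
variance) is a unit-variance linear combination of the standardised
traits plus residual style noise:

    g_u = Σ_t β[t] z_t(u) + √(1 − βᵀCβ) · η_u ,

so a coefficient β *is* the latent trait–feature correlation before
attenuation.  The channel is then mapped affinely to its natural scale
(e.g. people share 0.20 + 0.12·g, value variance 2500 + 800·g) and
clipped to a plausible range.  Per-photo values add photo-level noise
(multinomial category draws, the 0/1/3 face-count mixture, per-face
happiness noise, warm-share and value-variance jitter), which
attenuates the observed user-level correlation by a factor the design
keeps between ~0.86 and ~1.0 at 30–60 photos per user.

Default signs mirror the correlation structure this kind of study
reports: narcissism → more people-related and one-faced photos;
life satisfaction → happier faces; family loneliness → fewer and less
happy faces; romantic loneliness → more animal content, less warm and
less contrasty pixels.  Strong effects default to |β| = 0.35 (0.30 on
the shared happiness channel).  This magnitude was set by an a-priori
power analysis: after survey-measurement (~×0.93) and finite-photo
(~×0.86–0.99) attenuation the realised correlations are ≈0.28–0.37,
giving ≥95% power per effect at n = 179 and α = 0.05, which is what a
≥90% sign-recovery guarantee across replicates requires.  Weak effects
default to |β| = 0.12, deliberately below detectability at this sample
size, mirroring non-significant cells.  Magnitudes are conventions of
the generator, not estimates of any real population.

**Rendering.**  Synthetic photos are flat-hue color fields, not
photographs: each photo's spec fixes exact integer pixel counts per
color class (largest-remainder rounding of the target shares), painted
at within-interval hues (0, 15, 29, 60, 110, 150 half-degrees) at high
saturation, with two brightness levels in exact halves so the value
variance is exactly ((v_hi−v_lo)/2)².  Color positions are shuffled
with the photo's seed.  Feature extraction on a rendered photo returns
the spec's color shares and value variance exactly, which is what makes
end-to-end exactness testable.  Faces exist only in the annotation
tables — the pipeline consumes annotations, so rendering faces would
add nothing.  RGB variances are not directly controlled; they co-move
with the value variance through the rendering, reproducing the
empirical pattern that dull photos are dull in every channel.

**Seeds.**  A cohort is fully determined by (config, master seed).
Per-user generators derive from (seed, user index, stream), so a user's
photos are reproducible in isolation and a smaller cohort is a prefix
of a larger one.

## What the synthetic data does not emulate

Real photographs have textured, spatially structured content, JPEG
artifacts, correlated category/face/pixel structure (e.g. "people"
photos containing the faces), non-Gaussian trait distributions and
non-linear trait–feature links.  Passing tests therefore establish that
the *pipeline* is correct and calibrated — exact feature arithmetic,
nominal type-I error, unbiased correlation recovery, leakage-free
cross-validation — not that any particular real-world effect exists or
has a given size.  Published numeric tables from private corpora are
not reproduction targets.

## Problem sizes and numerical choices

The acceptance checks run the full pipeline at the study scale (179
users × 30–60 photos) with 64×64 images and 100 replicates for sign
recovery; calibration checks use 1000 null cohorts and 200 planted
replicates at the user level.  64×64 keeps the pixel stage
representative (4096 pixels give share granularity 2.4×10⁻⁴) while
keeping a full replicate a few seconds of CPU.  Tolerances: share sums
to 1e-9; Gini vs oracle to 1e-12; null rejection rate 0.05±0.02;
planted ρ = 0.25 recovered within ±0.02 over 200 replicates.  Ties in
hue classification cannot occur (intervals are half-open); degenerate
inputs (empty images, all-zero Gini vectors, zero-variance features,
constant prediction targets) raise input errors or are reported as
missing, as documented per function.
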