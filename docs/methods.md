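# Methods

This note documents the statistical model behind `syntopy`, the
synthetic data that exercises it, the numerical conventions, and the
places where a genuine design choice had to be made.

## Data model

The unit of observation is one worker ant with 18 mean RGB channel
intensities (six body parts × R, G, B; each in [0, 255]) and cephalic
length and width (µm).  Workers belong to nests, nests to one of 18
collection sites, and each site hosts exactly one model species
(*scutellaris* sites 1–3 and 5–8, *schmidti* 4 and 9–13, *ionia*
14–18 in the default registry).  A mimic's category
(`<taxon>-syntopic`) is always derived from the site registry, never
stored, so labels cannot drift from the design.  Tables with any blank,
out-of-range, or duplicate-key cell are rejected at read time with the
offending row and column named.

All color analysis happens on square-rooted channels: raw RGB
intensities are right-skewed, and the square root is the standard
variance-stabilizing choice in this kind of morphometric work.  Size
analysis uses CS = (CL + CW)/2 (µm) on the raw scale.  The two scales
never mix: display-color reconstruction averages raw RGB, statistics
average sqrt channels.

## Trait comparisons (mixed model)

Each per-specimen trait (per-body-part PC1 of the three sqrt channels,
or CS) is modelled as

    y = µ + β_group + u_site + v_nest(site) + ε,
    u ~ N(0, σ²_site),  v ~ N(0, σ²_nest),  ε ~ N(0, σ²_res),

with group (model species, or mimic category) fixed and site and
nest-within-site random.  Fitting is REML via `statsmodels.MixedLM`
(random intercept per site plus a variance component for nests inside
each site); variance components are clamped at zero and non-convergence
raises rather than returning junk.  PC1 per body part is computed on
models and mimics pooled, so both genera share one axis per part; the
PC sign is fixed so the mean loading is positive (larger PC1 = lighter/
redder).

Pairwise contrasts use Wald z statistics on the REML fixed-effect
covariance with two-sided p-values and Holm step-down control at a
global α = 0.05, plus a compact-letter display.  The z approximation
has no small-sample degrees-of-freedom correction; a simulation in the
test suite documents its type-I error on small nested designs at
roughly the nominal level (accepted band 3–8 %).  Likelihood-ratio
testing would be the natural alternative where the z approximation is a
concern.

## Syntopy statistic

Nest means of the 18 sqrt channels (and of CS) are the analysis units.
The pooled nest-mean matrix is reduced by covariance PCA to the
smallest set of leading components whose cumulative explained variance
reaches 0.80 (default, configurable); scores are unweighted
projections.  For each site s:

* syntopic(s) = mean Euclidean distance over all (mimic nest at s,
  model nest at s) pairs;
* allotopic(s) = unweighted mean over the 17 foreign sites t of the
  per-site mean distance from s's mimic nests to t's model nests.

The unweighted two-stage mean matters: sites contribute equally
regardless of nest counts (a pooled mean over all foreign pairs would
weight nest-rich sites more; a fixture in the tests distinguishes the
two).  The 18 (syntopic, allotopic) pairs enter a one-sided paired
t-test of mean(syntopic − allotopic) < 0 with df = 17.  Size runs
identically with |ΔCS| in µm — absolute differences, since "smaller in
syntopy" is only meaningful for magnitudes.  All-zero differences
return t = 0, p = 0.5 by convention; zero-variance nonzero differences
are an error.

Known property: with heterogeneous model species, the per-site paired
differences carry a fixed structural component (each site class has its
own baseline-to-model distance), which inflates the sample SD of the
differences relative to the sampling fluctuation of their mean.  Under
a true null (mimic color unrelated to site) the test is therefore
*conservative* — simulations here show near-zero rejection rather than
the nominal 5 % — while syntopic and allotopic means still agree in
expectation.  This is an intrinsic property of the statistic in a
multi-model design, not an implementation artifact; it means
significant results are trustworthy but the test understates power
near the null.

## Discriminant analysis

Calibration uses model-species workers only (the defended species are
what a predator learns).  Variable selection is stepwise Wilks'-lambda
minimization on the 18 sqrt channels: at each step the candidate
giving the smallest Λ = |W|/|T| enters if its partial F,

    F = ((n − g − p)/(g − 1)) · (Λ_p / Λ_{p+1} − 1),

meets F_enter = 3.84; entered variables with F-to-remove < 2.71 then
leave.  These thresholds are the long-standing defaults of stepwise
discriminant analysis; on a one-variable two-class problem the entry F
reduces to the one-way ANOVA F (asserted in tests).  Variables whose
addition makes an SSCP singular are skipped with a warning.

Classification uses Fisher linear classification functions — the
Gaussian equal-covariance Bayes rule with class means, pooled
within-class covariance (divisor n − g) and equal priors by default
(configurable).  Ties in the argmax break by canonical class order
(scutellaris, schmidti, ionia).  Leave-one-out cross-validation holds
the selected variable set fixed and re-estimates only class statistics
per held-out worker.  Mimic workers are then classified as wild cards
against the calibration model; allocation tables report row-normalized
percentages per site and per category, with "correct" meaning the
syntopic model species.

## Synthetic data generator

The generator emulates the sampling design: 18 sites with the fixed
site→model mapping, 4 model and 5 mimic nests per site, 8 workers per
nest (≈1300 workers; the field design had 3–9 nests and ~30–50 workers
per site and genus).  Every trait is

    value = archetype + site effect + nest effect + individual effect

with independent Gaussian effects on the analysis scale; sqrt-channel
values are clamped to [0, √255] before squaring back to stored RGB
(clamping, not resampling — simple and documented boundary behavior).

Archetypes are stylized from the species' described color patterns:
*scutellaris* a reddish head (sqrt-RGB ≈ 12.2/7.7/6.3, i.e. raw
≈ 150/59/40) on a blackish body (≈ 6.7/5.9/5.5); *schmidti* reddish
head + mesosoma + petiole, blackish gaster; *ionia* uniformly dark
brownish; the mimic baseline a reddish head, intermediate mesosoma and
dark gaster.  Species CS means are 1079, 990 and 996 µm, the mimic
baseline 1030 µm.

The mimic archetype at a site is (1 − λ)·baseline + λ·(syntopic model
archetype), with λ = 0.9 by default for color (accurate mimicry) and
λ_size = 0.3 for CS (weak size mimicry).  Site effects are drawn
independently for model and mimic at the same site, so syntopic
convergence can arise only through λ — the statistic stays falsifiable
(λ = 0 is a true null, verified by a near-zero cross-genus correlation
of latent site effects).

Default variance components: σ_site = σ_nest = 0.3 and σ_ind = 0.5 on
the sqrt-channel scale (individual noise roughly ±16 raw units around
mid-range values, site/nest layers visibly smaller, matching the idea
that regional identity dominates within-population scatter); for size,
σ_site = σ_nest = 30 µm and σ_ind = 85 µm (within-nest SDs of 60–90 µm
are typical for these workers).

What the generator does **not** emulate: non-Gaussian or skewed trait
distributions beyond the sqrt back-transform, correlations between
channels within a body part beyond those induced by shared effects,
unbalanced nest/worker counts, measurement error structure of the
imaging workflow, geographic gradients within a species' range, and
predator perception.  Passing tests therefore demonstrate the
pipeline's correctness and its operating characteristics under a clean
hierarchical Gaussian world, not field-data robustness.

## Numerical conventions

* Sample (n − 1) covariance and SD everywhere.
* Covariance-matrix PCA (never correlation): all 18 channels share one
  physical scale.  Explained-variance fractions are eigenvalue shares.
* Component count k for the nest-mean reduction: smallest k with
  cumulative fraction ≥ threshold (tolerance 1e−12 against float
  round-off at the boundary).
* PC sign: mean loading positive per component.
* 95 % confidence ellipses: 2×2 score covariance scaled by the χ²(2)
  0.95 quantile (≈ 5.991); groups under three points get no ellipse.
* Seeds: a single integer seeds `numpy.random.default_rng`; identical
  configs produce byte-identical CSVs.

## Open choices made here

* The mixed model is Gaussian with identity link — the natural choice
  for continuous PC/size traits — and fitted by REML, mirroring the
  standard lmer-style workflow for nested designs.
* Nest-mean PCA pools both genera before reduction, since inter-genus
  distances are computed in the reduced space; a genus-constant offset
  (e.g. the gaster channels) largely cancels in the syntopic-vs-
  allotopic contrast, so no channel is excluded.
* PC scores enter distances unweighted (plain projections), not
  eigenvalue-rescaled.
* Stepwise selection uses F-value thresholds (3.84/2.71) rather than
  probability-of-F stepping.
* The problem sizes used in simulation-based tests (replicate counts,
  grid resolutions, reduced per-replicate designs for the type-I-error
  study) were chosen to give Monte-Carlo error comfortably inside the
  asserted bands.

## Limitations

* Wald-z contrast p-values are approximate; no Satterthwaite/
  Kenward–Roger correction is provided.
* The stepwise variable set can be unstable under resampling; the
  pipeline runs with any selected set, and the selection trace is
  always written so sensitivity can be checked.
* The paired syntopy t-test is conservative under the null when model
  archetypes are heterogeneous (see above).
* No geographic covariates: allotopic sites contribute equally
  regardless of distance.
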