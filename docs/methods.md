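# Methods notes

This note documents the models, numerical conventions and design choices
behind `langexp`, and what the synthetic-data generator does and does not
emulate.

## Lexical distance (LDND)

For strings the distance is the classic unit-cost Levenshtein edit
distance; LDN divides by the length of the longer string, so LDN ∈ [0, 1].
For two word lists, LDND is the mean same-concept LDN divided by the mean
LDN over all *ordered* cross-concept pairs (concept i in list A against
concept j in list B, i ≠ j, both concepts present in both lists).  The
denominator estimates the chance-resemblance level of the two phoneme
inventories; identical lexicons give 0, unrelated ones cluster near 1, and
the raw ratio can exceed 1 by chance.  Because downstream quadratic-entropy
weighting assumes d ∈ [0, 1], values are clipped at 1 for analysis while
the raw ratio is retained in outputs.

Conventions that the distance depends on, fixed here deterministically:

* **Synonyms** (several forms for one concept): the per-concept LDN is the
  mean over all cross-language form pairs.  This is symmetric in the two
  languages and has no tie-breaking; other tools may take the minimum.
  Equivalence with any particular external implementation is not claimed.
* **Missing concepts**: pairs are scored over shared concepts only, with
  the shared count reported so callers can enforce a floor (at least two
  shared concepts are required; the cross-concept mean needs one
  off-diagonal pair).
* **Orthography**: forms are assumed pre-transcribed to a
  one-character-per-segment alphabet; comparison is byte-for-byte after
  trimming and lower-casing.

## Exposure indices

Each child contributes cumulative exposure years per language, plus age.
Exposure proportions `p_i` are taken over the *sum* of exposure years —
not over age — because concurrent contexts (home + school) mean the years
need not sum to the child's age.  The English exposure proportion, by
contrast, is cumulative English years divided by age (capped at 1); the
two denominators intentionally differ.  Diversity is Shannon entropy in
bits (log base 2, `0·log 0 := 0`); Typological Diversity is Rao's
quadratic entropy over the clipped distances.  Proportions must sum to 1
within 1e−9 after normalization.

Two sample filters mirror the analysis design: the majority-English rule
(proportion ≥ 0.5 retained, closed boundary — "less than 50%" is excluded)
removes children for whom proportion-based indices are ambiguous between
mirrored ratios; the bilingual rule keeps children whose top two languages
cover ≥ 95% of exposure with English among them, attaching the L2 identity
and its clipped distance to English (monolinguals pass with L2 distance 0).

## Model ladders and Bayes factors

All rungs are OLS with intercept; categoricals are treatment-coded with
lexicographically sorted levels (first level is the reference), so designs
are deterministic.  Rank-deficient designs and missing values are hard
errors that name the offending columns or cases: an all-zero regressor is
rank deficiency, not a silent no-op.

BIC uses the Gaussian profile form `n·ln(RSS/n) + k·ln n` with
`k = slopes + intercept + 1` (error variance).  Conventions differ across
software by additive constants and by whether the variance is counted;
both cancel in the BIC *differences* that feed
`BF₁₀ = exp((BIC₀ − BIC₁)/2)`, and a test pins our ΔBIC to the statsmodels
value.  Evidence labels follow the log-Bayes-factor bands: BF 1–3
anecdotal, 3–20 positive, 20–150 strong, above 150 very strong; a BF below
1 is reported as evidence for the other model.  BFs compose exactly:
BF(m3, m0) = BF(m3, m1)·BF(m1, m0).

A numerically perfect fit (RSS at rounding level relative to the total sum
of squares) has no finite Gaussian likelihood; such fits are flagged and
`bic()` raises rather than returning −∞.

Residual normality uses the classic Kolmogorov–Smirnov test on residuals
standardized by their own mean and SD.  Without the Lilliefors correction
this is *conservative* (p-values skew high when the null holds); it is the
procedure as specified, and the caveat matters only if one wanted exact
nominal levels.  Outliers are defined once on the full score vector as
|z| > 3 (boundary retained, no iteration).  The mean-100/SD-15 rescaling
exists purely for display and is never fitted on.

## Threshold discovery

Three probes share one question — is the exposure–vocabulary relation
linear, or is there a minimal-exposure threshold? — and one adjudicator
(BIC → BF):

* **Segmented regression**: continuous hinge `y = b₀ + b₁x + b₂(x−c)₊`,
  with the breakpoint `c` grid-searched over distinct observed x values
  after trimming 10% of cases on each side.  The searched breakpoint
  counts as one estimated parameter (k = 5 with the variance), which
  penalizes the hinge against the 3-parameter line.
* **Smooth fit**: natural cubic regression spline with 4 df (patsy `cr`
  basis) against the line, both returned as curves for plotting.
* **Two-stage clustering**: Ward hierarchical clustering on standardized
  (exposure, adjusted score) pairs, k selected by silhouette over 2–5,
  then k-means refinement seeded from the hierarchical centroids.  A best
  silhouette below 0.5 flags "no cluster structure" — homogeneous Gaussian
  clouds sit around 0.35–0.40 at k = 2, clearly separated groups above
  0.6.  The reported threshold is the exposure midpoint between adjacent
  clusters.

The original supplementary procedures behind these analyses are not
specified in the text available to us; the three probes here are generic
re-designs that preserve the inferential question, with their parameters
documented above, and no procedural identity is claimed.

## Cross-validated log model evidence

For a group GLM with design X (intercept implicit) and per-voxel data y,
subjects are split once into halves (sizes differ by at most 1; for odd n
the first part takes the extra subject).  The split is seeded by the
number of datasets by default so that every model of the same data shares
the same partition without coordination.  Training on one half under the
non-informative conjugate normal–gamma limit gives the posterior
`β | τ ~ N(β̂, (τ X'X)⁻¹)`, `τ ~ Gamma(n₁/2, RSS₁/2)` with β̂ the OLS
estimate; the held-out half then follows a multivariate t with n₁ degrees
of freedom, location X₂β̂ and scale `(RSS₁/n₁)(I + X₂(X₁'X₁)⁻¹X₂')`.  The
cvLME is the sum of the two held-out log densities.  A dense quadrature
over (slope, log precision) reproduces the closed form to better than
1e−3 on small fixtures (in practice ~1e−9); the quadrature grid must span
many nominal SDs of the slope because the small-precision region fattens
the marginal's tails at tiny fold sizes.

LBF maps are voxel-wise differences of two cvLME maps (antisymmetric by
construction).  Cluster tables take connected components of the
supra-threshold set at 26-connectivity (6 selectable), drop components
under 10 voxels, and report size, peak LBF and 0-based peak coordinates,
largest first.  The pipeline thresholds at LBF > 3 and falls back to 1.5
when nothing survives — the indices are strongly correlated, so
between-index comparisons often carry only modest evidence.  ROI percent
signal change is `100 · mean-over-ROI(contrast)/mean-over-ROI(baseline)`
per subject, a deliberate simplification of the featquery convention (no
peristimulus scaling); the typology follow-up correlates it with the
Typological Diversity index residualized on the Diversity index, partialing
out the covariates.

Evidence comparisons need residual degrees of freedom *within each half*:
with 20 subjects and the full 7-covariate session design only one residual
df remains per fold and the comparison is essentially noise (per-voxel LBF
SD around 13).  Operating-characteristic runs at n = 20 therefore use the
four behavioral covariates in the GLM family; the full covariate set is
the default for realistic sample sizes (the pipeline's generated cohorts
run near n = 100 post-filter).

## Synthetic data: what it emulates, and what it does not

* **Lexicons**: one ancestral form per concept (3–7 segments over a
  17-consonant/5-vowel alphabet), copied per language with per-character
  substitution (rate r), deletion (r/4) and insertion (r/4).  English has
  rate 0; the others span 0.15–0.95, giving clipped LDND values from ~0.2
  to ~1.  The target ordering `1 − (1−r_i)(1−r_j)` must agree with the
  realized distances at Spearman ρ ≥ 0.8 (asserted at generation).  The
  mutation model is non-linguistic: it orders distances, which is all the
  indices consume, and no phonological realism is claimed.
* **Cohorts**: ages uniform on 5.05–6.41; the number of languages per
  child follows the 1–5 breakdown 11/79/47/18/7 out of 162; English is
  always present from birth; each multilingual child's English share is
  uniform on 0.2–1.0 (so the 50% filter genuinely bites — roughly a third
  of multilinguals fall below it) with the remainder Dirichlet-split.
  Covariates: SES ~ N(17, 1.99) years of parental education, balanced
  gender, nonverbal standard score ~ N(100, 15).  For ladder experiments
  cohorts of 220 children leave ≈144 analyzed cases after filtering,
  matching the analysis-scale the ladders were designed around.
* **Outcomes**: linear in one chosen index plus covariate effects and
  Gaussian noise (SD 15 on a standard-score-like scale).  The index slope
  is calibrated against the cohort's realized covariate-residualized index
  variance so a requested Cohen's f² (defaults 0.10 for exposure, 0.06 for
  the entropy indices — the published small-effect band) is attained in
  expectation; signs follow the observed directions (positive for
  exposure, negative for the diversity indices).  The bilingual generator
  produces main effects of exposure (medium, f² ≈ 0.16) and L2 distance
  (small, ≈ 0.03), with the interaction coefficient zero unless requested.
* **Volumes**: 16×16×8 grids with a 30-voxel box ROI.  ROI voxels carry
  `β · z` per subject, where z is the Typological Diversity index
  residualized on the covariates and standardized; elsewhere pure
  N(0, noise²).  Residualizing on the covariates keeps the signal inside
  the span of the GLM that carries the index, so that model can explain
  its own activation while the Diversity model cannot.  Defaults β = 2.5,
  noise 1.  Session covariates are generated as a continuous handedness
  laterality quotient, continuous d′, and a balanced two-level headphone
  factor — a rare categorical level would be constant within a half-split
  at these sample sizes and make the fold design singular.
* **Randomness**: one seed per generator call, fanned out through spawned
  `SeedSequence` streams (one per generator stage), so fixed seeds give
  byte-identical artifacts.

What passing tests on these data do **not** show: robustness to realistic
fMRI noise (autocorrelation, drift, motion residuals — the volumes are
white noise plus signal), to exposure measurement error in the
questionnaire-derived years, to non-Gaussian outcome noise, or to lexicons
whose distances violate the simple divergence ordering (borrowing,
dialect continua).  First-level fMRI modelling is entirely out of scope;
the generator produces the per-subject contrast summaries that a
first-level analysis would deliver.

## Operating characteristics (as measured by `scripts/acceptance.py`)

At the default study conditions: the ladder recovers the generating index
as the top Bayes factor in a plurality of 200 cohorts per regime (rates
≈ 0.58–0.71 against two highly correlated competitors); under the null the
best index clears BF > 3 in < 4% of cohorts; an absent interaction is
rejected (BF(m3 vs m2) < 1) in ≈ 97% of bilingual cohorts; purely linear
exposure–score cohorts are called linear in ≈ 99% of seeds while a planted
hinge at 0.6 is relocated within ±0.05 in ≈ 93%; and the ROI planted in
the volume fixtures is recovered (peak inside the ROI) in ≈ 94% of 50
seeds.  These figures are recomputed, not asserted, on every acceptance
run; seeds shift them by a few points.

## Known limitations

* The LDND synonym/rounding conventions of external lexicostatistical
  tools are not replicated exactly; only the documented convention is.
* BIC-based Bayes factors inherit the unit-information-prior
  approximation; they are not bridge-sampled marginal likelihoods.
* The KS normality check is conservative (no Lilliefors correction).
* The two-stage clustering silhouette cut-off (0.5) is a convention; near
  the boundary the "structure" flag is unstable.
* cvLME fold accumulation uses exactly two folds with posterior-as-prior
  in closed form; toolbox implementations may differ in prior limits and
  fold bookkeeping, and bit-identity with any of them is not claimed.
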