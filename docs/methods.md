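# Methods

This note records the models, numerical choices and known limitations
of the package; nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## The synthetic cohort generator

The generator is the package's stand-in for the unavailable development
cohort; it emulates the statistical structure the downstream analysis
assumes, with ground truth retained so every stage can be checked for
parameter recovery.

**Latent traits.**  Each dog carries seven latent behavioural traits on
a standard-normal scale at each of the three assessment ages (5, 8 and
12 months).  The full 21-dimensional latent correlation matrix is built
from (a) a signed 7×7 inter-trait correlation matrix and (b) a per-trait
3×3 age-stability block, with cross-trait cross-age entries
`corr(i,j)·sqrt(S_i[a,b]·S_j[a,b])`.  The matrix is verified positive
semi-definite at configuration time; eigenvalues in (−10⁻⁶, 0) are
clipped and the matrix rescaled to unit diagonal, anything more negative
is a hard error.  Per-trait age blocks are solved *exactly* from three
pairwise targets rather than an AR(1) recursion, because the published
5–12-month stabilities are not the product of the adjacent pairs.

**Stability calibration.**  The configured stability targets are
*observed* scale-score Spearman correlations (defaults: the published
per-scale values, with pair means 0.58 / 0.63 / 0.48 for 5–8 / 8–12 /
5–12 months).  The generator converts each target to a latent Pearson
correlation by (i) the bivariate-normal conversion r = 2·sin(πρ/6) and
(ii) division by the squared analytic attenuation of a k-item mean
score, a = m/√(m² + σ²/k) with m the mean absolute loading and σ the
item noise SD.  Clipping to [0, 100] and rounding to integer mm cause a
further ~1% attenuation that is absorbed by the ±0.05 acceptance band.

**Items.**  The 39-item catalogue mirrors the questionnaire: 35 items
across seven scales (six Trainability items and one Excitability item
reverse-keyed, generated with *negative* loadings so the reverse-key
detector has real work to do) plus four unscored miscellaneous items
with weak (sub-salience) loadings.  Loading magnitudes are solved from
per-scale target alphas via r = α/(k−(k−1)α), c = √r,
λ = σ·c/√(1−c²), with a ±10% deterministic per-item jitter.  The
targets follow the published mean reliabilities with one deliberate
idealisation: Body Sensitivity is generated at α = 0.75 rather than its
reported 0.58, because a faithfully unreliable Body Sensitivity would
be rejected by the > 0.70 acceptance floor and the seven-trait
structure would be unrecoverable by design.  Passing recovery tests
therefore show that the pipeline finds reliable structure where it
exists — not that every real scale was this reliable.

**Inter-trait correlations.**  The a-priori construct predictions are
encoded as a signed matrix with |r| between 0.30 and 0.55.  Magnitudes
were chosen so that the seven-trait structure is separable by PCA (as
it evidently was in the real data, where the five smaller scales
emerged as distinct components at every age); couplings involving the
two-item scales are kept weakest because strong coupling chains their
items into neighbouring components.  A consequence worth knowing:
after item-noise attenuation, most *observed* inter-scale correlations
sit below the 0.40 construct-validity criterion, so the default
generator yields a conservative construct-validity verdict sheet.  The
verdict machinery itself is tested with explicitly strengthened pairs.

**Outcomes.**  Non-behavioural outcomes (health withdrawal, breeding,
transfer, death) are assigned independently of the latents at the
published base rates; remaining dogs are withdrawn for behaviour with
probability logistic(β₀ + Σβᵗ·Tᵗ(12M)), else qualify.  Coefficient
signs follow the published odds directions (anxiety-type traits
increase withdrawal odds, Trainability and Adaptability decrease
them).  The intercept is solved by Gauss–Hermite quadrature so that the
marginal withdrawal probability among behaviour-decided dogs equals the
configured 32% (384/1,200).

**Attrition and missingness.**  Dropout is monotone (absent at 8M ⇒
absent at 12M) with default rates matching the published per-age sample
sizes (1,401 → 1,288 → 1,239).  "Not Known" responses are missing
completely at random at rate 0.02; no informative-missingness mechanism
is modelled because none is described for the real data.  Attrition is
independent of the latents — real attrition is partly outcome-driven,
which the generator does not emulate.

**Behaviour-test measures.**  A configurable subsample (default 93
dogs at 5M and 8M) receives coded test measures: ordinal obedience
response codes (1–5, higher = slower, driven negatively by
Trainability), head-ring tail/ear/posture codes (driven by Body
Sensitivity, emitted as the published numeric codes), log-normal
distraction durations (Distractibility), Poisson event counts (jumps
and barks from Excitability, whines from General Anxiety, scratches
from Adaptability) and a binary low-greeting-posture indicator (General
Anxiety).  A single association-strength parameter scales all latent
effects; zero gives exact nulls.  The scratch count is generated with a
*positive* Adaptability link while the default hypothesis sheet
predicts a negative one, deliberately reproducing a
significant-but-opposite-direction finding so that the anomaly-flagging
path is exercised.

## Scale construction

**PCA grouping.**  Pearson-correlation PCA on listwise-complete dogs;
components with eigenvalue > 1 retained; varimax rotation by classic
pairwise planar rotations with Kaiser normalisation (tolerance 10⁻⁶ on
the rotation angle, 100 sweeps; cross-checked in the tests against R's
`stats::varimax`, which stops earlier on a flat criterion — hence
agreement is asserted on the criterion value and the salience grouping,
not element-wise).  Component signs are fixed so the largest-|loading|
item is positive.  An item joins the component where its |loading| is
largest provided that loading reaches 0.40; an item salient on several
components is thereby removed from all but its strongest.

**Cross-age stability.**  A grouping is stable when its items co-load
together in at least two of the three per-age solutions.  This is
implemented at the item-pair level (two items co-load if they share a
component at ≥ 2 ages; connected components of that relation are the
stable groupings) rather than by exact item-set equality, which would
let a single item drifting at one age destroy the stability of a
13-item grouping.

**Alpha refinement.**  Items outside any stable grouping are pooled,
oriented to a common direction by the sign of their first-PC loading,
and refined greedily: remove the single item whose removal most
improves alpha while the improvement exceeds the 0.05 gain threshold.
The threshold is configurable because 0.05 is an unusually large gain
for a k-item pool (0.005 would be conventional); with the default, the
procedure mainly strips strongly discordant items.  Survivors form a
candidate grouping only if their reference-age alpha clears the same
0.70 floor used for acceptance — without this quality gate the
procedure would emit arbitrary unreliable leftovers (e.g. a 2-item pool
with α = 0.1).  Removed items are re-pooled and the procedure repeats.

**Reverse-key detection.**  The criterion — an item is reverse-keyed
iff it correlates negatively with the mean of the remaining items — is
applied as a fixed-point iteration over direction-corrected rest-means,
initialised from first-PC loading signs, with the overall orientation
chosen so at most half the items are flipped.  The one-shot version of
the rule is ill-posed for nearly balanced keying (with 6 of 13 items
reversed, the raw rest-mean carries almost no net trait signal).  A
correlation of exactly zero keeps "+": reversal must be evidenced.

**Scoring.**  Scale score = mean over answered items of (x, or 100 − x
for reverse-keyed items); the score is missing when fewer than half the
scale's items were answered.  The half rule is this package's choice —
no missing-item rule is published.  Alpha and PCA use listwise-complete
rows throughout, the simplest defensible treatment.

**Item screen.**  Univariate binary logistic regression of outcome on
item value per age (statsmodels MLE); an item survives if p < 0.05 at
any age.  Perfect separation is recorded as "separated" and counts as
significant; a zero-variance item has no p and is removed.

## Standardisation and flags

Sample (n−1) SDs are used in z-scores, matching the default of
mainstream statistics tooling; population SD is a configuration switch.
Breed × sex cells with fewer than 10 dogs fall back to breed, then to
whole-sample statistics; an unseen breed at apply time falls back to
whole-sample with a warning.  Reference statistics are never refitted
at apply time (a rolling-reference mode can be had by simply refitting,
but thresholds are defined against the stored references).

The pure-zone cut-off is the z of the most extreme opposite-outcome dog
in the target tail, so the zone strictly beyond it is 100% correct on
the development sample; a zone supported by fewer than `min_support`
(default 5) target dogs is rejected as an outlier artefact — this is
the package's deterministic operationalisation of the original visual
inspection of probability plots.  The tail direction per scale × age
comes from the sign of the univariate logistic slope.  The yellow
cut-off is the 50% crossing −β₀/β₁ of that logistic fit, declared
unassignable when the slope is non-significant (p ≥ 0.05), the
crossing falls outside the observed z range, or the fit separates.
Yellow flags use the red flag's selected z-scheme, falling back to the
green flag's scheme when red is unassignable.  Scheme selection
maximises pure-zone support with ties broken whole > breed >
breed × sex.  Flag metrics deliberately follow the development study's
swapped PPV/sensitivity definitions, with conventionally defined values
emitted alongside under explicit names.

Time savings assume a red-flagged, later-withdrawn dog would have left
the programme on the questionnaire date (taken as birth + 152/243/365
days for the three ages); weeks before training entry count as
puppy-walking savings and weeks after as formal-training savings, each
floored at zero.

## Validity suite

Spearman correlations use average ranks on ties (scipy).  Temporal
consistency requires ≥ 10 dogs with both ages and reports NA for
constant scores.  Construct validity uses 12-month scores only, to
avoid pseudo-replication.  Predictive regressions code breed as a
categorical factor with the most frequent breed as reference (the
original coding is unstated) and report the covariates' joint Wald
p-values.  Mann-Whitney tests are exact for total n ≤ 20, otherwise
normal-approximated with tie correction; all tests are two-sided; no
multiple-testing adjustment is applied anywhere (matching the original
analysis), and result tables carry the number of tests run.  The KMO
statistic is computed from the anti-image partial-correlation matrix
via pseudo-inverse; variable sets with KMO ≤ 0.6 (or a singular
correlation matrix) are returned unreduced and analysed measure by
measure.

## Problem sizes and determinism

Test and acceptance runs use cohorts of 400–1,200 dogs: structure
recovery uses ten seeds at n = 592 (the size of the original
scale-formation subsample), calibration checks use n = 1,200 (≈ the
12-month evaluation sample), and null-calibration checks use 1,000
univariate replicates at n = 800.  All randomness flows through
`numpy.random.default_rng` seeds carried in the configuration objects;
a fixed seed reproduces every table byte-for-byte.

## Known limitations

* No kennel, litter, sire/dam or supervisor clustering — the analyses
  the package implements do not model them either.
* The generator's breed and sex effects are small additive item shifts;
  real breed differences in trait *variance* are not modelled, so the
  breed and breed × sex z-schemes differ from the whole-sample scheme
  less than they might in real data.
* Multivariate (stepwise) combination of scales is out of scope: the
  original attempt found no additive model, and the flag system treats
  each scale × age as a separate predictor.
* Cut-offs are point estimates; no cross-validation or uncertainty is
  attached to them (the unbalanced cohort was judged too small to
  partition, and the package follows that design).
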