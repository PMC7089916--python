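# Methods

`assocpat` quantifies the predictability of association patterns in
group-living animals observed by focal-follow scan sampling, on two levels:
the whole subgroup (composition entropy against a constrained permutation
null) and the dyad (simple ratio indices, permutation significance, and
assortativity regressions with information-theoretic multimodel inference).
This note records the models, the parameters that matter, the numerical
choices, and what the synthetic generator does and does not emulate.

## Data model

A season's data are an ordered sequence of scans over a fixed roster; each
scan records a focal individual and the set of roster members in visual
contact with it (the focal's *subgroup* or *party*). Internally a season is
a boolean presence matrix (scans × members), which every downstream
statistic consumes directly. Rosters include only individuals above 3 years
at the season's October start and present for the whole season; adulthood
is reached above 5 years for females and above 7 for males. A scan whose
focal is not marked present is repaired, not rejected: the subgroup is
defined around the focal.

## Constrained permutation null

Observed scan streams are not exchangeable rows: focal follows fix who is
being sampled, subgroup size varies with habitat and activity, individuals
differ in gregariousness, and consecutive scans within a follow are
autocorrelated. The null model therefore randomizes group membership while
preserving, per realization:

1. the per-scan subgroup size;
2. the focal's identity and membership in every scan;
3. each individual's occurrence likelihood — non-focal slots are drawn
   without replacement with probability proportional to the member's
   observed occurrence frequency;
4. runs: maximal blocks of consecutive scans that are identical (same
   composition *and* same focal) in the observed data are redrawn once and
   copied across the block.

Weighted sampling without replacement is specified as successive draws with
renormalization; the implementation uses Gumbel-key ranking
(Efraimidis–Spirakis), which yields exactly the same distribution and
vectorizes across all runs of a realization. Two adjacent observed runs can
by chance be redrawn to the same composition; the constraint set governs
observed runs only, so the validator compares run structure at observed
boundaries (each observed run internally constant, no new boundaries
inside one).

Occurrence weights are the raw observed frequencies, including scans where
the candidate was itself focal. Because only relative weights matter within
a draw, the meaningful alternative reading — rating each candidate by its
occurrence in scans where it was *not* focal — is available as
`weight_mode="exclude_focal_scans"`. With sampling without replacement the
realized occurrence frequencies are mildly compressed toward the mean
relative to the weights (a well-known property of successive sampling);
preservation is monotone and close, not exact, and is tested as such.

Per-realization seeds are spawned from the master seed with
`numpy.random.SeedSequence`, so ensembles are bit-reproducible regardless of
worker count, and any single realization can be regenerated on demand. An
ensemble stores O(dyads) sufficient statistics per realization (entropy,
per-dyad SRI, occurrence frequencies) plus the pooled composition multiset,
never B full datasets.

## Composition entropy

The composition of a scan is one categorical outcome — the exact member
set. Observed entropy is Shannon entropy of the empirical composition
distribution in bits (base 2 throughout; configurable). Expected entropy is
the mean of per-realization entropies over the ensemble, not the entropy of
the pooled distribution — pooling mixes B samples and is biased upward by
concavity; the pooled distribution is used only where a single null
reference distribution is required (KL/JS). The comparative statistic is
the **entropy ratio** (observed / expected): 1 indicates compositions as
random as the constraint set allows.

KL divergence needs the null's probability on every observed composition;
compositions observed but never permuted get a smoothing floor, by default
`1/(B·n_scans)` (the resolution of the pooled sample), after which the null
vector is renormalized. Jensen–Shannon distance needs no smoothing. The
`bias_experiment` grid shows why the ratio is the cross-dataset measure of
choice: under random association KL and JS drift strongly with group size
and scan count (support overlap between observed and null collapses as the
composition space explodes), while the ratio stays flat to within
Monte-Carlo error.

## Dyadic association

SRI = P_AB / (P_A + P_B + P_AB) with P_A, P_B the counts of scans containing
exactly one member of the dyad — the standard simple-ratio definition, which
spans [0, 1]. A literal variant in which P_A and P_B include joint sightings
(bounding the index below 1) exists behind `literal=True` for comparison;
it is never used in the pipeline. A dyad never sighted at all scores 0.

PAV (pairwise affinity value) is observed SRI minus the ensemble-mean SRI,
in [−1, 1]; positive means more association than expected. Significance is
a strict permutation rank: the dyad is a *significant associate* when its
observed SRI strictly exceeds more than (1 − α)·B permuted values (for
B = 1000, α = 0.05: higher than 950 of 1000). Ties count against
significance, a deliberately conservative choice. Precision comes from a
scan bootstrap: scans resampled with replacement R times, SRI recomputed
per replicate, per-dyad sample SD reported.

## Assortativity and multimodel inference

Dominance ranks come from non-aggressive feeding supplants via standard
sequential Elo (logistic expectation on the base-10/400 scale; k = 16 and
initial score 1000 by default, both configurable). Since ranks enter the
models only through daily *standardized ordinal ranks* — ordinal position
mapped linearly to [0, 1], top rank 1, ties sharing the mean position —
cardinal detail of the rating variant is discarded anyway, which is why a
likelihood-optimized Elo was not implemented. Yearly rank is the mean of
daily values; the dyadic covariate is the absolute yearly rank difference,
z-standardized across the pooled table for fitting (raw values retained).

Each dyad contributes one row per season both members were present, with
responses (significant-associate flag; PAV) and covariates: binary maternal
kinship (mother–offspring or maternal siblings), sex combination
(reference female_female), age combination (reference adult_adult), infant
combination (reference no_no), and rank difference. The full model adds
sex × rank-difference and sex × age interactions.

The candidate set is every predictor subset of the full model honoring
marginality (interaction ⇒ both parents), 52 models for this full model,
enumeration brute-force-verified. Each submodel's AICc
(−2 logL + 2k + 2k(k+1)/(n−k−1), n = dyad-year rows, k counting the
residual variance for gaussian fits) yields Akaike weights, the 95%
best-model confidence set (smallest weight-sorted prefix reaching 0.95),
and per-predictor summed weights. The *expected* weight of a predictor is
defined here as the share of candidate models containing it — the summed
weight if all models performed equally. Other definitions exist in the
literature (e.g. conditioning on the confidence set); the definition is
pluggable, and published expected-weight values computed under a different
convention will not match this one. Summed weights are interpreted only
when the intercept-only model falls outside the confidence set (flagged).

**Estimation.** Fitting is delegated to statsmodels. The default engine is
a fixed-effects GLM: it is the exact likelihood when random-effect variance
is zero (as in the synthetic fixtures, where rows are generated
independently) and keeps the 52-submodel × n-selection loops tractable. A
gaussian mixed engine adds variance components for both individual
identities, the dyad and the season via `MixedLM` (ML, not REML, so
log-likelihoods are comparable across fixed-effects structures); random
slopes are not fitted by default. No maximum-likelihood binomial GLMM is
available in the stack, so the binomial family always uses the
fixed-effects engine. Non-convergent fits are dropped from weight
normalization with a logged count.

**Dyad-flip resampling.** Assigning an unordered dyad's members to the
individual-1/individual-2 slots is arbitrary but not inert once the slots
enter a model; each of `n_selections` selections randomly re-orients every
dyad, refits the full model and (by default) reruns the whole all-subsets
inference; reported estimates and summed weights are means over converged
selections. Under the fixed-effects engine the flip is a no-op by symmetry
of the dyadic covariates — the machinery still executes so that
orientation-sensitive engines plug in unchanged, and this invariance is
itself a test.

**Diagnostics.** Collinearity is screened with generalized VIFs
(det-of-correlation-submatrix form; equals 1/(1−R²) for single-column
terms), computed on the fixed-effects design without interactions. R² for
mixed fits follows Nakagawa: marginal = var(fixed linear predictor) over
total, conditional adds the summed variance components, with π²/3 as the
logit-scale residual variance for binomial fits. Influence is checked by
removing one level of a random-effect factor (individual or season) at a
time and recording coefficient shifts.

## Synthetic generator

The study system is observational; the generator is the package's own
artifact, built so its *outputs* have the structure the analysis must cope
with, with full ground truth exported for recovery tests. Defaults describe
one field season: 30 individuals (55% female, 8 matrilines, 30% subadult,
30% of adult females with a newborn), 5000 scans in focal-follow blocks of
four 15-minute scans, subgroup sizes 1 + negative binomial (mean 5,
shape 10) truncated at 17 (mean ≈ 6, max 17), per-individual
log-gregariousness N(0, 0.3²), and a 0.1 probability that a within-follow
scan repeats the previous composition exactly. Non-focal slots are filled
sequentially with log-weight = gregariousness + mean latent affinity to the
already-selected members (the mean, so early picks do not dominate);
affinity is a symmetric log-weight matrix assembled from configurable kin,
rank-similarity, subadult-same-sex, adult-mixed-sex and both-infants
effects.

What the generator does *not* emulate: spatial structure and movement,
demographic turnover within a season, observation error in identification,
day/night structure of sampling, and any dependence of subgroup size on the
focal's identity. Passing calibration tests on synthetic data therefore
demonstrates internal consistency of the statistics under the stated
sampling structure — not that real field data meet those assumptions.

Row-level fixtures for the regression machinery come from
`simulate_dyad_rows`, which draws covariates and responses directly from
the logistic/gaussian model with zero random-effect variance, so the
fixed-effects engine is the exactly-correct estimator and recovery bounds
are meaningful.

## Numerical and scale choices

- Bits (log base 2) everywhere; a 4615-scan season bounds entropy at
  log2(4615) ≈ 12.17 bits.
- Entropy ratio conventions: 0/0 → 1; positive observed with zero expected
  entropy is an error.
- KL smoothing floor 1/(B·n_scans), configurable; ε = 0 requires nested
  support.
- Significance uses strict inequality; B = 1000 and α = 0.05 reproduce the
  "higher than 950 of 1000" rule.
- Compositions are hashed as packed 64-bit words (rosters ≤ 64 members;
  larger rosters fall back to byte tuples).
- Desk-scale problem sizes used by the test suite and the acceptance
  script: calibration at n = 30 individuals × 2000 scans with B = 100–200
  over 20 replicates; bias grid {10, 20, 40} × {500, 2000, 5000} scans with
  3 replicates × B = 50; the acceptance study runs three 5000-scan seasons
  with B = 1000, R = 1000 bootstrap replicates and 20 dyad-flip selections
  with full subset refits.

## Known limitations

- The permutation null conditions on observed occurrence frequencies
  estimated from the same data; for very small scan counts this makes the
  null slightly conservative.
- Occurrence-frequency preservation is approximate (compression toward the
  mean) whenever subgroup sizes are a large fraction of the roster.
- Binomial models are fixed-effects only; variance explained by individual
  or dyad identity in the binary response is folded into the residual.
- The mixed gaussian engine fits variance components without random slopes
  and may sit on the boundary (zero variance) for synthetic data, which is
  expected and harmless for the reported fixed effects.
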