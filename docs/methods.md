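# Methods

## The titration model

Each discounting block pits a fixed $2.00 reward for a hard-SNR sentence
against a titrated reward for the same task at the +20 dB reference. The
easy offer starts at $1.00; after a "harder" choice it rises by the current
step, after an "easier" choice it falls; the step halves each trial,
starting at $0.50 (half the initial $1 gap). Six trials therefore implement
a standard binary search on (0, 2) with terminal resolution $0.03125
(= 1/32 dollar). The step sequence is not stated numerically in the
paradigm's published description beyond the halving rule; $0.50 is the
unique choice that makes the search span the full reward interval while
keeping every reachable offer strictly inside it, and it reproduces the
canonical offer path $1.00 → $1.50 → $1.75 → … → $1.96875.

Offers are stored as integer counts of grid units (`gap/32` dollars), so
the halving recursion is exact; the unit is a negative power of two for the
default bounds, so the dollar views are also exact in binary floating
point, and CSV serialization with five fractional digits is lossless.

The block estimator is the *lowest selection*: the minimum chosen amount
over the six trials ($2.00 when no easy offer was accepted). For a
noiseless threshold decision-maker an exhaustive sweep shows the estimator
lands within $0.0625 (one terminal step plus resolution) of the true
indifference point for thresholds in (0.05, 1.95); the test suite verifies
this on a $0.01 grid.

Degenerate configurations are rejected at initialization: the easy starting
offer must be positive, strictly below the hard reward, and large enough
that the all-easier path cannot cross $0.

## Scheduling

The discounting phase comprises 20 six-trial blocks, four per hard SNR
(+4, 0, −4, −8, −12 dB). Block order and the assignment of the 20 matched
sentence lists to blocks are independent seeded permutations, so each seed
yields a unique order/combination and every list is used once. The
familiarization phase has 80 trials: four cycles over the five hard SNRs in
easiest-to-hardest order, four trials per condition block, two targets and
two fillers each, strictly alternating with a seeded coin flip deciding
which kind leads a block (the original procedure does not specify
within-block order). Of the 160-target sentence pool, a seeded shuffle
reserves 40 for familiarization; the other 120 are partitioned into the
discounting lists.

List matching minimizes the spread (max − min) of list-mean prior
intelligibility scores via a serpentine greedy seeding followed by
pairwise-swap descent (variance of list means as tie-break, so the descent
terminates). This replaces the external "Match" program with a documented
objective; the result is locally optimal under single swaps, and on small
instances it attains the brute-force optimum.

## Synthetic listeners

**Decision model.** Agent *i* holds one latent indifference point
v_i(s) ∈ [0, 2] per hard SNR s. Choice probability of "easier" at offer x
is logistic((x − v_i(s))/τ) with temperature τ (τ = 0 is a threshold agent;
ties at x = v go to "easier", a documented convention — latent ties are
unobservable in humans).

**Generative links.** v_i(s) = b_g(s) + β_PTA,g·(PTA_i − c_g) +
β_WM,g·(WM_i − w_g) + u_i + ε_is, clamped to [0, 2], with group baselines

| SNR (dB) | young | older |
|---|---|---|
| +4 | 1.90 | 1.80 |
| 0 | 1.85 | 1.70 |
| −4 | 1.70 | 1.45 |
| −8 | 1.45 | 0.95 |
| −12 | 1.25 | 0.75 |

subject noise u_i ~ N(0, 0.10²), condition noise ε ~ N(0, 0.15²), τ = 0.15.
Exact human coefficients and curve levels are not reproducible without a
human dataset, so these values were chosen once to encode the paradigm's
reported qualitative structure: a ≈$0.5 older–young gap at
−8/−12 dB, and within the older group β_PTA = −0.011 $/dB and β_WM =
0.83 $/unit, which with the simulated covariate spreads put the PTA–AUC and
WM–AUC correlations near −0.5 and +0.55. Young-group coefficients are 0,
mirroring the null relationships reported for normal-hearing young adults
(their restricted covariate range). An optional `performance_sensitivity`
parameter couples listening ability into the indifference points (default
0; no published value anchors it). A `monotone` flag enforces
non-increasing indifference with difficulty via a running minimum
(default off, so condition noise is unbiased).

**Covariates.** Ages are truncated normals matching the study groups
(young 19.9 ± 1.5 in 18–24; older 70.9 ± 3.6 in 65–79). Audiograms combine
a group median audiogram (presbycusis-sloped for older adults), a subject
shift, and per-ear/frequency noise, rounded to 5 dB steps; PTA is the
500/1000/2000 Hz mean per ear and analyses use the better (lower) ear.
Working memory is a recall proportion (young 0.55 ± 0.08, older
0.42 ± 0.12, clamped to [0, 1]). Hearing handicap (older only, 0–40 in
steps of 2) loads 0.75 on the standardized PTA, giving an HHIE–AUC
correlation of roughly −0.4 through the shared hearing factor. Income band
(1–8) is generated but linked to nothing, reflecting the null
socioeconomic result; motivation ratings (1–7) differ by group in the
reported directions but do not enter the decision model.

**Performance model.** Keyword recognition (4 keywords/sentence, Bernoulli
per keyword) is calibrated to the published group intelligibility norms
(mean and SD of proportion correct per SNR for both groups). A
two-parameter logistic psychometric function fitted by least squares
supplies recognition at arbitrary SNRs (e.g., the +20 dB reference, where
both groups are near ceiling). At the five calibrated SNRs the logistic
alone cannot match the norms — the young means are non-monotone near
ceiling and the older profile is steeper than logistic — so each agent's
keyword probability there is drawn as clip(μ*(s) + σ_b(s)·z_i, 0, 1),
where z_i ~ N(0,1) is a subject ability factor (loading −0.5 on
standardized PTA), σ_b(s) is the published SD with the binomial
measurement component removed (32 scored keywords per SNR), and the latent
location μ*(s) is solved numerically so the *clamped* mean equals the
published mean exactly. Group means of a 50-subject cohort then match the
norms within sampling error (≈ SD/√50), which the acceptance suite checks
at the 2-SE level.

What the simulator does **not** emulate: trial-order fatigue, learning or
strategy shifts across blocks, feedback-driven choice adjustment, social
incentives, and keyword-level dependence within a sentence. Passing tests
therefore demonstrate that the machinery recovers known structure under
the stated generative model, not that human data will show these effect
sizes.

## Analysis pipeline

- **AUC.** Sum of the five per-SNR mean lowest selections divided by the
  $10 maximum; algebraically identical to (mean of means)/2. Values
  outside [0, 1] are rejected as input errors.
- **Group curves.** Means of subject-level condition means with t-based
  95% CIs over subjects (the CI construction is a package choice; a
  bootstrap can be layered on the same summaries). Single-subject groups
  are flagged rather than given degenerate intervals.
- **Group contrasts.** Two-sided Wilcoxon rank-sum on subject-level
  condition means at −8 and −12 dB. When C(n₁+n₂, n₁) ≤ 50,000 the exact
  permutation distribution of the mid-rank sum is enumerated (exact even
  under ties); otherwise the normal approximation with tie and continuity
  corrections is used. Two-sided p is twice the smaller tail, capped at 1.
  Subject-level means (not block values) are the contrast unit.
- **Correlation battery.** Five planned Pearson tests — AUC × WM (both
  groups), AUC × better-ear PTA (both groups), AUC × HHIE (older) — at the
  Bonferroni-corrected per-test threshold 0.05/5 = 0.01. Zero-variance
  covariates yield a flagged undefined correlation.
- **Mixed model.** Block-level lowest selection with subject random
  intercepts. Fixed effects: categorical SNR treatment-coded against the
  +4 dB reference (the reporting convention for per-level contrasts),
  age group (young reference), intelligibility, SNR × age,
  SNR × intelligibility, age × intelligibility, working memory, better-ear
  PTA. Intelligibility enters as the per-subject-per-SNR proportion of
  keywords correct on familiarization target trials, z-standardized (its
  scaling is a package convention). Terms are assessed by sequential
  likelihood-ratio tests on maximum-likelihood fits; coefficients and SEs
  come from the REML fit. Rank-deficient designs are rejected with the
  aliased columns named.

### Numerical notes

For a Gaussian random-intercept model the ML problem reduces, after
profiling out the fixed effects and residual variance in closed form
(Woodbury identity per subject), to a one-dimensional concave search over
log(τ²/σ²). `random_intercept_ml` implements this profile exactly;
generic gradient-based optimizers can stop short of the optimum on these
likelihood surfaces, which systematically deflates likelihood-ratio
statistics, so all LR tests and the null-calibration simulation use the
profiled fit (cross-checked against statsmodels to ~1e-6 when the latter
converges). The REML coefficient table uses statsmodels `MixedLM` with the
Powell optimizer for the same reason. The LR statistic is floored at 0 and
referred to χ² with df = the number of added fixed-effect columns.

## Problem sizes used by the test and acceptance suites

Structural and titration checks are exhaustive (all 2⁶ choice paths, full
$0.01 threshold sweeps). Calibration is checked on the study-sized 50 + 50
cohort. The likelihood-ratio null calibration uses 2,000 replicates of a
24-subject × 8-observation design; end-to-end age-difference recovery uses
100 seeds with 25 subjects per group, a deliberately scaled-down cohort
that still gives the Wilcoxon contrast near-unit power under the default
generative effect sizes.

## Known limitations

- The swap-descent list matcher guarantees local, not global, optimality.
- The exact rank-sum path enumerates combinations; above the enumeration
  limit inference switches to the tie-corrected normal approximation.
- The mixed model supports a single random intercept per subject (the
  design of record); random slopes are out of scope.
- Generative effect sizes are package conventions encoding reported
  directions, not fitted to any human dataset; absolute coefficient values
  from human studies should not be compared against simulator output.
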