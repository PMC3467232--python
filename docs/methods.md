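# Methods notes

This note records the modeling assumptions, parameter choices, numerical
conventions and known limitations behind `srtlearn`. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Task model

The task is a bimanual SRT paradigm: eight cues map onto the eight
non-thumb fingers (1 = left pinky … 4 = left index, 5 = right index … 8 =
right pinky). Sequence blocks cycle the fixed 32-item sequence
6-8-5-6-3-5-4-1-3-6-8-4-1-2-7-3-1-8-2-7-5-2-4-5-7-3-1-6-8-2-4-7 eight
times (256 trials), starting at a uniformly random offset; the sequence is
cycled circularly and never re-ordered. Each key appears exactly 4 times
per cycle. Random blocks use a pseudo-random cue order with immediate
repeats removed (next cue drawn uniformly from the other seven keys).
A day holds nine 256-trial blocks: two Random training blocks, five
adaptive Sequence blocks (response window = previous block's RT mean + SD,
reset to 600 ms when that value is below 200 ms or the previous block's
accuracy below 75%), then a Random probe and a Sequence probe at the fixed
600 ms window. All analyses consume only the two probes.

The published 32-item sequence does contain repeated trigrams (e.g. 7-3-1
twice), so its "no triplet structure" property evidently refers to
relational runs/trills rather than literal trigram uniqueness; the
generator ships the printed sequence verbatim and makes no attempt to
regenerate constrained sequences.

The daily awareness questionnaire is scored 0–3 (0 noticed nothing; 1
noticed something but did not name a pattern; 2 named the pattern with the
keywords *pattern/sequence/sequential/order/ordering* but thought it always
present; 3 knew it was occasional and reproduced ≥ 4 consecutive items);
2 marks the implicit-to-explicit transition. Scoring is provided as a pure
function; the generator does not simulate awareness.

## Synthetic cohort generator

No public dataset with this design exists, so the generator is a
first-class component: it produces trial tables with exactly the
statistical structure each analysis stage assumes, which is what makes the
estimator-calibration tests meaningful.

Per subject, the latent response plan in a block is

    plan_t = mean_t + AR1_t + PES_t,   mean_t = base − slope·day·[sequence] + key_bias[cue_t]

- **AR(1) binding**: `AR1_t = α_day · AR1_{t−1} + N(0, σ_P²)`, stationary
  initialization; α_day follows a per-subject sigmoid rising from ≈ 0 to
  an asymptote (default cohort ≈ 0.85) around day 3–4, i.e. binding
  saturates at the end of week one. α = 0 in Random blocks.
- **Post-error slowing**: each error adds a geometrically decaying delay
  (halving per lag, truncated at 4 lags) to the next trials' plans, in
  Sequence blocks only; its lag-1 magnitude grows across days in
  proportion to the binding schedule toward ≈ 15 ms. Random blocks get no
  injected PES, matching the empirical pattern that post-error slowing is
  a Sequence-probe phenomenon.
- **Errors** are cue-independent Bernoulli draws whose daily rate follows
  1 − accuracy, with accuracy rising quadratically from ≈ 76% to a ≈ 94%
  plateau reached at day ~5–7 and constant afterwards. The pressed key on
  an error trial is a uniformly random non-cue key.
- **Observation**: RT = plan + N(0, σ_R²); responses slower than the
  block's window are censored to missing (no press recorded, trial
  incorrect). Default σ_P = 25 ms, σ_R = 30 ms, base RT 420 ms, RT slope
  ≈ 14 ms/day — chosen so Random-probe RT SD sits near 40 ms and the
  cohort-level sequence-specific learning rate lands around 0.35 z/day.

The day-linear RT improvement applies in Sequence blocks only; the
sequence-specific z-score is then driven by genuine sequence learning
rather than generic speedup. The 200 ms inter-trial interval and error
feedback flash are not modeled (no analysis consumes them), and the
generator has no awareness-dependent strategy switching.

What the generator does **not** emulate: RT distributions are Gaussian
(real RTs are right-skewed), errors are independent of cue identity and of
the subject's current speed (no speed–accuracy coupling at the trial
level), and binding is homogeneous across sequence positions (no
within-sequence chunk boundaries). Passing calibration tests on this
generator therefore demonstrates estimator correctness under the model's
assumptions, not robustness to every property of real data.

## Metrics

- z = (μ_Random − μ_Sequence)/σ_Random per day; missing RTs excluded (not
  imputed) since no time-series structure is needed here. Sample SD
  (ddof = 1) throughout.
- Learning rates use raw day regressors 1..10 (non-orthogonal
  polynomials), because λ = β_lin + β_quad is only meaningful on the raw
  basis. The LR statistic is 2·Δloglik with Gaussian MLE log-likelihoods,
  referred to χ²(1); the quadratic model is selected at p < 0.05 per
  subject, uncorrected across subjects (the multiple-comparison caveat is
  a reporting matter, surfaced in output metadata, not a change to the
  per-subject rule).
- The day-by-day variability/learning association resamples subjects with
  replacement (1000 draws by default). Significance is a one-sample t of
  the bootstrap distribution against r = 0 computed on the Fisher-z scale
  with df = n_subjects − 1, at α/10: on the raw r scale the statistic has
  null SD ≈ 1.25 at n = 23 and the family-wise error target is missed by
  a factor of ~4; variance-stabilizing restores nominal calibration
  (verified by simulation in the test suite). Pearson correlation is used
  inside the bootstrap, with a flag for Spearman.
- Median split: values strictly above the median are "high"; the median
  element (odd n) and full ties go to "low". Deterministic by design.

## ERF

Every error opens its own 6-lag window; windows overlap and truncate at
the block end. Trials that are themselves errors still open windows but
contribute no RT (their RTs belong to a different event class), and
missing RTs contribute nothing. Lag means are deviations from the block
mean, making the ERF translation-equivariant. A block with no errors has
no ERF (absent, not zero). With overlapping windows and mean-centering the
null ERF is offset by O(error rate · kernel mass) ≈ −1 ms at typical
rates; the tests account for this.

## Chunk estimator

Preprocessing: drop the first 32 trials (first sequence cycle, which shows
a settling transient on later days), mean-impute missing RTs, remove the
OLS linear trend, zero-mean. ACF uses the biased (1/n) normalization —
the common signal-processing default, which also guarantees |ρ| ≤ 1 — at
lags 1..31 (the sequence span minus one). The null is built per day from
the same day's Random-probe ACFs across subjects (mean μ(l), SD σ(l));
t(l) = (ρ(l) − μ(l))/σ(l) is referred two-sided to t with
n_subjects − 1 df at α/31, and a lag counts toward the chunk only when
ρ(l) > μ(l): a significantly *negative* autocorrelation is not binding.
Referring a per-subject statistic to an across-subject null is
nonstandard; a z-reference fallback flag is provided. The tested subject's
own Sequence-probe ACF never enters the null (the null uses Random probes
only, so the exclusion question does not arise).

Calibration is designed analytically before simulation: with n = 1024
trials and 23 null subjects, the corrected threshold is
t(22, 0.05/62)/√n ≈ 0.112 in ρ units; an AR(1) with α = 0.55, σ_P = 10,
σ_E = 4.605 puts the theoretical ACF at 0.479/0.263/0.145/0.080 for lags
1–4, i.e. a planted span of exactly 3 with balanced margins. The geometric
decay of an AR(1) makes long planted spans (e.g. 7) infeasible with usable
margins at ρ ≤ 1, so the recovery check plants span 3; the cohort-level
growth toward ~6–7 consecutive lags is exercised separately on the default
cohort. By construction this estimator cannot localize chunk boundaries or
detect variable chunk sizes.

## Binding toy model

x_t = μ_P + α(x_{t−1} − μ_P) + N(0, σ_P²), y_t = x_t + N(0, σ_E²), first
plan drawn from the stationary distribution so block ACFs need no burn-in.
Whether the AR(1) is written mean-centered or as x_{t+1} = αx_t + (1−α)μ_P
+ noise is inconsequential: the ACF is identical. Block ACFs are centered
on the grand mean across blocks by default (`center="global"`): the blocks
share one stationary mean and per-block centering injects an O(1/n)
negative bias (≈ 1.7 Monte-Carlo SEs at the 100 × 1000 reference scale).

## State-space model

Scalar-state LDS with deterministic inputs; exact filter/smoother and EM
with closed-form M-steps (joint regression for A, **B**, F from expected
sufficient statistics; per-cue means for **D**; expected residual
variances for Q and R). Numerical conventions:

- **B input**: the previous-press one-hot, read literally from the state
  equation. The alternative reading (previous *reaction time* weighting)
  is available as `b_input="rt"`, which scales the one-hot by the previous
  trial's mean-centered RT; the mode is recorded in fit metadata.
- **F timing**: an error on trial t−1 delays the state on trial t
  (previous-trial convention).
- **Missing RTs**: the filter propagates without an update (the
  alternative, mean imputation, biases R downward). Omitted presses leave
  the press one-hot at zero.
- **Initial state**: x₁ ~ N(0, 10·Q_init), fixed for the whole fit — a
  weak prior. Holding it fixed (rather than re-tying it to the current Q)
  keeps the EM likelihood exactly non-decreasing.
- **Identifiability**: the state mean trades off against **D**, so
  `fit_probe_block` centers y per block and reports **D** as deviations
  plus the block mean.
- **Initialization**: A = 0.5, B = F = 0, D = per-key mean RT, Q = R =
  half the residual variance around the per-key means. Variance floors at
  1e-10 prevent degenerate collapse; divergent statistics raise a failure
  signal carrying the iteration index.
- Convergence: relative log-likelihood improvement < 1e-6 or the
  iteration cap (200 default; 60–100 in the pipeline).

Blocks are fitted independently (one probe block per fit in the pipeline);
pooled multi-block fits reinitialize x₁ per block and share parameters.

## Repeated-measures ANOVA

Standard within-subject sums-of-squares decomposition; each effect tested
against its own subject-by-effect interaction; no sphericity correction by
default (a Greenhouse–Geisser flag exists on the one-way form). Reported
df conventions in the literature for this design vary; the module
implements the standard decomposition and its printed dfs follow from
that, not from any particular publication.

## Problem sizes and reproducibility

Simulation-based checks use sizes chosen to make their Monte-Carlo error
small relative to the asserted tolerances: binding-ACF agreement at 100
blocks × 1000 trials (3 MC SE bound), chunk calibration at 200 null
replicates and 50 planted-span seeds (1024 trials, 23 null subjects), LDS
recovery at 20 seeds × 8 pooled 256-trial blocks, and cohort contrasts on
23 subjects × 10 days. Every random quantity flows from a single seed;
`run_pipeline` writes a manifest (seed, version, decision flags) and the
same configuration reproduces byte-identical tables.

## Known limitations

- The chunk estimator reports one span per subject-day; it cannot segment
  chunks, locate boundaries, or grade binding strength.
- The LDS is scalar-state and linear; no per-finger latent states,
  switching, or nonlinear dynamics.
- Printed group-level numbers from any particular empirical study are not
  reproduction targets here: the package validates its methods on
  synthetic ground truth, and the default cohort is a qualitative, not
  quantitative, emulation.
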