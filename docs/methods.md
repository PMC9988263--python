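# Methods

## The behavioural model

The package models choices and reaction times in a two-option pain-relief
gambling task ("wheel of fortune"): on each test trial the subject picks one
of two colours; one colour wins pain relief (−3 °C off a tonic painful heat
stimulus) with probability 0.75, the other with 0.25; losing raises the
temperature by +1 °C. Each of 5 blocks holds 4 test, 4 control (passive,
outcome-matched) and 1 neutral trial — 45 trials and 20 choices per session.
Subjects play one session per drug condition (placebo, levodopa, naltrexone).

### Value learning

Expected values Q for the two colours start at 0 and are updated after each
test trial from the signed outcome R ∈ {+1 (relief), −1 (increase)}:

    δ_t = ρ·R_t − Q_chosen,t
    Q_chosen,t+1 = Q_chosen,t + η⁺·δ_t   if δ_t > 0
    Q_chosen,t+1 = Q_chosen,t + η⁻·δ_t   if δ_t ≤ 0

with separate learning rates for positive and non-positive prediction errors
and an individual outcome-sensitivity scaling ρ (the *static* variants fix
ρ = 1). The unchosen colour's value carries forward unchanged; control,
neutral and unanswered trials never update Q. The tie δ = 0 is routed
through η⁻ (the value is unchanged either way; the convention only fixes
which branch formally applies). The value entering a trial's decision rule
is the *pre-update* value — the standard sequential-sampling convention.

### Choice rule

A Wiener diffusion with boundary separation α, non-decision time τ, relative
start point β ∈ (0,1) and trial drift ν_t is the likelihood of each
(choice, RT) pair. The upper boundary is, by convention, the
high-contingency colour; β > 0.5 is a bias toward it. The trial drift is
either linear in the value difference,

    ν_t = (Q_high − Q_low)·ν ,

or a saturating (sigmoid) mapping bounded at ±ν_max,

    ν_t = 2·ν_max / (1 + exp(−(Q_high − Q_low)·ν)) − ν_max .

Crossing the 2 × 2 grid (static/scaled sensitivity × linear/sigmoid drift)
gives model variants 1–4; variant 4 (scaled + sigmoid) is the richest.

The sigmoid form deserves a note: it is implemented as
S(x) = 2ν_max/(1+e^(−x)) − ν_max, the only form with S(0) = 0 and limits
±ν_max; for weak value signals it degenerates to the linear map with
effective slope ν·ν_max/2, which matters for model identifiability (below).

### Wiener first-passage density

The density is evaluated through the classic dual series representation
(mirror/small-time sum and sine/large-time sum) of the first passage of a
unit-diffusion Wiener process, with the cheaper series chosen per evaluation
from the number of terms each needs for an absolute truncation error of
1e−7. Continuity across the switch and agreement with long fixed-K
reference series and with a 10⁶-path Euler–Maruyama simulation are tested.
The diffusion coefficient is fixed at 1 (the Stan-style scale convention; a
0.1 convention also exists in the older literature — parameters differ by a
factor of 10 between the two). Analytic partial derivatives with respect to
(ν_t, α, τ, β) are propagated through the value recursion (forward
sensitivities of Q wrt η⁺, η⁻, ρ) and the drift mapping, giving an exact
gradient of the full hierarchical log posterior (verified against central
finite differences to ~1e−8 relative error).

## Hierarchy, priors, inference

Each native parameter θ ∈ {η⁺, η⁻, ρ, α, τ, β, ν, ν_max} gets, on an
unconstrained scale, a group intercept (location + scale), a main effect per
non-reference drug (location + scale, placebo as reference — the contrast
coding is a package choice, exposed in the API), and standardized
per-subject deviates for both, combined non-centrally:

    raw[s, d] = μ + σ·z_s + 1[d ≠ ref]·(d_loc_d + d_scale_d·w_{s,d})

The per-subject drug deviates w share a 2 × 2 correlation matrix per
parameter with an LKJ(1) prior (uniform over correlations). Natives are
logistic transforms (η⁺, η⁻, β), exponentials (ρ, α, ν, ν_max), and for τ a
logistic fraction times the subject-session *minimum observed RT*, keeping τ
strictly below every RT it must explain.

Priors (location, scale):

| parameter | intercept loc | intercept scale | drug loc | drug scale |
|---|---|---|---|---|
| η⁺, η⁻, τ | N(0,1) | HN(1) | N(0,1) | HN(0.1) |
| β | N(0,0.5) | HN(0.1) | N(0,0.5) | HN(0.1) |
| ρ | N(0.1,0.1) | HN(0.1) | N(0,0.5) | HN(0.1) |
| α | N(0,0.1) | HN(0.1) | N(0,0.5) | HN(0.1) |
| ν | N(0.2,0.2) | HN(0.1) | N(0,0.5) | HN(0.1) |
| ν_max | N(0.5,0.2) | HN(0.1) | N(0,0.5) | HN(0.1) |

All standardized deviates are N(0,1). Scales are sampled on the log scale
with the half-normal prior applied through the Jacobian.

### Sampler

The posterior is sampled with a hand-written adaptive Hamiltonian Monte
Carlo: leapfrog integration with a uniformly jittered number of steps
(avoiding resonant trajectory lengths), dual-averaging step-size adaptation
toward 0.85 acceptance, and a windowed diagonal mass matrix estimated from
warmup draws (20% unit-mass step tuning / 60% mass estimation / 20% final
tuning). Energy errors above 500 after warmup are counted as divergences.
The sampler was validated on correlated Gaussians and cross-checked against
an independent affine-invariant ensemble sampler (emcee) on small versions
of the actual posterior; agreement of group-level means and SDs is part of
the test suite. R̂ (via arviz, split-chain for single-chain fits) is
reported for every group-level quantity with warn/fail thresholds 1.01/1.1
— thresholds are a package choice.

Fit profiles: `paper` (4 chains × 4000 iterations, first 1000 discarded)
mirrors the published analysis scale; `desk` (2 × 800/400) and `smoke`
(1 × 300/150) are reduced profiles for experiments and tests. Desk-scale
fits of the full 3-drug model typically reach R̂ ≈ 1.1–1.4 on the hardest
scale parameters; results that feed publication-style claims should use the
paper profile.

## Model comparison

K-fold cross-validation partitions *subjects* (k = 10 at study scale; folds
of 2–3 subjects at n = 28). For each fold the model is re-fit to the
remaining subjects and the held-out subjects' trials are scored by their
log pointwise predictive density. Held-out subjects have no subject-level
posterior; by default their parameters are *simulated from the group-level
distribution* of each retained posterior draw (new-subject prediction,
averaging the per-trial density over draws × simulated subjects). A plug-in
alternative using group locations is exposed for sensitivity analysis; the
choice between the two is a genuinely open design point and both are
documented rather than presented as canonical. A model is decisively better
when |ΔELPD| ≥ 2·se(ΔELPD), the se computed from the pointwise difference
vector.

Identifiability caveat: in weak-learning regimes (small ΔQ·ν) the sigmoid
mapping is locally linear and ρ trades off against ν, so variants 1–4 make
nearly identical predictions and cross-validation cannot (and should not)
separate them. Model-recovery experiments therefore use a *discriminating*
generating regime (strong learning, saturating drift, ρ well away from 1;
`RECOVERY_GROUP_PARAMS`).

## Posterior analyses

- **HDI**: narrowest window over order statistics (cross-checked against
  arviz).
- **Drug contrasts**: draw-wise differences of group-level drug effects on
  the unconstrained scale, summarized by the 95% HDI and whether it encloses
  zero.
- **Posterior predictive check**: replicated cohorts simulated from
  posterior draws play fresh schedules; the statistic is the group-mean
  proportion of high-contingency choices in the last two blocks. The
  posterior p-value is reported one-sided (P(replicate ≥ observed)) with a
  two-sided companion 2·min(p, 1−p); the sidedness convention is a package
  choice.
- **Prediction-error extraction**: posterior means of each subject-session's
  native parameters (condition-specific, i.e. per drug) are plugged into the
  value recursion over the realized choice/outcome sequence; one δ_t per
  completed test trial.

## Pain modulation

Trial-wise endogenous modulation = test-trial value − mean of the session's
*matching-outcome* passive controls (wins vs relief controls, losses vs
increase controls), separately for the VAS intensity rating (0–200) and the
behaviourally self-adjusted temperature (°C); negative = inhibition.
Control means pool across all blocks of a session. The modulation records
are regressed on PE with drug and PE × drug fixed effects and a random
subject intercept (statsmodels MixedLM, REML; large-sample Wald inference —
a deliberate simplification relative to small-sample df corrections). The
above-chance choice-preference test is a random-intercept logistic
intercept model fit by variational Bayes (statsmodels
BinomialBayesMixedGLM).

## The synthetic cohort

The generator stands in for the study's (downloadable) behavioural data so
the pipeline is testable offline. It emulates: 28 subjects × 3 drug
sessions (order counterbalanced by latin square), 45 trials per session in
the 5-block composition, the 75%/25% contingency implemented as a pre-drawn
per-trial lottery, choices and RTs from an RL-DDM agent (Euler–Maruyama
paths, dt = 1 ms), control outcomes copied from the realized test outcomes
in shuffled order, and VAS/behavioural modulation generated as
slope × PE + drug offset + Gaussian noise with slopes −0.36 (VAS) and
−0.06 (°C) and noise SDs 21.51 / 0.64 taken from the study's printed
trial-wise dispersion. Test-trial ratings are built as the realized
outcome-matched control mean plus the simulated modulation, so the
downstream test-minus-control computation recovers the coupling exactly in
the noiseless limit.

Generator population defaults were chosen once, by forward simulation, to
reproduce the study's stated behavioural conditions — late-block
high-contingency preference ≈ 64% under placebo and ≈ 0.51 under both
active drugs — and the subject-level scatter is drawn inside the support of
the inference model's scale priors so that recovery experiments simulate
from the assumed model family. Since the agent has no built-in bias toward
the low-contingency colour, the generator cannot produce below-chance
preference (the study reports 0.467 under naltrexone); ≈ 0.51 is the
closest attainable condition.

What the generator does *not* emulate: thermode temperature dynamics,
staircase calibration, missed-response patterns (an optional miss-rate
exists but defaults to 0), habituation/sensitization drifts within a
session, questionnaire measures, and any outcome-conditional drug effect on
modulation beyond the PE coupling (the per-drug offsets are
outcome-independent; win/lose mean asymmetry in synthetic cohorts arises
from the PE sign alone and is therefore smaller than the study's printed
win/lose contrast). Passing tests show the pipeline's estimators recover
known generative structure; they do not certify behaviour on the real
deposit's idiosyncrasies (column layout aside — a column-mapping adapter is
provided).

The non-decision time is the one knowingly scale-incommensurate parameter
between generation (logistic fraction of a fixed 0.6 s reference) and
inference (logistic fraction of the observed session minimum RT); group-
location recovery checks tolerate τ as the expected miss (≥ 7 of 8
parameters covered).

## Numerical choices and degenerate inputs

- Series truncation 1e−7 absolute; density floor 1e−290 before log.
- The Euler–Maruyama path simulator absorbs at boundaries pulled in by
  0.5826·σ·√dt (the standard boundary-layer correction for discrete-time
  first passage); without it the O(√dt) hitting-probability bias at
  dt = 10⁻⁴ (~0.006) would exceed Monte-Carlo error at the sample sizes the
  validation experiments use. Normals are drawn in memory-capped blocks by
  a vectorized generator and consumed by a compiled stepping kernel.
- Parameter regions that cannot produce data (rt ≤ τ, α outside
  [1e−6, 1e6], |ν_t| ≥ 1e8, β at 0/1 after transform overflow) return
  log-density −∞ and are rejected by the sampler rather than clipped.
- Unconstrained exponentials are capped at exp(50) before the likelihood
  (the kernel rejects such states anyway); this only guards floating-point
  overflow, not the posterior geometry.
- Sessions are processed in deterministic sorted order; all randomness
  flows from explicit integer seeds (numpy Generators at the Python level,
  seeded numba RNG inside kernels), making every pipeline stage bit-
  reproducible on a fixed platform.

## Problem sizes used by the validation experiments

Chosen as desk-scale package defaults: parameter recovery uses 15 subjects
× 60 test trials × 1 condition with desk-profile fits over 3 generator
seeds; model recovery uses 12 subjects × 60 trials, k = 4 folds,
smoke-profile fits, 10 replicates; the PE-coupling recovery runs the full
pipeline at study scale (28 × 3 × 45). The end-to-end reproduction script
(`scripts/acceptance.py`) uses the study-scale cohort with a 2 × 1600/800
fit and reports every quantity it computes.

## Known limitations

- The sampler is plain adaptive HMC, not a dynamic-trajectory (NUTS)
  implementation; very long-tailed posteriors may need more leapfrog steps
  (`max_leapfrog`) or a higher `target_accept`.
- Desk-scale profiles under-converge on the weakly identified group scale
  parameters (reported honestly by R̂); they are for experiments, not
  inference.
- Across-trial variability parameters of the full Ratcliff model (sv, st,
  sz) are out of scope, as are eligibility traces, perseveration kernels
  and forgetting of the unchosen option.
- `BinomialBayesMixedGLM` is a variational approximation; its intervals are
  mildly overconfident relative to a Laplace/ML GLMM.
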