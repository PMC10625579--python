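# Methods

This note documents the models, numerical choices and open design
decisions behind the package, and what the synthetic-data tests do and do
not establish.

## Task schedule

A block's volatile trajectory must satisfy three constraints at once:
every epoch (run at one probability level) lasts 14–30 trials, the block
has 80 trials, and the block-mean scheduled probability is exactly 0.5
(equal trial counts at 0.85 and 0.15). Under strict alternation of
levels these constraints force a four-epoch structure per block: with
epochs a, b, c, d the two same-level pairs must each sum to 40 (three
same-level epochs would already exceed 40 at the 14-trial minimum, and a
40-trial single epoch violates the 30-trial cap). The generator therefore
draws epoch lengths by a budget rule (sample uniformly on [14, 30] until
the remainder is below 14, absorbing the remainder into the final epoch)
and rejection-samples until the partition is balanced; the starting level
is random. Configurations with no legal balanced partition (e.g. epoch
bounds [14, 18]) are rejected with a diagnostic. Win-before-loss display
order alternates deterministically within a block (exact counterbalance);
the delay between the two outcome displays is uniform on [2, 6] s.

Schedules are regenerated per subject by default; a shared-schedule
policy (one schedule per block order) is available because either design
is defensible and the analyses do not depend on the choice.

## Agents

Value estimates are tracked for shape A only (shape B's probabilities are
the complements by construction) and updated for both valences on every
trial, because the task reveals both shapes' outcomes regardless of
choice. Estimates start at 0.5 and restart at 0.5 at each block boundary,
since the stimuli change between blocks and carry no learning history.
The choice rule is a logistic over the net value difference
2(v_win − v_loss) with a single inverse temperature, plus an optional
constant bias toward shape A. Win and loss values enter with equal
weight; the model family varies only learning-rate sharing (single, per
valence, per block × valence) and the presence of the bias, each with one
β — six variants. Because feedback is full, the latent state trajectory
is a function of the schedule alone; this is what makes the simulation
vectorisable and the likelihood independent of the subject's own choices.

## Fitting

Parameters are transformed to an unconstrained scale (logit α, log β,
identity bias) with independent normal priors; the default prior is
weakly informative (logit α ~ N(0, 2²), log β ~ N(log 6, 1²),
bias ~ N(0, 1²)). MAP estimation uses L-BFGS-B from the prior mean plus
random restarts (3 by default). The sampler is adaptive random-walk
Metropolis: the proposal scale is tuned every 50 burn-in iterations
toward a 20–45 % acceptance rate, and runs ending below 5 % acceptance
raise a diagnostic error. Per-trial choice probabilities are floored at
1e-10 in the log-likelihood.

Model comparison uses an integrated BIC. A factorised normal group prior
on the transformed scale is fitted empirically (iterate: MAP-fit all
subjects under the current prior; refit the prior moments to the
estimates, flooring sds at 0.1; 3 cycles by default). Each subject's
marginal likelihood is then estimated by Monte-Carlo averaging the
likelihood over prior draws, and

    iBIC = −2 Σ_s log p̂(data_s) + k · log(N)

where k counts the prior hyperparameters (a mean and sd per free
parameter) and N is the total number of choices across subjects — the
sample-size convention is stated explicitly because only the score's name
fixes it. The Monte-Carlo estimator is validated against brute-force
grid quadrature on a one-dimensional problem (β pinned by a near-delta
prior) and for stability under doubling of the draw count.

A caveat observed while validating the fitter: choices generated at
β = 0 are not "uninformative" about β under this likelihood — pure coin
flips are evidence *for* a small β, so the MAP β falls below the prior
mode rather than staying at it. The corresponding test asserts the real
property (the fit gains essentially no likelihood over chance and β
collapses toward zero).

## Behavioural statistics

Subjects whose final total is at or below the £1.50 stake are excluded as
non-learners. Stay proportions are computed per valence on trials where
the chosen shape received that outcome, excluding each block's last trial
(the stimuli change, so stay/switch is undefined across the boundary);
the volatile cell pools block 1 with the valence-volatile block. The
proportion receives an add-half continuity correction,
(k + ½)/(n + 1), before the logit so that 0 and 1 stay finite.

Learning-rate adjustment summarises the fitted grid as
α_volatile(valence) = mean(α_block1, α_valence-volatile-block) — block 1
and the single-volatile block both carry volatile information and the
paper-level analyses pool them; averaging is the symmetric combining rule
that keeps the learning-rate units. One-sample t-tests stack the two
valence adjustments per subject (n = 2 × subjects), matching the degrees
of freedom convention of the group analyses.

The mixed ANOVA is implemented from first principles as a split-plot
decomposition (orthonormal within-subject contrast sets; Type-III
between tests via effect-coded model comparison; within effects tested
against the subject × effect error stratum) because no installed package
handles the full two-between × two-within design. It is cross-checked in
the test suite against pingouin on the designs pingouin supports, and
its type-I error is verified by simulation on null data (rejection rate
within 5 % ± 3 % for every effect at 500 replicates). Greenhouse–Geisser
epsilon is estimated per within effect from the error covariance of its
orthonormal contrasts; two-level factors have ε = 1 identically. Subjects
with missing cells are dropped listwise; between-cells with fewer than
two subjects raise an error.

Fisher's r-to-z comparison follows
z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)). Recomputing published
three-decimal inputs reproduces z = 2.56 for r = .512 (n 24) vs −.176
(n 30); the analogous computation for r = .512 (n 24) vs .067 (n 25)
yields z ≈ 1.64 rather than a sometimes-quoted 1.71 — the package
documents its own formula output and does not tune to match.

## Pupillometry

Exact preprocessing conventions are not standardised, so the defaults
are the common ones and all are config-exposed: invalid or non-positive
samples are treated as blink, the blink mask is padded ±100 ms, gaps are
linearly interpolated from flanking valid samples, an optional
moving-average low-pass is off by default, and the stream is resampled
to a 50 Hz working rate (cluster inference is smooth at this scale and
keeps 1000 permutations fast). Traces more than 95 % invalid are
unprocessable.

Epochs span −1000 to +6000 ms around each outcome display (351 samples
at 50 Hz), baseline-corrected by subtracting the mean of the pre-onset
second (subtraction, not division; units are arbitrary). Epochs with
more than half their samples interpolated are dropped; a subject is
removed when more than half of the task trials are that badly
interpolated (a trial's interpolation is the mean over its two outcome
epochs). Both rules read the same per-epoch fractions, so their order is
immaterial.

Inference uses one series per subject per valence: the receipt-minus-
non-receipt contrast under volatile outcomes (block 1 pooled) minus the
same contrast under stable outcomes. Because each subject contributes a
single averaged series per valence, a per-subject valence random slope
reduces to subject-paired valence differences, and the pointwise model
is implemented as a split-plot ANOVA of group (between) and valence
(within-paired). Clusters are maximal runs of pointwise p < 0.05; the
cluster statistic is the summed F (mass); the null is the distribution
of the maximal cluster mass over permutations that shuffle group labels
across subjects and flip valence labels within subjects, and
p = (1 + #{null ≥ observed})/(n_perm + 1). Window post-hocs average the
series over a window and permute group labels on the scalar.

## Synthetic cohort

The generator's defaults are the study conditions: group sizes 25/25/32,
per-valence adjustments drawn from the groups' normal distributions
(RA 0.191 ± 0.169, EA 0.134 ± 0.180, HC 0.107 ± 0.195), stable learning
rates logit-normal around 0.2 (sd 0.4 on the logit scale), β log-normal
with median 6 and σ 0.4 — the stable-α and β distributions are
unpublished, so these are calibrations chosen to keep simulated stay
proportions in the descriptive range of human play (roughly 0.6–0.9),
never reported as facts about participants. Sampled learning rates are
clipped to [0.02, 0.98] and the generator warns if clipping shifts a
group's mean adjustment by more than 0.05. Block-1 learning rates equal
the valence's volatile rate (block 1 is volatile for both valences); the
fitted model still estimates all six cells freely.

Pupil streams are a constant baseline plus a unit-peak gamma-density
impulse response (shape 3, scale 0.5 s; mode 1 s after onset — the
standard pupillometry convention) at every outcome display, scaled by a
base response plus a condition-specific receipt effect, plus white noise,
slow drift and Poisson blinks (zeroed and invalid-flagged). The RA
preset's receipt effects express the published direction (elevated
dilation to stable wins, suppressed to stable losses), and its
volatile-win effect adds a component proportional to the subject's
standardised reward adjustment, producing a positive within-RA
pupil-behaviour correlation by construction.

What the synthetic data do **not** emulate: reaction times, luminance
and gaze confounds, slow arousal state changes, questionnaire scores, or
any correlation structure between β and the learning rates. Passing
tests therefore demonstrate that the pipeline is correct and calibrated
under its own assumptions, not that real data would show these effects.

## Problem sizes and determinism

Simulation-based tests use reduced but fixed problem sizes chosen as the
smallest that make the checks statistically meaningful: 500 replicates
for ANOVA calibration, 200 for cluster-test calibration (n_perm = 200),
20 replicate 30-subject cohorts for model recovery, and five replicate
cohorts of 24/30 subjects for the adjustment-recovery checks. All
stochastic stages are seeded; the pipeline derives each stage's
generator from the master seed plus the stage name, so a rerun with the
same seed reproduces every number exactly.

## Known limitations

- The MCMC sampler is single-chain random-walk Metropolis; it is adequate
  for these ≤ 8-parameter posteriors but reports no cross-chain
  convergence diagnostic.
- The empirical-Bayes prior is fitted from MAP point estimates, which
  understates group-level variance relative to a full hierarchical fit;
  the sd floor (0.1) guards against collapse.
- Volatility-estimating Bayesian learners (hierarchical filters) are out
  of scope; the agent family is the delta-rule roster described above.
- Group-level adjustment recovery is approximately unbiased under the
  default weak priors, but single-subject estimates shrink toward the
  prior and should not be interpreted individually.
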