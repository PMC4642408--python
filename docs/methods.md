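# Methods

## Scope and intent

`tempotrain` simulates the computational core of a two-arm randomized
auditory temporal-training trial: estimating each participant's
auditory temporal-order threshold (ATOT) with an adaptive
maximum-likelihood procedure, running block-adaptive temporal or
loudness-control training, and analyzing pre/post/follow-up outcomes
with nonparametric tests. No real participant data enter the package;
synthetic observers with known parameters make every stage testable,
including parameter recovery, type-I error and power.

## Observer model

A temporal-order judgment (2AFC, guess rate 0.5) follows a logistic
psychometric function of the inter-stimulus interval (ISI):

P(correct | x) = γ + (1 − γ − λ)·σ((x − μ)/s),  σ the logistic CDF.

* `mu` (ms): threshold location; with λ = 0 it is exactly the
  75%-correct point, the quantity the assessment procedure tracks.
* `spread` (ms, default 20 in cohorts): logistic scale. The assessment
  assumes a spread rather than estimating it; threshold-only tracking
  is standard for this class of procedure, and a moderate mismatch
  between true and assumed spread leaves the 75% point nearly unbiased
  because trials concentrate at the running estimate.
* `lapse_rate` (default 0): attention lapses; with λ > 0 the 75% point
  no longer coincides with `mu` and tests account for that separately.

The loudness-control observer uses the same logistic form on the
amplitude-difference axis (`delta75` default 0.005 of the amplitude
range, spread 0.0015). These defaults make a mid-range difference of
0.0125 essentially always discriminable while leaving the adaptive
track informative near threshold. Note a structural limit of the
logistic tail: at a vanishing difference the model approaches
γ + (1 − γ)·σ(−delta75/spread) ≈ 0.52, not exactly chance.

Observers are stationary within a session; all learning happens
between sessions (no within-session learning model is included).

## Adaptive threshold assessment

A grid of integer candidate thresholds 1..600 ms carries a
log-likelihood, updated additively per trial under the assumed-spread
model. Design choices:

* **Placement:** each trial at the current best estimate, rounded half
  up to an integer ms and clamped to [1, 600]. The first trial is
  placed at 300 ms (range midpoint); starting at the flat-state argmax
  (1 ms by the tie-break) would trap early runs at the floor.
* **Tie-break:** argmax ties resolve to the smallest candidate.
* **Stopping:** terminate once ≥ 95% of normalized likelihood mass lies
  within ±5 ms of the estimate, gated by a 10-trial minimum that
  prevents spurious convergence on a near-degenerate likelihood.
* **Budget:** `max_trials` defaults to 500. With an assumed spread of
  20 ms, the Fisher information of a Bernoulli trial at the 75% point
  implies roughly 700 trials to reach a ±5 ms 95% interval, so default
  sessions frequently end un-converged (the estimate is still
  reported, flagged `converged=False`). Analyses that need the stop
  rule to fire (convergence audits, the acceptance script) raise the
  budget to 1 500–6 000 trials; analyses that only need an unbiased
  threshold measurement (power and type-I simulations) lower it to
  80–150 trials, trading precision for speed without bias.
* **Identity:** because updates add in log space, the sequential
  estimate equals a batch refit over the same log exactly; the batch
  refit is also how the training scheduler refreshes its "actual
  threshold" from session trials.

The per-phase ATOT is the arithmetic mean over the phase's assessment
sessions (two in the adult preset, one in the child preset); sessions
are independent runs.

## Training schedulers

Temporal training: 10-trial blocks at fixed ISI, first session opening
at the pre-training ATOT. A block at ≥ 90% correct lowers the next ISI
by 5 ms (actual ATOT > 100 ms), 2 ms (50–100 ms inclusive) or 1 ms
(< 50 ms); below 90% it rises by the same step. Boundary readings:
exactly 100 ms falls in the 2 ms regime ("longer than 100" exclusive),
exactly 50 ms also 2 ms (the middle band read inclusively). ISI is
clamped to [1, 600] ms. After each session the actual ATOT is refit
from that session's trials; how often the original procedure refreshed
it is not specified anywhere, and per-session refit keeps the step
regime tracking ability without inventing extra assessments.

Control training mirrors the protocol on loudness discrimination:
constant 0.00025 amplitude step inside [0.00025, 0.025], start 0.0125
(range midpoint; no published start value), the same ≥ 90% criterion
(mirrored from the temporal rule — the control task's own criterion is
not documented), one carrier per block rotating 400→600→800→1000 Hz in
fixed cyclic order. Tone duration (1 s) and the 3 s within-pair ISI are
logged as metadata only.

Motivation bookkeeping is shared: +1 point per correct, −1 per error,
one puzzle reward per completed block; cumulative points equal the sum
of block net points by construction, and nothing in the observer model
responds to points (no behavioral mechanism is modeled).

Session trial budgets stand in for wall-clock durations: 300
temporal / 150 control trials per session (the control task's stimuli
are an order of magnitude longer).

## Between-session effect and transfer model

* Temporal session: μ ← max(floor, μ·(1 − r)) with `mu_floor` 1 ms (the
  smallest presentable ISI). The default rate r = 1 − (85/179)^(1/16) ≈
  0.0454/session is calibrated so sixteen sessions carry the adult
  group-mean threshold 179 → 85 ms; the child preset uses
  1 − (127/196)^(1/24). Per-participant rates get a small Gaussian
  jitter (SD 0.008 / 0.004) to produce realistic heterogeneity.
* Control session: order threshold untouched (configurable
  `control_order_rate` for sensitivity analyses); optionally shrinks
  `delta75` to model learning in the trained loudness task itself —
  whether that happened in practice is undocumented, so the default is
  off.
* Follow-up: thresholds freeze after training (no forgetting model);
  the stability analysis therefore expects null follow-up-vs-post
  differences, which is the published pattern.

Outcome batteries: for each measure,
value = baseline − sign·c·max(0, (ATOT_pre − ATOT_now)/ATOT_pre)·baseline + ε,
ε ~ N(0, noise_sd), clamped to the measure's legal range (percent
errors to [0, 100], spans/RTs to non-negative). `sign` is +1 for
lower-is-better measures and −1 for higher-is-better ones, so positive
transfer always moves the measure toward improvement. Transfer
coefficients in the measure registry are calibrated from the published
group-mean pre/post changes divided by the group-mean relative ATOT
gain; negative coefficients encode measures that drifted against
improvement. The runner feeds *measured* (not latent) ATOT values into
the transfer formula, since only measurements are observable.

What the generator deliberately does not emulate: practice effects
independent of ATOT gain (in the child study both arms improved on two
executive-function tests; a model tying transfer to ATOT gain cannot
reproduce the control arm's share), floor/ceiling learning curves
within measures, correlated noise across measures, and dropout
mechanisms other than random attrition. Passing tests therefore show
the pipeline's statistical machinery is correct under its stated
model, not that the model captures every feature of real cohorts.

## Cohort generation and randomization

Baseline thresholds are truncated-normal (adult preset: mean 172 ms —
pooled across arms — SD 53, range [40, 450]; child preset: 203 ± 70).
Group assignment is stratified on baseline threshold: sort, split
adjacent pairs by a coin flip, route overflow to the unfilled arm for
unequal sizes (15/13, 17/15). Pair-matching makes baseline
between-group tests conservative relative to simple randomization, so
the balance check asserts the significant fraction does not exceed the
nominal rate rather than equaling it.

Seeding is hierarchical: every stage of every participant draws from
`SeedSequence(master_seed, spawn_key=(participant_index, stage))`, so
changing the cohort size or toggling a stage never perturbs another
participant's stream, and full runs are byte-reproducible.

## Statistical stage

* Wilcoxon signed-rank: zero differences dropped, midranks for tied
  magnitudes; exact two-sided p by enumerating all 2^n sign
  assignments for n ≤ 12 (two-sided = doubled smaller tail, capped at
  1), otherwise normal approximation with tie-corrected variance and a
  0.5 continuity correction; z carries the sign of the post−pre rank
  sum difference.
* Mann–Whitney U: midranks, exact enumeration of all labelings for
  n₁+n₂ ≤ 14, otherwise the tie-corrected, continuity-corrected normal
  approximation. The reported statistic is min(U₁, U₂).
* Two-sided p throughout; no multiple-testing correction by default (a
  Holm option exists) — matching common practice in small clinical
  training studies that report per-measure tests.
* Stability tables use complete cases (both post and follow-up
  present); cells with fewer than 4 effective pairs are flagged not
  testable rather than tested.
* Degenerate inputs: all-zero differences give p = 1 with a
  `degenerate` method tag; zero-variance normal approximations also
  return p = 1.

Validation harnesses: `type_one_error_sim` measures the within-group
threshold test's rejection rate under a null effect model (assessment
precision cannot bias the level, so the simulation uses a reduced
trial budget and an 8-per-arm design for speed); the power suite runs
200 replicate full studies at the published 15/13 sizes with the
calibrated effect, skipping individual training trials because the
threshold dynamics are the deterministic between-session effect model.

## Numerical choices

* Grid spacing 1 ms; posterior summaries (argmax, symmetric-window
  mass, 95% half-width) computed by prefix sums over the uniform grid,
  exactly matching the definitional implementations.
* Rounding of proposed ISIs: nearest integer, half up.
* Exact-test enumeration cutoffs (2^12 sign patterns, C(14,7) = 3432
  labelings) keep the exact regime effectively instantaneous.
* Truncated-normal draws use rejection sampling from the seeded
  generator (guaranteeing reproducibility without inverse-CDF special
  cases).
* CSV logs write floats via `repr` so write-then-read round-trips are
  exact.

## Known limitations

* The assumed-spread tracker is asymptotically biased if the true
  spread differs grossly from the assumed one; cohorts here draw the
  true spread equal to the assumed default.
* The transfer model is linear with independent Gaussian noise; it is
  parameter-recoverable by design but not a cognitive model.
* Control-arm improvements that are unrelated to temporal processing
  (practice, motivation) are not modeled.
* The follow-up freeze means stability is reproduced by construction,
  not predicted.
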