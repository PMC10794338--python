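# Methods

This note documents the models, rules and numerical choices implemented in
`partialpress`, the defaults and why they were chosen, and what the bundled
simulator can and cannot establish.

## Signal model and detection rules

The raw measurement is a change-only log of analog key values: one row per
(trial, key, timestamp, value) written only when the retrieved value differs
from the previous retrieval at 1000 Hz. Under change-only recording the
underlying signal is exactly a right-continuous step function on the 1 ms
grid, so reconstruction is zero-order hold: the value holds until the next
event, and is 0 before the first event. `sparsify ∘ densify` is the identity
for grid-aligned event lists (property-tested), and all detection rules can
therefore be evaluated on the sparse event lists directly — a level can only
be crossed at an event. The test suite nevertheless re-checks every rule
against brute-force evaluation of densified 1 kHz trajectories on >10,000
simulated trials.

Rules, with strict inequalities throughout:

- **Response**: earliest time ≤ deadline at which either response key's
  value exceeds **.95** (the threshold is below 1.0 because keys pressed at
  an angle may not reach the maximum). The pressed key determines
  correctness against the trial's required key.
- **Simultaneous crossing** of both keys at the same millisecond is broken
  by the larger analog value at that sample; an exact tie marks the trial as
  an error. The recording hardware makes this a measure-zero corner, but a
  deterministic rule is needed.
- **Partial error**: both response keys attain value **> 0** at some time
  *strictly before* the response crossing. The two keys need not be nonzero
  simultaneously: the responded key is necessarily nonzero on the way to its
  press, so the criterion is effectively "the incorrect key moved before the
  response was committed".
- **Starts-pressed**: any response key with value > 0 at any time in the
  first 5 ms (inclusive window) — a carry-over press from the previous
  trial; such trials are excluded, and partial-error scoring is undefined on
  them.

## Exclusion pipeline and aggregation

Exclusion reasons are assigned in fixed priority order — starts_pressed →
no_response → too_fast (< 200 ms) → too_slow (above the task deadline:
1500 ms CIT, 2500 ms Sternberg) → error → target_trial — so that per-reason
counts partition the trials unambiguously (retained + Σ counts = total, an
invariant under test). Target trials are excluded from the CIT
probe-vs-irrelevant analyses but their outcomes (including partial errors)
are still computed. Participant summaries take mean/SD of RT and the
proportion of partial errors per item type over *retained* trials; an empty
cell is reported absent, never zero. The Sternberg performance filter drops
a participant when any item category falls strictly below 60% correct — a
boundary of exactly 60% keeps, reading "less than 60%" literally.

## Task designs

The CIT generator enforces: 5 information categories × 6 items (1 probe,
1 target drawn from the candidate pool, 4 irrelevants), every item exactly
once per 30-trial block, 3 practice blocks (deadlines 10 s/1.5 s/1.5 s,
slow-feedback thresholds 10 s/1.2 s/0.8 s) and 20 test blocks (deadline
1.5 s), response–stimulus intervals uniform on [500, 1000] ms, target items
mapped to the YES key. The practice pass rule fails a block when any item
type's accuracy is below 50% or the overall mean RT of responded trials
exceeds 800 ms; the repetition policy (up to 4 attempts) is metadata only.

The Sternberg generator emits exactly 60 match trials plus 48/12
(low-validity) or 18/42 (high-validity) intrusion/new trials in a seeded
order; each trial carries two fresh 3-word lists (blue/yellow), the probe
and its serial position; no word occurs twice anywhere in a session. Cue
color and serial position are balanced exactly over match and over intrusion
trials (the stated counts are all divisible by the 6 color × position
combinations; for other counts the generator falls back to maximal evenness
with seeded remainders — the general rule the code documents). New trials
balance cue color. These counts make the familiarity-only responder's
accuracy identically (60 + 12)/120 = 60% and (60 + 42)/120 = 85%, which the
acceptance script recomputes from generated designs.

## Simulator

Each simulated trial draws a threshold-crossing latency from a per-item-type
ex-Gaussian, rounded to the 1 ms grid; the responded key is a piecewise
linear ramp (default 80 ms rise) placed so that its first sample above .95
is exactly that latency, followed by a plateau and release. Latency is thus
*defined* as the > .95 crossing, making extracted RTs exactly comparable to
injected ones (the pipeline recovers them bit-for-bit, which the tests
exploit). With probability `p_partial` the incorrect key receives a
triangular aborted press with amplitude uniform on (0.05, 0.6) — capped
strictly below .95 so it can never register as a response — and duration
uniform on (40, 120) ms, onset near the responded key's movement onset and
clipped to end strictly before the crossing and to start after the 5 ms
guard window. No empirical distribution of partial-press amplitude or
duration is available, so these ranges are placeholders chosen to be
unambiguous for threshold logic, not biomechanically calibrated. Error
trials swap the roles of the two keys; lapses and beyond-deadline draws
produce no response; `starts_pressed_rate` injects a decaying residual
depression at t = 0 (and only those trials are flagged — an exactness the
tests assert). Kinematics are deliberately minimal: the detection logic is
threshold-based, so only crossing times and nonzero support matter; no
force/velocity realism is attempted.

Default generative parameters emulate the empirical pattern of the two
tasks: CIT means near 470 ms (irrelevant, ex-Gaussian 370/40/100) and
583 ms (probe, 430/50/150), partial rates 0.5% and 2.9%, low error rates;
Sternberg means near 941/1094/1216 ms for new/match/intrusion with partial
rates 0.2/1.7/1.7% and error rates dominating a ~16% exclusion fraction.
Target-trial parameters (higher partial and error rates) are an assumption —
only the direction is constrained by the observation that partial errors are
relatively frequent on target trials. What passing recovery tests show is
that the pipeline is an unbiased measure of the generative partial rate
under ideal threshold-shaped presses; they cannot show robustness to drift,
tremor, fingers hovering off the keys, or non-monotone press shapes that
real hands produce.

## Bayes factors

The mixed-ANOVA Bayes factors follow the default g-prior construction for
mixed models: sum-to-zero-projected fixed effects (Cauchy scale 0.5) and
participant random intercepts (scale 1), each effect batch with its own
relative variance g carrying an inverse-gamma(1/2, r²/2) prior; grand mean
and error variance get the Jeffreys prior. Conditional on g the marginal is
closed-form; the g integral is estimated by seeded Monte-Carlo sampling from
the prior (default 20,000 draws, batched Cholesky), with the Monte-Carlo
standard error of each log marginal reported and propagated to the log BFs.
Exact numerical parity with any particular software release is not claimed;
parity with the stated model is verified in the test suite against two
independent integration routes (tensor-grid Simpson quadrature in log g and
a 2¹⁷-point scrambled-Sobol quasi-Monte-Carlo oracle), which agree with the
implementation to well under ±0.1 on log BFs. The BFs are invariant to dv
location/scale and participant relabeling (tested), and null simulations
yield median evidence favoring the smaller model.

The t-test BF integrates the noncentral-t likelihood of the observed t
statistic against the Cauchy(0, .707) effect-size prior with adaptive
quadrature; one-sided variants truncate and renormalize the prior (the two
one-sided BFs average to the two-sided one, a tested identity). A degenerate
all-equal difference vector is an error, not a number.

The Bayesian signed-rank test is explicitly approximate: latent
normal-scale values constrained to the observed signs and absolute-value
ordering are Gibbs-sampled jointly with the effect size, and the point-null
BF is a Rao-Blackwellized Savage–Dickey ratio at δ = 0, rescaled by the
posterior directional mass for one-sided hypotheses. With strong effects
the density at 0 is tiny and its log estimate noisy; the result should be
read as an order of magnitude.

## Ex-Gaussian fitting

Likelihood-based (scipy's `exponnorm`), not MCMC: per-cell MLE over
(μ, log σ, log β) by Nelder–Mead from moment-based starts, standard errors
from a central-difference observed-information matrix; the regression
structure ties cells with fixed effects (μ ~ item type × partial, log σ and
log β ~ main effects); the hierarchical variant adds Gaussian random
intercepts on μ for participant and stimulus category by penalized (MAP)
likelihood with the random SDs profiled jointly — a deliberate, documented
approximation to a full Bayesian mixed model, which is out of scope. Cells
need ≥ 50 RTs by default (overridable); all-equal RTs flag non-convergence
rather than raising; the fitted density's unit integral is checked
numerically in tests. Recovery at n = 10,000 from (500, 50, 100) lands
within 3 standard errors, and the moment identities mean = μ̂ + β̂,
variance = σ̂² + β̂² hold on converged fits.

## Problem sizes and seeds

All randomness flows through integer seeds (numpy `SeedSequence` derivation
per participant), and fixed seeds reproduce event logs byte-for-byte. The
test suite uses the study-scale configurations where the claim depends on
them — 35 virtual participants × 600-trial CIT designs across 10 replicates
for rate recovery, ≥10,000 trials for the detection-rule equivalence,
n = 10,000 for ex-Gaussian recovery — and smaller sizes (6–20 participants,
a few thousand Monte-Carlo draws) where only direction or invariance is at
stake.

## Known limitations

- The detection rules assume the two declared response keys are the only
  relevant channels; stray presses of other keys are ignored by design.
- The partial-press amplitude/duration defaults are placeholders (see
  above); conclusions about real-hand sensitivity do not follow.
- The signed-rank BF construction is one of several reasonable
  data-augmentation schemes; it is labeled approximate in its result object.
- The hierarchical ex-Gaussian uses penalized likelihood, which shrinks
  random-effect SDs relative to marginal (integrated) ML.
- Live keyboard capture, vendor SDKs and OS key events are out of scope;
  the package starts from recorded change-event logs.
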