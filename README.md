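# partialpress

Partial-error detection from analog keyboard trajectories in
response-conflict tasks.

## The problem

In speeded response-conflict tasks, the losing response channel often becomes
partially active before the correct response wins: electromyography picks
these *partial errors* up as sub-threshold muscle bursts on the incorrect
effector. Analog gaming keyboards offer a far cheaper window on the same
phenomenon: every key reports a continuous depression value in [0, 1] at
1000 Hz, so an aborted press of the incorrect key is directly observable.
This matters for the reaction-time Concealed Information Test (RT-CIT), where
slower responses to concealed *probe* items than to matched *irrelevant*
items are attributed to response conflict, and for cued recognition tasks
like the modified Sternberg task, where *intrusion* probes (familiar, but in
the wrong list) induce the same familiarity–recollection conflict.

`partialpress` is the complete desk-side toolchain for this measurement:

- **`keystream`** — data model and I/O for change-only event logs
  (timestamp, key, analog value recorded only when it changes) and
  reconstruction of the continuous per-key signal by zero-order hold;
- **`trialproc`** — trial outcomes: the response is the first analog value
  **> .95** within the deadline; a **partial error** is scored when both
  response keys show values **> 0** strictly before that crossing; trials
  starting with a pressed key (value > 0 in the first 5 ms) are flagged;
  the standard exclusion pipeline (RT < 200 ms, RT above the task deadline,
  response errors, target trials) and participant-level aggregation;
- **`taskgen`** — exact generators for the RT-CIT design (5 categories × 6
  items; 3 practice blocks of 30; 600 test trials = 100 probes + 100 targets
  + 400 irrelevants) and the modified Sternberg design (120 trials; 50%
  match; 40/10 or 15/35 % intrusion/new by cue-validity condition; balanced
  cue colors and serial positions; no word repeated);
- **`simulate`** — a generative model with ex-Gaussian threshold-crossing
  latencies and injectable incorrect-key partial presses, with ground truth
  for recovery testing;
- **`stats`** — JZS (Cauchy-prior) Bayes factors for the mixed-effects ANOVA
  and the one-sided t test, an approximate Bayesian signed-rank test,
  maximum-likelihood ex-Gaussian fitting, the arcsine transform and LexTALE
  scoring;
- **`cli`** — `partialpress simulate | process | analyze` to run the whole
  pipeline from a shell.

## Statistical core

Participant mean RTs (or partial-press proportions) per item type enter a
two-factor Bayesian mixed ANOVA. With participant random intercepts
`u ~ N(0, g_u σ²)` and standardized fixed effects carrying JZS priors
(Cauchy scale 0.5; equivalently normal slabs with inverse-gamma(1/2, r²/2)
mixing on g), marginal likelihoods of the nested models

    Null (participant) ⊂ Fam (+ between) ⊂ Main (+ item type) ⊂ Full (+ interaction)

are computed by seeded Monte-Carlo integration over the g parameters (the
conditional marginal given g is closed-form after integrating effects, grand
mean and σ² under the Jeffreys prior). `BF(Main, Fam)` is the evidence for
the item-type effect; `BF(Full, Main)` the evidence for its moderation by
group. The paired t-test Bayes factor integrates the noncentral-t likelihood
against a Cauchy(0, .707) prior on the effect size, one-sided by truncation.
RT distributions are summarized by the ex-Gaussian (Gaussian μ, σ convolved
with an exponential of mean β; mean = μ + β, variance = σ² + β²), fitted by
MLE with log links on σ and β, optionally with fixed effects of item type ×
partial-error status and penalized random intercepts.

## Worked example

```sh
partialpress simulate --task cit --condition low --seed 7 --participants 8 --out runs/demo
partialpress process  --task cit --out runs/demo
partialpress analyze  --task cit --out runs/demo --seed 7
```

prints

```
simulated 8 participant(s), 4800 test trials -> runs/demo
processed 4800 trials; exclusions: error=127, no_response=2, target_trial=738
log BF Fam vs Null: -0.005
log BF Main vs Fam: 20.485
log BF Full vs Main: 0.002
report -> runs/demo/report.json
```

Reading the report: of 4800 simulated trials, 18.1% were excluded (738
target trials plus errors and misses). The retained cells give participant
mean RTs of 471 ms (irrelevant) versus 568 ms (probe) and mean partial-press
proportions of 0.6% versus 2.2% — the simulated conflict effect. The ANOVA
on mean RTs yields log BF(Main, Fam) = 20.5 (BF ≈ 8·10⁸): overwhelming
evidence for the item-type effect, while log BF(Full, Main) ≈ 0 correctly
reports no interaction evidence (this run has a single condition, so the
between factor is inert and BF(Fam, Null) ≈ 1). Monte-Carlo errors of every
log BF are in `report.json`.

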