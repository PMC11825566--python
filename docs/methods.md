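# Methods

## Models

### Diffusion Model of Conflict (DMC)

Evidence `X(t)` accumulates from `x0 = 0` between symmetric absorbing
boundaries `±b` (upper = correct) with time-dependent drift and constant
diffusion:

    dX = μ_cond(t) dt + σ dW.

The controlled process contributes a constant drift `μ_c`; the automatic
process contributes the derivative of the expected pulse activation

    E(t) = A · exp(−t/τ) · [ t·e / ((a−1)·τ) ]^(a−1),

a rescaled-gamma pulse that vanishes at `t → 0` and `t → ∞` and attains
its maximum `A` exactly at `t* = (a−1)·τ`.  The condition drift is
`μ_c + E'(t)` (congruent), `μ_c` (neutral), `μ_c − E'(t)` (incongruent),
so congruent and incongruent drifts mirror around the neutral one at every
instant.  RT adds a non-decision time drawn from `N(t_er, sd_er)`
truncated below zero by resampling.

Defaults (all configurable): `A = 20`, `a = 2`, `μ_c = 0.5` evidence/ms,
`σ = 4` evidence/√ms, `t_er = 300 ± 30` ms, `dt = 1` ms, censoring at
2500 ms (the response window).  Pulse timing distinguishes tasks:
`τ = 150` ms (late peak, flanker/Stroop presets) and `τ = 30` ms (early
peak, Simon preset).  The response-focus manipulation changes only the
boundary: 31.30 (speed) / 71.30 (accuracy) for the flanker-type preset
and 34.56 / 74.56 for the Simon-type preset, with the balanced focus at
the midpoint of the two anchors since no balanced value is printed
anywhere; midpoint interpolation is the least-committal monotone choice.

### Shrinking Spotlight Model (SSP)

Attention over the standard five-item flanker display (unit-width items,
target spanning [−0.5, 0.5]) is a centered Gaussian whose SD shrinks
linearly, `s(t) = max(sd0 − r·t, sd_min)`.  Each item's attention share
is the Gaussian mass over its interval (evaluated with the normal CDF);
the drift is

    v(t) = p·[target share] + s_f · p·[inner + outer shares],

with `s_f = +1 / 0 / −1` for congruent / neutral / incongruent — neutral
flankers carry perceptual input with no response signal, hence contribute
nothing to the drift.  Early in incongruent trials the flanker shares
outweigh the target and `v(t) < 0`; the drift crosses zero exactly once
as the spotlight narrows.  Accumulation, boundaries, non-decision time
and censoring follow the same contract as DMC.

Defaults: `p = 8` evidence/ms, `sd0 = 1.8`, `r = 0.01` widths/ms,
`sd_min = 0.001`, `σ = 100` evidence/√ms, boundaries 2000 (speed) /
3000 (balanced) / 4000 (accuracy).  The two outer boundary values are
the printed anchors; the remaining scale parameters were calibrated once
so that speed-focus accuracy falls in the band observed empirically
(~80–90% across conditions) with realistic RTs, and are not tuned
thereafter.

### Numerical scheme

Euler–Maruyama with `dt = 1` ms; the drift is precomputed on the step
grid at midpoints `(k + ½)·dt`, which halves the weak discretization bias
of the left endpoint and keeps evaluation strictly inside the pulse's
domain (`t > 0`).  A walk is absorbed when it touches either boundary at
the end of a step; unabsorbed walks at the censoring horizon are recorded
as omissions (no RT, incorrect).  Noise is consumed only by active walks,
so identical drift laws under one seed give bitwise identical
trajectories — this makes the `A = 0` collapse of the three congruency
conditions an exact identity rather than a statistical one.

## Synthetic SAT experiments

The generator reproduces the three experimental protocols: letter flanker
(60 practice, 54 trials/block, 10 blocks per focus: 1620 test trials),
numeric Stroop (72 practice, 72 × 8) and dot Simon (60 practice, 60 × 7).
Block order is a uniform permutation of the focus multiset; within a
block the congruency counts are exact (equal thirds by default — the only
split consistent with all three block sizes — and configurable).

A participant first completes practice at the balanced boundary; the
deadlines are then `mean − SD` (speed), `mean + SD` (balanced) and
`mean + 3·SD` (accuracy) of the practice RTs (sample SD).  After every
block the deadline of that block's focus is updated by a proportional
controller, `d ← d·(1 − g·(observed − target))` with gain `g = 0.5`,
floored at 150 ms, toward the target accuracies 65% / 82% / 97.5%.
Responses slower than the deadline are recorded and only marked
(`exceeded_deadline`), mirroring the notify-but-keep protocol; responses
under 150 ms are flagged as anticipatory.

Cohorts perturb each participant's primary drift parameter (`μ_c` or
`p`) and mean non-decision time with independent normal draws (defaults:
SD 0.05 evidence/ms for `μ_c`, 0.8 evidence/ms for `p`, 20 ms for
`t_er`), giving between-participant mean-RT spreads of a few tens of ms.
Per-participant seeds derive from the cohort seed and index, so a cohort
is exactly the concatenation of its individually generated members.

What the generator does *not* emulate: the deadline does not feed back
into the simulated decision process (the boundary per focus is fixed), so
observed accuracy reflects the boundary, not the deadline — under the
defaults the speed-focus deadline walks to its floor without pulling
accuracy to 65%.  It also omits sequence effects (congruency-sequence /
post-error slowing), practice-induced parameter drift, and stimulus
identity.  Passing tests on synthetic cohorts therefore validate the
analysis chain and the models' distributional signatures, not the
behavioral realism of deadline adaptation.

## Analysis chain

- **Filtering.** No trial is excluded by RT.  Participants are removed
  when overall accuracy < 75% (printed criterion) or when more than 10%
  of responses are flagged < 150 ms (this package's operationalization of
  the flag-and-evaluate rule; configurable).  RT analyses use correct,
  non-omitted trials; error analyses use all responded trials.
- **Quantiles.** Linear interpolation of order statistics with the k-th
  of n values at probability (k−1)/(n−1) (numpy's `linear` method),
  fixed explicitly so outputs are bit-comparable across implementations.
  Grids: ten percentiles 5%…95% (default) or eight 6.25%…93.75% (used
  when per-cell trial counts are too small for ten).
- **Delta curves.** Per participant × focus, `d_fac`, `d_inh`, `d_cong`
  from the three conditions' quantiles; the abscissa is the mean of the
  three condition quantiles (the two-condition mean is available as an
  alternative).  Group curves are Vincentized means; the additivity
  identity survives averaging by linearity.
- **Percent-error (CAF) deltas.** Within each condition, responded trials
  are rank-split into five equal-count RT bins (the discrete counterpart
  of within-condition quantile edges; exact conservation of the overall
  error rate under ties), centered at 10%…90%.
- **ANOVA.** Classical balanced fully-within-subject decomposition, each
  effect tested against its own subject × effect interaction;
  partial η² = SS_effect / (SS_effect + SS_error).  Replicates collapse
  to subject × cell means.  No sphericity correction by default (matching
  the integer degrees of freedom reported in this literature); a
  Greenhouse–Geisser option estimates Box's ε from the covariance of
  orthonormal effect contrasts and deflates both dfs.  The implementation
  is cross-checked in the tests against statsmodels' `AnovaRM` on random
  tables and against a hand-computed sums-of-squares oracle on toy data.

## Design choices on genuinely open points

- Balanced-focus boundaries (midpoints of the printed anchors) and the
  proportional deadline controller are this package's choices; neither is
  specified by the protocols the generator emulates.
- Practice runs at the balanced boundary (nothing else is defensible
  before the SAT instructions are introduced).
- Deadline adaptation is per block, the natural granularity of the
  blocked focus manipulation.
- The statistical power of the three-way (focus × congruency ×
  percentile) interaction test is verified on a parametric generator of
  Vincentized quantile tables with a boundary-dependent congruency slope,
  rather than on replicate diffusion cohorts, keeping the check at
  desk scale; the effect magnitudes mimic the flanker-task interaction
  (congruency-slope differences of 10–40 ms across foci against ~12 ms
  quantile noise).

## Known limitations

- No parameter fitting: the simulators are generative only.
- DMC/SSP scale parameters beyond the printed boundary anchors are
  calibrated defaults, so quantitative simulator output is meaningful in
  pattern (slopes, orderings, convergence), not in absolute ms values.
- The dual-stage (DSTP) model, starting-point variability and
  trial-to-trial drift variability are not modeled.
- Under the default SSP scaling the inhibition delta curve spikes early
  and then plateaus; a strict decline at the far tail is below
  Monte-Carlo resolution at 100,000 trials per condition.
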