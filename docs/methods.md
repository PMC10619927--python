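# Methods

`chemloop` closes the loop between a recipe-proposing optimizer and a
simulated robotic batch-reactor laboratory. This note records the models,
the calibration of the simulator, the numerical choices, and what the
synthetic benchmark does and does not demonstrate.

## The optimization problem

A campaign searches a discrete condition space — one categorical choice per
role (catalyst, ligand, base, solvent), with the reaction temperature tied
to the solvent — for a condition whose measured conversion yield meets a
target. The target is conventionally set as the reference recipe's
conversion plus a 5-point margin (`target_from_reference`). Spaces are
products of per-role candidate lists minus explicit exclusion patterns;
exclusions are first-class because realistic screens rule out specific
combinations (insoluble bases in certain solvents, incompatible
ligand/metal pairings), and because it lets a fixture hit an exact
condition count such as 2722.

## Surrogate model

The surrogate is a Gaussian process over per-role level indices with the
sum kernel

    k(c, c') = sigma^2 * exp( - sum_r w_r * (1 - [c_r = c'_r]) )
               + tau^2 * sum_r [c_r = c'_r]

plus i.i.d. observation noise. The exponential term is a
squared-exponential over the weighted role-Hamming distance and carries the
interaction structure; the linear term is exactly a Bayesian ridge over
additive per-role level effects (a linear kernel on the one-hot encoding).
The linear term matters: a pure overlap kernel cannot push its posterior
mean above the best observed yield, so an optimizer built on it degrades to
coordinate-wise hill climbing. With the additive component the posterior
extrapolates to untried combinations of individually favorable levels —
the defining structure of reaction-condition landscapes — while still
reporting honest uncertainty for levels never observed. (A fitted ridge
*mean function* was considered and rejected: without propagating
coefficient uncertainty it collapses the posterior sd at unexplored levels
and starves exploration.)

Hyperparameters (four role weights, sigma^2, tau^2, noise variance) are fit
by maximizing the marginal likelihood with L-BFGS-B from five seeded
restarts, re-optimized after every result while fewer than ~12 observations
exist and every third result afterwards; the posterior is re-conditioned on
every result regardless. The GP is centred on the weighted mean of the
observations; with no data the prior mean is a deliberately pessimistic
20 % conversion. The surrogate sits behind a small interface
(`posterior(levels) -> (mean, sd)`), so a learned condition-recommendation
model — the role played by a reaction-database-trained neural network in a
production system — can be dropped in without touching the loop.

## Proposals, acquisition, and the recipe repository

Cold start: three recipes by prior ranking (a constant prior degenerates to
lexicographic order) plus three from a greedy maximin design under
role-Hamming distance — the categorical analogue of space-filling
Latin-hypercube initialization. The maximin half is anchored on the
prior-ranked picks (it maximizes its minimum distance to them as well), so
the six probes jointly cover the space. Warm batches: three
top-posterior-mean conditions (exploitation) plus three top
expected-improvement conditions (exploration, with conditions containing a
never-observed candidate screened first), de-duplicated against everything
tried or currently running.

Proposals land in the recipe repository scored by their expected
improvement; dispatch always takes the maximum-score pending entry, ties
lexicographic. After every completed or withdrawn run the surrogate is
updated, stale pending entries of the route are cancelled, and a fresh
batch is inserted, so the queue always reflects the latest posterior.
Withdrawn runs enter the training set at their forecast plateau with weight
0.5 (their noise variance is doubled); completed runs at their final
measured conversion with weight 1.

## Decision policy

Each new sample triggers a three-way decision with fixed precedence:
TargetMet (last measurement at or above target) always wins; fewer than 3
samples is always Continue; Withdraw requires BOTH a pessimistic forecast
(fitted plateau plus twice its standard error below target minus a 5-point
margin) and a stalled recent slope (< 0.5 %/h) — the conjunction protects
slow-but-high reactions; Sweep fires when a route has at least 10 finished
recipes and its best conversion is under half the target, cancelling the
route's queue and activating the next-ranked route. The orchestrator
suppresses Sweep when no further route exists, since the signal means
"switch to another synthetic path". All thresholds live in `PolicyConfig`
and are recorded in the campaign log.

Plateau forecasting fits y(t) = Yinf (1 - e^(-k t)) by nonlinear least
squares with multi-start initialization (Yinf in {last, 1.2 x last}, k in
{0.1, 0.5, 2} / h, bounds Yinf in [0, 120], k in (0, 50]). Fewer than three
samples is underdetermined and an all-zero trajectory degenerate; both fall
back to the last measured value.

## Virtual laboratory

Ground truth per condition is first-order saturating kinetics
y(t) = Yinf (1 - e^(-kt)) — the simplest law consistent with monotone
conversion-versus-time curves; k is drawn log-uniformly from [0.3, 2] / h.
The plateau surface is additive per-role main effects (sd 9) around a 45 %
baseline plus weak pairwise interactions (sd 2), clipped to [0, 100]; the
additive argmax is pinned at 100 %. Under these defaults roughly 0.2–0.4 %
of a 2722-condition space reaches >= 95 % conversion — a handful of
near-quantitative combinations per screen, and the best of them combines
individually favorable reagent choices, which is the structure that makes
surrogate-guided search effective in practice. Scenario fixtures
additionally pin a designated reference condition to a prescribed
conversion (86.5 %, 15.0 % or 50.9 %) purely as a scenario parameter; no
claim is made about the underlying chemistry.

Noise has two calibrated sources. Dispensing is normal around the target
mass with CV 2.55 % (floor 0.05 mg), truncated at zero; the pooled (mean)
relative error of the catalyst, ligand and base dispenses shifts the run's
effective (Yinf, k) multiplicatively through `effect_gain` (default 0.5).
Measurement is multiplicative normal error per sample with a CV that
shrinks linearly from 3.5 % at t = 0 to 1.2 % at the scheduled end,
reflecting the better reproducibility of converged readings; measured
conversions are clipped to [0, 100] and reported at 0.01 % resolution.
These values are calibrated so that a 12-replicate study reproduces the
reproducibility envelope of a well-tuned robotic platform: dispensing MAE
well under 0.73 mg at 10–30 mg targets, yield CV below 5 % at every
monitored time and below 2.5 % once trajectories converge — with the
margin real instruments show against such bounds. Setting the measurement
CV equal to the bounds themselves would make half of all replicate studies
breach them, since the dispensing-induced plateau spread (~0.7 % relative)
adds to the measurement term and a 12-sample CV estimate fluctuates by
~20 % relatively.

The simulator does not model side products, mass balance of byproducts,
temperature ramps, pressure, LC-MS peak-area arithmetic or analysis
latency; it emits conversion yield directly.

## Scheduling

Simulated time is event-driven: a deterministic queue orders events by
(time, class, insertion order) with analysis before dispatch before
decision at equal times. Six reactor slots run independently; the dispenser
and the sampler are single shared resources with fixed service times
(0.25 h per dispense sequence, 0.05 h per sample analysis). Every source of
randomness derives from the campaign master seed through fixed spawn keys,
so a rerun reproduces the JSON-lines run log byte for byte. Withdrawn
trials count against the trial budget (they consume reactor time); a swept
route is never revisited.

## The synthetic benchmark: what it shows

The m1-like benchmark (7 x 8 x 7 x 8 candidates, 414 auto-generated
exclusions, exactly 2722 conditions) measures trials-to-target with target
= planted optimum − 5 points over 20 seeded landscapes, against paired
uniform-random search with the same stopping rule and a 136-trial (5 %)
budget. Campaign sizes were chosen so the whole benchmark runs in a few
minutes on one CPU. Passing it shows that the closed loop exploits additive
landscape structure far better than unguided search under calibrated noise;
it does not show anything about real chemistry — reagent identities, the
reference conversions, and the targets are scenario parameters, the
landscape is synthetic, and a learned chemistry-aware surrogate would be
needed for transfer to a real screen.

## Known limitations

- The surrogate's additive+overlap kernel cannot represent strong
  three-way reagent interactions; landscapes dominated by them would blunt
  the efficiency advantage.
- Plateau forecasts from three early samples are optimistic for strongly
  sigmoidal (induction-period) kinetics, which first-order trajectories do
  not produce; the Withdraw rule inherits that assumption.
- The scheduler models only slot/dispenser/sampler contention with fixed
  service times; throughput claims about a physical platform are out of
  scope.
- Exact-size spaces are produced by excluding full assignments; partial
  (slab) exclusion patterns are supported in configuration but not used by
  the generated fixtures.
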