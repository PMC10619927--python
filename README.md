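# chemloop

Closed-loop optimization of reaction conditions against a simulated robotic
batch-reactor laboratory.

Autonomous synthesis platforms search a discrete space of reaction
conditions — one categorical choice per role (catalyst, ligand, base,
solvent, with the temperature fixed by the solvent) — for a recipe whose
measured conversion yield meets a target, typically the reference recipe's
conversion plus a 5-point margin. `chemloop` implements the full software
loop of such a platform and closes it against a calibrated virtual
laboratory, so the search strategy, decision policy and scheduler can be
developed and benchmarked with no robot:

- **chem_space** — condition spaces (products of candidate lists minus
  exclusions), deterministic enumeration, one-hot/descriptor featurization,
  and greedy multi-start maximin designs under the role-Hamming distance;
- **recipe_engine** — quantification of abstract recipes into
  human-readable action sequences (solid mass = mmol x equivalents x
  MW / purity; volumes via density or molarity; ligand equivalents default
  to twice the catalyst's) and their translation into symbolic robot
  commands under a hardware profile;
- **virtual_lab** — seeded yield landscapes with first-order kinetics
  y(t) = Y∞(1 − e^(−kt)), dispensing noise (CV 2.55 %, truncated normal)
  that perturbs the effective (Y∞, k), and measurement noise whose CV
  shrinks as trajectories converge; 12-replicate studies reproduce a
  dispensing MAE ≤ 0.73 mg and yield CVs under 5 % (under 2.5 % at
  converged timepoints);
- **hdo_optimizer** — a Gaussian-process surrogate over conditions with a
  categorical-overlap kernel plus a linear (additive per-role effect)
  component, expected-improvement acquisition, batched proposals (3
  exploitation + 3 exploration) and the ranked recipe repository;
- **decision_policy** — plateau forecasting by nonlinear least squares on
  y(t) = Y∞(1 − e^(−kt)) and Continue / Withdraw / Sweep / TargetMet
  signals with explicit, logged thresholds;
- **orchestrator** — an event-driven six-slot scheduler running the whole
  campaign deterministically from one seed, with a JSON-lines run log;
- **io_fixtures** — reagent-library CSV and campaign YAML I/O, run-log
  round-tripping, and seeded scenario fixtures, including a
  2722-condition space built from 7 x 8 x 7 x 8 candidates and 414
  exclusions.

See `docs/methods.md` for the models, the noise calibration and the design
choices.

## Worked example

Run a small campaign on the bundled 16-condition scenario:

```
$ chemloop campaign --profile tiny --seed 4 --target 95 --max-trials 16
          trials  best_yield  fraction_pct  completed  withdrawn  swept_runs  cancelled  route_swept
route_id
tiny-1        12       99.11          75.0          1          6           0          5        False
tiny-2         0         NaN           0.0          0          0           0          0        False
termination: target_met   best yield: 99.11 %   trials: 12 (37.50 % of space)
```

Twelve recipes were dispatched onto the six reactor slots; six were
withdrawn early by the decision policy (plateau forecast below target and
stalled slope), one measured 99.11 % conversion, meeting the 95 % target,
which ended the campaign with five queued-or-running recipes cancelled. The
second, lower-ranked route was never needed. Adding `--outdir out/` writes
the schema-versioned run log (`runlog.jsonl`) and the summary CSV;
`chemloop report out/runlog.jsonl` regenerates the same table from the log
alone.

The other subcommands expose the pieces: `chemloop enumerate` (space size
and lexicographic enumeration), `chemloop design -k 6` (maximin initial
design), `chemloop simulate` (one yield trajectory), and
`chemloop replicates -n 12` (reproducibility study with per-timepoint CVs
and dispensing error statistics).

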