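"""Closed-loop campaign execution.

Runs the full loop: the recipe repository is seeded from a cold-start
batch, six simulated reactor slots draw the highest-ranked pending recipe,
sampling events feed the decision policy, terminal results update the
surrogate and refresh the repository, and route switching follows Sweep
signals — until the target conversion is met, the trial budget is spent, or
every space is exhausted.

Time is simulated and event-driven: a deterministic priority queue orders
events by (time, event-class, insertion order) with analysis events
processed before dispatches and dispatches before decisions at equal
simulated times.  The dispenser and the sampler are single shared resources
with fixed service times; reactor slots are the only parallel resource.
The whole campaign is reproducible from its master seed, and every event is
appended to a schema-versioned JSON-lines-ready run log.
"""

from __future__ import annotations

import hashlib
import heapq
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .chem_space import Condition, ConditionSpace, enumerate_conditions
from .decision_policy import DecisionSignal, PolicyConfig, RouteHistory, assess, estimate_plateau
from .hdo_optimizer import (
    KernelConfig,
    Observation,
    RecipeRepository,
    SpaceExhausted,
    SurrogateState,
    expected_improvement,
    fit_surrogate,
    propose_batch,
    update_repository,
)
from .recipe_engine import RecipeSpec, quantify
from .virtual_lab import NoiseConfig, RunRecord, YieldTrajectory, simulate_reaction

logger = logging.getLogger("chemloop.orchestrator")

__all__ = [
    "Route",
    "CampaignConfig",
    "CampaignResult",
    "SimulatedLab",
    "EventQueue",
    "Event",
    "run_campaign",
    "formal_run_records",
    "random_baseline",
    "summarize",
    "report_from_log",
    "target_from_reference",
]

LOG_SCHEMA_VERSION = 1

#: default goal-setting margin: target = reference conversion + 5 points
TARGET_MARGIN_PCT = 5.0


def target_from_reference(reference_yield: float, margin: float = TARGET_MARGIN_PCT) -> float:
    """Campaign target = reference recipe's conversion plus a safety margin."""
    if not 0 <= reference_yield <= 100:
        raise ValueError("reference yield must be a percentage in [0, 100]")
    return reference_yield + margin


@dataclass(frozen=True)
class Route:
    """One synthetic route: a ranked reaction scheme with its own condition
    space and stoichiometry template (ranks come from upstream synthesis
    planning and are consumed as input)."""

    route_id: str
    rank: int
    label: str
    space: ConditionSpace
    reactant1: str
    amount_mmol: float = 0.5
    co_reactants: tuple[tuple[str, float], ...] = ()
    catalyst_equiv: float = 0.05
    ligand_equiv: float | None = None
    base_equiv: float = 2.0
    concentration: float = 0.2
    max_duration: float = 8.0
    sampling_schedule: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0)

    def make_spec(self, condition: Condition, recipe_id: str, target_yield: float) -> RecipeSpec:
        return RecipeSpec(
            recipe_id=recipe_id,
            route_id=self.route_id,
            step_index=0,
            reactant1=self.reactant1,
            amount_mmol=self.amount_mmol,
            condition=condition,
            co_reactants=self.co_reactants,
            catalyst_equiv=self.catalyst_equiv,
            ligand_equiv=self.ligand_equiv,
            base_equiv=self.base_equiv,
            concentration=self.concentration,
            max_duration=self.max_duration,
            sampling_schedule=self.sampling_schedule,
            target_yield=target_yield,
        )


@dataclass(frozen=True)
class CampaignConfig:
    target_yield: float = 90.0
    max_trials: int = 100
    n_slots: int = 6
    n_exploit: int = 3
    n_explore: int = 3
    seed: int = 0
    policy: PolicyConfig = PolicyConfig()
    noise: NoiseConfig = NoiseConfig()
    kernel: KernelConfig = KernelConfig()
    withdrawn_weight: float = 0.5
    dispense_service_h: float = 0.25
    sample_service_h: float = 0.05
    revisit_swept: bool = False
    #: re-optimize kernel hyperparameters every this many terminal results
    #: (the posterior is re-conditioned on every result regardless)
    hyperopt_every: int = 3

    def __post_init__(self) -> None:
        if self.max_trials < 1 or self.n_slots < 1:
            raise ValueError("max_trials and n_slots must be >= 1")


class SimulatedLab:
    """Virtual robot layer bound to one landscape per route; an optional
    reagent library lets the orchestrator quantify and fingerprint the
    action sequence of every dispatched recipe."""

    def __init__(self, landscapes: dict, noise: NoiseConfig = NoiseConfig(), library: dict | None = None):
        self.landscapes = landscapes
        self.noise = noise
        self.library = library

    def trajectory(self, route_id: str, spec: RecipeSpec, seed) -> YieldTrajectory:
        return simulate_reaction(spec, self.landscapes[route_id], self.noise, seed)

    def space_size(self, route_id: str) -> int:
        return len(self.landscapes[route_id].conditions)


# ---------------------------------------------------------------------------
# Event queue
# ---------------------------------------------------------------------------

#: event-class priority at equal simulated time
_EVENT_PRIORITY = {"draw": 0, "analysis": 0, "dispatch": 1, "decision": 2}


@dataclass(frozen=True)
class Event:
    time: float
    kind: str
    payload: dict


class EventQueue:
    """Deterministic event ordering by (time, class priority, insertion order)."""

    def __init__(self) -> None:
        self._heap: list[tuple[float, int, int, Event]] = []
        self._seq = 0

    def push(self, time: float, kind: str, payload: dict | None = None) -> None:
        ev = Event(time=time, kind=kind, payload=payload or {})
        heapq.heappush(self._heap, (time, _EVENT_PRIORITY[kind], self._seq, ev))
        self._seq += 1

    def pop(self) -> Event | None:
        if not self._heap:
            return None
        return heapq.heappop(self._heap)[3]

    def __len__(self) -> int:
        return len(self._heap)


def schedule_event_queue(queue: EventQueue) -> Event | None:
    """Pop the next event under the strict (time, class, insertion) order."""
    return queue.pop()


# ---------------------------------------------------------------------------
# Campaign state
# ---------------------------------------------------------------------------


@dataclass
class _Run:
    run_id: str
    trial_index: int
    route_id: str
    spec: RecipeSpec
    slot: int
    seed: int
    full_trajectory: YieldTrajectory  # ground-truth draw, revealed sample by sample
    sequence_digest: str = ""
    revealed: list[tuple[float, float]] = field(default_factory=list)
    active: bool = True
    disposition: str | None = None  # completed | withdrawn | swept | cancelled

    def revealed_trajectory(self, status: str = "running") -> YieldTrajectory:
        return YieldTrajectory(self.spec.recipe_id, list(self.revealed), status)


@dataclass
class _RouteState:
    route: Route
    conditions: list[Condition]
    history: list[tuple[Condition, float]] = field(default_factory=list)
    observations: list[Observation] = field(default_factory=list)
    surrogate: SurrogateState | None = None
    hyperparams: tuple | None = None
    n_at_last_hyperopt: int = -(10**9)
    stats: RouteHistory = field(default_factory=RouteHistory)
    swept: bool = False
    exhausted: bool = False
    dispatched_keys: set = field(default_factory=set)


@dataclass
class CampaignResult:
    termination: str  # target_met | budget_exhausted | spaces_exhausted
    best_yield: float
    best_condition: Condition | None
    best_route: str | None
    trials_used: int
    trials_to_target: int | None
    fraction_evaluated: float
    per_route: dict
    run_records: list
    log: list
    target_yield: float
    total_space_size: int


class _Campaign:
    def __init__(self, routes: Sequence[Route], lab: SimulatedLab, config: CampaignConfig):
        if not routes:
            raise ValueError("at least one route is required")
        ranks = [r.rank for r in routes]
        if len(set(ranks)) != len(ranks):
            raise ValueError("route ranks must be unique")
        self.routes = sorted(routes, key=lambda r: r.rank)
        self.lab = lab
        self.config = config
        self.queue = EventQueue()
        self.repo = RecipeRepository()
        self.route_states = {
            r.route_id: _RouteState(route=r, conditions=enumerate_conditions(r.space))
            for r in self.routes
        }
        self.active_idx = 0
        self.slots: list[_Run | None] = [None] * config.n_slots
        self.runs: list[_Run] = []
        self.trials_used = 0
        self.trials_to_target: int | None = None
        self.best_yield = -1.0
        self.best_condition: Condition | None = None
        self.best_route: str | None = None
        self.termination: str | None = None
        self.log: list[dict] = []
        self.now = 0.0
        self.dispenser_free_at = 0.0
        self.sampler_free_at = 0.0
        self._fit_counter = 0

    # -- seeding -----------------------------------------------------------
    _SEED_TAGS = {"fit": 1, "design": 2, "run": 3}

    def _seed_for(self, tag: str, i: int) -> int:
        child = np.random.SeedSequence(entropy=self.config.seed, spawn_key=(self._SEED_TAGS[tag], i))
        return int(child.generate_state(1)[0] % (2**31))

    # -- logging -----------------------------------------------------------
    def _log(self, event: str, **fields) -> None:
        rec = {"schema_version": LOG_SCHEMA_VERSION, "t": round(self.now, 6), "event": event}
        rec.update(fields)
        self.log.append(rec)

    # -- proposals ---------------------------------------------------------
    def _active_state(self) -> _RouteState | None:
        while self.active_idx < len(self.routes):
            st = self.route_states[self.routes[self.active_idx].route_id]
            if not st.swept and not st.exhausted:
                return st
            self.active_idx += 1
        return None

    def _refresh_repository(self) -> None:
        """Cancel stale pending entries of the active route and insert a
        fresh batch ranked by the latest posterior."""
        st = self._active_state()
        if st is None:
            return
        route_id = st.route.route_id
        running = [r.spec.condition for r in self.runs if r.active and r.route_id == route_id]
        cold = not st.history
        if st.surrogate is None:
            st.surrogate = fit_surrogate([], self.config.kernel, seed=self._seed_for("fit", self._fit_counter))
        try:
            proposals = propose_batch(
                st.surrogate,
                st.route.space,
                st.history,
                n_exploit=self.config.n_exploit,
                n_explore=self.config.n_explore,
                seed=self._seed_for("design", self._fit_counter),
                exclude=running,
                pool=st.conditions,
            )
        except SpaceExhausted:
            if not running and not self.repo.pending(route_id):
                st.exhausted = True
                self._log("route_exhausted", route_id=route_id)
                self._refresh_repository()
            return
        self.repo.cancel_route(route_id)
        if cold:
            scores = [0.0] * len(proposals)
        else:
            # every queued entry is ranked by its expected improvement; the
            # batch itself is selected by posterior mean (exploitation half)
            # and EI (exploration half)
            best = max(y for _, y in st.history)
            scores = [
                float(expected_improvement(st.surrogate, st.route.space.level_indices(c), best))
                for c in proposals
            ]
        update_repository(self.repo, proposals, scores, route_id)
        self._log(
            "propose",
            route_id=route_id,
            cold_start=cold,
            conditions=[list(c.key()) for c in proposals],
            scores=[round(s, 6) for s in scores],
            surrogate={
                "n_obs": len(st.observations),
                "weights": [round(float(w), 6) for w in st.surrogate.weights],
                "signal_var": round(float(st.surrogate.signal_var), 6),
                "linear_var": round(float(st.surrogate.linear_var), 6),
                "noise_var": round(float(st.surrogate.noise_var), 6),
            },
        )

    # -- dispatch ----------------------------------------------------------
    def _free_slot(self) -> int | None:
        for i, s in enumerate(self.slots):
            if s is None:
                return i
        return None

    def _handle_dispatch(self) -> None:
        st = self._active_state()
        if st is None:
            return
        route_id = st.route.route_id
        while self.trials_used < self.config.max_trials:
            slot = self._free_slot()
            if slot is None:
                return
            entry = self.repo.dispatch(route_id)
            if entry is None:
                return
            self.trials_used += 1
            trial = self.trials_used
            recipe_id = f"{route_id}-r{trial:04d}"
            spec = st.route.make_spec(entry.condition, recipe_id, self.config.target_yield)
            entry.payload = spec
            seed = self._seed_for("run", trial)
            digest = ""
            if self.lab.library is not None:
                seq_text = quantify(spec, self.lab.library).to_text()
                digest = hashlib.sha256(seq_text.encode()).hexdigest()[:16]
            start = max(self.now, self.dispenser_free_at) + self.config.dispense_service_h
            self.dispenser_free_at = start
            run = _Run(
                run_id=recipe_id,
                trial_index=trial,
                route_id=route_id,
                spec=spec,
                slot=slot,
                seed=seed,
                full_trajectory=self.lab.trajectory(route_id, spec, np.random.default_rng(seed)),
                sequence_digest=digest,
            )
            self.slots[slot] = run
            self.runs.append(run)
            st.dispatched_keys.add(entry.condition.key())
            for j, t in enumerate(spec.sampling_schedule):
                self.queue.push(start + t, "draw", {"run": run, "sample_index": j})
            self._log(
                "dispatch",
                run_id=recipe_id,
                trial=trial,
                route_id=route_id,
                slot=slot,
                condition=list(entry.condition.key()),
                score=round(entry.score, 6),
                sequence_digest=digest,
                start_t=round(start, 6),
                seed=seed,
                n_running=sum(s is not None for s in self.slots),
            )

    # -- run termination ---------------------------------------------------
    def _finalize_run(self, run: _Run, disposition: str) -> None:
        run.active = False
        run.disposition = disposition
        self.slots[run.slot] = None
        st = self.route_states[run.route_id]
        traj = run.revealed_trajectory(status=disposition)
        final = traj.last_yield if run.revealed else 0.0

        if disposition == "completed":
            obs_yield, weight = final, 1.0
        else:  # withdrawn / swept: use the plateau forecast, down-weighted
            est = estimate_plateau(traj) if run.revealed else None
            obs_yield = float(np.clip(est.y_inf, 0.0, 100.0)) if est else 0.0
            weight = self.config.withdrawn_weight

        levels = st.route.space.level_indices(run.spec.condition)
        st.observations.append(Observation(levels=levels, yield_pct=obs_yield, weight=weight))
        st.history.append((run.spec.condition, obs_yield))
        st.stats.record(final)

        if final > self.best_yield:
            self.best_yield = final
            self.best_condition = run.spec.condition
            self.best_route = run.route_id
        self._log(
            "terminal",
            run_id=run.run_id,
            disposition=disposition,
            final_yield=final,
            model_yield=round(obs_yield, 4),
            weight=weight,
            n_samples=len(run.revealed),
        )
        if self.termination is None and disposition in ("completed", "withdrawn"):
            self._fit_counter += 1
            # refresh hyperparameters on every result while data is scarce,
            # then periodically
            due = (
                len(st.observations) <= 12
                or len(st.observations) - st.n_at_last_hyperopt >= self.config.hyperopt_every
            )
            if due or st.hyperparams is None:
                st.surrogate = fit_surrogate(
                    st.observations, self.config.kernel, seed=self._seed_for("fit", self._fit_counter)
                )
                st.hyperparams = (
                    st.surrogate.weights,
                    st.surrogate.signal_var,
                    st.surrogate.linear_var,
                    st.surrogate.noise_var,
                )
                st.n_at_last_hyperopt = len(st.observations)
            else:
                st.surrogate = fit_surrogate(
                    st.observations, self.config.kernel,
                    seed=self._seed_for("fit", self._fit_counter), hyperparams=st.hyperparams,
                )
            self._refresh_repository()
            self.queue.push(self.now, "dispatch")

    def _handle_sweep(self, route_id: str) -> None:
        st = self.route_states[route_id]
        st.swept = True
        n_cancelled = self.repo.cancel_route(route_id)
        swept_runs = [r for r in self.runs if r.active and r.route_id == route_id]
        for r in swept_runs:
            r.active = False
            r.disposition = "swept"
            self.slots[r.slot] = None
        self._log("sweep", route_id=route_id, cancelled=n_cancelled, swept_running=len(swept_runs))
        self._refresh_repository()
        self.queue.push(self.now, "dispatch")

    # -- event handlers ----------------------------------------------------
    def _handle_draw(self, run: _Run, sample_index: int) -> None:
        if not run.active or self.termination:
            return
        done_at = max(self.now, self.sampler_free_at) + self.config.sample_service_h
        self.sampler_free_at = done_at
        self.queue.push(done_at, "analysis", {"run": run, "sample_index": sample_index})

    def _handle_analysis(self, run: _Run, sample_index: int) -> None:
        if not run.active or self.termination:
            return
        t, y = run.full_trajectory.samples[sample_index]
        run.revealed.append((t, y))
        self._log("sample", run_id=run.run_id, sample_t=t, yield_pct=y)
        self.queue.push(self.now, "decision", {"run": run, "sample_index": sample_index})

    def _handle_decision(self, run: _Run, sample_index: int) -> None:
        if not run.active or self.termination:
            return
        st = self.route_states[run.route_id]
        signal = assess(run.revealed_trajectory(), run.spec, st.stats, self.config.policy)
        self._log("decision", run_id=run.run_id, signal=signal.value, sample_t=run.revealed[-1][0])
        last_sample = sample_index == len(run.spec.sampling_schedule) - 1

        if signal is DecisionSignal.TARGET_MET:
            if self.trials_to_target is None:
                self.trials_to_target = run.trial_index
            self._finalize_run(run, "completed")
            self._terminate("target_met")
        elif signal is DecisionSignal.WITHDRAW:
            self._finalize_run(run, "withdrawn")
        elif signal is DecisionSignal.SWEEP:
            # a Sweep means "switch to another synthetic path": with no
            # remaining route to switch to, the search continues instead
            has_next = any(
                not s.swept and not s.exhausted
                for rid, s in self.route_states.items()
                if rid != run.route_id
            )
            if has_next:
                if last_sample:
                    self._finalize_run(run, "completed")
                self._handle_sweep(run.route_id)
            else:
                self._log("sweep_suppressed", route_id=run.route_id)
                if last_sample:
                    self._finalize_run(run, "completed")
        elif last_sample:
            self._finalize_run(run, "completed")

    def _terminate(self, reason: str) -> None:
        self.termination = reason
        for run in self.runs:
            if run.active:
                run.active = False
                run.disposition = "cancelled"
                self.slots[run.slot] = None
        self._log("campaign_end", reason=reason, trials=self.trials_used, best_yield=self.best_yield)

    # -- main loop ---------------------------------------------------------
    def run(self) -> CampaignResult:
        self._log(
            "campaign_start",
            target_yield=self.config.target_yield,
            max_trials=self.config.max_trials,
            n_slots=self.config.n_slots,
            seed=self.config.seed,
            routes=[r.route_id for r in self.routes],
            policy=vars(self.config.policy),
            noise=vars(self.config.noise),
        )
        self._refresh_repository()
        self.queue.push(0.0, "dispatch")
        while self.termination is None:
            ev = schedule_event_queue(self.queue)
            if ev is None:
                if any(s is not None for s in self.slots):  # pragma: no cover
                    raise RuntimeError("running reactions with an empty event queue")
                st = self._active_state()
                if st is None:
                    self._terminate("spaces_exhausted")
                elif self.trials_used >= self.config.max_trials:
                    self._terminate("budget_exhausted")
                elif not self.repo.pending(st.route.route_id):
                    # nothing schedulable for the active route: treat as exhausted
                    st.exhausted = True
                    self._refresh_repository()
                    self.queue.push(self.now, "dispatch")
                else:  # pragma: no cover - pending entries imply a dispatch event
                    self.queue.push(self.now, "dispatch")
                continue
            self.now = ev.time
            if ev.kind == "dispatch":
                self._handle_dispatch()
            elif ev.kind == "draw":
                self._handle_draw(**ev.payload)
            elif ev.kind == "analysis":
                self._handle_analysis(**ev.payload)
            elif ev.kind == "decision":
                self._handle_decision(**ev.payload)
        return self._result()

    def _result(self) -> CampaignResult:
        total_size = sum(len(st.conditions) for st in self.route_states.values())
        per_route = {}
        for rid, st in self.route_states.items():
            runs = [r for r in self.runs if r.route_id == rid]
            finals = [(r.revealed[-1][1], r.spec.condition) for r in runs if r.revealed]
            best = max(finals, key=lambda p: p[0]) if finals else (float("nan"), None)
            per_route[rid] = {
                "best_yield": best[0],
                "best_condition": best[1],
                "trials": len(runs),
                "fraction_pct": 100.0 * len(runs) / len(st.conditions),
                "dispositions": pd.Series([r.disposition for r in runs]).value_counts().to_dict(),
                "swept": st.swept,
            }
        return CampaignResult(
            termination=self.termination or "budget_exhausted",
            best_yield=self.best_yield if self.best_yield >= 0 else float("nan"),
            best_condition=self.best_condition,
            best_route=self.best_route,
            trials_used=self.trials_used,
            trials_to_target=self.trials_to_target,
            fraction_evaluated=self.trials_used / total_size,
            per_route=per_route,
            run_records=self.runs,
            log=self.log,
            target_yield=self.config.target_yield,
            total_space_size=total_size,
        )


def run_campaign(routes: Sequence[Route], lab: SimulatedLab, config: CampaignConfig) -> CampaignResult:
    """Execute one closed-loop campaign (see module docstring)."""
    return _Campaign(routes, lab, config).run()


def formal_run_records(result: CampaignResult) -> list[RunRecord]:
    """Archival view of a campaign's runs: spec, action-sequence digest,
    revealed trajectory, final yield, disposition and seed per dispatch."""
    records = []
    for run in result.run_records:
        disposition = run.disposition or "running"
        records.append(
            RunRecord(
                spec=run.spec,
                sequence_digest=run.sequence_digest,
                trajectory=run.revealed_trajectory(status=disposition),
                final_yield=run.revealed[-1][1] if run.revealed else 0.0,
                disposition=disposition,
                seed=run.seed,
            )
        )
    return records


def random_baseline(route: Route, lab: SimulatedLab, config: CampaignConfig) -> int:
    """Uniform-random search without replacement under the same stopping
    rule: trials dispatched until some measured sample meets the target
    (capped at the trial budget)."""
    conditions = enumerate_conditions(route.space)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(999,)))
    order = rng.permutation(len(conditions))
    for i, idx in enumerate(order[: config.max_trials], start=1):
        spec = route.make_spec(conditions[int(idx)], f"rand-{i:04d}", config.target_yield)
        seed = int(np.random.SeedSequence(entropy=config.seed, spawn_key=(998, i)).generate_state(1)[0] % 2**31)
        traj = lab.trajectory(route.route_id, spec, np.random.default_rng(seed))
        if any(y >= config.target_yield for _, y in traj.samples):
            return i
    return config.max_trials


def summarize(result: CampaignResult) -> pd.DataFrame:
    """Per-route campaign report."""
    rows = []
    for rid, info in result.per_route.items():
        disp = info["dispositions"]
        rows.append(
            {
                "route_id": rid,
                "trials": info["trials"],
                "best_yield": info["best_yield"],
                "fraction_pct": round(info["fraction_pct"], 4),
                "completed": disp.get("completed", 0),
                "withdrawn": disp.get("withdrawn", 0),
                "swept_runs": disp.get("swept", 0),
                "cancelled": disp.get("cancelled", 0),
                "route_swept": info["swept"],
            }
        )
    return pd.DataFrame(rows).set_index("route_id")


def report_from_log(records: Sequence[dict]) -> pd.DataFrame:
    """Rebuild the per-route summary from a run log (round-trip check for
    the report generator)."""
    runs: dict[str, dict] = {}
    for rec in records:
        if rec["event"] == "dispatch":
            runs[rec["run_id"]] = {
                "route_id": rec["route_id"],
                "final_yield": float("nan"),
                "disposition": "cancelled",
            }
        elif rec["event"] == "sample":
            runs[rec["run_id"]]["final_yield"] = rec["yield_pct"]
        elif rec["event"] == "terminal":
            runs[rec["run_id"]]["disposition"] = rec["disposition"]
    swept_routes = {rec["route_id"] for rec in records if rec["event"] == "sweep"}
    route_ids = next(rec["routes"] for rec in records if rec["event"] == "campaign_start")
    rows = []
    for rid in route_ids:
        rruns = [r for r in runs.values() if r["route_id"] == rid]
        finals = [r["final_yield"] for r in rruns if not np.isnan(r["final_yield"])]
        counts = pd.Series([r["disposition"] for r in rruns]).value_counts().to_dict()
        rows.append(
            {
                "route_id": rid,
                "trials": len(rruns),
                "best_yield": max(finals) if finals else float("nan"),
                "completed": counts.get("completed", 0),
                "withdrawn": counts.get("withdrawn", 0),
                "swept_runs": counts.get("swept", 0),
                "cancelled": counts.get("cancelled", 0),
                "route_swept": rid in swept_routes,
            }
        )
    return pd.DataFrame(rows).set_index("route_id")
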