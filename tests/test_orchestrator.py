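import numpy as np
import pytest

from chemloop import (
    CampaignConfig,
    PolicyConfig,
    Route,
    SimulatedLab,
    generate_landscape,
    run_campaign,
    summarize,
    target_from_reference,
)
from chemloop.io_fixtures import runlog_bytes
from chemloop.orchestrator import EventQueue, report_from_log, schedule_event_queue
from chemloop.virtual_lab import ZERO_NOISE, LandscapeParams, NoiseConfig, noiseless_yield


def _route(space, route_id="r1", rank=1, schedule=None):
    schedule = schedule or tuple(np.arange(1, 9) * 1.5)
    return Route(
        route_id=route_id, rank=rank, label=route_id, space=space,
        reactant1="R1", max_duration=schedule[-1], sampling_schedule=schedule,
    )


@pytest.fixture
def noiseless_setup(space_2222):
    # k >= 0.75 and 12 h horizon: every trajectory converges to its plateau
    # within the printed 0.01 % yield resolution
    schedule = tuple(np.arange(1, 9) * 1.5)
    route = _route(space_2222, schedule=schedule)
    landscape = generate_landscape(space_2222, seed=13, params=LandscapeParams(k_range=(1.0, 2.0)))
    lab = SimulatedLab({"r1": landscape}, noise=ZERO_NOISE)
    return route, landscape, lab


class TestEventQueue:
    def test_analysis_before_dispatch_at_equal_time(self):
        q = EventQueue()
        q.push(1.0, "dispatch")
        q.push(1.0, "analysis")
        q.push(1.0, "decision")
        kinds = [schedule_event_queue(q).kind for _ in range(3)]
        assert kinds == ["analysis", "dispatch", "decision"]

    def test_time_dominates_priority(self):
        q = EventQueue()
        q.push(2.0, "analysis")
        q.push(1.0, "decision")
        assert q.pop().kind == "decision"

    def test_insertion_order_breaks_full_ties(self):
        q = EventQueue()
        q.push(1.0, "analysis", {"i": 1})
        q.push(1.0, "analysis", {"i": 2})
        assert [q.pop().payload["i"], q.pop().payload["i"]] == [1, 2]

    def test_empty_queue_returns_none(self):
        assert schedule_event_queue(EventQueue()) is None


class TestTargetSetting:
    def test_reference_plus_margin(self):
        assert target_from_reference(86.5) == 91.5

    def test_custom_margin(self):
        assert target_from_reference(50.9, margin=29.1) == 80.0

    def test_rejects_out_of_range_reference(self):
        with pytest.raises(ValueError):
            target_from_reference(130.0)


class TestClosedLoop:
    def test_trivial_target_met_on_first_analysis(self, noiseless_setup):
        route, _, lab = noiseless_setup
        config = CampaignConfig(target_yield=0.0, max_trials=1, seed=0, noise=ZERO_NOISE)
        result = run_campaign([route], lab, config)
        assert result.termination == "target_met"
        assert result.trials_used == 1

    def test_exhaustive_budget_finds_brute_force_maximum(self, noiseless_setup):
        """With budget = space size on a noiseless lab the loop evaluates the
        whole space, so its best equals the brute-force maximum exactly."""
        route, landscape, lab = noiseless_setup
        config = CampaignConfig(
            target_yield=landscape.optimum_value, max_trials=16, seed=3, noise=ZERO_NOISE,
        )
        result = run_campaign([route], lab, config)
        brute = max(
            round(noiseless_yield(landscape.plateau(c), landscape.rate(c), route.max_duration), 2)
            for c in landscape.conditions
        )
        assert result.best_yield == brute
        assert result.termination in ("target_met", "budget_exhausted", "spaces_exhausted")

    def test_slot_concurrency_never_exceeds_limit(self, noiseless_setup):
        route, _, lab = noiseless_setup
        config = CampaignConfig(target_yield=101.0, max_trials=16, seed=1, noise=ZERO_NOISE)
        result = run_campaign([route], lab, config)
        for rec in result.log:
            if rec["event"] == "dispatch":
                assert rec["n_running"] <= config.n_slots

    def test_budget_accounting(self, noiseless_setup):
        route, _, lab = noiseless_setup
        config = CampaignConfig(target_yield=101.0, max_trials=7, seed=2, noise=ZERO_NOISE)
        result = run_campaign([route], lab, config)
        assert result.trials_used <= 7
        assert result.termination == "budget_exhausted"
        assert all(r.disposition is not None for r in result.run_records)

    def test_replay_is_byte_identical(self, space_2222):
        route = _route(space_2222)
        params = LandscapeParams(k_range=(0.5, 2.0))
        config = CampaignConfig(target_yield=90.0, max_trials=12, seed=7, noise=NoiseConfig())

        def once():
            landscape = generate_landscape(space_2222, seed=40, params=params)
            lab = SimulatedLab({"r1": landscape}, noise=NoiseConfig())
            return runlog_bytes(run_campaign([route], lab, config).log)

        assert once() == once()

    def test_incumbent_yield_nondecreasing(self, noiseless_setup):
        route, _, lab = noiseless_setup
        config = CampaignConfig(target_yield=101.0, max_trials=16, seed=5, noise=ZERO_NOISE)
        result = run_campaign([route], lab, config)
        best = -1.0
        for rec in result.log:
            if rec["event"] == "terminal" and rec["disposition"] == "completed":
                assert rec["final_yield"] >= 0
                best = max(best, rec["final_yield"])
        assert best == result.best_yield

    def test_no_condition_dispatched_twice(self, noiseless_setup):
        route, _, lab = noiseless_setup
        config = CampaignConfig(target_yield=101.0, max_trials=16, seed=6, noise=ZERO_NOISE)
        result = run_campaign([route], lab, config)
        keys = [tuple(r.spec.condition.key()) for r in result.run_records]
        assert len(keys) == len(set(keys))

    def test_no_routes_rejected(self, noiseless_setup):
        _, _, lab = noiseless_setup
        with pytest.raises(ValueError):
            run_campaign([], lab, CampaignConfig())


class TestSweepSemantics:
    def _two_route_lab(self, space_2222):
        routes = [_route(space_2222, "bad", 1), _route(space_2222, "good", 2)]
        bad = generate_landscape(
            space_2222, seed=3,
            params=LandscapeParams(baseline=5.0, main_effect_sd=1.0, interaction_sd=0.5,
                                   optimum_value=20.0, k_range=(1.0, 2.0)),
        )
        good = generate_landscape(space_2222, seed=4, params=LandscapeParams(k_range=(1.0, 2.0)))
        return routes, SimulatedLab({"bad": bad, "good": good}, noise=ZERO_NOISE)

    def test_sweep_switches_to_next_route(self, space_2222):
        # stall_slope 0 disables Withdraw on noiseless (rising) trajectories,
        # so the route-level Sweep rule is what terminates the bad route
        routes, lab = self._two_route_lab(space_2222)
        config = CampaignConfig(
            target_yield=90.0, max_trials=32, seed=9, noise=ZERO_NOISE,
            policy=PolicyConfig(sweep_min_recipes=4, stall_slope=0.0),
        )
        result = run_campaign(routes, lab, config)
        assert result.per_route["bad"]["swept"]
        assert result.per_route["good"]["trials"] > 0
        # after the sweep no further recipe of the swept route is dispatched
        sweep_at = next(i for i, r in enumerate(result.log) if r["event"] == "sweep")
        later = [r for r in result.log[sweep_at:] if r["event"] == "dispatch"]
        assert all(r["route_id"] != "bad" for r in later)

    def test_single_route_is_never_swept(self, space_2222):
        routes, lab = self._two_route_lab(space_2222)
        config = CampaignConfig(
            target_yield=90.0, max_trials=16, seed=9, noise=ZERO_NOISE,
            policy=PolicyConfig(sweep_min_recipes=4, stall_slope=0.0),
        )
        result = run_campaign([routes[0]], lab, config)
        assert not result.per_route["bad"]["swept"]
        assert any(r["event"] == "sweep_suppressed" for r in result.log)


class TestRunRecords:
    def test_formal_records_carry_stable_sequence_digests(self):
        from chemloop import formal_run_records, make_fixture

        fx = make_fixture("tiny", 3)
        config = fx.campaign
        result_a = run_campaign(fx.routes, fx.make_lab(), config)
        result_b = run_campaign(fx.routes, fx.make_lab(), config)
        recs_a, recs_b = formal_run_records(result_a), formal_run_records(result_b)
        assert len(recs_a) == len(recs_b) > 0
        for a, b in zip(recs_a, recs_b):
            assert a.sequence_digest and a.sequence_digest == b.sequence_digest
            assert a.disposition == b.disposition
            if a.disposition == "completed":
                assert a.final_yield == a.trajectory.samples[-1][1]

    def test_exploration_only_mode_runs(self, noiseless_setup):
        # surrogate-free operation: zero exploitation proposals per batch
        route, _, lab = noiseless_setup
        config = CampaignConfig(
            target_yield=101.0, max_trials=10, seed=2, noise=ZERO_NOISE,
            n_exploit=0, n_explore=3,
        )
        result = run_campaign([route], lab, config)
        assert result.trials_used == 10


class TestReporting:
    def test_summary_round_trips_through_log(self, noiseless_setup):
        route, _, lab = noiseless_setup
        config = CampaignConfig(target_yield=90.0, max_trials=10, seed=11, noise=ZERO_NOISE)
        result = run_campaign([route], lab, config)
        direct = summarize(result)
        from_log = report_from_log(result.log)
        assert list(direct.index) == list(from_log.index)
        for col in ("trials", "completed", "withdrawn", "route_swept"):
            assert list(direct[col]) == list(from_log[col])
        assert np.allclose(direct["best_yield"], from_log["best_yield"], equal_nan=True)

    def test_fraction_is_trials_over_space(self, noiseless_setup):
        route, _, lab = noiseless_setup
        config = CampaignConfig(target_yield=0.0, max_trials=1, seed=0, noise=ZERO_NOISE)
        result = run_campaign([route], lab, config)
        assert result.fraction_evaluated == 1.0 / 16.0
        assert summarize(result).loc["r1", "fraction_pct"] == pytest.approx(100 / 16)
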