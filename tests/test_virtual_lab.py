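import numpy as np
import pytest

from chemloop import (
    LandscapeParams,
    NoiseConfig,
    RecipeSpec,
    YieldTrajectory,
    enumerate_conditions,
    generate_landscape,
    run_replicates,
    simulate_dispense,
    simulate_reaction,
)
from chemloop.virtual_lab import ZERO_NOISE, noiseless_yield


@pytest.fixture
def landscape(space_2222):
    return generate_landscape(space_2222, seed=7)


@pytest.fixture
def spec(space_2222, landscape):
    cond = landscape.conditions[3]
    return RecipeSpec(
        recipe_id="vl-1", route_id="r", step_index=0, reactant1="R1",
        amount_mmol=0.5, condition=cond,
        sampling_schedule=(1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0), max_duration=8.0,
    )


class TestLandscape:
    def test_regeneration_is_bit_identical(self, space_2222):
        a = generate_landscape(space_2222, seed=5)
        b = generate_landscape(space_2222, seed=5)
        assert np.array_equal(a.plateau_array(), b.plateau_array())
        assert all(a.rate(c) == b.rate(c) for c in a.conditions)

    def test_planted_optimum_is_configured_max(self, space_2222):
        model = generate_landscape(space_2222, seed=1, params=LandscapeParams(optimum_value=97.0))
        assert model.plateau(model.optimum) == 97.0
        assert model.plateau_array().max() == 97.0

    def test_plateaus_bounded(self, landscape):
        pl = landscape.plateau_array()
        assert (pl >= 0).all() and (pl <= 100).all()

    def test_zero_interactions_make_shared_roles_additive(self, space_2222):
        params = LandscapeParams(interaction_sd=0.0, baseline=50.0, main_effect_sd=5.0)
        model = generate_landscape(space_2222, seed=3, params=params)
        conds = enumerate_conditions(space_2222)
        # two pairs differing in the same single role must differ by the same
        # main effect everywhere (purely additive surface away from clipping)
        by_key = {c.key(): c for c in conds}

        def delta(base_key, role_idx):
            other = list(base_key)
            other[role_idx] = "CATB" if role_idx == 0 else other[role_idx]
            return model.plateau(by_key[tuple(other)]) - model.plateau(by_key[base_key])

        k1 = ("CATA", "LIGA", "BASA", "SOLA")
        k2 = ("CATA", "LIGB", "BASB", "SOLB")
        pl = model.plateau_array()
        if (pl > 0).all() and (pl < 100).all() and model.plateau(model.optimum) != 100.0:
            assert delta(k1, 0) == pytest.approx(delta(k2, 0), abs=1e-9)

    def test_rates_within_configured_range(self, landscape):
        lo, hi = landscape.params.k_range
        assert all(lo <= landscape.rate(c) <= hi for c in landscape.conditions)

    def test_unknown_condition_raises(self, landscape, space_2222):
        from chemloop.chem_space import Condition, LookupError_

        ghost = Condition(
            choice={"catalyst": "CATX", "ligand": "LIGA", "base": "BASA", "solvent": "SOLA"},
            temperature=25.0,
        )
        with pytest.raises(LookupError_):
            landscape.plateau(ghost)


class TestDispense:
    def test_zero_noise_is_exact(self):
        assert simulate_dispense(100.0, ZERO_NOISE, 0) == 100.0

    def test_nonpositive_target_rejected(self):
        with pytest.raises(ValueError):
            simulate_dispense(0.0, NoiseConfig(), 0)

    def test_sample_sd_matches_configured_cv(self):
        noise = NoiseConfig(dispense_cv=0.0255, dispense_floor_sd=0.0)
        rng = np.random.default_rng(0)
        draws = np.array([simulate_dispense(100.0, noise, rng) for _ in range(10_000)])
        assert draws.std(ddof=1) == pytest.approx(2.55, rel=0.05)

    def test_small_sample_mae_near_half_normal_mean(self):
        # 12 draws: MAE concentrates near cv * target * sqrt(2/pi)
        noise = NoiseConfig(dispense_cv=0.0255, dispense_floor_sd=0.0)
        rng = np.random.default_rng(1)
        maes = []
        for _ in range(400):
            draws = np.array([simulate_dispense(100.0, noise, rng) for _ in range(12)])
            maes.append(np.abs(draws - 100.0).mean())
        assert np.mean(maes) == pytest.approx(2.55 * np.sqrt(2 / np.pi), rel=0.05)

    def test_floor_sd_applies_to_small_masses(self):
        noise = NoiseConfig(dispense_cv=0.01, dispense_floor_sd=1.0)
        rng = np.random.default_rng(2)
        draws = np.array([simulate_dispense(5.0, noise, rng) for _ in range(5_000)])
        assert draws.std(ddof=1) == pytest.approx(1.0, rel=0.1)


class TestReaction:
    def test_noiseless_saturation_and_half_life(self, spec, landscape):
        y_inf = landscape.plateau(spec.condition)
        k = landscape.rate(spec.condition)
        assert noiseless_yield(y_inf, k, 1e9) == pytest.approx(y_inf)
        assert noiseless_yield(y_inf, k, np.log(2) / k) == pytest.approx(y_inf / 2)
        assert noiseless_yield(y_inf, k, 0.0) == 0.0

    def test_noiseless_trajectory_matches_closed_form(self, spec, landscape):
        traj = simulate_reaction(spec, landscape, ZERO_NOISE, 0)
        y_inf = landscape.plateau(spec.condition)
        k = landscape.rate(spec.condition)
        for t, y in traj.samples:
            assert y == pytest.approx(noiseless_yield(y_inf, k, t), abs=0.005)

    def test_noiseless_trajectory_monotone(self, spec, landscape):
        traj = simulate_reaction(spec, landscape, ZERO_NOISE, 0)
        ys = [y for _, y in traj.samples]
        assert all(b >= a for a, b in zip(ys, ys[1:]))

    def test_measurements_clipped_to_percentage_range(self, spec, landscape):
        noise = NoiseConfig(measure_cv_early=0.5, measure_cv_late=0.5)
        for seed in range(25):
            traj = simulate_reaction(spec, landscape, noise, seed)
            assert all(0 <= y <= 100 for _, y in traj.samples)

    def test_seeded_reproducibility(self, spec, landscape):
        a = simulate_reaction(spec, landscape, NoiseConfig(), 99)
        b = simulate_reaction(spec, landscape, NoiseConfig(), 99)
        assert a.samples == b.samples

    def test_trajectory_validation(self):
        with pytest.raises(ValueError):
            YieldTrajectory("x", [(1.0, 10.0), (1.0, 11.0)])
        with pytest.raises(ValueError):
            YieldTrajectory("x", [(1.0, 101.0)])


class TestReplicates:
    def test_zero_noise_gives_zero_cv(self, spec, landscape):
        study = run_replicates(spec, landscape, ZERO_NOISE, 4, seed=0)
        assert study.max_cv == 0.0

    def test_requires_two_replicates(self, spec, landscape):
        with pytest.raises(ValueError):
            run_replicates(spec, landscape, NoiseConfig(), 1, seed=0)

    def test_cv_scales_with_measurement_cv(self, spec, landscape):
        """With dispensing noise off, replicate yield CV tracks the
        configured measurement CV proportionally."""
        ratios = []
        for cv in (0.01, 0.025, 0.05):
            noise = NoiseConfig(
                dispense_cv=0.0, dispense_floor_sd=0.0, effect_gain=0.0,
                measure_cv_early=cv, measure_cv_late=cv,
            )
            study = run_replicates(spec, landscape, noise, 50, seed=4)
            ratios.append(study.cv_by_time.mean() / (100 * cv))
        assert max(ratios) / min(ratios) == pytest.approx(1.0, abs=0.25)

    def test_dispense_stats_reported_with_library(self, spec, landscape, library_2222):
        study = run_replicates(spec, landscape, NoiseConfig(), 12, seed=0, library=library_2222)
        assert study.dispense_mae is not None and study.dispense_mae > 0
        assert 0 < study.dispense_cv_max < 0.10

    def test_replicate_table_shape(self, spec, landscape):
        study = run_replicates(spec, landscape, NoiseConfig(), 5, seed=0)
        assert study.yields.shape == (5, len(spec.sampling_schedule))
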