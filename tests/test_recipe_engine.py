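import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chemloop import ActionSequence, RecipeSpec, quantify, translate
from chemloop.chem_space import enumerate_conditions
from chemloop.recipe_engine import DEFAULT_PROFILE, Action, ProfileError


@pytest.fixture
def spec(space_2222):
    cond = enumerate_conditions(space_2222)[0]
    return RecipeSpec(
        recipe_id="t-1",
        route_id="route-1",
        step_index=0,
        reactant1="R1",
        amount_mmol=0.5,
        condition=cond,
        co_reactants=(("R2", 1.0),),
        catalyst_equiv=0.05,
        base_equiv=2.0,
        concentration=0.2,
        max_duration=8.0,
        sampling_schedule=(1.0, 2.0, 4.0, 8.0),
        target_yield=90.0,
    )


def _mass(seq, reagent_id):
    return next(a.quantity for a in seq.steps if a.reagent_id == reagent_id and a.verb == "dispense_solid")


class TestQuantify:
    def test_solid_mass_from_mw_and_purity(self, spec, library_2222):
        lib = dict(library_2222)
        lib["R1"] = lib["R1"]
        seq = quantify(spec, lib)
        # 0.5 mmol x 1.0 eq x 200 g/mol / 1.0 purity = 100 mg
        assert _mass(seq, "R1") == 100.00

    def test_purity_inflates_mass(self, spec, library_2222):
        from chemloop import Reagent

        lib = dict(library_2222)
        lib["R2"] = Reagent("R2", "r2", "reactant", 200.0, 0.8, "solid")
        seq = quantify(spec, lib)
        assert _mass(seq, "R2") == 125.00  # 0.5 * 1.0 * 200 / 0.8

    def test_default_ligand_equiv_is_twice_catalyst(self, spec, library_2222):
        seq = quantify(spec, library_2222)
        lig = library_2222["LIGA"]
        expected = round(0.5 * 2 * 0.05 * lig.molecular_weight / lig.purity, 2)
        assert _mass(seq, "LIGA") == expected

    def test_explicit_ligand_equiv_overrides(self, spec, library_2222):
        from dataclasses import replace

        seq = quantify(replace(spec, ligand_equiv=0.3), library_2222)
        lig = library_2222["LIGA"]
        assert _mass(seq, "LIGA") == round(0.5 * 0.3 * lig.molecular_weight / lig.purity, 2)

    def test_solvent_volume_from_concentration(self, spec, library_2222):
        seq = quantify(spec, library_2222)
        solvent = next(a for a in seq.steps if a.verb == "dispense_solvent")
        assert solvent.quantity == 2.5  # 0.5 mmol / 0.2 mol/L

    def test_step_ordering(self, spec, library_2222):
        seq = quantify(spec, library_2222)
        verbs = [a.verb for a in seq.steps]
        solids_end = max(i for i, v in enumerate(verbs) if v == "dispense_solid")
        assert verbs[solids_end + 1] == "dispense_solvent"
        tail = verbs[solids_end + 1:]
        assert tail[:4] == ["dispense_solvent", "cap", "set_temperature", "stir"]
        assert tail[4:] == ["sample"] * 4 + ["end"]

    def test_unknown_reagent_raises(self, spec, library_2222):
        lib = dict(library_2222)
        del lib["R2"]
        with pytest.raises(KeyError):
            quantify(spec, lib)

    def test_mass_conservation_within_rounding(self, spec, library_2222):
        seq = quantify(spec, library_2222)
        for a in seq.steps:
            if a.verb != "dispense_solid":
                continue
            reagent = library_2222[a.reagent_id]
            mmol = a.quantity * reagent.purity / reagent.molecular_weight
            # target mmol recoverable to within the 0.01 mg rounding effect
            nominal = {
                "R1": 0.5, "R2": 0.5,
                "CATA": 0.5 * 0.05, "LIGA": 0.5 * 0.10, "BASA": 0.5 * 2.0,
            }[a.reagent_id]
            assert mmol == pytest.approx(nominal, abs=0.01 * reagent.purity / reagent.molecular_weight)

    def test_no_hardware_identifiers_in_sequence(self, spec, library_2222):
        text = quantify(spec, library_2222).to_text()
        for device in ("powder_dispenser", "reactor", "lcms", "pantry_robot"):
            assert device not in text


@settings(max_examples=30, deadline=None)
@given(
    amount=st.floats(0.05, 5.0),
    equiv=st.floats(0.01, 5.0),
    mw=st.floats(40.0, 1200.0),
)
def test_quantify_monotone_in_equivalents_and_mw(amount, equiv, mw):
    """Larger equivalents or heavier reagents never produce smaller masses."""
    from chemloop import ConditionSpace, Reagent

    space = ConditionSpace(
        candidates={"catalyst": ["CATA"], "ligand": ["LIGA"], "base": ["BASA"], "solvent": ["SOLA"]},
        temperature_map={"SOLA": 110.0},
    )
    cond = enumerate_conditions(space)[0]
    lib = {
        "R1": Reagent("R1", "r1", "reactant", 200.0, 1.0, "solid"),
        "CATA": Reagent("CATA", "cata", "catalyst", 224.51, 0.98, "solid"),
        "LIGA": Reagent("LIGA", "liga", "ligand", 476.72, 0.98, "solid"),
        "BASA": Reagent("BASA", "basa", "base", 138.21, 0.98, "solid"),
        "SOLA": Reagent("SOLA", "sola", "solvent", 92.14, 0.995, "liquid", density=0.87),
    }
    lib["X"] = Reagent("X", "x", "reactant", mw, 1.0, "solid")
    lib["X2"] = Reagent("X2", "x2", "reactant", mw * 2, 1.0, "solid")

    def mass(e, rid):
        spec = RecipeSpec(
            recipe_id="h", route_id="r", step_index=0, reactant1="R1",
            amount_mmol=amount, condition=cond, co_reactants=((rid, e),),
            sampling_schedule=(1.0,), max_duration=2.0,
        )
        return _mass(quantify(spec, lib), rid)

    assert mass(equiv * 2, "X") >= mass(equiv, "X")
    assert mass(equiv, "X2") >= mass(equiv, "X")


class TestSerialization:
    def test_text_round_trip(self, spec, library_2222):
        seq = quantify(spec, library_2222)
        again = ActionSequence.from_text(seq.to_text())
        assert again == seq

    def test_round_trip_preserves_quantities(self, spec, library_2222):
        seq = quantify(spec, library_2222)
        again = ActionSequence.from_text(seq.to_text())
        assert [a.quantity for a in again.steps] == [a.quantity for a in seq.steps]


class TestTranslate:
    def test_terminal_only_sequence(self):
        seq = ActionSequence("x", [Action("end", None, None, None, 0.0)])
        assert len(translate(seq)) == 1

    def test_command_count_is_sum_of_template_lengths(self, spec, library_2222):
        seq = quantify(spec, library_2222)
        commands = translate(seq)
        expected = sum(len(DEFAULT_PROFILE[a.verb]) for a in seq.steps)
        assert len(commands) == expected

    def test_three_solids_with_four_command_template(self):
        profile = {"dispense_solid": DEFAULT_PROFILE["dispense_solid"], "end": DEFAULT_PROFILE["end"]}
        steps = [Action("dispense_solid", f"S{i}", 10.0, "mg", 0.0) for i in range(3)]
        steps.append(Action("end", None, None, None, 0.0))
        assert len(translate(ActionSequence("x", steps), profile)) == 3 * 4 + 1

    def test_deterministic(self, spec, library_2222):
        seq = quantify(spec, library_2222)
        a = [c.render() for c in translate(seq)]
        b = [c.render() for c in translate(seq)]
        assert a == b

    def test_missing_template_raises(self):
        seq = ActionSequence("x", [Action("end", None, None, None, 0.0)])
        with pytest.raises(ProfileError):
            translate(seq, profile={})

    def test_commands_carry_only_sequence_quantities(self, spec, library_2222):
        seq = quantify(seq_spec := spec, library_2222)
        quantities = {f"{a.quantity:g}" for a in seq.steps if a.quantity is not None}
        for cmd in translate(seq):
            for key, value in cmd.params:
                if key.startswith("target_") or key.startswith("setpoint"):
                    assert value in quantities
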