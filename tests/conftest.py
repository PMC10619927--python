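import pytest

from chemloop import ConditionSpace, Reagent


@pytest.fixture
def space_2222() -> ConditionSpace:
    """Minimal 2x2x2x2 space with two solvents at distinct temperatures."""
    return ConditionSpace(
        candidates={
            "catalyst": ["CATA", "CATB"],
            "ligand": ["LIGA", "LIGB"],
            "base": ["BASA", "BASB"],
            "solvent": ["SOLA", "SOLB"],
        },
        temperature_map={"SOLA": 110.0, "SOLB": 65.0},
    )


@pytest.fixture
def library_2222(space_2222) -> dict:
    lib = {
        "R1": Reagent("R1", "aryl halide", "reactant", 200.0, 1.0, "solid"),
        "R2": Reagent("R2", "boronic acid", "reactant", 150.0, 0.97, "solid"),
    }
    mws = {"CATA": 224.51, "CATB": 915.72, "LIGA": 476.72, "LIGB": 578.62,
           "BASA": 138.21, "BASB": 325.82}
    for role in ("catalyst", "ligand", "base"):
        for rid in space_2222.candidates[role]:
            lib[rid] = Reagent(rid, rid.lower(), role, mws[rid], 0.98, "solid")
    for rid in space_2222.candidates["solvent"]:
        lib[rid] = Reagent(rid, rid.lower(), "solvent", 92.14, 0.995, "liquid", density=0.87)
    return lib
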