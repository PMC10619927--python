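"""Recipe quantification and translation.

An abstract recipe (route step + condition + scales) becomes a quantified,
human-readable action sequence — masses and volumes computed from molecular
weight, purity, density and concentration — and the action sequence is then
expanded into symbolic device-level commands under a hardware profile.
Action sequences carry no hardware identifiers; robot commands carry no
chemistry beyond the quantities already present in the sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .chem_space import Condition, LookupError_, Reagent

__all__ = [
    "RecipeSpec",
    "Action",
    "ActionSequence",
    "RobotCommand",
    "DEFAULT_PROFILE",
    "quantify",
    "translate",
]

#: aliquot volume recorded for each sampling action (metadata only)
SAMPLE_ALIQUOT_UL = 25.0

VERBS = (
    "dispense_solid",
    "dispense_liquid",
    "dispense_solvent",
    "cap",
    "transfer",
    "set_temperature",
    "stir",
    "sample",
    "end",
)


class DataError(ValueError):
    """Reagent data inconsistent with its declared form/role."""


class ProfileError(KeyError):
    """Hardware profile lacks a template for a verb."""


@dataclass(frozen=True)
class RecipeSpec:
    """Fully parameterized single reaction to run.

    Equivalents are molar ratios relative to reactant 1.  When
    ``ligand_equiv`` is None it defaults to twice ``catalyst_equiv``.
    ``concentration`` is mol/L of reactant 1 in the reaction solvent.
    """

    recipe_id: str
    route_id: str
    step_index: int
    reactant1: str
    amount_mmol: float
    condition: Condition
    co_reactants: tuple[tuple[str, float], ...] = ()
    catalyst_equiv: float = 0.05
    ligand_equiv: float | None = None
    base_equiv: float = 2.0
    concentration: float = 0.2
    max_duration: float = 8.0
    sampling_schedule: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0)
    target_yield: float = 100.0

    def __post_init__(self) -> None:
        if self.amount_mmol <= 0:
            raise ValueError("reactant 1 amount must be > 0 mmol")
        for _, eq in self.co_reactants:
            if eq <= 0:
                raise ValueError("co-reactant equivalents must be > 0")
        if self.catalyst_equiv <= 0 or self.base_equiv <= 0:
            raise ValueError("equivalents must be > 0")
        if self.ligand_equiv is not None and self.ligand_equiv <= 0:
            raise ValueError("ligand equivalents must be > 0")
        if self.concentration <= 0:
            raise ValueError("concentration must be > 0")
        times = self.sampling_schedule
        if not times or any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("sampling schedule must be non-empty and strictly increasing")
        if times[-1] > self.max_duration:
            raise ValueError("sampling times must not exceed max_duration")

    @property
    def effective_ligand_equiv(self) -> float:
        """Ligand loading; defaults to twice the catalyst loading."""
        return self.ligand_equiv if self.ligand_equiv is not None else 2.0 * self.catalyst_equiv


@dataclass(frozen=True)
class Action:
    verb: str
    reagent_id: str | None
    quantity: float | None
    unit: str | None
    t_offset: float  # hours from reaction start

    def render(self) -> str:
        return "\t".join([
            f"{self.t_offset:.3f}h",
            self.verb,
            self.reagent_id if self.reagent_id is not None else "-",
            f"{self.quantity!r}" if self.quantity is not None else "-",
            self.unit if self.unit is not None else "-",
        ])

    @classmethod
    def parse(cls, line: str) -> "Action":
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 5:
            raise ValueError(f"malformed action line: {line!r}")
        t = float(fields[0].rstrip("h"))
        verb = fields[1]
        if verb not in VERBS:
            raise ValueError(f"unknown verb {verb!r}")
        reagent = None if fields[2] == "-" else fields[2]
        quantity = None if fields[3] == "-" else float(fields[3])
        unit = None if fields[4] == "-" else fields[4]
        return cls(verb=verb, reagent_id=reagent, quantity=quantity, unit=unit, t_offset=t)


@dataclass
class ActionSequence:
    recipe_id: str
    steps: list[Action]

    def __post_init__(self) -> None:
        for a in self.steps:
            if a.verb.startswith("dispense") and not (a.quantity and a.quantity > 0):
                raise ValueError(f"non-positive dispense quantity in {a}")

    def to_text(self) -> str:
        lines = [f"# recipe\t{self.recipe_id}"]
        lines += [a.render() for a in self.steps]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "ActionSequence":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        if not lines or not lines[0].startswith("# recipe\t"):
            raise ValueError("missing recipe header line")
        recipe_id = lines[0].split("\t", 1)[1]
        return cls(recipe_id=recipe_id, steps=[Action.parse(ln) for ln in lines[1:]])

    def to_records(self) -> list[dict]:
        return [
            {
                "recipe_id": self.recipe_id,
                "verb": a.verb,
                "reagent_id": a.reagent_id,
                "quantity": a.quantity,
                "unit": a.unit,
                "t_offset_h": a.t_offset,
            }
            for a in self.steps
        ]


@dataclass(frozen=True)
class RobotCommand:
    device: str
    operation: str
    params: tuple[tuple[str, str], ...]

    def render(self) -> str:
        kv = ",".join(f"{k}={v}" for k, v in self.params)
        return f"{self.device}:{self.operation}({kv})"


def _round_mg(mass_mg: float) -> float:
    """Round-half-even to 0.01 mg."""
    return round(mass_mg, 2)


def _round_ul(volume_ul: float) -> float:
    """Round-half-even to 0.1 uL."""
    return round(volume_ul, 1)


def _dispense_action(reagent: Reagent, mmol: float) -> Action:
    """Quantify one reagent dispense from its target molar amount."""
    if reagent.form == "solid":
        mass_mg = mmol * reagent.molecular_weight / reagent.purity
        return Action("dispense_solid", reagent.id, _round_mg(mass_mg), "mg", 0.0)
    if reagent.form == "liquid":
        mass_g = mmol * reagent.molecular_weight / reagent.purity / 1000.0
        vol_ul = mass_g / reagent.density * 1000.0  # type: ignore[operator]
        return Action("dispense_liquid", reagent.id, _round_ul(vol_ul), "uL", 0.0)
    # solution: volume from molarity
    vol_ul = mmol / reagent.concentration * 1000.0  # type: ignore[operator]
    return Action("dispense_liquid", reagent.id, _round_ul(vol_ul), "uL", 0.0)


def quantify(spec: RecipeSpec, library: Mapping[str, Reagent]) -> ActionSequence:
    """Turn a recipe spec into a quantified action sequence.

    Mass of a solid (mg) = amount(mmol) x equivalents x MW(g/mol) / purity;
    liquid volumes follow from mass via density, solution volumes from
    molarity; reaction solvent volume (mL) = reactant-1 mmol / concentration.
    Step order is fixed: solids, liquids, solvent, cap, set_temperature,
    stir, scheduled samples, end.
    """

    def resolve(rid: str) -> Reagent:
        if rid not in library:
            raise LookupError_(f"reagent {rid!r} not in library")
        return library[rid]

    dispenses: list[tuple[Reagent, float]] = [(resolve(spec.reactant1), spec.amount_mmol)]
    for rid, eq in spec.co_reactants:
        dispenses.append((resolve(rid), spec.amount_mmol * eq))
    dispenses.append((resolve(spec.condition.choice["catalyst"]), spec.amount_mmol * spec.catalyst_equiv))
    dispenses.append((resolve(spec.condition.choice["ligand"]), spec.amount_mmol * spec.effective_ligand_equiv))
    dispenses.append((resolve(spec.condition.choice["base"]), spec.amount_mmol * spec.base_equiv))

    actions = [_dispense_action(r, mmol) for r, mmol in dispenses]
    solids = [a for a in actions if a.verb == "dispense_solid"]
    liquids = [a for a in actions if a.verb == "dispense_liquid"]

    solvent = resolve(spec.condition.choice["solvent"])
    solvent_ml = spec.amount_mmol / spec.concentration
    solvent_action = Action(
        "dispense_solvent", solvent.id, _round_ul(solvent_ml * 1000.0) / 1000.0, "mL", 0.0
    )

    steps = solids + liquids + [
        solvent_action,
        Action("cap", None, None, None, 0.0),
        Action("set_temperature", None, spec.condition.temperature, "degC", 0.0),
        Action("stir", None, spec.max_duration, "h", 0.0),
    ]
    steps += [Action("sample", None, SAMPLE_ALIQUOT_UL, "uL", t) for t in spec.sampling_schedule]
    steps.append(Action("end", None, None, None, spec.max_duration))
    return ActionSequence(recipe_id=spec.recipe_id, steps=steps)


#: Symbolic default hardware profile: verb -> list of (device, operation) command
#: templates; ``{...}`` placeholders are filled from the action being expanded.
DEFAULT_PROFILE: dict[str, list[dict[str, str]]] = {
    "dispense_solid": [
        {"device": "pantry_robot", "op": "fetch", "params": "container={reagent_id}"},
        {"device": "powder_dispenser", "op": "dose", "params": "target_mg={quantity}"},
        {"device": "powder_dispenser", "op": "verify", "params": "target_mg={quantity}"},
        {"device": "pantry_robot", "op": "return", "params": "container={reagent_id}"},
    ],
    "dispense_liquid": [
        {"device": "pantry_robot", "op": "fetch", "params": "container={reagent_id}"},
        {"device": "liquid_dispenser", "op": "dose", "params": "target_ul={quantity}"},
        {"device": "pantry_robot", "op": "return", "params": "container={reagent_id}"},
    ],
    "dispense_solvent": [
        {"device": "solvent_dispenser", "op": "dose", "params": "target_ml={quantity}"},
    ],
    "cap": [{"device": "capper", "op": "cap_vial", "params": ""}],
    "transfer": [{"device": "transfer_robot", "op": "move_vial", "params": ""}],
    "set_temperature": [
        {"device": "reactor", "op": "set_temperature", "params": "setpoint_c={quantity}"},
    ],
    "stir": [{"device": "reactor", "op": "stir", "params": "duration_h={quantity}"}],
    "sample": [
        {"device": "sampler", "op": "draw_aliquot", "params": "volume_ul={quantity};t_h={t_offset}"},
        {"device": "sample_prep", "op": "dilute_filter", "params": ""},
        {"device": "lcms", "op": "inject", "params": "t_h={t_offset}"},
    ],
    "end": [{"device": "reactor", "op": "release_slot", "params": ""}],
}


def translate(
    seq: ActionSequence, profile: Mapping[str, list[dict[str, str]]] = DEFAULT_PROFILE
) -> list[RobotCommand]:
    """Order-preserving expansion of an action sequence into robot commands."""
    commands: list[RobotCommand] = []
    for action in seq.steps:
        if action.verb not in profile:
            raise ProfileError(f"no command template for verb {action.verb!r}")
        ctx = {
            "reagent_id": action.reagent_id or "",
            "quantity": "" if action.quantity is None else f"{action.quantity:g}",
            "unit": action.unit or "",
            "t_offset": f"{action.t_offset:g}",
        }
        for tmpl in profile[action.verb]:
            raw = tmpl.get("params", "")
            params: tuple[tuple[str, str], ...] = ()
            if raw:
                params = tuple(
                    (k, v.format(**ctx)) for k, v in (p.split("=", 1) for p in raw.split(";"))
                )
            commands.append(RobotCommand(device=tmpl["device"], operation=tmpl["op"], params=params))
    return commands
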