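"""Interchange formats and seeded scenario fixtures.

Readers/writers: reagent libraries (CSV), condition-space and campaign
configuration (YAML), JSON-lines run logs.  Fixture generation builds
complete, self-consistent campaign scenarios — reagent library, condition
space (sized to an exact condition count via automatic exclusion
insertion), synthetic routes, campaign configuration and a seeded yield
landscape — from one master seed.
"""

from __future__ import annotations

import csv
import io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .chem_space import ROLES, ConditionSpace, Reagent
from .decision_policy import PolicyConfig
from .hdo_optimizer import KernelConfig
from .orchestrator import CampaignConfig, Route, SimulatedLab, target_from_reference
from .virtual_lab import LandscapeModel, LandscapeParams, NoiseConfig, generate_landscape

logger = logging.getLogger("chemloop.io")

__all__ = [
    "FormatError",
    "FixtureSet",
    "read_reagents",
    "write_reagents",
    "write_runlog",
    "read_runlog",
    "make_fixture",
    "composition_percentages",
    "space_to_dict",
    "space_from_dict",
]

REAGENT_HEADER = [
    "id", "name", "role", "smiles", "molecular_weight", "purity", "form", "density", "concentration",
]


class FormatError(ValueError):
    """Malformed interchange file."""


# ---------------------------------------------------------------------------
# Reagent CSV
# ---------------------------------------------------------------------------

def _parse_row(row: dict, line_no: int) -> Reagent:
    def num(key: str) -> float | None:
        raw = (row.get(key) or "").strip()
        if raw == "":
            return None
        try:
            return float(raw)
        except ValueError:
            raise FormatError(f"line {line_no}: non-numeric {key} {raw!r}") from None

    try:
        return Reagent(
            id=(row.get("id") or "").strip(),
            name=(row.get("name") or "").strip(),
            role=(row.get("role") or "").strip(),
            smiles=(row.get("smiles") or "").strip() or None,
            molecular_weight=num("molecular_weight") or 0.0,
            purity=num("purity") if num("purity") is not None else 1.0,
            form=(row.get("form") or "solid").strip(),
            density=num("density"),
            concentration=num("concentration"),
        )
    except ValueError as exc:
        raise FormatError(f"line {line_no}: {exc}") from None


def read_reagents(path: str | Path) -> dict[str, Reagent]:
    """Parse a reagent-library CSV into an id-keyed mapping.

    Malformed rows are reported with their line number; duplicate ids and
    unknown role tokens are format errors.  An empty file yields an empty
    library with a warning.
    """
    text = Path(path).read_text(encoding="utf-8")
    if not text.strip():
        logger.warning("reagent library %s is empty", path)
        return {}
    reader = csv.DictReader(io.StringIO(text))
    if reader.fieldnames is None or [f.strip() for f in reader.fieldnames] != REAGENT_HEADER:
        raise FormatError(f"unexpected reagent CSV header: {reader.fieldnames}")
    library: dict[str, Reagent] = {}
    for line_no, row in enumerate(reader, start=2):
        reagent = _parse_row(row, line_no)
        if reagent.id in library:
            raise FormatError(f"line {line_no}: duplicate reagent id {reagent.id!r}")
        library[reagent.id] = reagent
    return library


def write_reagents(library: Mapping[str, Reagent], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(REAGENT_HEADER)
        for reagent in library.values():
            writer.writerow([
                reagent.id, reagent.name, reagent.role, reagent.smiles or "",
                f"{reagent.molecular_weight:g}", f"{reagent.purity:g}", reagent.form,
                "" if reagent.density is None else f"{reagent.density:g}",
                "" if reagent.concentration is None else f"{reagent.concentration:g}",
            ])


# ---------------------------------------------------------------------------
# Run log (JSON lines)
# ---------------------------------------------------------------------------

def write_runlog(records: Iterable[dict], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(rec, separators=(",", ":"), sort_keys=False) + "\n")


def read_runlog(path: str | Path) -> list[dict]:
    records = []
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                records.append(json.loads(line))
            except json.JSONDecodeError:
                raise FormatError(f"line {line_no}: invalid JSON record") from None
    return records


def runlog_bytes(records: Iterable[dict]) -> bytes:
    """Canonical serialized form of a run log (replay-comparison helper)."""
    return "".join(json.dumps(r, separators=(",", ":")) + "\n" for r in records).encode()


# ---------------------------------------------------------------------------
# Space / config serialization
# ---------------------------------------------------------------------------

def space_to_dict(space: ConditionSpace) -> dict:
    return {
        "candidates": {r: list(space.candidates[r]) for r in ROLES},
        "temperatures": dict(space.temperature_map),
        "exclusions": [dict(p) for p in space.exclusions],
    }


def space_from_dict(data: Mapping) -> ConditionSpace:
    return ConditionSpace(
        candidates={r: list(v) for r, v in data["candidates"].items()},
        temperature_map={k: float(v) for k, v in data["temperatures"].items()},
        exclusions=[dict(p) for p in data.get("exclusions", [])],
    )


def save_config(fixture: "FixtureSet", directory: str | Path) -> Path:
    """Write a fixture as a reagents CSV + YAML campaign config; returns the
    YAML path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    reagents_path = directory / "reagents.csv"
    write_reagents(fixture.library, reagents_path)
    doc = {
        "reagents": reagents_path.name,
        "space": space_to_dict(fixture.routes[0].space),
        "routes": [
            {
                "route_id": r.route_id, "rank": r.rank, "label": r.label,
                "reactant1": r.reactant1, "amount_mmol": r.amount_mmol,
                "co_reactants": [list(c) for c in r.co_reactants],
                "catalyst_equiv": r.catalyst_equiv, "ligand_equiv": r.ligand_equiv,
                "base_equiv": r.base_equiv, "concentration": r.concentration,
                "max_duration": r.max_duration,
                "sampling_schedule": list(r.sampling_schedule),
            }
            for r in fixture.routes
        ],
        "campaign": {
            "target_yield": fixture.campaign.target_yield,
            "max_trials": fixture.campaign.max_trials,
            "n_slots": fixture.campaign.n_slots,
            "n_exploit": fixture.campaign.n_exploit,
            "n_explore": fixture.campaign.n_explore,
            "seed": fixture.campaign.seed,
        },
        "noise": vars(fixture.noise),
        "policy": vars(fixture.campaign.policy),
        "landscape": {
            "seed": fixture.landscape_seed,
            **{k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(fixture.landscape_params).items()},
        },
        "reference": {
            "yield_pct": fixture.reference_yield,
            "rate_per_h": fixture.reference_rate,
        },
    }
    cfg_path = directory / "campaign.yaml"
    cfg_path.write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")
    return cfg_path


def load_config(path: str | Path) -> "FixtureSet":
    """Load a campaign configuration written by :func:`save_config`."""
    path = Path(path)
    doc = yaml.safe_load(path.read_text(encoding="utf-8"))
    library = read_reagents(path.parent / doc["reagents"])
    space = space_from_dict(doc["space"])
    routes = [
        Route(
            route_id=r["route_id"], rank=int(r["rank"]), label=r.get("label", r["route_id"]),
            space=space, reactant1=r["reactant1"], amount_mmol=float(r["amount_mmol"]),
            co_reactants=tuple((str(a), float(b)) for a, b in r.get("co_reactants", [])),
            catalyst_equiv=float(r["catalyst_equiv"]),
            ligand_equiv=None if r.get("ligand_equiv") is None else float(r["ligand_equiv"]),
            base_equiv=float(r["base_equiv"]), concentration=float(r["concentration"]),
            max_duration=float(r["max_duration"]),
            sampling_schedule=tuple(float(t) for t in r["sampling_schedule"]),
        )
        for r in doc["routes"]
    ]
    noise = NoiseConfig(**doc["noise"])
    campaign = CampaignConfig(
        **doc["campaign"], noise=noise, policy=PolicyConfig(**doc["policy"]),
    )
    land = dict(doc["landscape"])
    landscape_seed = int(land.pop("seed"))
    land["k_range"] = tuple(land["k_range"])
    params = LandscapeParams(**land)
    return FixtureSet(
        profile="custom", master_seed=campaign.seed, library=library, routes=routes,
        campaign=campaign, noise=noise, landscape_params=params, landscape_seed=landscape_seed,
        reference_yield=(
            None if doc["reference"]["yield_pct"] is None else float(doc["reference"]["yield_pct"])
        ),
        reference_rate=(
            None if doc["reference"]["rate_per_h"] is None else float(doc["reference"]["rate_per_h"])
        ),
    )


# ---------------------------------------------------------------------------
# Fixture generation
# ---------------------------------------------------------------------------

# a handful of real reagents (name, SMILES, MW) to head each candidate list;
# the remainder are generated placeholders
_NAMED = {
    "catalyst": [
        ("Pd(OAc)2", "CC(=O)O[Pd]OC(C)=O", 224.51),
        ("Pd2(dba)3", None, 915.72),
        ("Pd(PPh3)4", None, 1155.56),
        ("Pd(dba)2", None, 575.00),
        ("PdCl2", "Cl[Pd]Cl", 177.33),
    ],
    "ligand": [
        ("XPhos", None, 476.72),
        ("XantPhos", None, 578.62),
        ("BrettPhos", None, 536.75),
        ("APhos", "CC(C)(C)P(C(C)(C)C)c1ccc(N(C)C)cc1", 265.37),
        ("PtBu3", "CC(C)(C)P(C(C)(C)C)C(C)(C)C", 202.32),
        ("PPh3", "c1ccc(P(c2ccccc2)c2ccccc2)cc1", 262.29),
    ],
    "base": [
        ("K2CO3", "C(=O)([O-])[O-].[K+].[K+]", 138.21),
        ("Cs2CO3", "C(=O)([O-])[O-].[Cs+].[Cs+]", 325.82),
        ("NaOtBu", "CC(C)(C)[O-].[Na+]", 96.10),
        ("K3PO4", None, 212.27),
        ("NaOH", "[OH-].[Na+]", 40.00),
    ],
    # (name, smiles, MW, density g/mL, reflux-ish reaction temperature degC)
    "solvent": [
        ("toluene", "Cc1ccccc1", 92.14, 0.867, 110.0),
        ("THF", "C1CCOC1", 72.11, 0.889, 65.0),
        ("DMF", "CN(C)C=O", 73.09, 0.944, 100.0),
        ("1,4-dioxane", "C1COCCO1", 88.11, 1.033, 100.0),
        ("EtOH", "CCO", 46.07, 0.789, 78.0),
    ],
}


@dataclass
class FixtureSet:
    """A complete seeded campaign scenario."""

    profile: str
    master_seed: int
    library: dict[str, Reagent]
    routes: list[Route]
    campaign: CampaignConfig
    noise: NoiseConfig
    landscape_params: LandscapeParams
    landscape_seed: int
    reference_yield: float | None = None
    reference_rate: float | None = None
    reference_condition_index: int = 1

    @property
    def space(self) -> ConditionSpace:
        return self.routes[0].space

    def landscape(self, route: Route | None = None) -> LandscapeModel:
        """Seeded landscape for a route, with the scenario's reference
        condition pinned to its prescribed conversion (when configured)."""
        route = route or self.routes[0]
        model = generate_landscape(route.space, self.landscape_seed, self.landscape_params)
        if self.reference_yield is not None:
            ref = self.reference_condition(model)
            model.set_reference(ref, self.reference_yield, self.reference_rate or 0.6)
        return model

    def reference_condition(self, model: LandscapeModel | None = None):
        model = model or generate_landscape(
            self.routes[0].space, self.landscape_seed, self.landscape_params
        )
        idx = self.reference_condition_index % len(model.conditions)
        if model.conditions[idx].key() == model.optimum.key():
            idx = (idx + 1) % len(model.conditions)
        return model.conditions[idx]

    def make_lab(self) -> SimulatedLab:
        return SimulatedLab(
            landscapes={r.route_id: self.landscape(r) for r in self.routes},
            noise=self.noise,
            library=self.library,
        )


def _mk_candidates(role: str, n: int, rng: np.random.Generator) -> list[Reagent]:
    named = _NAMED[role]
    out: list[Reagent] = []
    for i in range(n):
        rid = f"{role[:3].upper()}{i + 1}"
        if role == "solvent":
            if i < len(named):
                name, smiles, mw, density, _temp = named[i]
            else:
                name, smiles = f"solvent-{i + 1}", None
                mw = float(np.round(rng.uniform(60, 160), 2))
                density = float(np.round(rng.uniform(0.7, 1.1), 3))
            out.append(Reagent(rid, name, "solvent", mw, 0.995, "liquid", smiles, density=density))
        else:
            if i < len(named):
                name, smiles, mw = named[i]
            else:
                name, smiles = f"{role}-{i + 1}", None
                mw = float(np.round(rng.uniform(100, 900), 2))
            purity = float(np.round(rng.uniform(0.95, 1.0), 3))
            out.append(Reagent(rid, name, role, mw, purity, "solid", smiles))
    return out


def _solvent_temperature(i: int, rng: np.random.Generator) -> float:
    named = _NAMED["solvent"]
    if i < len(named):
        return named[i][4]
    return float(rng.choice([60.0, 80.0, 90.0, 100.0, 110.0, 120.0]))


def _make_space(
    cards: Mapping[str, int], target_size: int | None, rng: np.random.Generator
) -> tuple[ConditionSpace, dict[str, Reagent]]:
    library: dict[str, Reagent] = {}
    candidates: dict[str, list[str]] = {}
    temperature_map: dict[str, float] = {}
    for role in ROLES:
        reagents = _mk_candidates(role, cards[role], rng)
        candidates[role] = [r.id for r in reagents]
        library.update({r.id: r for r in reagents})
    for i, sid in enumerate(candidates["solvent"]):
        temperature_map[sid] = _solvent_temperature(i, rng)

    exclusions: list[dict[str, str]] = []
    product = int(np.prod([cards[r] for r in ROLES]))
    if target_size is not None:
        if not 1 <= target_size <= product:
            raise ValueError("target size outside the product-space range")
        n_excl = product - target_size
        if n_excl:
            # exclude specific full assignments chosen uniformly at random
            picks = rng.choice(product, size=n_excl, replace=False)
            shape = tuple(cards[r] for r in ROLES)
            for flat in sorted(int(p) for p in picks):
                idx = np.unravel_index(flat, shape)
                exclusions.append({role: candidates[role][j] for role, j in zip(ROLES, idx)})
    space = ConditionSpace(candidates=candidates, temperature_map=temperature_map, exclusions=exclusions)
    return space, library


_PROFILES = {
    # cards per role, exact size target, reference conversion %, campaign target %
    "tiny": (dict(catalyst=2, ligand=2, base=2, solvent=2), None, None, 90.0),
    "m1_like": (dict(catalyst=7, ligand=8, base=7, solvent=8), 2722, 86.5, target_from_reference(86.5)),
    "m2_like": (dict(catalyst=6, ligand=6, base=5, solvent=6), None, 15.0, 70.0),
    "m3_like": (dict(catalyst=6, ligand=6, base=5, solvent=6), None, 50.9, 80.0),
}


def make_fixture(profile: str, seed: int = 0) -> FixtureSet:
    """Build a named campaign scenario, fully determined by ``seed``.

    ``tiny`` is a 16-condition smoke-test space with two rank-ordered
    routes; ``m1_like`` is a 2722-condition space (exclusion-constrained
    product space) with a planted 100 % optimum and a pinned 86.5 %
    reference condition; ``m2_like``/``m3_like`` are harder scenarios whose
    reference conditions sit at 15.0 % / 50.9 % with campaign targets
    70 % / 80 %.
    """
    if profile not in _PROFILES:
        raise ValueError(f"unknown fixture profile {profile!r}")
    cards, size, ref_yield, target = _PROFILES[profile]
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(11,)))
    space, library = _make_space(cards, size, rng)

    # reactants shared by every profile
    library["R1"] = Reagent("R1", "aryl halide", "reactant", 236.10, 0.98, "solid", None)
    library["R2"] = Reagent("R2", "coupling partner", "reactant", 158.98, 0.97, "solid", None)

    step = 2.0 if profile == "m1_like" else 1.0
    schedule = tuple(float(i) * step for i in range(1, 9))
    max_duration = float(schedule[-1])
    route_kwargs = dict(
        space=space, reactant1="R1", amount_mmol=0.5, co_reactants=(("R2", 1.2),),
        catalyst_equiv=0.05, ligand_equiv=None, base_equiv=2.0, concentration=0.2,
        max_duration=max_duration, sampling_schedule=schedule,
    )
    routes = [Route(route_id=f"{profile}-1", rank=1, label=f"{profile} step 1", **route_kwargs)]
    if profile == "tiny":
        routes.append(Route(route_id=f"{profile}-2", rank=2, label=f"{profile} step 2", **route_kwargs))

    landscape_seed = int(np.random.SeedSequence(entropy=seed, spawn_key=(12,)).generate_state(1)[0] % 2**31)
    params = LandscapeParams()
    noise = NoiseConfig()
    campaign = CampaignConfig(
        target_yield=target,
        max_trials=max(16, int(round(0.05 * (size or space.size)))),
        seed=seed,
        noise=noise,
        kernel=KernelConfig(),
    )
    ref_idx = int(rng.integers(1, space.size))
    return FixtureSet(
        profile=profile, master_seed=seed, library=library, routes=routes,
        campaign=campaign, noise=noise, landscape_params=params,
        landscape_seed=landscape_seed, reference_yield=ref_yield,
        reference_rate=0.6, reference_condition_index=ref_idx,
    )


# ---------------------------------------------------------------------------
# Scenario metadata arithmetic
# ---------------------------------------------------------------------------

def composition_percentages(counts: Mapping[str, int], total: int, ndigits: int = 1) -> dict[str, float]:
    """Percentage share of each class count in a dataset of ``total`` records
    (e.g. the reaction-class composition of a condition-model training set)."""
    if total <= 0:
        raise ValueError("total must be positive")
    if any(c < 0 or c > total for c in counts.values()):
        raise ValueError("class counts must lie in [0, total]")
    return {k: round(100.0 * v / total, ndigits) for k, v in counts.items()}
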