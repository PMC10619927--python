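"""Discrete reaction-condition search spaces.

A condition space is the Cartesian product of per-role candidate reagent
lists (catalyst, ligand, base, solvent) minus a set of excluded
assignments.  Temperature is not a free dimension: each solvent carries a
fixed reaction temperature, so every condition inherits the temperature of
its solvent choice.

The module also provides deterministic enumeration, featurization of
conditions for surrogate models, and space-filling initial designs by
greedy multi-start maximin selection under the role-wise Hamming distance.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ROLES",
    "Reagent",
    "ConditionSpace",
    "Condition",
    "FeatureVector",
    "ConfigurationError",
    "LookupError_",
    "enumerate_conditions",
    "featurize",
    "role_hamming",
    "maximin_design",
]

#: Optimized roles, in canonical (lexicographic enumeration) order.
ROLES: tuple[str, ...] = ("catalyst", "ligand", "base", "solvent")

VALID_ROLES = set(ROLES) | {"reactant"}
VALID_FORMS = {"solid", "liquid", "solution"}


class ConfigurationError(ValueError):
    """Invalid space / campaign configuration."""


class LookupError_(KeyError):
    """A reagent or condition reference could not be resolved."""


@dataclass(frozen=True)
class Reagent:
    """One chemical in the reagent library.

    ``purity`` is a mass fraction in (0, 1]; ``density`` (g/mL) is required
    for liquids and ``concentration`` (mol/L) for solutions, since dispense
    quantification needs them to convert moles to volumes.
    """

    id: str
    name: str
    role: str
    molecular_weight: float
    purity: float = 1.0
    form: str = "solid"
    smiles: str | None = None
    density: float | None = None
    concentration: float | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ConfigurationError("reagent id must be non-empty")
        if self.role not in VALID_ROLES:
            raise ConfigurationError(f"unknown role {self.role!r} for reagent {self.id}")
        if self.form not in VALID_FORMS:
            raise ConfigurationError(f"unknown form {self.form!r} for reagent {self.id}")
        if not self.molecular_weight > 0:
            raise ConfigurationError(f"molecular_weight must be > 0 for reagent {self.id}")
        if not (0 < self.purity <= 1):
            raise ConfigurationError(f"purity must be in (0, 1] for reagent {self.id}")
        if self.form == "liquid" and not (self.density and self.density > 0):
            raise ConfigurationError(f"liquid reagent {self.id} requires density > 0")
        if self.form == "solution" and not (self.concentration and self.concentration > 0):
            raise ConfigurationError(f"solution reagent {self.id} requires concentration > 0")


@dataclass(frozen=True)
class Condition:
    """One point of the search space: a reagent id per role plus the
    solvent-derived temperature (degC)."""

    choice: Mapping[str, str]
    temperature: float

    def key(self) -> tuple[str, ...]:
        return tuple(self.choice[r] for r in ROLES)

    def __repr__(self) -> str:  # compact, stable
        inner = ", ".join(f"{r}={self.choice[r]}" for r in ROLES)
        return f"Condition({inner}, T={self.temperature:g})"


@dataclass(frozen=True)
class FeatureVector:
    values: tuple[float, ...]
    scheme: str


@dataclass
class ConditionSpace:
    """Product space over per-role candidate lists with exclusions.

    ``exclusions`` are partial role->id patterns; any full assignment
    matching every entry of some pattern is removed from the space.
    """

    candidates: dict[str, list[str]]
    temperature_map: dict[str, float]
    exclusions: list[dict[str, str]] = field(default_factory=list)
    _full_exclusions: set[tuple[str, ...]] = field(
        init=False, repr=False, compare=False, default_factory=set
    )
    _partial_exclusions: list[dict[str, str]] = field(
        init=False, repr=False, compare=False, default_factory=list
    )

    def __post_init__(self) -> None:
        for role in ROLES:
            if role not in self.candidates or not self.candidates[role]:
                raise ConfigurationError(f"empty or missing candidate list for role {role!r}")
            if len(set(self.candidates[role])) != len(self.candidates[role]):
                raise ConfigurationError(f"duplicate candidate ids for role {role!r}")
        for solvent in self.candidates["solvent"]:
            if solvent not in self.temperature_map:
                raise ConfigurationError(f"solvent {solvent!r} has no temperature entry")
        for pat in self.exclusions:
            for role, rid in pat.items():
                if role not in ROLES:
                    raise ConfigurationError(f"exclusion pattern uses unknown role {role!r}")
                if rid not in self.candidates[role]:
                    raise ConfigurationError(
                        f"exclusion pattern references unknown candidate {rid!r} for {role!r}"
                    )
        # split exclusions into full assignments (fast set lookup) and
        # genuinely partial patterns
        for pat in self.exclusions:
            if len(pat) == len(ROLES):
                self._full_exclusions.add(tuple(pat[r] for r in ROLES))
            else:
                self._partial_exclusions.append(pat)
        if self.size < 1:
            raise ConfigurationError("exclusions remove every condition from the space")

    @property
    def cardinalities(self) -> tuple[int, ...]:
        return tuple(len(self.candidates[r]) for r in ROLES)

    @property
    def product_size(self) -> int:
        return int(np.prod(self.cardinalities))

    @property
    def size(self) -> int:
        """Number of non-excluded full assignments."""
        if not self.exclusions:
            return self.product_size
        return sum(
            1
            for assignment in itertools.product(*(self.candidates[r] for r in ROLES))
            if not self._excluded(dict(zip(ROLES, assignment)))
        )

    def _excluded(self, choice: Mapping[str, str]) -> bool:
        if self._full_exclusions and tuple(choice.get(r) for r in ROLES) in self._full_exclusions:
            return True
        return any(
            all(choice.get(role) == rid for role, rid in pat.items())
            for pat in self._partial_exclusions
        )

    def contains(self, condition: Condition) -> bool:
        for role in ROLES:
            if condition.choice.get(role) not in self.candidates[role]:
                return False
        return not self._excluded(condition.choice)

    def make_condition(self, choice: Mapping[str, str]) -> Condition:
        """Build a validated condition, deriving temperature from the solvent."""
        missing = [r for r in ROLES if r not in choice]
        if missing:
            raise ConfigurationError(f"condition missing roles {missing}")
        for role in ROLES:
            if choice[role] not in self.candidates[role]:
                raise LookupError_(f"{choice[role]!r} is not a {role} candidate")
        if self._excluded(choice):
            raise ConfigurationError(f"condition {dict(choice)} is excluded from the space")
        return Condition(
            choice={r: choice[r] for r in ROLES},
            temperature=self.temperature_map[choice["solvent"]],
        )

    def level_indices(self, condition: Condition) -> tuple[int, ...]:
        """Per-role candidate-list indices of a condition (surrogate encoding)."""
        out = []
        for role in ROLES:
            try:
                out.append(self.candidates[role].index(condition.choice[role]))
            except ValueError:
                raise LookupError_(
                    f"{condition.choice[role]!r} unknown for role {role!r}"
                ) from None
        return tuple(out)


def enumerate_conditions(space: ConditionSpace) -> list[Condition]:
    """All conditions of the space in lexicographic (catalyst, ligand, base,
    solvent) candidate-index order."""
    out: list[Condition] = []
    for assignment in itertools.product(*(space.candidates[r] for r in ROLES)):
        choice = dict(zip(ROLES, assignment))
        if space._excluded(choice):
            continue
        out.append(Condition(choice=choice, temperature=space.temperature_map[choice["solvent"]]))
    if not out:
        raise ConfigurationError("space enumerates to zero conditions")
    return out


def featurize(
    condition: Condition,
    space: ConditionSpace,
    scheme: str = "one_hot",
    library: Mapping[str, Reagent] | None = None,
) -> FeatureVector:
    """Encode a condition as a numeric vector.

    ``one_hot``: concatenated per-role indicator blocks (block length = role
    cardinality, exactly one 1 per block).  ``descriptor``: per-role reagent
    descriptors (molecular weight and purity) from the library, plus the
    condition temperature.
    """
    idx = space.level_indices(condition)
    if scheme == "one_hot":
        values: list[float] = []
        for card, i in zip(space.cardinalities, idx):
            block = [0.0] * card
            block[i] = 1.0
            values.extend(block)
        return FeatureVector(values=tuple(values), scheme="one_hot")
    if scheme == "descriptor":
        if library is None:
            raise ConfigurationError("descriptor featurization requires a reagent library")
        values = []
        for role in ROLES:
            rid = condition.choice[role]
            if rid not in library:
                raise LookupError_(f"reagent {rid!r} not in library")
            reagent = library[rid]
            values.extend([reagent.molecular_weight, reagent.purity])
        values.append(condition.temperature)
        return FeatureVector(values=tuple(values), scheme="descriptor")
    raise ConfigurationError(f"unknown featurization scheme {scheme!r}")


def role_hamming(a: Condition, b: Condition) -> int:
    """Number of roles on which two conditions differ (0..4)."""
    return sum(a.choice[r] != b.choice[r] for r in ROLES)


def maximin_design(
    space: ConditionSpace,
    k: int,
    seed: int | np.random.Generator = 0,
    n_starts: int = 64,
    pool: Sequence[Condition] | None = None,
    anchors: Sequence[Condition] = (),
) -> list[Condition]:
    """Space-filling design of ``k`` distinct conditions.

    Greedy maximin under the role-Hamming distance with ``n_starts`` random
    multi-starts: each start seeds the design with a uniformly random
    condition and repeatedly adds the candidate maximizing its minimum
    distance to the selected set (ties to the lexicographically first
    candidate).  The start whose design has the largest minimum pairwise
    distance wins; ties between starts go to the lexicographically smallest
    design.  ``pool`` restricts the design to a subset of the space (e.g.
    untried conditions); it must be in enumeration order.  ``anchors`` are
    already-selected conditions the design must also stay far from (they are
    not returned and do not count toward ``k``).
    """
    conditions = list(pool) if pool is not None else enumerate_conditions(space)
    n = len(conditions)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    levels = np.array([space.level_indices(c) for c in conditions], dtype=np.int32)
    anchor_levels = (
        np.array([space.level_indices(c) for c in anchors], dtype=np.int32)
        if anchors
        else None
    )

    if k == 1 and anchor_levels is None:
        # Degenerate design: defined min-distance is +inf.
        return [conditions[0]]

    best_idx: list[int] | None = None
    best_score = -1.0
    for _ in range(max(1, n_starts)):
        if anchor_levels is not None:
            # distance to the anchors seeds the selection greedily
            mindist = (levels[:, None, :] != anchor_levels[None, :, :]).sum(axis=2).min(axis=1)
            selected: list[int] = []
            n_grow = k
        else:
            start = int(rng.integers(n))
            selected = [start]
            # min role-Hamming distance from every pool point to the selected set
            mindist = (levels != levels[start]).sum(axis=1)
            mindist[start] = -1  # never reselect
            n_grow = k - 1
        for _ in range(n_grow):
            nxt = int(np.argmax(mindist))  # argmax takes first (lexicographic) tie
            selected.append(nxt)
            d = (levels != levels[nxt]).sum(axis=1)
            np.minimum(mindist, d, out=mindist)
            mindist[nxt] = -1
        sel = sorted(selected)
        sub = levels[sel]
        if anchor_levels is not None:
            sub = np.vstack([sub, anchor_levels])
        pair = (sub[:, None, :] != sub[None, :, :]).sum(axis=2)
        score = float(pair[np.triu_indices(len(sub), 1)].min())
        if score > best_score or (score == best_score and best_idx is not None and sel < best_idx):
            best_score = score
            best_idx = sel
        if anchor_levels is not None:
            break  # anchored greedy growth is deterministic; no restarts needed
    assert best_idx is not None
    return [conditions[i] for i in best_idx]


def min_pairwise_distance(design: Sequence[Condition]) -> float:
    """Smallest role-Hamming distance among design pairs (+inf for singletons)."""
    if len(design) < 2:
        return math.inf
    return float(
        min(role_hamming(a, b) for a, b in itertools.combinations(design, 2))
    )
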