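"""Continue / Withdraw / Sweep decisions from in-progress yield trajectories.

The policy forecasts where a running reaction is heading by fitting the
saturating first-order form y(t) = Yinf (1 - exp(-k t)) to the measured
trajectory, then applies a fixed precedence of qualitative rules:

1. the last measurement already meets the target  ->  TargetMet;
2. too few samples to judge                       ->  Continue;
3. pessimistic plateau forecast AND stalled slope ->  Withdraw
   (both are required so that slow-but-high reactions are not abandoned);
4. the whole synthetic route looks hopeless       ->  Sweep
   (enough recipes finished and the route's best is far below target);
otherwise Continue.

Every threshold is an explicit, logged configuration value: the branching
structure is principled, the numbers are tunable defaults.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.optimize import curve_fit

from .recipe_engine import RecipeSpec
from .virtual_lab import YieldTrajectory

__all__ = [
    "PlateauEstimate",
    "PolicyConfig",
    "DecisionSignal",
    "RouteHistory",
    "estimate_plateau",
    "assess",
]


class DecisionSignal(str, Enum):
    CONTINUE = "Continue"
    WITHDRAW = "Withdraw"
    SWEEP = "Sweep"
    TARGET_MET = "TargetMet"


@dataclass(frozen=True)
class PlateauEstimate:
    y_inf: float  # % (soft-capped at 120 to allow noise overshoot)
    k: float | None  # 1/h, > 0 when status == "ok"
    residual_sd: float
    se_y_inf: float
    se_k: float
    status: str  # ok | underdetermined | degenerate


@dataclass(frozen=True)
class PolicyConfig:
    """Decision thresholds (all in trajectory units: %, h)."""

    continue_margin: float = 5.0  # % below target still worth waiting for
    min_samples: int = 3  # samples required before judging
    stall_slope: float = 0.5  # %/h; slower recent progress counts as stalled
    sweep_min_recipes: int = 10  # route recipes finished before Sweep is considered
    sweep_best_fraction: float = 0.5  # route best must exceed this fraction of target

    def __post_init__(self) -> None:
        if min(self.continue_margin, self.stall_slope, self.sweep_best_fraction) < 0:
            raise ValueError("policy thresholds must be >= 0")
        if self.min_samples < 1 or self.sweep_min_recipes < 1:
            raise ValueError("sample/recipe counts must be >= 1")


@dataclass
class RouteHistory:
    """Per-route statistics the Sweep rule operates on."""

    n_finished: int = 0  # completed or withdrawn recipes of the route
    best_yield: float = 0.0

    def record(self, final_yield: float) -> None:
        self.n_finished += 1
        self.best_yield = max(self.best_yield, final_yield)


def _model(t: np.ndarray, y_inf: float, k: float) -> np.ndarray:
    return y_inf * (1.0 - np.exp(-k * t))


def estimate_plateau(trajectory: YieldTrajectory) -> PlateauEstimate:
    """Plateau forecast by nonlinear least squares with multi-start
    initialization (Yinf in {last, 1.2*last}, k in {0.1, 0.5, 2}).

    Fewer than 3 samples is underdetermined (two parameters); an all-zero
    trajectory is degenerate.  Both fall back to the last measured yield.
    """
    if not trajectory.samples:
        raise ValueError("trajectory has no samples")
    t = np.array([s[0] for s in trajectory.samples])
    y = np.array([s[1] for s in trajectory.samples])
    last = float(y[-1])

    if np.all(y == 0):
        return PlateauEstimate(0.0, None, 0.0, 0.0, 0.0, "degenerate")
    if len(y) < 3:
        return PlateauEstimate(last, None, 0.0, float("inf"), float("inf"), "underdetermined")

    best = None
    for y0 in (min(max(last, 1.0), 119.0), min(max(1.2 * last, 1.0), 119.0)):
        for k0 in (0.1, 0.5, 2.0):
            try:
                popt, pcov = curve_fit(
                    _model, t, y, p0=(y0, k0),
                    bounds=([0.0, 1e-6], [120.0, 50.0]), maxfev=2000,
                )
            except (RuntimeError, ValueError):
                continue
            rss = float(np.sum((y - _model(t, *popt)) ** 2))
            if best is None or rss < best[0]:
                best = (rss, popt, pcov)
    if best is None:
        return PlateauEstimate(last, None, 0.0, float("inf"), float("inf"), "degenerate")
    rss, (y_hat, k_hat), pcov = best
    dof = max(len(y) - 2, 1)
    resid_sd = float(np.sqrt(rss / dof))
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    return PlateauEstimate(
        y_inf=float(y_hat), k=float(k_hat), residual_sd=resid_sd,
        se_y_inf=float(se[0]), se_k=float(se[1]), status="ok",
    )


def _recent_slope(trajectory: YieldTrajectory) -> float:
    (t0, y0), (t1, y1) = trajectory.samples[-2], trajectory.samples[-1]
    return (y1 - y0) / (t1 - t0)


def assess(
    trajectory: YieldTrajectory,
    spec: RecipeSpec,
    route_history: RouteHistory,
    config: PolicyConfig = PolicyConfig(),
) -> DecisionSignal:
    """Three-way trajectory decision with fixed precedence (see module doc).

    Deterministic in its inputs; TargetMet always wins, and Withdraw
    requires both a pessimistic forecast (upper confidence bound of the
    fitted plateau below target minus margin) and a stalled recent slope.
    """
    if not trajectory.samples:
        raise ValueError("trajectory has no samples")
    target = spec.target_yield

    if trajectory.last_yield >= target:
        return DecisionSignal.TARGET_MET
    if len(trajectory.samples) < config.min_samples:
        return DecisionSignal.CONTINUE

    est = estimate_plateau(trajectory)
    ucb = est.y_inf + 2.0 * (est.se_y_inf if np.isfinite(est.se_y_inf) else 0.0)
    if ucb < target - config.continue_margin and _recent_slope(trajectory) < config.stall_slope:
        return DecisionSignal.WITHDRAW

    if (
        route_history.n_finished >= config.sweep_min_recipes
        and route_history.best_yield < config.sweep_best_fraction * target
    ):
        return DecisionSignal.SWEEP

    return DecisionSignal.CONTINUE
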