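"""Hybrid surrogate/Bayesian-optimization loop over categorical condition spaces.

Exploitation is driven by a Gaussian-process surrogate with a categorical
overlap kernel

    k(c, c') = signal_var * exp( sum_r w_r * [c_r == c'_r]  -  sum_r w_r )
               + linear_var * sum_r [c_r == c'_r],

i.e. a squared-exponential over the weighted role-Hamming distance (one
learnable weight per role) plus a linear kernel on the one-hot role encoding.
The linear term is a Bayesian ridge over additive per-role level effects: it
lets the posterior mean extrapolate to untried combinations of individually
favorable levels — the signature of structured reaction-condition landscapes
— while the exponential term captures interactions and the residual
variance.  The surrogate is a pluggable stand-in for a
learned condition-recommendation model: anything exposing
``posterior(levels) -> (mean, sd)`` can replace it.  Exploration uses the
expected-improvement acquisition; batches mix top-posterior-mean
(exploitation) with top-EI (exploration) proposals, seeded at cold start by
prior ranking plus a maximin space-filling design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from scipy.stats import norm

from .chem_space import Condition, ConditionSpace, enumerate_conditions, maximin_design

logger = logging.getLogger("chemloop.hdo")

__all__ = [
    "KernelConfig",
    "Observation",
    "SurrogateState",
    "RecipeRepository",
    "RepoEntry",
    "SpaceExhausted",
    "fit_surrogate",
    "expected_improvement",
    "propose_batch",
    "update_repository",
]

_JITTER = 1e-10


class SpaceExhausted(RuntimeError):
    """Every condition of the space has been tried."""


@dataclass(frozen=True)
class KernelConfig:
    """Hyperparameter priors/bounds for the overlap-kernel GP.

    ``prior_mean`` is the conversion (%) assumed for unseen chemistry — a
    deliberately pessimistic 20 % so that unexplored regions are proposed on
    uncertainty, not optimism.  ``fixed_noise_var`` pins the observation
    noise instead of fitting it (0 gives an interpolating GP).
    """

    prior_mean: float = 20.0
    signal_var0: float = 400.0
    noise_var0: float = 4.0
    weight_bounds: tuple[float, float] = (0.05, 10.0)
    signal_bounds: tuple[float, float] = (1.0, 2500.0)
    noise_bounds: tuple[float, float] = (1e-8, 1e3)
    n_restarts: int = 5
    fixed_noise_var: float | None = None
    #: center the GP on the (weighted) mean of the observations once data
    #: exists; the configured prior_mean applies only to the empty posterior
    center_on_data: bool = True
    #: additive component: a linear kernel on the one-hot role encoding
    #: (tau^2 * number of matching roles), i.e. a Bayesian ridge over per-role
    #: level effects; lets the posterior extrapolate to untried combinations
    #: of individually favorable levels with honest uncertainty
    linear_var0: float = 64.0
    linear_bounds: tuple[float, float] = (1e-2, 1e3)


@dataclass(frozen=True)
class Observation:
    levels: tuple[int, ...]  # per-role candidate indices
    yield_pct: float
    weight: float = 1.0  # <1 down-weights (inflates noise of) the observation


def _overlap_kernel(
    X1: np.ndarray, X2: np.ndarray, weights: np.ndarray, signal_var: float,
    linear_var: float = 0.0,
) -> np.ndarray:
    mismatch = X1[:, None, :] != X2[None, :, :]
    k = signal_var * np.exp(-(mismatch * weights).sum(axis=2))
    if linear_var > 0:
        k = k + linear_var * (~mismatch).sum(axis=2)
    return k


@dataclass
class SurrogateState:
    """Fitted GP posterior over a condition space."""

    X: np.ndarray  # (n, n_roles) int levels
    y: np.ndarray  # (n,) observed conversions (%)
    obs_weights: np.ndarray  # (n,)
    weights: np.ndarray  # per-role kernel weights
    signal_var: float
    noise_var: float
    prior_mean: float
    linear_var: float = 0.0
    log_marginal_likelihood: float = float("nan")
    _chol: tuple | None = field(default=None, repr=False)
    _alpha: np.ndarray | None = field(default=None, repr=False)

    def _ensure_factorized(self) -> None:
        if self._chol is not None or len(self.y) == 0:
            return
        K = _overlap_kernel(self.X, self.X, self.weights, self.signal_var, self.linear_var)
        K[np.diag_indices_from(K)] += self.noise_var / self.obs_weights + _JITTER
        self._chol = cho_factor(K, lower=True)
        self._alpha = cho_solve(self._chol, self.y - self.prior_mean)

    def posterior(self, levels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mean and sd of the latent conversion at each query row."""
        levels = np.atleast_2d(np.asarray(levels, dtype=np.int32))
        n_roles = levels.shape[1]
        prior_var = self.signal_var + n_roles * self.linear_var
        if len(self.y) == 0:
            mean = np.full(len(levels), self.prior_mean)
            sd = np.full(len(levels), np.sqrt(prior_var))
            return mean, sd
        self._ensure_factorized()
        Ks = _overlap_kernel(levels, self.X, self.weights, self.signal_var, self.linear_var)
        mean = self.prior_mean + Ks @ self._alpha
        v = cho_solve(self._chol, Ks.T)
        var = prior_var - np.einsum("ij,ji->i", Ks, v)
        return mean, np.sqrt(np.clip(var, 0.0, None))

    def posterior_one(self, levels: Sequence[int]) -> tuple[float, float]:
        m, s = self.posterior(np.asarray([levels]))
        return float(m[0]), float(s[0])


def _nll(log_params: np.ndarray, X: np.ndarray, y: np.ndarray, w_obs: np.ndarray,
         prior_mean: float, fixed_noise: float | None) -> float:
    n_roles = X.shape[1]
    weights = np.exp(log_params[:n_roles])
    signal = np.exp(log_params[n_roles])
    linear = np.exp(log_params[n_roles + 1])
    noise = fixed_noise if fixed_noise is not None else np.exp(log_params[n_roles + 2])
    K = _overlap_kernel(X, X, weights, signal, linear)
    K[np.diag_indices_from(K)] += noise / w_obs + _JITTER
    try:
        c = cho_factor(K, lower=True)
    except np.linalg.LinAlgError:  # pragma: no cover
        return 1e12
    r = y - prior_mean
    alpha = cho_solve(c, r)
    logdet = 2.0 * np.sum(np.log(np.diag(c[0])))
    return float(0.5 * r @ alpha + 0.5 * logdet + 0.5 * len(y) * np.log(2 * np.pi))


def fit_surrogate(
    observations: Iterable[Observation],
    config: KernelConfig = KernelConfig(),
    seed: int | np.random.Generator = 0,
    hyperparams: tuple[np.ndarray, float, float, float] | None = None,
) -> SurrogateState:
    """Fit kernel hyperparameters by marginal-likelihood maximization.

    Uses L-BFGS-B from ``config.n_restarts`` seeded random initializations
    in log-parameter space.  With zero observations the returned state is
    the prior.  Duplicate conditions with conflicting yields are retained
    and explained by the fitted noise term.  Passing ``hyperparams``
    (per-role weights, signal variance, linear variance, noise variance)
    skips the marginal-likelihood optimization and only conditions on the
    data — useful between periodic hyperparameter refreshes.
    """
    obs = list(observations)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if not obs:
        return SurrogateState(
            X=np.zeros((0, 4), dtype=np.int32),
            y=np.zeros(0),
            obs_weights=np.zeros(0),
            weights=np.ones(4),
            signal_var=config.signal_var0,
            noise_var=config.fixed_noise_var if config.fixed_noise_var is not None else config.noise_var0,
            prior_mean=config.prior_mean,
            linear_var=config.linear_var0,
        )

    X = np.array([o.levels for o in obs], dtype=np.int32)
    y = np.array([o.yield_pct for o in obs], dtype=float)
    w_obs = np.array([max(o.weight, 1e-6) for o in obs], dtype=float)
    n_roles = X.shape[1]
    prior_mean = (
        float(np.average(y, weights=w_obs)) if config.center_on_data else config.prior_mean
    )
    if hyperparams is not None:
        weights, signal, linear, noise = hyperparams
        return SurrogateState(
            X=X, y=y, obs_weights=w_obs,
            weights=np.asarray(weights, dtype=float), signal_var=float(signal),
            noise_var=float(noise), prior_mean=prior_mean, linear_var=float(linear),
        )

    lb = [np.log(config.weight_bounds[0])] * n_roles + [np.log(config.signal_bounds[0]), np.log(config.linear_bounds[0])]
    ub = [np.log(config.weight_bounds[1])] * n_roles + [np.log(config.signal_bounds[1]), np.log(config.linear_bounds[1])]
    x0_center = [np.log(1.0)] * n_roles + [np.log(config.signal_var0), np.log(config.linear_var0)]
    if config.fixed_noise_var is None:
        lb.append(np.log(config.noise_bounds[0]))
        ub.append(np.log(config.noise_bounds[1]))
        x0_center.append(np.log(config.noise_var0))
    bounds = list(zip(lb, ub))

    best = None
    for i in range(max(1, config.n_restarts)):
        x0 = np.array(x0_center) if i == 0 else rng.uniform(np.array(lb), np.array(ub))
        res = minimize(
            _nll,
            x0,
            args=(X, y, w_obs, prior_mean, config.fixed_noise_var),
            method="L-BFGS-B",
            bounds=bounds,
        )
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    p = best.x
    weights = np.exp(p[:n_roles])
    signal = float(np.exp(p[n_roles]))
    linear = float(np.exp(p[n_roles + 1]))
    noise = config.fixed_noise_var if config.fixed_noise_var is not None else float(np.exp(p[n_roles + 2]))
    state = SurrogateState(
        X=X, y=y, obs_weights=w_obs,
        weights=weights, signal_var=signal, noise_var=noise,
        prior_mean=prior_mean, linear_var=linear,
        log_marginal_likelihood=-float(best.fun),
    )
    logger.debug(
        "surrogate fit: n=%d weights=%s signal=%.3g noise=%.3g lml=%.3f",
        len(y), np.round(weights, 3), signal, noise, state.log_marginal_likelihood,
    )
    return state


def expected_improvement(
    state: SurrogateState, levels: Sequence[int] | np.ndarray, best_observed: float
) -> float | np.ndarray:
    """Closed-form expected improvement over the incumbent.

    At zero posterior sd this degenerates to max(mean - best, 0).
    """
    arr = np.atleast_2d(np.asarray(levels, dtype=np.int32))
    mean, sd = state.posterior(arr)
    imp = mean - best_observed
    ei = np.where(imp > 0, imp, 0.0).astype(float)
    pos = sd > 0
    z = np.zeros_like(ei)
    z[pos] = imp[pos] / sd[pos]
    ei[pos] = imp[pos] * norm.cdf(z[pos]) + sd[pos] * norm.pdf(z[pos])
    out = np.clip(ei, 0.0, None)
    return out if np.ndim(levels) > 1 else float(out[0])


def propose_batch(
    state: SurrogateState,
    space: ConditionSpace,
    history: Sequence[tuple[Condition, float]],
    n_exploit: int = 3,
    n_explore: int = 3,
    seed: int | np.random.Generator = 0,
    exclude: Iterable[Condition] = (),
    pool: Sequence[Condition] | None = None,
) -> list[Condition]:
    """Propose the next batch of distinct, untried conditions.

    Cold start (empty history): ``n_exploit`` by prior-mean ranking (which
    degenerates to lexicographic order under a constant prior) plus
    ``n_explore`` from a maximin space-filling design over the untried pool.
    Warm: ``n_exploit`` top-posterior-mean plus ``n_explore`` top-EI
    conditions, de-duplicated and backfilled by EI rank.  ``exclude`` marks
    additional conditions (e.g. currently running) that must not be
    re-proposed.  Raises :class:`SpaceExhausted` when no candidates remain.
    """
    conditions = list(pool) if pool is not None else enumerate_conditions(space)
    tried = {c.key() for c, _ in history} | {c.key() for c in exclude}
    untried = [c for c in conditions if c.key() not in tried]
    if not untried:
        raise SpaceExhausted("all conditions of the space have been tried")
    want = min(n_exploit + n_explore, len(untried))
    if want == 0:
        return []

    levels = np.array([space.level_indices(c) for c in untried], dtype=np.int32)

    if not history:
        picks = untried[: min(n_exploit, len(untried))]
        chosen = {c.key() for c in picks}
        remaining = [c for c in untried if c.key() not in chosen]
        k = min(n_explore, len(remaining), want - len(picks))
        if k > 0:
            # the space-filling half also keeps its distance from the
            # prior-ranked picks, so the whole cold batch covers the space
            picks += maximin_design(space, k, seed=seed, pool=remaining, anchors=picks)
        return picks[:want]

    best = max(y for _, y in history)
    mean, sd = state.posterior(levels)
    ei = np.asarray(expected_improvement(state, levels, best))

    # exploration screens unobserved reagents first: conditions are ranked by
    # how many of their levels have never produced a result, then by EI —
    # once every candidate of every role has been observed this reduces to
    # pure EI ranking
    seen = [set() for _ in range(levels.shape[1])]
    for cond, _ in history:
        for r, lvl in enumerate(space.level_indices(cond)):
            seen[r].add(lvl)
    unseen_count = np.zeros(len(untried), dtype=int)
    for r in range(levels.shape[1]):
        unseen_count += ~np.isin(levels[:, r], sorted(seen[r]))
    has_unseen = (unseen_count > 0).astype(int)

    # stable ranks: descending score, lexicographic (pool order) tie-break
    exploit_rank = np.lexsort((np.arange(len(untried)), -mean))
    explore_rank = np.lexsort((np.arange(len(untried)), -ei, -has_unseen))

    picks_idx: list[int] = []
    for i in exploit_rank[:n_exploit]:
        picks_idx.append(int(i))
    for i in explore_rank:
        if len(picks_idx) >= want:
            break
        if int(i) not in picks_idx:
            picks_idx.append(int(i))
    return [untried[i] for i in picks_idx[:want]]


# ---------------------------------------------------------------------------
# Recipe repository
# ---------------------------------------------------------------------------

@dataclass
class RepoEntry:
    condition: Condition
    score: float
    route_id: str
    state: str = "pending"  # pending | dispatched | done | cancelled
    payload: object | None = None  # e.g. the RecipeSpec attached at dispatch time


@dataclass
class RecipeRepository:
    """Ranked queue of candidate recipes: descending acquisition score,
    lexicographic condition tie-break; dispatch always removes the current
    maximum-score pending entry."""

    entries: list[RepoEntry] = field(default_factory=list)

    def pending(self, route_id: str | None = None) -> list[RepoEntry]:
        return [
            e for e in self.entries
            if e.state == "pending" and (route_id is None or e.route_id == route_id)
        ]

    def ranked_pending(self, route_id: str | None = None) -> list[RepoEntry]:
        return sorted(self.pending(route_id), key=lambda e: (-e.score, e.condition.key()))

    def dispatch(self, route_id: str | None = None) -> RepoEntry | None:
        ranked = self.ranked_pending(route_id)
        if not ranked:
            return None
        ranked[0].state = "dispatched"
        return ranked[0]

    def cancel_route(self, route_id: str) -> int:
        n = 0
        for e in self.entries:
            if e.route_id == route_id and e.state == "pending":
                e.state = "cancelled"
                n += 1
        return n

    def known_conditions(self, route_id: str) -> set[tuple[str, ...]]:
        return {
            e.condition.key()
            for e in self.entries
            if e.route_id == route_id and e.state in ("pending", "dispatched", "done")
        }


def update_repository(
    repo: RecipeRepository,
    proposals: Sequence[Condition],
    scores: Sequence[float],
    route_id: str,
) -> RecipeRepository:
    """Insert scored proposals, skipping conditions the route has already
    queued, dispatched or completed; restores the ranking invariant."""
    if len(proposals) != len(scores):
        raise ValueError("scores must align with proposals")
    known = repo.known_conditions(route_id)
    for cond, score in zip(proposals, scores):
        if cond.key() in known:
            continue
        repo.entries.append(RepoEntry(condition=cond, score=float(score), route_id=route_id))
        known.add(cond.key())
    return repo
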