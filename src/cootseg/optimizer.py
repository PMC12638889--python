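"""COOT and improved COOT (ICOOT) population optimizers.

The COOT algorithm is a swarm optimizer modelled on the movement of coot
waterbirds over a water surface.  A population of ``N`` agents is split into
a small group of *leaders* (the best-ranked agents after initialisation) and
*followers*.  Each iteration every follower either

* moves toward its assigned leader (oscillating approach scaled by
  ``2 R2 cos(2 pi R3)``),
* performs a *chain* move to the midpoint between itself and the preceding
  agent, or
* performs a *random* move toward a fresh uniform point in the box, damped
  by the linearly decaying factor ``B = 1 - Ic / Imax``;

leaders then orbit the elitist global best ``gBest``.

The improved variant (ICOOT) appends two greedy refinement passes per
iteration: a heavy-tailed **Lévy-flight** perturbation of each agent
(Mantegna's method) that injects occasional long exploratory jumps, and a
**quasi-opposition-based learning** (QOBL) pass that evaluates, for every
agent, a random point between the search-interval centre and the agent's
opposite point ``ub + lb - x``, keeping whichever of the pair is fitter.
With both passes disabled ICOOT reduces exactly to baseline COOT (same seed,
same trajectory).

All randomness flows through one :class:`numpy.random.Generator` seeded from
``OptimizerConfig.seed``; the draw order is fixed and documented in
:func:`run_coot` / :func:`run_icoot`, so runs are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
from scipy.special import gamma as _gamma_fn

__all__ = [
    "Bounds",
    "OptimizerConfig",
    "Population",
    "OptResult",
    "init_population",
    "compute_b",
    "random_movement",
    "chain_movement",
    "select_leader_index",
    "follow_leader",
    "leader_movement",
    "levy_sigma",
    "levy_step",
    "levy_step_from_draws",
    "levy_perturb",
    "opposite",
    "quasi_opposite",
    "run_coot",
    "run_icoot",
]

Objective = Callable[[np.ndarray], float]


@dataclass(frozen=True)
class Bounds:
    """Box constraints ``[lb, ub]^dim`` for the continuous search space.

    ``lb``/``ub`` may be scalars (shared across dimensions) or length-``dim``
    sequences.  ``ub > lb`` is required in every dimension.
    """

    lb: float | Sequence[float]
    ub: float | Sequence[float]
    dim: int

    def __post_init__(self) -> None:
        if int(self.dim) < 1:
            raise ValueError(f"dim must be >= 1, got {self.dim}")
        lb = np.broadcast_to(np.asarray(self.lb, dtype=float), (self.dim,)).copy()
        ub = np.broadcast_to(np.asarray(self.ub, dtype=float), (self.dim,)).copy()
        if not (np.isfinite(lb).all() and np.isfinite(ub).all()):
            raise ValueError("bounds must be finite")
        if not np.all(ub > lb):
            raise ValueError("ub must be strictly greater than lb in every dimension")
        object.__setattr__(self, "dim", int(self.dim))
        object.__setattr__(self, "_lb", lb)
        object.__setattr__(self, "_ub", ub)

    @property
    def lower(self) -> np.ndarray:
        return self._lb  # type: ignore[attr-defined]

    @property
    def upper(self) -> np.ndarray:
        return self._ub  # type: ignore[attr-defined]

    @property
    def span(self) -> np.ndarray:
        return self.upper - self.lower

    def clip(self, x: np.ndarray) -> np.ndarray:
        """Clamp a position to the nearest bound, entrywise."""
        return np.clip(np.asarray(x, dtype=float), self.lower, self.upper)

    def contains(self, x: np.ndarray) -> bool:
        x = np.asarray(x, dtype=float)
        return bool(np.all(x >= self.lower) and np.all(x <= self.upper))


@dataclass(frozen=True)
class OptimizerConfig:
    """Tunables for a COOT/ICOOT run.

    Parameters
    ----------
    n_agents
        Population size ``N``.
    leader_fraction
        Fraction of agents designated leaders; ``NL = ceil(fraction * N)``,
        at least one, and strictly fewer than ``N``.
    max_iter
        Number of iterations ``Imax``.
    beta
        Lévy stability exponent (``0 < beta <= 2``); 1.5 is the customary
        heavy-tailed default.
    alpha
        Lévy step scale applied to each perturbation.
    p_follow
        Probability a follower moves toward its leader.
    p_chain
        Probability of a chain move (vs a random move) when not following.
    p_levy
        Per-agent probability of a Lévy perturbation each iteration
        (ICOOT only; 0 disables the pass entirely).
    jumping_rate
        Per-iteration probability of a quasi-opposition pass over the whole
        population (ICOOT only; 0 disables the pass entirely).
    seed
        RNG seed; identical seeds give bitwise-identical runs.
    mode
        ``"maximize"`` or ``"minimize"``.
    levy_mode
        ``"additive"`` (default, ``x + alpha * step``) or ``"multiplicative"``
        (literal ``x * (alpha * step)``).
    levy_gaussian
        Draw Mantegna variates from a standard normal (default) or, behind
        this flag set to ``False``, from uniform [0, 1].
    scalar_r1
        If True, the random-move damping draw R1 is a scalar instead of
        per-dimension.
    """

    n_agents: int = 30
    leader_fraction: float = 0.1
    max_iter: int = 100
    beta: float = 1.5
    alpha: float = 1.0
    p_follow: float = 0.5
    p_chain: float = 0.5
    p_levy: float = 0.5
    jumping_rate: float = 0.3
    seed: int = 0
    mode: Literal["maximize", "minimize"] = "minimize"
    levy_mode: Literal["additive", "multiplicative"] = "additive"
    levy_gaussian: bool = True
    scalar_r1: bool = False

    def __post_init__(self) -> None:
        if self.n_agents < 2:
            raise ValueError("n_agents must be >= 2")
        if not (0.0 < self.leader_fraction < 1.0):
            raise ValueError("leader_fraction must be in (0, 1)")
        if self.n_leaders >= self.n_agents:
            raise ValueError("n_agents must exceed the number of leaders")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not (0.0 < self.beta <= 2.0):
            raise ValueError("beta must be in (0, 2]")
        for name in ("p_follow", "p_chain", "p_levy", "jumping_rate"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.mode not in ("maximize", "minimize"):
            raise ValueError(f"mode must be 'maximize' or 'minimize', got {self.mode!r}")

    @property
    def n_leaders(self) -> int:
        return max(1, math.ceil(self.leader_fraction * self.n_agents))

    def replace(self, **kwargs) -> "OptimizerConfig":
        from dataclasses import replace as _replace

        return _replace(self, **kwargs)


@dataclass
class Population:
    """Agent positions and fitnesses; leaders occupy the first rows."""

    positions: np.ndarray  # (N, dim)
    fitness: np.ndarray  # (N,)
    n_leaders: int


@dataclass
class OptResult:
    """Outcome of a COOT/ICOOT run.

    ``trace`` holds the elitist best-so-far fitness after each iteration, so
    it is monotone in the optimization direction and has length ``max_iter``.
    """

    best_position: np.ndarray
    best_fitness: float
    trace: np.ndarray
    n_evaluations: int = 0


# ---------------------------------------------------------------------------
# movement operators (pure functions of explicit draws, for testability)
# ---------------------------------------------------------------------------


def compute_b(current_iter: int, max_iter: int) -> float:
    """Linearly decaying damping factor ``B = 1 - Ic / Imax``."""
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if not (0 <= current_iter <= max_iter):
        raise ValueError("current_iter must satisfy 0 <= Ic <= Imax")
    return 1.0 - current_iter / max_iter


def random_movement(
    position: np.ndarray,
    b: float,
    bounds: Bounds,
    r: np.ndarray,
    r1: float | np.ndarray,
) -> np.ndarray:
    """Damped move toward a random point ``r`` in the box.

    ``x + B * R1 * (r - x)``, clamped to the bounds.  ``r`` is a uniform
    point in ``[lb, ub]`` and ``R1`` a uniform [0, 1] draw (scalar or
    per-dimension).
    """
    position = np.asarray(position, dtype=float)
    return bounds.clip(position + b * np.asarray(r1) * (np.asarray(r, float) - position))


def chain_movement(pos_i: np.ndarray, pos_prev: np.ndarray) -> np.ndarray:
    """Entrywise mean of an agent and its predecessor in the chain."""
    pos_i = np.asarray(pos_i, dtype=float)
    pos_prev = np.asarray(pos_prev, dtype=float)
    if pos_i.shape != pos_prev.shape:
        raise ValueError("chain_movement requires equal-length positions")
    return 0.5 * (pos_i + pos_prev)


def select_leader_index(j: int, n_leaders: int) -> int:
    """1-based leader label ``K = 1 + (j mod NL)`` for follower count ``j``."""
    if n_leaders < 1:
        raise ValueError("n_leaders must be >= 1")
    if j < 0:
        raise ValueError("j must be >= 0")
    return 1 + (j % n_leaders)


def follow_leader(
    coot_pos: np.ndarray,
    leader_pos: np.ndarray,
    r2: float,
    r3: float,
    bounds: Bounds,
) -> np.ndarray:
    """Oscillating move toward an assigned leader.

    ``L + 2 R2 cos(2 pi R3) (L - x)`` with ``R2 in [0, 1]``,
    ``R3 in [-1, 1]``; clamped.
    """
    coot_pos = np.asarray(coot_pos, dtype=float)
    leader_pos = np.asarray(leader_pos, dtype=float)
    if coot_pos.shape != leader_pos.shape:
        raise ValueError("follow_leader requires equal-length positions")
    step = 2.0 * r2 * math.cos(2.0 * math.pi * r3) * (leader_pos - coot_pos)
    return bounds.clip(leader_pos + step)


def leader_movement(
    leader_pos: np.ndarray,
    gbest: np.ndarray,
    b: float,
    r3: float,
    r4: float,
    r5: float,
    bounds: Bounds,
) -> np.ndarray:
    """Leader orbit around the global best.

    ``B R4 cos(2 pi R3) (gBest - L) + gBest`` when ``R5 < 0.5``, and the same
    term ``- gBest`` otherwise; clamped.
    """
    leader_pos = np.asarray(leader_pos, dtype=float)
    gbest = np.asarray(gbest, dtype=float)
    term = b * r4 * math.cos(2.0 * math.pi * r3) * (gbest - leader_pos)
    new = term + gbest if r5 < 0.5 else term - gbest
    return bounds.clip(new)


def levy_sigma(beta: float) -> float:
    """Mantegna scale ``sigma(beta)`` for Lévy-stable step generation.

    ``sigma = [ Gamma(1+b) sin(pi b / 2) / (Gamma((1+b)/2) b 2^((b-1)/2)) ]^(1/b)``.
    """
    if not (0.0 < beta <= 2.0):
        raise ValueError("beta must be in (0, 2]")
    num = _gamma_fn(1.0 + beta) * math.sin(math.pi * beta / 2.0)
    den = _gamma_fn((1.0 + beta) / 2.0) * beta * 2.0 ** ((beta - 1.0) / 2.0)
    return float((num / den) ** (1.0 / beta))


def levy_step_from_draws(
    r6: np.ndarray, r7: np.ndarray, beta: float = 1.5
) -> np.ndarray:
    """Lévy step from explicit variates: ``0.01 R6 sigma / |R7|^(1/beta)``."""
    sigma = levy_sigma(beta)
    r6 = np.asarray(r6, dtype=float)
    r7 = np.asarray(r7, dtype=float)
    return 0.01 * r6 * sigma / np.abs(r7) ** (1.0 / beta)


def levy_step(
    dim: int,
    beta: float,
    rng: np.random.Generator,
    gaussian: bool = True,
) -> np.ndarray:
    """Draw a heavy-tailed Lévy step vector by Mantegna's method.

    Per dimension, ``R6`` and ``R7`` are independent standard-normal variates
    (or uniform [0, 1] when ``gaussian`` is False); zero denominators are
    resampled.  Draw order: the full ``R6`` vector, then ``R7``.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    draw = rng.standard_normal if gaussian else rng.random
    r6 = draw(dim)
    r7 = draw(dim)
    while np.any(r7 == 0.0):  # measure-zero for normals; guards uniform mode
        r7 = np.where(r7 == 0.0, draw(dim), r7)
    return levy_step_from_draws(r6, r7, beta)


def levy_perturb(
    position: np.ndarray,
    alpha: float,
    beta: float,
    bounds: Bounds,
    rng: np.random.Generator,
    mode: Literal["additive", "multiplicative"] = "additive",
    gaussian: bool = True,
) -> np.ndarray:
    """Lévy-flight perturbation of a position, clamped to bounds.

    Additive mode (default) performs the standard Lévy walk
    ``x + alpha * step``; multiplicative mode applies the literal entrywise
    product ``x * (alpha * step)``.
    """
    position = np.asarray(position, dtype=float)
    step = levy_step(position.size, beta, rng, gaussian=gaussian)
    if mode == "additive":
        new = position + alpha * step
    elif mode == "multiplicative":
        new = position * (alpha * step)
    else:
        raise ValueError(f"unknown levy mode {mode!r}")
    return bounds.clip(new)


def opposite(position: np.ndarray, bounds: Bounds) -> np.ndarray:
    """Opposition-based-learning mirror point ``ub + lb - x``, entrywise."""
    position = np.asarray(position, dtype=float)
    return bounds.upper + bounds.lower - position


def quasi_opposite(
    position: np.ndarray,
    bounds: Bounds,
    u: np.ndarray,
) -> np.ndarray:
    """Quasi-opposite point: uniform between the box centre and the mirror.

    Entrywise, with centre ``c = (ub + lb) / 2`` and mirror
    ``x_obl = ub + lb - x``, returns ``a + u (b - a)`` where
    ``a = min(c, x_obl)``, ``b = max(c, x_obl)`` (order-normalised so the
    draw works whichever endpoint is larger).  ``u`` holds uniform [0, 1]
    draws, one per dimension.
    """
    position = np.asarray(position, dtype=float)
    centre = 0.5 * (bounds.upper + bounds.lower)
    mirror = opposite(position, bounds)
    lo = np.minimum(centre, mirror)
    hi = np.maximum(centre, mirror)
    return lo + np.asarray(u, dtype=float) * (hi - lo)


# ---------------------------------------------------------------------------
# main loops
# ---------------------------------------------------------------------------


def _evaluate(objective: Objective, x: np.ndarray, context: str) -> float:
    f = float(objective(x))
    if not math.isfinite(f):
        raise ValueError(f"objective returned non-finite value {f!r} at {context}: {x!r}")
    return f


def init_population(
    config: OptimizerConfig,
    bounds: Bounds,
    objective: Objective | None = None,
    rng: np.random.Generator | None = None,
) -> Population:
    """Uniformly initialise ``N`` agents; leaders are the best ``NL`` ranks.

    Positions are drawn per-dimension as ``rand * (ub - lb) + lb``.  When an
    objective is given the agents are evaluated and sorted best-first (in the
    configured direction) so the first ``NL`` rows form the leader group.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    pos = rng.random((config.n_agents, bounds.dim)) * bounds.span + bounds.lower
    if objective is None:
        fit = np.full(config.n_agents, np.nan)
    else:
        fit = np.array(
            [_evaluate(objective, pos[i], f"init agent {i}") for i in range(config.n_agents)]
        )
        order = np.argsort(-fit if config.mode == "maximize" else fit, kind="stable")
        pos = pos[order]
        fit = fit[order]
    return Population(positions=pos, fitness=fit, n_leaders=config.n_leaders)


def _run(
    objective: Objective,
    bounds: Bounds,
    config: OptimizerConfig,
    improved: bool,
) -> OptResult:
    rng = np.random.default_rng(config.seed)
    maximize = config.mode == "maximize"

    def better(a: float, b: float) -> bool:
        return a > b if maximize else a < b

    pop = init_population(config, bounds, objective, rng)
    pos, fit = pop.positions, pop.fitness
    n, nl = config.n_agents, pop.n_leaders
    n_eval = n

    gbest = pos[0].copy()
    gbest_fit = float(fit[0])
    trace = np.empty(config.max_iter, dtype=float)

    for it in range(1, config.max_iter + 1):
        b = compute_b(it, config.max_iter)

        # follower moves, in index order (chain uses the already-updated i-1)
        for i in range(nl, n):
            if rng.random() < config.p_follow:
                k = select_leader_index(i - nl, nl) - 1
                r2 = rng.random()
                r3 = rng.uniform(-1.0, 1.0)
                pos[i] = follow_leader(pos[i], pos[k], r2, r3, bounds)
            elif rng.random() < config.p_chain:
                pos[i] = bounds.clip(chain_movement(pos[i], pos[i - 1]))
            else:
                r = rng.random(bounds.dim) * bounds.span + bounds.lower
                r1 = rng.random() if config.scalar_r1 else rng.random(bounds.dim)
                pos[i] = random_movement(pos[i], b, bounds, r, r1)
            fit[i] = _evaluate(objective, pos[i], f"follower {i}, iter {it}")
            n_eval += 1
            if better(fit[i], gbest_fit):
                gbest, gbest_fit = pos[i].copy(), float(fit[i])

        # leader moves (draw order per leader: R3, R4, R5)
        for i in range(nl):
            r3 = rng.uniform(-1.0, 1.0)
            r4 = rng.random()
            r5 = rng.random()
            pos[i] = leader_movement(pos[i], gbest, b, r3, r4, r5, bounds)
            fit[i] = _evaluate(objective, pos[i], f"leader {i}, iter {it}")
            n_eval += 1
            if better(fit[i], gbest_fit):
                gbest, gbest_fit = pos[i].copy(), float(fit[i])

        if improved:
            # Lévy pass: greedy keep-fitter, per agent with probability p_levy.
            # Skipped entirely (no draws) when p_levy == 0 so ICOOT reduces
            # exactly to COOT.
            if config.p_levy > 0.0:
                for i in range(n):
                    if rng.random() < config.p_levy:
                        cand = levy_perturb(
                            pos[i],
                            config.alpha,
                            config.beta,
                            bounds,
                            rng,
                            mode=config.levy_mode,
                            gaussian=config.levy_gaussian,
                        )
                        cf = _evaluate(objective, cand, f"levy agent {i}, iter {it}")
                        n_eval += 1
                        if better(cf, fit[i]):
                            pos[i], fit[i] = cand, cf
                            if better(cf, gbest_fit):
                                gbest, gbest_fit = cand.copy(), float(cf)
            # QOBL pass over the whole population, gated by jumping_rate.
            if config.jumping_rate > 0.0 and rng.random() < config.jumping_rate:
                for i in range(n):
                    u = rng.random(bounds.dim)
                    cand = bounds.clip(quasi_opposite(pos[i], bounds, u))
                    cf = _evaluate(objective, cand, f"qobl agent {i}, iter {it}")
                    n_eval += 1
                    if better(cf, fit[i]):
                        pos[i], fit[i] = cand, cf
                        if better(cf, gbest_fit):
                            gbest, gbest_fit = cand.copy(), float(cf)

        trace[it - 1] = gbest_fit

    return OptResult(
        best_position=gbest, best_fitness=gbest_fit, trace=trace, n_evaluations=n_eval
    )


def run_coot(objective: Objective, bounds: Bounds, config: OptimizerConfig) -> OptResult:
    """Run the baseline COOT optimizer.

    Per iteration: followers move (follow-leader with probability
    ``p_follow``, else chain with probability ``p_chain``, else random move
    damped by ``B``), then leaders orbit ``gBest``; the global best is kept
    elitistically.  Deterministic given ``config.seed``.
    """
    return _run(objective, bounds, config, improved=False)


def run_icoot(objective: Objective, bounds: Bounds, config: OptimizerConfig) -> OptResult:
    """Run the improved COOT optimizer (COOT + Lévy flights + QOBL).

    Executes the :func:`run_coot` iteration body, then (a) perturbs each
    agent by a Lévy flight with probability ``p_levy``, keeping the fitter of
    the pair, and (b) with probability ``jumping_rate`` runs a
    quasi-opposition pass over the population, again keeping the fitter of
    each pair.  With ``p_levy = 0`` and ``jumping_rate = 0`` the run is
    bitwise identical to :func:`run_coot` at the same seed.
    """
    return _run(objective, bounds, config, improved=True)
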