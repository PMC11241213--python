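"""Population-based binary metaheuristic engines for subset selection.

Five swappable algorithms evolve real-valued positions that are mapped to
binary feature masks through a sigmoid transfer function:

* ``FMO``  — fisher-mantis search: each candidate is pulled toward the best
  known solution (attack phase) and then perturbed by Gaussian noise whose
  amplitude follows the linear decay schedule m_t = m - m*it/MaxIt
  (ambush/retreat phase), so exploration shrinks linearly to zero.
* ``GA``   — generational genetic algorithm on the masks themselves
  (tournament mate selection, uniform crossover, bit-flip mutation, elitism).
* ``PSO``  — inertia-weight particle swarm on the positions.
* ``ACO``  — per-bit pheromone ant system: each ant samples its mask from
  Bernoulli(pheromone), pheromone evaporates toward the best mask.
* ``GWO``  — grey wolf encircling around the three best wolves, with the
  customary linear a: 2 -> 0 decay.

All engines share one contract: a single seeded generator drives every
draw in fixed order, the best-so-far candidate never worsens, and the
population size, dimension and {0,1} mask domain are conserved.  Fitness
functions score masks (binary vectors); ``direction`` picks maximization
or minimization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "OptimizerSchedule",
    "CandidateSolution",
    "Population",
    "OptimizerConfig",
    "OptimizerResult",
    "ConfigurationError",
    "EvaluationError",
    "decay_schedule",
    "binarize",
    "fmo_step",
    "baseline_step",
    "run_optimizer",
    "ALGORITHMS",
]

ALGORITHMS = ("FMO", "GA", "PSO", "ACO", "GWO")
BINARIZATION_RULES = ("sigmoid_stochastic", "sigmoid_threshold")

# Positions are clipped here so sigmoid probabilities stay away from exact
# 0/1 saturation (sigmoid(6) ~= 0.9975) and runs cannot diverge.
POSITION_BOUND = 6.0


class ConfigurationError(ValueError):
    """Raised for invalid optimizer configuration."""


class EvaluationError(RuntimeError):
    """Raised when a fitness function returns a non-finite value."""


@dataclass(frozen=True)
class OptimizerSchedule:
    """Linear exploration-decay schedule.

    ``m_initial`` is the initial state scale m, ``max_iter`` the iteration
    budget MaxIt, ``current_iter`` the 0-based iteration counter it.
    """

    m_initial: float
    max_iter: int
    current_iter: int = 0

    def __post_init__(self) -> None:
        if self.m_initial < 0:
            raise ConfigurationError("m_initial must be non-negative")
        if self.max_iter < 0:
            raise ConfigurationError("max_iter must be non-negative")
        if not 0 <= self.current_iter <= max(self.max_iter, 0):
            raise ConfigurationError(
                f"current_iter {self.current_iter} outside [0, {self.max_iter}]"
            )

    def at(self, it: int) -> "OptimizerSchedule":
        return replace(self, current_iter=it)


def decay_schedule(schedule: OptimizerSchedule) -> float:
    """Decayed state scale m_t = m - m*it/MaxIt; linear from m down to 0."""
    if schedule.max_iter == 0:
        raise ConfigurationError("decay schedule undefined for max_iter = 0")
    m = schedule.m_initial
    # grouping (it/MaxIt) makes the endpoints exact: it=0 -> m, it=MaxIt -> 0
    return m - m * (schedule.current_iter / schedule.max_iter)


@dataclass
class CandidateSolution:
    """A search point: continuous position, its binary mask, and fitness."""

    position: np.ndarray
    mask: np.ndarray
    fitness: Optional[float] = None
    state: dict = field(default_factory=dict)  # per-algorithm extras (PSO pbest...)

    def copy(self) -> "CandidateSolution":
        return CandidateSolution(
            position=self.position.copy(),
            mask=self.mask.copy(),
            fitness=self.fitness,
            state={k: (v.copy() if isinstance(v, np.ndarray) else v) for k, v in self.state.items()},
        )


@dataclass
class Population:
    members: list[CandidateSolution]
    best_ever: CandidateSolution
    rng: np.random.Generator
    state: dict = field(default_factory=dict)  # population-level extras (ACO pheromone)


@dataclass(frozen=True)
class OptimizerConfig:
    """Resolved optimizer configuration; all defaults overridable."""

    algorithm: str = "FMO"
    pop_size: int = 30
    max_iter: int = 100
    m_initial: float = 1.0
    binarization: str = "sigmoid_stochastic"
    direction: str = "maximize"
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ConfigurationError(
                f"unknown algorithm {self.algorithm!r}; expected one of {ALGORITHMS}"
            )
        if self.pop_size < 2:
            raise ConfigurationError("pop_size must be >= 2")
        if self.max_iter < 0:
            raise ConfigurationError("max_iter must be >= 0")
        if self.binarization not in BINARIZATION_RULES:
            raise ConfigurationError(f"unknown binarization rule {self.binarization!r}")
        if self.direction not in ("maximize", "minimize"):
            raise ConfigurationError("direction must be 'maximize' or 'minimize'")
        for key in ("crossover_rate", "mutation_rate", "evaporation"):
            v = self.params.get(key)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{key} must lie in [0, 1]")

    @property
    def schedule(self) -> OptimizerSchedule:
        return OptimizerSchedule(self.m_initial, self.max_iter)

    def resolved_params(self, n: int) -> dict:
        """Fill in the textbook hyperparameter defaults for the algorithm."""
        defaults = {
            "GA": {"crossover_rate": 0.9, "mutation_rate": 1.0 / n, "tournament_size": 2},
            "PSO": {"inertia": 0.7, "c1": 1.5, "c2": 1.5, "v_max": 4.0},
            "ACO": {"evaporation": 0.1, "tau_min": 0.01, "tau_max": 0.99},
            "GWO": {"a_initial": 2.0},
            "FMO": {},
        }[self.algorithm]
        out = dict(defaults)
        out.update(self.params)
        return out


@dataclass
class OptimizerResult:
    best: CandidateSolution
    history: np.ndarray  # best-so-far fitness, length iterations+1
    n_iterations: int
    config: OptimizerConfig


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def binarize(position: np.ndarray, rule: str, rng: np.random.Generator) -> np.ndarray:
    """Map a real position to a {0,1} mask via the sigmoid transfer function.

    ``sigmoid_stochastic``: bit i is 1 with probability sigmoid(position_i).
    ``sigmoid_threshold``: bit i is 1 iff sigmoid(position_i) > 0.5 (so a
    probability of exactly 0.5 maps to 0 — the tie rule is strict).
    """
    position = np.asarray(position, dtype=float)
    if not np.all(np.isfinite(position)):
        raise ValueError("position contains non-finite values")
    p = _sigmoid(position)
    if rule == "sigmoid_stochastic":
        return (rng.random(position.shape) < p).astype(np.int8)
    if rule == "sigmoid_threshold":
        return (p > 0.5).astype(np.int8)
    raise ConfigurationError(f"unknown binarization rule {rule!r}")


def _is_better(a: float, b: Optional[float], direction: str) -> bool:
    if b is None:
        return True
    return a > b if direction == "maximize" else a < b


def _evaluate(
    member: CandidateSolution, fitness_fn: Callable[[np.ndarray], float], index: int
) -> None:
    value = float(fitness_fn(member.mask))
    if not np.isfinite(value):
        raise EvaluationError(
            f"fitness function returned non-finite value {value!r} for member {index}"
        )
    member.fitness = value


def _update_best(pop: Population, direction: str) -> None:
    for m in pop.members:
        if _is_better(m.fitness, pop.best_ever.fitness, direction):
            pop.best_ever = m.copy()


RepairFn = Callable[[np.ndarray, np.random.Generator], np.ndarray]


def _encode_mask(mask: np.ndarray) -> np.ndarray:
    """Saturated position encoding of a binary solution: bit b -> ±bound.

    Attractors (best-so-far solutions) are anchored at the saturated
    encoding of their masks rather than at the raw positions that sampled
    them, so pulls toward good solutions drive sigmoid probabilities
    toward 0/1 instead of hovering near 0.5 — the usual recipe in binary
    swarm optimizers.
    """
    return (2.0 * mask.astype(float) - 1.0) * POSITION_BOUND


def _finalize_mask(
    member: CandidateSolution, cfg: OptimizerConfig, rng: np.random.Generator,
    repair: Optional[RepairFn],
) -> None:
    member.mask = binarize(member.position, cfg.binarization, rng)
    if repair is not None:
        member.mask = repair(member.mask, rng)


def fmo_step(
    pop: Population,
    cfg: OptimizerConfig,
    fitness_fn: Callable[[np.ndarray], float],
    it: int,
    repair: Optional[RepairFn] = None,
) -> Population:
    """One fisher-mantis iteration.

    Attack phase pulls each candidate toward the best-known position with a
    uniform random step; the ambush phase adds Gaussian exploration noise
    whose amplitude is the linearly decayed scale m_t, so the move
    degenerates to a pure pull toward the best at the final iteration.
    """
    rng = pop.rng
    amplitude = decay_schedule(cfg.schedule.at(it))
    best_pos = _encode_mask(pop.best_ever.mask)
    n = best_pos.size
    for i, member in enumerate(pop.members):
        r = rng.random(n)
        hunt = member.position + r * (best_pos - member.position)
        hunt = hunt + amplitude * rng.normal(size=n)
        member.position = np.clip(hunt, -POSITION_BOUND, POSITION_BOUND)
        _finalize_mask(member, cfg, rng, repair)
        _evaluate(member, fitness_fn, i)
    _update_best(pop, cfg.direction)
    return pop


def _ga_step(pop, cfg, fitness_fn, it, repair):
    rng = pop.rng
    p = cfg.resolved_params(pop.best_ever.mask.size)
    cx, mut, tsize = p["crossover_rate"], p["mutation_rate"], int(p["tournament_size"])
    masks = [m.mask for m in pop.members]
    fits = [m.fitness for m in pop.members]
    n = masks[0].size

    def tournament() -> np.ndarray:
        idx = rng.integers(0, len(masks), size=tsize)
        best = max(idx, key=lambda j: fits[j]) if cfg.direction == "maximize" else min(
            idx, key=lambda j: fits[j]
        )
        return masks[best]

    for i, member in enumerate(pop.members):
        # crossover replaces member i's mask with a recombination of two
        # tournament winners; otherwise the mask is inherited unchanged, so
        # zero rates leave the population multiset intact.
        if rng.random() < cx:
            pa, pb = tournament(), tournament()
            take_a = rng.random(n) < 0.5
            child = np.where(take_a, pa, pb).astype(np.int8)
        else:
            child = masks[i].copy()
        if mut > 0:
            flip = rng.random(n) < mut
            child = np.where(flip, 1 - child, child).astype(np.int8)
        member.mask = repair(child, rng) if repair is not None else child
        member.position = (member.mask.astype(float) * 2.0 - 1.0)
        _evaluate(member, fitness_fn, i)
    # elitism: if the best-ever mask was lost to variation, reinstate it in
    # place of the worst child (a no-op when no child beats the incumbent
    # and the incumbent is still represented, e.g. under zero-rate variation)
    child_fits = [m.fitness for m in pop.members]
    best_child = max(child_fits) if cfg.direction == "maximize" else min(child_fits)
    if _is_better(pop.best_ever.fitness, best_child, cfg.direction):
        worst = int(np.argmin(child_fits)) if cfg.direction == "maximize" \
            else int(np.argmax(child_fits))
        elite = pop.best_ever.copy()
        elite.state = pop.members[worst].state
        pop.members[worst] = elite
    _update_best(pop, cfg.direction)
    return pop


def _pso_step(pop, cfg, fitness_fn, it, repair):
    rng = pop.rng
    n = pop.best_ever.position.size
    p = cfg.resolved_params(n)
    w, c1, c2, v_max = p["inertia"], p["c1"], p["c2"], p["v_max"]
    gbest = _encode_mask(pop.best_ever.mask)
    for i, member in enumerate(pop.members):
        st = member.state
        v = st.get("velocity")
        if v is None:
            v = np.zeros(n)
            st["pbest_mask"] = member.mask.copy()
            st["pbest_fitness"] = member.fitness
        pbest = _encode_mask(st["pbest_mask"])
        r1, r2 = rng.random(n), rng.random(n)
        v = (
            w * v
            + c1 * r1 * (pbest - member.position)
            + c2 * r2 * (gbest - member.position)
        )
        v = np.clip(v, -v_max, v_max)
        st["velocity"] = v
        member.position = np.clip(member.position + v, -POSITION_BOUND, POSITION_BOUND)
        _finalize_mask(member, cfg, rng, repair)
        _evaluate(member, fitness_fn, i)
        if _is_better(member.fitness, st["pbest_fitness"], cfg.direction):
            st["pbest_mask"] = member.mask.copy()
            st["pbest_fitness"] = member.fitness
    _update_best(pop, cfg.direction)
    return pop


def _aco_step(pop, cfg, fitness_fn, it, repair):
    rng = pop.rng
    n = pop.best_ever.mask.size
    p = cfg.resolved_params(n)
    rho, tau_min, tau_max = p["evaporation"], p["tau_min"], p["tau_max"]
    tau = pop.state.setdefault("pheromone", np.full(n, 0.5))
    for i, member in enumerate(pop.members):
        mask = (rng.random(n) < tau).astype(np.int8)
        member.mask = repair(mask, rng) if repair is not None else mask
        member.position = member.mask.astype(float) * 2.0 - 1.0
        _evaluate(member, fitness_fn, i)
    _update_best(pop, cfg.direction)
    # evaporate toward the global-best trail
    tau = (1.0 - rho) * tau + rho * pop.best_ever.mask.astype(float)
    pop.state["pheromone"] = np.clip(tau, tau_min, tau_max)
    return pop


def _gwo_step(pop, cfg, fitness_fn, it, repair):
    rng = pop.rng
    n = pop.best_ever.position.size
    p = cfg.resolved_params(n)
    if cfg.max_iter > 0:
        a = p["a_initial"] * (1.0 - (it + 1) / cfg.max_iter)
    else:  # pragma: no cover - no iterations run with max_iter = 0
        a = 0.0
    order = sorted(
        range(len(pop.members)),
        key=lambda j: pop.members[j].fitness,
        reverse=(cfg.direction == "maximize"),
    )
    leaders = [_encode_mask(pop.members[j].mask) for j in order[:3]]
    for i, member in enumerate(pop.members):
        estimates = []
        for leader in leaders:
            A = 2.0 * a * rng.random(n) - a
            C = 2.0 * rng.random(n)
            D = np.abs(C * leader - member.position)
            estimates.append(leader - A * D)
        member.position = np.clip(
            np.mean(estimates, axis=0), -POSITION_BOUND, POSITION_BOUND
        )
        _finalize_mask(member, cfg, rng, repair)
        _evaluate(member, fitness_fn, i)
    _update_best(pop, cfg.direction)
    return pop


_BASELINES = {"GA": _ga_step, "PSO": _pso_step, "ACO": _aco_step, "GWO": _gwo_step}


def baseline_step(
    pop: Population,
    cfg: OptimizerConfig,
    fitness_fn: Callable[[np.ndarray], float],
    it: int,
    repair: Optional[RepairFn] = None,
) -> Population:
    """One iteration of the configured baseline (GA, PSO, ACO or GWO)."""
    try:
        step = _BASELINES[cfg.algorithm]
    except KeyError:
        raise ConfigurationError(
            f"baseline_step expects one of {tuple(_BASELINES)}, got {cfg.algorithm!r}"
        ) from None
    return step(pop, cfg, fitness_fn, it, repair)


def _init_population(
    n: int, cfg: OptimizerConfig, fitness_fn, repair: Optional[RepairFn]
) -> Population:
    rng = np.random.default_rng(cfg.seed)
    members = []
    for i in range(cfg.pop_size):
        position = rng.uniform(-1.0, 1.0, size=n)
        mask = binarize(position, "sigmoid_stochastic", rng)
        if repair is not None:
            mask = repair(mask, rng)
        member = CandidateSolution(position=position, mask=mask)
        _evaluate(member, fitness_fn, i)
        members.append(member)
    best = members[0]
    for m in members[1:]:
        if _is_better(m.fitness, best.fitness, cfg.direction):
            best = m
    return Population(members=members, best_ever=best.copy(), rng=rng)


def run_optimizer(
    n: int,
    fitness_fn: Callable[[np.ndarray], float],
    cfg: OptimizerConfig,
    repair: Optional[RepairFn] = None,
    patience: Optional[int] = None,
) -> OptimizerResult:
    """Run the configured algorithm for ``cfg.max_iter`` iterations.

    Returns the best candidate ever seen and the best-so-far fitness
    trajectory (length iterations+1, including the random initialization).
    ``patience`` optionally stops early after that many iterations without
    improvement of the best fitness.  Runs are bitwise reproducible for a
    given seed and configuration.
    """
    if n < 1:
        raise ConfigurationError("problem dimension must be >= 1")
    pop = _init_population(n, cfg, fitness_fn, repair)
    history = [pop.best_ever.fitness]
    step = fmo_step if cfg.algorithm == "FMO" else baseline_step
    stall = 0
    iterations = 0
    for it in range(cfg.max_iter):
        previous = pop.best_ever.fitness
        step(pop, cfg, fitness_fn, it, repair)
        history.append(pop.best_ever.fitness)
        iterations = it + 1
        if patience is not None:
            stall = 0 if _is_better(pop.best_ever.fitness, previous, cfg.direction) else stall + 1
            if stall >= patience:
                break
    return OptimizerResult(
        best=pop.best_ever.copy(),
        history=np.asarray(history, dtype=float),
        n_iterations=iterations,
        config=cfg,
    )
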