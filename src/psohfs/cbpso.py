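"""Chaotic binary particle swarm optimization (CBPSO) for subset search.

Each particle is a binary vector over the D syndrome features (1 = feature
selected).  The engine augments standard binary PSO (sigmoid velocity
transfer, inertia-weighted update) with four devices against premature
convergence:

* **chaotic initialization** — candidate particles are drawn from logistic-
  map trajectories (mu = 4, the fully chaotic regime) thresholded at 0.5,
  and the N fittest of k candidates seed the swarm;
* **probabilistic reinitialization** — each particle is re-randomized with
  probability rk * p_c(t), where p_c(t) = 1 - 1/(1 + ln t) grows with the
  iteration count;
* **gbest mutation** — after a stagnation window the global best is bit-flip
  mutated, keeping the mutant only on improvement;
* **elitism** — after longer stagnation the worst particles are replaced by
  fresh chaotic newcomers, never touching the gbest holder.

Fitness is the cross-validated LS-SVR error of the candidate subset plus a
weighted mean feature-ranking score, so the search favours subsets that are
both predictive and individually relevant.  Disabling all four devices
reduces the engine to plain BPSO (the PWM baseline).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .lssvr import LSSVRConfig, cv_mse, cv_mse_gram

__all__ = [
    "SwarmConfig",
    "Particle",
    "SwarmState",
    "RunResult",
    "logistic_series",
    "chaotic_init",
    "inertia_weight",
    "update_particle",
    "subset_fitness",
    "make_fitness",
    "reinit_probability",
    "maybe_reinitialize",
    "mutate_gbest",
    "elitist_refresh",
    "run",
    "decode_solution",
]

EMPTY_SUBSET_FITNESS = float("inf")

#: logistic-map seeds with degenerate (eventually fixed) orbits at mu = 4
_DEGENERATE_SEEDS = (0.25, 0.5, 0.75)


@dataclass(frozen=True)
class SwarmConfig:
    """All tunables of the CBPSO engine.

    Defaults follow the study configuration: velocity clamp [-6, 6],
    nonlinear inertia decay from ws=1.2 to wl=0.4 shaped by c3=10,
    reinitialization gate rk=0.3, chaotic series length k=500 with mu=4,
    and gbest mutation after 10 stagnant iterations.  ``p`` weights the
    mean feature-ranking score inside the fitness.  The four ``use_*``
    flags disable the chaotic devices individually; all off = plain BPSO.
    """

    N: int = 100
    D: int = 27
    t_max: int = 100
    c1: float = 2.0
    c2: float = 2.0
    c3: float = 10.0
    V_min: float = -6.0
    V_max: float = 6.0
    ws: float = 1.2
    wl: float = 0.4
    rk: float = 0.3
    p: float = 0.2
    k: int = 500
    mu: float = 4.0
    stagnation_mutate: int = 10
    stagnation_elite: int = 20
    elite_fraction: float = 0.2
    pm: float | None = None  # per-bit mutation prob; None -> 1/D
    seed: int = 0
    use_chaos_init: bool = True
    use_reinit: bool = True
    use_mutation: bool = True
    use_elitism: bool = True

    def __post_init__(self) -> None:
        if self.ws <= self.wl:
            raise ValueError("ws must exceed wl")
        if self.V_min >= self.V_max:
            raise ValueError("V_min must be below V_max")
        if not 0 < self.p < 1:
            raise ValueError("p must lie in (0, 1)")
        if self.use_chaos_init and self.N > self.k:
            raise ValueError("swarm size N must not exceed chaotic length k")

    @property
    def bit_mutation_prob(self) -> float:
        return 1.0 / self.D if self.pm is None else self.pm


@dataclass
class Particle:
    position: np.ndarray
    velocity: np.ndarray
    pbest_position: np.ndarray
    pbest_fitness: float


@dataclass
class SwarmState:
    particles: list[Particle]
    gbest_position: np.ndarray
    gbest_fitness: float
    iteration: int = 0
    gbest_stagnation: int = 0


@dataclass
class RunResult:
    best_position: np.ndarray
    best_fitness: float
    trace: list[float]
    events: list[dict] = field(default_factory=list)

    @property
    def bitstring(self) -> str:
        return "".join(str(int(b)) for b in self.best_position)


def logistic_series(q0: float, k: int, mu: float = 4.0) -> np.ndarray:
    """k iterates of the logistic map q <- mu q (1 - q), starting after q0.

    q0 must lie strictly inside (0, 1) and avoid the degenerate seeds
    {0.25, 0.5, 0.75} whose orbits collapse at mu = 4.
    """
    if not 0.0 < q0 < 1.0:
        raise ValueError("q0 must lie strictly inside (0, 1)")
    if q0 in _DEGENERATE_SEEDS:
        raise ValueError(f"degenerate logistic seed {q0}")
    out = np.empty(k)
    q = q0
    for i in range(k):
        q = mu * q * (1.0 - q)
        out[i] = q
    return out


def _chaotic_candidates(D: int, k: int, mu: float, rng: np.random.Generator) -> np.ndarray:
    """k binary candidate vectors from D independent chaotic trajectories.

    Candidate j thresholds the j-th iterate of every trajectory at 0.5
    (iterate >= 0.5 -> bit 1).
    """
    q0 = rng.random(D)
    bad = (q0 <= 0) | (q0 >= 1) | np.isin(q0, _DEGENERATE_SEEDS)
    while np.any(bad):  # pragma: no cover - measure-zero resample
        q0[bad] = rng.random(bad.sum())
        bad = (q0 <= 0) | (q0 >= 1) | np.isin(q0, _DEGENERATE_SEEDS)
    traj = np.column_stack([logistic_series(q, k, mu) for q in q0])
    return (traj >= 0.5).astype(np.int8)


def chaotic_init(
    config: SwarmConfig,
    fitness_fn: Callable[[np.ndarray], float],
    rng: np.random.Generator,
) -> SwarmState:
    """Seed the swarm with the N fittest of k chaotic binary candidates."""
    cand = _chaotic_candidates(config.D, config.k, config.mu, rng)
    fits = np.array([fitness_fn(c) for c in cand])
    order = np.argsort(fits, kind="stable")[: config.N]
    particles = []
    for j in order:
        pos = cand[j].copy()
        vel = rng.uniform(config.V_min, config.V_max, config.D)
        particles.append(Particle(pos, vel, pos.copy(), float(fits[j])))
    return _with_gbest(particles)


def random_init(
    config: SwarmConfig,
    fitness_fn: Callable[[np.ndarray], float],
    rng: np.random.Generator,
) -> SwarmState:
    """Plain uniform-random initialization (the BPSO baseline)."""
    particles = []
    for _ in range(config.N):
        pos = (rng.random(config.D) < 0.5).astype(np.int8)
        vel = rng.uniform(config.V_min, config.V_max, config.D)
        particles.append(Particle(pos, vel, pos.copy(), fitness_fn(pos)))
    return _with_gbest(particles)


def _with_gbest(particles: list[Particle]) -> SwarmState:
    best = min(range(len(particles)), key=lambda i: particles[i].pbest_fitness)
    return SwarmState(
        particles,
        particles[best].pbest_position.copy(),
        particles[best].pbest_fitness,
    )


def inertia_weight(t: int, config: SwarmConfig) -> float:
    """Nonlinear decay w = wl * (ws/wl)^(1 / (1 + c3 t / t_max))."""
    if not 0 <= t <= config.t_max:
        raise ValueError("iteration out of range")
    expo = 1.0 / (1.0 + config.c3 * t / config.t_max)
    return config.wl * (config.ws / config.wl) ** expo


def _sigmoid(v: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-v))


def update_particle(
    particle: Particle,
    gbest: np.ndarray,
    w: float,
    config: SwarmConfig,
    rng: np.random.Generator,
) -> None:
    """One inertia-weighted velocity/position update, in place.

    Per dimension: v <- w v + c1 r1 (pbest - x) + c2 r2 (gbest - x), clamped
    to [V_min, V_max]; the new bit is 1 iff a fresh uniform draw falls below
    the sigmoid S(v) = 1/(1 + e^-v).
    """
    r1 = rng.random(config.D)
    r2 = rng.random(config.D)
    v = (
        w * particle.velocity
        + config.c1 * r1 * (particle.pbest_position - particle.position)
        + config.c2 * r2 * (gbest - particle.position)
    )
    np.clip(v, config.V_min, config.V_max, out=v)
    particle.velocity = v
    particle.position = (rng.random(config.D) < _sigmoid(v)).astype(np.int8)


def subset_fitness(
    position: np.ndarray,
    syndromes: np.ndarray,
    ps: np.ndarray,
    fr: np.ndarray,
    lssvr_config: LSSVRConfig,
    p: float,
) -> float:
    """Prediction error plus relevance penalty of one candidate subset.

    fitness(X) = cv_mse(selected columns) + p * mean fr of selected features;
    the empty subset gets an infinite sentinel so it can never become gbest.
    """
    sel = np.nonzero(np.asarray(position).ravel())[0]
    if sel.size == 0:
        return EMPTY_SUBSET_FITNESS
    err = cv_mse(syndromes[:, sel], ps, lssvr_config)
    return err + p * float(np.mean(fr[sel]))


def make_fitness(
    syndromes: np.ndarray,
    ps: np.ndarray,
    fr: np.ndarray,
    lssvr_config: LSSVRConfig,
    p: float,
) -> Callable[[np.ndarray], float]:
    """Memoized fitness closure (fitness is deterministic per position).

    Per-feature pairwise squared-distance matrices are precomputed once, so
    each new position costs one matrix sum + exponential + the fold solves;
    repeated positions are free.
    """
    from sklearn.model_selection import KFold

    from .lssvr import _solve_dual

    syndromes = np.atleast_2d(np.asarray(syndromes, dtype=float))
    ps = np.asarray(ps, dtype=float).ravel()
    n, D = syndromes.shape
    # (D, n*n) per-feature squared distances: the RBF exponent of a subset
    # is position @ sqdist (one BLAS matrix-vector product)
    diffs = syndromes.T[:, :, None] - syndromes.T[:, None, :]
    sqdist = (diffs**2).reshape(D, n * n)
    fr = np.asarray(fr, dtype=float)
    kf = KFold(n_splits=lssvr_config.folds, shuffle=True,
               random_state=lssvr_config.seed)
    folds = [(tr, te) for tr, te in kf.split(ps)]
    cache: dict[bytes, float] = {}

    def fn(position: np.ndarray) -> float:
        pos = np.asarray(position, dtype=np.int8).ravel()
        key = pos.tobytes()
        if key in cache:
            return cache[key]
        if not pos.any():
            cache[key] = EMPTY_SUBSET_FITNESS
            return cache[key]
        K = np.exp(
            (pos.astype(float) @ sqdist).reshape(n, n)
            / -lssvr_config.sigma2
        )
        errors = []
        for tr, te in folds:
            b, alpha = _solve_dual(
                K[tr[:, None], tr[None, :]], ps[tr], lssvr_config.gamma
            )
            pred = K[te[:, None], tr[None, :]] @ alpha + b
            errors.append(float(np.mean((pred - ps[te]) ** 2)))
        sel = np.nonzero(pos)[0]
        cache[key] = float(np.mean(errors)) + p * float(np.mean(fr[sel]))
        return cache[key]

    return fn


def reinit_probability(currun: int) -> float:
    """Swarm reinitialization schedule p_c = 1 - 1/(1 + ln currun)."""
    if currun < 1:
        raise ValueError("currun must be at least 1")
    return 1.0 - 1.0 / (1.0 + math.log(currun))


def maybe_reinitialize(
    state: SwarmState,
    config: SwarmConfig,
    fitness_fn: Callable[[np.ndarray], float],
    rng: np.random.Generator,
) -> int:
    """Re-randomize each particle with probability rk * p_c(currun).

    Reinitialized particles keep their pbest record, updating it (and the
    gbest) only on improvement.  Returns the number of particles touched.
    """
    p_reinit = config.rk * reinit_probability(max(state.iteration, 1))
    if p_reinit <= 0:
        return 0
    n_reinit = 0
    for particle in state.particles:
        if rng.random() >= p_reinit:
            continue
        n_reinit += 1
        particle.position = (rng.random(config.D) < 0.5).astype(np.int8)
        particle.velocity = rng.uniform(config.V_min, config.V_max, config.D)
        fit = fitness_fn(particle.position)
        if fit < particle.pbest_fitness:
            particle.pbest_fitness = fit
            particle.pbest_position = particle.position.copy()
            if fit < state.gbest_fitness:
                state.gbest_fitness = fit
                state.gbest_position = particle.position.copy()
                state.gbest_stagnation = 0
    return n_reinit


def mutate_gbest(
    state: SwarmState,
    config: SwarmConfig,
    fitness_fn: Callable[[np.ndarray], float],
    rng: np.random.Generator,
) -> bool:
    """Bit-flip mutate the gbest; adopt the mutant only if strictly better."""
    flips = rng.random(config.D) < config.bit_mutation_prob
    if not flips.any():
        return False
    candidate = state.gbest_position.copy()
    candidate[flips] = 1 - candidate[flips]
    fit = fitness_fn(candidate)
    if fit < state.gbest_fitness:
        state.gbest_position = candidate
        state.gbest_fitness = fit
        state.gbest_stagnation = 0
        return True
    return False


def elitist_refresh(
    state: SwarmState,
    config: SwarmConfig,
    fitness_fn: Callable[[np.ndarray], float],
    rng: np.random.Generator,
) -> int:
    """Replace the worst particles by fresh chaotic newcomers.

    ceil(elite_fraction * N) particles with the worst pbest fitness are
    replaced; the particle holding the gbest record is never removed, and
    the gbest itself can only improve.
    """
    n_replace = math.ceil(config.elite_fraction * config.N)
    if n_replace == 0:
        return 0
    order = sorted(
        range(len(state.particles)),
        key=lambda i: (-state.particles[i].pbest_fitness, -i),
    )
    holder = min(
        range(len(state.particles)),
        key=lambda i: state.particles[i].pbest_fitness,
    )
    victims = [i for i in order if i != holder][:n_replace]
    newcomers = _chaotic_candidates(config.D, len(victims), config.mu, rng)
    for i, pos in zip(victims, newcomers):
        vel = rng.uniform(config.V_min, config.V_max, config.D)
        fit = fitness_fn(pos)
        state.particles[i] = Particle(pos.copy(), vel, pos.copy(), fit)
        if fit < state.gbest_fitness:
            state.gbest_fitness = fit
            state.gbest_position = pos.copy()
            state.gbest_stagnation = 0
    return len(victims)


def run(
    config: SwarmConfig,
    fitness_fn: Callable[[np.ndarray], float],
) -> RunResult:
    """Full CBPSO search: init, then t_max generations of update /
    pbest-gbest bookkeeping / reinitialization / mutation / elitism.

    The returned per-generation gbest trace is non-increasing.
    """
    rng = np.random.default_rng(config.seed)
    if config.use_chaos_init:
        state = chaotic_init(config, fitness_fn, rng)
    else:
        state = random_init(config, fitness_fn, rng)
    trace: list[float] = []
    events: list[dict] = []

    for t in range(1, config.t_max + 1):
        state.iteration = t
        w = inertia_weight(t - 1, config)
        improved = False
        for particle in state.particles:
            update_particle(particle, state.gbest_position, w, config, rng)
            fit = fitness_fn(particle.position)
            if fit < particle.pbest_fitness:
                particle.pbest_fitness = fit
                particle.pbest_position = particle.position.copy()
                if fit < state.gbest_fitness:
                    state.gbest_fitness = fit
                    state.gbest_position = particle.position.copy()
                    improved = True
        state.gbest_stagnation = 0 if improved else state.gbest_stagnation + 1

        if config.use_reinit:
            n = maybe_reinitialize(state, config, fitness_fn, rng)
            if n:
                events.append({"iteration": t, "event": "reinit", "count": n})
        if (
            config.use_mutation
            and state.gbest_stagnation >= config.stagnation_mutate
        ):
            if mutate_gbest(state, config, fitness_fn, rng):
                events.append({"iteration": t, "event": "gbest_mutation"})
        if (
            config.use_elitism
            and state.gbest_stagnation >= config.stagnation_elite
        ):
            n = elitist_refresh(state, config, fitness_fn, rng)
            events.append({"iteration": t, "event": "elitist_refresh", "count": n})
            state.gbest_stagnation = 0

        trace.append(state.gbest_fitness)

    return RunResult(state.gbest_position.copy(), state.gbest_fitness, trace, events)


def decode_solution(
    position: np.ndarray | str, feature_names: Sequence[str]
) -> list[str]:
    """Names of the selected (1-bit) features, preserving order."""
    if isinstance(position, str):
        bits = np.array([int(c) for c in position])
    else:
        bits = np.asarray(position).ravel()
    if len(bits) != len(feature_names):
        raise ValueError("position length does not match feature names")
    return [name for bit, name in zip(bits, feature_names) if bit]
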