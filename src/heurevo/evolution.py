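"""Generation loop, experiment grids and the fixed-consequence benchmark.

Each generation, every individual has ``n_interactions`` repeated
interactions with randomly matched partners.  An interaction draws one
true consequence c ~ Uniform(-3, 1) shared by the pair, each partner
privately perceives it once (the perception and hence the active
substrategy are fixed for all rounds), and the pair plays ``n_rounds``
simultaneous rounds with implementation errors.  Payoffs accumulate on
top of a baseline fitness; individuals then reproduce asexually by
roulette-wheel selection with mutation.

Two engines are provided: a readable pure-Python reference
(``engine="python"``) that builds per-interaction records, and a
compiled numba kernel (``engine="numba"``, the default) used for the
experiment grids.  They are statistically equivalent but consume
randomness differently, so trajectories match only in distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace, asdict

import numpy as np
import pandas as pd

from . import _kernel
from .game_core import Action, GameContext, Outcome, payoff
from .genotype import (
    Genotype,
    MutationMatrix,
    StrategyMode,
    Substrategy,
    active_substrategy,
    decide,
    decode_response,
    generate_mutation_matrix,
    mutate,
    random_genotype,
)
from .perception import PerceptionModel, perceive

logger = logging.getLogger("heurevo")

_SEED_MOD = 2**31  # kernel seeds stay below 2^31


@dataclass(frozen=True)
class SimulationConfig:
    """All parameters of one evolutionary simulation.

    Defaults are the full-scale study conditions: 1000 individuals, ten
    interactions of ten rounds each per generation, benefit b = 2,
    implementation error 0.01, mutation rate 0.001 with Gaussian kernel
    sd 0.1, baseline fitness 100, 10,000 generations.
    """

    N: int = 1000
    n_interactions: int = 10
    n_rounds: int = 10
    generations: int = 10_000
    b: float = 2.0
    epsilon: float = 0.01
    mu: float = 0.001
    sigma_mut: float = 0.1
    u: float = 0.0
    baseline_fitness: float = 100.0
    fitness_floor: float = 0.0
    seed: int = 0
    tie_to_c2: bool = True

    def __post_init__(self) -> None:
        if self.N < 2 or self.N % 2:
            raise ValueError("N must be even and >= 2")
        if min(self.n_interactions, self.n_rounds) < 1 or self.generations < 0:
            raise ValueError("counts must be positive")
        for name in ("epsilon", "mu", "u"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.sigma_mut <= 0 or self.b <= 0:
            raise ValueError("sigma_mut and b must be positive")

    @classmethod
    def desk_scale(cls, **overrides) -> "SimulationConfig":
        """Reduced preset (N = 200, 2500 generations) for desk-scale runs."""
        defaults = dict(N=200, generations=2500)
        defaults.update(overrides)
        return cls(**defaults)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GenerationStats:
    """Summary of one generation (census counts sum to N)."""

    generation: int
    cooperation_level: float
    heuristic_fraction: float
    strategy_census: dict[str, int]
    mean_first_move_by_strategy: dict[str, tuple[float, ...]]
    mean_T: float


@dataclass
class InteractionRecord:
    """Full log of one repeated interaction between two individuals."""

    c: float
    c_p_a: float
    c_p_b: float
    actions: list[tuple[Action, Action]]
    payoff_a: float
    payoff_b: float

    @property
    def n_cooperations(self) -> int:
        return sum((a is Action.COOPERATE) + (b is Action.COOPERATE)
                   for a, b in self.actions)


@dataclass
class SimulationResult:
    """Trajectory plus final-generation population and summary."""

    config: SimulationConfig
    cooperation: np.ndarray
    heuristic_fraction: np.ndarray
    mean_T: np.ndarray
    final_population: list[Genotype]
    final_stats: GenerationStats
    engine: str

    def trajectory_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "generation": np.arange(len(self.cooperation)),
            "cooperation": self.cooperation,
            "heuristic_fraction": self.heuristic_fraction,
            "mean_T": self.mean_T,
        })


# ---------------------------------------------------------------------------
# Strategy identity / census

def strategy_label(g: Genotype) -> str:
    """Identity of the strategy a genotype implements.

    Heuristics are identified by the response string of H (e.g.
    ``"H:CDDD"`` for heuristic grim); context-dependent genotypes by the
    response strings of the substrategy below and at-or-above the
    threshold (e.g. ``"X:CDDD/CDDC"``).  Continuous genes (first moves,
    T) are not part of the identity and are reported as means alongside.
    """
    if g.mode is StrategyMode.HEURISTIC:
        return f"H:{g.H.response_string}"
    return f"X:{g.C1.response_string}/{g.C2.response_string}"


def population_census(pop: list[Genotype]) -> dict[str, int]:
    census: dict[str, int] = {}
    for g in pop:
        lab = strategy_label(g)
        census[lab] = census.get(lab, 0) + 1
    return census


def population_stats(pop: list[Genotype], generation: int = 0,
                     cooperation_level: float = float("nan")) -> GenerationStats:
    """Build a :class:`GenerationStats` from a population snapshot."""
    census = population_census(pop)
    fm_acc: dict[str, list[list[float]]] = {}
    for g in pop:
        lab = strategy_label(g)
        fms = ([g.H.first_move] if g.mode is StrategyMode.HEURISTIC
               else [g.C1.first_move, g.C2.first_move])
        acc = fm_acc.setdefault(lab, [[] for _ in fms])
        for slot, fm in zip(acc, fms):
            slot.append(fm)
    mean_fm = {lab: tuple(float(np.mean(slot)) for slot in acc)
               for lab, acc in fm_acc.items()}
    heur = sum(1 for g in pop if g.mode is StrategyMode.HEURISTIC) / len(pop)
    return GenerationStats(
        generation=generation,
        cooperation_level=cooperation_level,
        heuristic_fraction=heur,
        strategy_census=census,
        mean_first_move_by_strategy=mean_fm,
        mean_T=float(np.mean([g.T for g in pop])),
    )


# ---------------------------------------------------------------------------
# Python reference engine

def pair_population(N: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Uniformly random perfect matching of indices 0..N-1."""
    if N % 2:
        raise ValueError("population size must be even to pair")
    perm = rng.permutation(N)
    return [(int(perm[2 * k]), int(perm[2 * k + 1])) for k in range(N // 2)]


def play_interaction(a: Genotype, b_g: Genotype, cfg: SimulationConfig,
                     rng: np.random.Generator) -> InteractionRecord:
    """One repeated interaction between two genotypes.

    The true consequence is drawn once and shared; each side perceives
    it privately and independently, fixing its active substrategy for
    all rounds.  Payoffs always use the true consequence.
    """
    c = float(rng.uniform(-3.0, 1.0))
    model = PerceptionModel(u=cfg.u)
    cpa = perceive(c, model, rng)
    cpb = perceive(c, model, rng)
    sub_a = active_substrategy(a, cpa, cfg.tie_to_c2)
    sub_b = active_substrategy(b_g, cpb, cfg.tie_to_c2)
    ctx = GameContext(c=c, b=cfg.b)
    actions: list[tuple[Action, Action]] = []
    pay_a = pay_b = 0.0
    prev_a: Outcome | None = None
    prev_b: Outcome | None = None
    for _ in range(cfg.n_rounds):
        act_a = decide(sub_a, prev_a, cfg.epsilon, rng)
        act_b = decide(sub_b, prev_b, cfg.epsilon, rng)
        actions.append((act_a, act_b))
        pay_a += payoff(act_a, act_b, ctx)
        pay_b += payoff(act_b, act_a, ctx)
        prev_a = Outcome.from_actions(act_a, act_b)
        prev_b = Outcome.from_actions(act_b, act_a)
    return InteractionRecord(c=c, c_p_a=cpa, c_p_b=cpb, actions=actions,
                             payoff_a=pay_a, payoff_b=pay_b)


def play_generation(pop: list[Genotype], cfg: SimulationConfig,
                    rng: np.random.Generator) -> tuple[np.ndarray, GenerationStats]:
    """Play all interaction bouts of one generation (no reproduction).

    Returns the floored fitness vector (baseline + accumulated payoff)
    and the generation summary.
    """
    N = len(pop)
    payoffs = np.zeros(N)
    ncoop = 0
    for _ in range(cfg.n_interactions):
        for i, j in pair_population(N, rng):
            rec = play_interaction(pop[i], pop[j], cfg, rng)
            payoffs[i] += rec.payoff_a
            payoffs[j] += rec.payoff_b
            ncoop += rec.n_cooperations
    fitness = np.maximum(cfg.baseline_fitness + payoffs, cfg.fitness_floor)
    coop = ncoop / (N * cfg.n_interactions * cfg.n_rounds)
    return fitness, population_stats(pop, cooperation_level=coop)


def select_reproduce(pop: list[Genotype], fitness: np.ndarray,
                     M: MutationMatrix, cfg: SimulationConfig,
                     rng: np.random.Generator) -> list[Genotype]:
    """Roulette-wheel selection with mutation; returns the offspring."""
    fitness = np.asarray(fitness, dtype=float)
    if (fitness < 0).any():
        raise ValueError("fitness must be non-negative (floor it first)")
    total = fitness.sum()
    if total <= 0.0:
        logger.warning("all-zero total fitness; falling back to uniform parents")
        parents = rng.integers(len(pop), size=len(pop))
    else:
        parents = rng.choice(len(pop), size=len(pop), p=fitness / total)
    return [mutate(pop[int(p)], cfg.mu, M, cfg.sigma_mut, rng) for p in parents]


# ---------------------------------------------------------------------------
# Population <-> array conversion (kernel interface)

def population_to_arrays(pop: list[Genotype]):
    N = len(pop)
    S = np.empty(N, dtype=np.int8)
    T = np.empty(N, dtype=np.float64)
    FM = np.empty((N, 3), dtype=np.float64)
    CODE = np.empty((N, 3), dtype=np.int8)
    for i, g in enumerate(pop):
        S[i] = 0 if g.mode is StrategyMode.HEURISTIC else 1
        T[i] = g.T
        for s, sub in enumerate((g.H, g.C1, g.C2)):
            FM[i, s] = sub.first_move
            CODE[i, s] = sub.code
    return S, T, FM, CODE


def arrays_to_population(S, T, FM, CODE) -> list[Genotype]:
    pop = []
    for i in range(len(S)):
        subs = [decode_response(int(CODE[i, s]), first_move=float(FM[i, s]))
                for s in range(3)]
        mode = StrategyMode.HEURISTIC if S[i] == 0 else StrategyMode.CONTEXT_DEPENDENT
        pop.append(Genotype(mode=mode, T=float(T[i]),
                            H=subs[0], C1=subs[1], C2=subs[2]))
    return pop


def initial_population(N: int, rng: np.random.Generator) -> list[Genotype]:
    return [random_genotype(rng) for _ in range(N)]


# ---------------------------------------------------------------------------
# Full simulations

def run_simulation(cfg: SimulationConfig, M: MutationMatrix | None = None,
                   engine: str = "numba") -> SimulationResult:
    """Run one evolutionary simulation, reproducible from (cfg.seed, M).

    If no mutation matrix is given, one is generated from the same seed.
    """
    rng = np.random.default_rng(cfg.seed)
    if M is None:
        M = generate_mutation_matrix(rng)
    pop = initial_population(cfg.N, rng)
    if cfg.generations == 0:
        return SimulationResult(cfg, np.empty(0), np.empty(0), np.empty(0),
                                pop, population_stats(pop), engine)
    if engine == "numba":
        S, T, FM, CODE = population_to_arrays(pop)
        kt = _kernel.build_kappa_table(cfg.u)
        kseed = int(rng.integers(_SEED_MOD))
        coop, heur, meanT, S, T, FM, CODE = _kernel.run_kernel(
            S, T, FM, CODE, M.targets, cfg.generations, cfg.n_interactions,
            cfg.n_rounds, cfg.b, cfg.epsilon, cfg.mu, cfg.sigma_mut, cfg.u,
            cfg.baseline_fitness, cfg.fitness_floor, kseed, kt)
        final = arrays_to_population(S, T, FM, CODE)
    elif engine == "python":
        coop = np.empty(cfg.generations)
        heur = np.empty(cfg.generations)
        meanT = np.empty(cfg.generations)
        for g in range(cfg.generations):
            fitness, stats = play_generation(pop, cfg, rng)
            coop[g] = stats.cooperation_level
            heur[g] = stats.heuristic_fraction
            meanT[g] = stats.mean_T
            if g < cfg.generations - 1:
                pop = select_reproduce(pop, fitness, M, cfg, rng)
        final = pop
    else:
        raise ValueError(f"unknown engine {engine!r}")
    final_stats = population_stats(final, generation=cfg.generations - 1,
                                   cooperation_level=float(coop[-1]))
    return SimulationResult(cfg, coop, heur, meanT, final, final_stats, engine)


def derive_seed(master_seed: int, *keys: int) -> int:
    """Deterministic child seed from the master seed and integer keys."""
    ss = np.random.SeedSequence((int(master_seed),) + tuple(int(k) for k in keys))
    return int(ss.generate_state(1)[0] % _SEED_MOD)


def experiment_matrices(master_seed: int, n_matrices: int) -> list[MutationMatrix]:
    """The deterministic mutation-matrix panel of an experiment grid."""
    return [generate_mutation_matrix(
        np.random.default_rng(derive_seed(master_seed, 977, mid)))
        for mid in range(n_matrices)]


def run_experiment(u_grid, n_matrices: int, n_replicates: int,
                   cfg_base: SimulationConfig,
                   dominance_threshold: float = 0.8,
                   engine: str = "numba") -> pd.DataFrame:
    """Grid of simulations over uncertainty x mutation matrix x replicate.

    One row per run: final cooperation level, heuristic fraction,
    dominant strategy (> ``dominance_threshold`` of the population, else
    None) with the mean first moves and threshold of the dominant
    carriers.  Every row's seed derives deterministically from
    (cfg_base.seed, u index, matrix id, replicate).
    """
    from .analysis import dominant_strategy

    matrices = experiment_matrices(cfg_base.seed, n_matrices)
    rows = []
    for ui, u in enumerate(u_grid):
        for mid, M in enumerate(matrices):
            for rep in range(n_replicates):
                seed = derive_seed(cfg_base.seed, ui, mid, rep)
                cfg = replace(cfg_base, u=float(u), seed=seed)
                res = run_simulation(cfg, M, engine=engine)
                dom = dominant_strategy(res.final_population,
                                        threshold=dominance_threshold)
                fm = res.final_stats.mean_first_move_by_strategy.get(
                    dom.label, ()) if dom.label else ()
                rows.append({
                    "u": float(u), "matrix_id": mid, "replicate": rep,
                    "seed": seed,
                    "cooperation": float(res.cooperation[-1]),
                    "heuristic_fraction": float(res.heuristic_fraction[-1]),
                    "dominant": dom.label,
                    "dominant_share": dom.share,
                    "dom_first_move_1": fm[0] if len(fm) > 0 else np.nan,
                    "dom_first_move_2": fm[1] if len(fm) > 1 else np.nan,
                    "mean_T": float(res.mean_T[-1]),
                })
                logger.info("experiment row u=%.2f matrix=%d rep=%d done",
                            u, mid, rep)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Fixed-consequence benchmark (no heterogeneity, no perception)

@dataclass
class FixedCResult:
    """Trajectory of a fixed-consequence benchmark run."""

    c: float
    cooperation: np.ndarray
    final_first_moves: np.ndarray
    final_codes: np.ndarray

    def tail_mean(self, window: int = 500) -> float:
        w = min(window, len(self.cooperation))
        return float(self.cooperation[-w:].mean())


def run_fixed_c_simulation(c: float, cfg: SimulationConfig,
                           M: MutationMatrix | None = None) -> FixedCResult:
    """Benchmark variant with constant consequence c.

    Genotypes collapse to a single substrategy (first move + four
    response genes); mutation uses the same matrix mechanism and
    Gaussian first-move kernel as the main model.
    """
    if not -3.0 <= c <= 1.0:
        raise ValueError(f"c={c} outside [-3, 1]")
    rng = np.random.default_rng(cfg.seed)
    if M is None:
        M = generate_mutation_matrix(rng)
    FM = rng.random(cfg.N)
    CODE = rng.integers(0, 16, cfg.N).astype(np.int8)
    kseed = int(rng.integers(_SEED_MOD))
    coop, FM, CODE = _kernel.run_fixed_c_kernel(
        FM, CODE, M.targets, cfg.generations, cfg.n_interactions,
        cfg.n_rounds, cfg.b, cfg.epsilon, cfg.mu, cfg.sigma_mut, float(c),
        cfg.baseline_fitness, cfg.fitness_floor, kseed)
    return FixedCResult(c=float(c), cooperation=coop,
                        final_first_moves=FM, final_codes=CODE)


def run_fixed_c_sweep(c_grid, n_replicates: int, cfg_base: SimulationConfig,
                      tail_window: int = 500) -> pd.DataFrame:
    """Fixed-c benchmark over a grid of consequences.

    Cooperation is averaged over the trailing ``tail_window``
    generations of each run to damp terminal-generation noise.
    """
    rows = []
    for ci, c in enumerate(c_grid):
        for rep in range(n_replicates):
            seed = derive_seed(cfg_base.seed, 555, ci, rep)
            cfg = replace(cfg_base, seed=seed)
            M = generate_mutation_matrix(
                np.random.default_rng(derive_seed(cfg_base.seed, 556, ci, rep)))
            res = run_fixed_c_simulation(float(c), cfg, M)
            rows.append({"c": float(c), "replicate": rep, "seed": seed,
                         "cooperation": res.tail_mean(tail_window)})
            logger.info("fixed-c row c=%.2f rep=%d done", c, rep)
    return pd.DataFrame(rows)
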