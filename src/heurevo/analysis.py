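"""Downstream analyses: summaries, dominance, monoculture cooperation,
four-parameter logistic fits and invasion fitness.

The monoculture cooperation rate has an exact solution: self-play of a
memory-one substrategy with implementation errors is a Markov chain over
the four joint outcomes, so the expected fraction of cooperative actions
over a finite repeated game follows from the round-1 action lottery and
the 4x4 transition matrix.  A vectorised Monte-Carlo route through the
same repeated game serves as an independent cross-check and powers the
invasion analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .game_core import Action
from .genotype import (
    Genotype,
    StrategyMode,
    Substrategy,
    named_strategy,
)
from .evolution import SimulationConfig, population_census, population_stats
from .perception import perceive_many

_MIRROR_IDX = np.array([0, 2, 1, 3])  # CC, CD, DC, DD from the partner's side


# ---------------------------------------------------------------------------
# Population summaries

def cooperation_level(actions) -> float:
    """Fraction of COOPERATE among a flat log of actions."""
    acts = list(actions)
    if not acts:
        raise ValueError("empty action log")
    return sum(1 for a in acts if a is Action.COOPERATE or a == 1) / len(acts)


def heuristic_fraction(pop: list[Genotype]) -> float:
    if not pop:
        raise ValueError("empty population")
    return sum(1 for g in pop if g.mode is StrategyMode.HEURISTIC) / len(pop)


@dataclass(frozen=True)
class DominantStrategy:
    """Outcome of the >threshold dominance test on a final population."""

    label: str | None
    share: float
    mean_first_moves: tuple[float, ...]
    mean_T: float


def dominant_strategy(pop: list[Genotype],
                      threshold: float = 0.8) -> DominantStrategy:
    """Most common strategy identity if it exceeds ``threshold``.

    Identity is the strategy label of :func:`~heurevo.evolution.strategy_label`
    (mode plus expressed response codes, ordered below/above the
    threshold for context-dependent strategies).  Continuous genes are
    summarised as means over the dominant carriers.
    """
    if not 0.5 < threshold <= 1.0:
        raise ValueError("threshold must be in (0.5, 1]")
    census = population_census(pop)
    label, count = max(census.items(), key=lambda kv: kv[1])
    share = count / len(pop)
    if share <= threshold:
        return DominantStrategy(None, share, (), float("nan"))
    stats = population_stats(pop)
    return DominantStrategy(label, share,
                            stats.mean_first_move_by_strategy[label],
                            stats.mean_T)


# ---------------------------------------------------------------------------
# Monoculture cooperation: exact Markov chain + Monte-Carlo cross-check

def _response_bits(sub: Substrategy) -> np.ndarray:
    return np.array([a.value for a in sub.response], dtype=float)


def monoculture_cooperation(sub: Substrategy, first_move: float | None = None,
                            epsilon: float = 0.01, n_rounds: int = 10) -> float:
    """Exact expected cooperation rate in self-play of one substrategy.

    The joint outcome (focal perspective) evolves as a Markov chain:
    from outcome o the focal intends response[o] and the partner intends
    response[mirror(o)], each executed action flipped independently with
    probability epsilon.  Round 1 is the first-move lottery on both
    sides.  Returns the mean probability of cooperating per action over
    ``n_rounds`` rounds — exact, no simulation.
    """
    f = sub.first_move if first_move is None else first_move
    bits = _response_bits(sub)
    p_coop = bits * (1 - epsilon) + (1 - bits) * epsilon   # P(C | outcome), focal
    p_coop_partner = p_coop[_MIRROR_IDX]
    P = np.empty((4, 4))
    for o in range(4):
        pf, pp = p_coop[o], p_coop_partner[o]
        P[o] = [pf * pp, pf * (1 - pp), (1 - pf) * pp, (1 - pf) * (1 - pp)]
    q = f * (1 - epsilon) + (1 - f) * epsilon
    d = np.array([q * q, q * (1 - q), (1 - q) * q, (1 - q) * (1 - q)])
    coop = [q]
    for _ in range(1, n_rounds):
        coop.append(float(d @ p_coop))
        d = d @ P
    return float(np.mean(coop))


def play_pairs(code_a: np.ndarray, fm_a: np.ndarray,
               code_b: np.ndarray, fm_b: np.ndarray,
               c: np.ndarray, b: float, epsilon: float, n_rounds: int,
               rng: np.random.Generator):
    """Vectorised repeated games for many pairs at once.

    All arguments are arrays over pairs (codes are response codes,
    ``c`` the true consequences).  Returns accumulated payoffs and
    cooperation counts per side, shape (n_pairs,).
    """
    code_a = np.asarray(code_a, dtype=np.int64)
    code_b = np.asarray(code_b, dtype=np.int64)
    n = code_a.shape[0]
    pay_a = np.zeros(n)
    pay_b = np.zeros(n)
    coop_a = np.zeros(n, dtype=np.int64)
    coop_b = np.zeros(n, dtype=np.int64)
    o_a = np.zeros(n, dtype=np.int64)
    o_b = np.zeros(n, dtype=np.int64)
    for r in range(n_rounds):
        if r == 0:
            a = (rng.random(n) < fm_a).astype(np.int64)
            bb = (rng.random(n) < fm_b).astype(np.int64)
        else:
            a = (code_a >> (3 - o_a)) & 1
            bb = (code_b >> (3 - o_b)) & 1
        a ^= rng.random(n) < epsilon
        bb ^= rng.random(n) < epsilon
        a = a.astype(np.int64)
        bb = bb.astype(np.int64)
        o_a = (1 - a) * 2 + (1 - bb)
        o_b = (1 - bb) * 2 + (1 - a)
        pay_a += b * bb + c * a
        pay_b += b * a + c * bb
        coop_a += a
        coop_b += bb
    return pay_a, pay_b, coop_a, coop_b


def monoculture_cooperation_mc(sub: Substrategy, first_move: float | None = None,
                               epsilon: float = 0.01, n_rounds: int = 10,
                               n_games: int = 100_000,
                               rng: np.random.Generator | None = None
                               ) -> tuple[float, float]:
    """Monte-Carlo monoculture cooperation rate with its standard error."""
    if rng is None:
        rng = np.random.default_rng()
    f = sub.first_move if first_move is None else first_move
    code = np.full(n_games, sub.code)
    fm = np.full(n_games, f)
    c = np.zeros(n_games)  # payoffs are irrelevant to the cooperation count
    _, _, ca, cb = play_pairs(code, fm, code, fm, c, 2.0, epsilon, n_rounds, rng)
    per_game = (ca + cb) / (2.0 * n_rounds)
    return float(per_game.mean()), float(per_game.std(ddof=1) / np.sqrt(n_games))


# ---------------------------------------------------------------------------
# Four-parameter logistic summaries

@dataclass
class FourPLFit:
    """Fitted 4PL curve y = y_min + (y_max - y_min)/(1 + exp((u_mid - u)/beta)).

    Group-level (mutation-matrix) variation is handled by per-group
    asymptotes and midpoints with a shared slope; the reported
    parameters are the across-group means, with bootstrap-over-groups
    95% confidence intervals.  ``identifiable`` is False when the data
    are essentially flat (y_max - y_min below noise), in which case
    u_mid is meaningless.
    """

    y_min: float
    y_max: float
    u_mid: float
    slope_beta: float
    ci: dict[str, tuple[float, float]]
    identifiable: bool = True
    per_group: dict[int, tuple[float, float, float]] | None = None

    def predict(self, u: np.ndarray) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        with np.errstate(over="ignore"):
            return self.y_min + (self.y_max - self.y_min) / (
                1.0 + np.exp((self.u_mid - u) / self.slope_beta))


def _fit_shared_slope(u: np.ndarray, y: np.ndarray, gidx: np.ndarray,
                      n_groups: int) -> tuple[np.ndarray, float]:
    """Least-squares 4PL with per-group (ymin, ymax, umid), shared slope."""

    def unpack(theta):
        per = theta[: 3 * n_groups].reshape(n_groups, 3)
        return per, theta[-1]

    def resid(theta):
        per, log_beta = unpack(theta)
        with np.errstate(over="ignore"):  # exp overflow saturates harmlessly
            beta = np.exp(log_beta)
            ymin, ymax, umid = (per[gidx, 0], per[gidx, 1], per[gidx, 2])
            pred = ymin + (ymax - ymin) / (1.0 + np.exp((umid - u) / beta))
        return pred - y

    lo, hi = float(y.min()), float(y.max())
    x0 = np.concatenate([np.tile([lo, hi, 0.5], n_groups), [np.log(0.1)]])
    sol = least_squares(resid, x0, method="lm", max_nfev=20_000)
    per, log_beta = unpack(sol.x)
    return per, float(np.exp(log_beta))


def fit_4pl(u, y, group=None, n_boot: int = 200,
            rng: np.random.Generator | None = None) -> FourPLFit:
    """Fit the four-parameter logistic to (u, y) data.

    ``group`` assigns each point to a mutation matrix (or other grouping
    unit); per-group curves share the slope.  With no grouping a single
    curve is fitted and the CI bootstraps over points instead.
    """
    u = np.asarray(u, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(u)) < 4:
        raise ValueError("need at least 4 distinct u values")
    if rng is None:
        rng = np.random.default_rng(0)
    if group is None:
        group = np.zeros(len(u), dtype=int)
    group = np.asarray(group)
    glabels, gidx = np.unique(group, return_inverse=True)
    n_groups = len(glabels)

    per, beta = _fit_shared_slope(u, y, gidx, n_groups)
    mean_params = per.mean(axis=0)
    y_min, y_max, u_mid = (float(v) for v in mean_params)
    if y_max < y_min:  # canonicalise: increasing parametrisation
        y_min, y_max = y_max, y_min
        beta = -beta
    identifiable = abs(y_max - y_min) > 1e-3

    # bootstrap over groups (over points when ungrouped)
    boots = {k: [] for k in ("y_min", "y_max", "u_mid", "slope_beta")}
    for _ in range(n_boot):
        if n_groups > 1:
            pick = rng.integers(n_groups, size=n_groups)
            mask_idx = np.concatenate([np.flatnonzero(gidx == p) for p in pick])
            bgidx = np.concatenate([np.full((gidx == p).sum(), i)
                                    for i, p in enumerate(pick)])
            bu, by, bg, ng = u[mask_idx], y[mask_idx], bgidx, n_groups
        else:
            idx = rng.integers(len(u), size=len(u))
            bu, by, bg, ng = u[idx], y[idx], np.zeros(len(idx), dtype=int), 1
            if len(np.unique(bu)) < 4:
                continue
        try:
            bper, bbeta = _fit_shared_slope(bu, by, bg, ng)
        except Exception:
            continue
        bm = bper.mean(axis=0)
        b_ymin, b_ymax, b_umid = float(bm[0]), float(bm[1]), float(bm[2])
        if b_ymax < b_ymin:
            b_ymin, b_ymax = b_ymax, b_ymin
            bbeta = -bbeta
        boots["y_min"].append(b_ymin)
        boots["y_max"].append(b_ymax)
        boots["u_mid"].append(b_umid)
        boots["slope_beta"].append(bbeta)
    ci = {}
    for k, vals in boots.items():
        if vals:
            ci[k] = (float(np.percentile(vals, 2.5)),
                     float(np.percentile(vals, 97.5)))
        else:  # pragma: no cover - all bootstrap refits failed
            ci[k] = (float("nan"), float("nan"))

    per_group = {int(glabels[i]): tuple(float(v) for v in per[i])
                 for i in range(n_groups)}
    return FourPLFit(y_min=y_min, y_max=y_max, u_mid=u_mid, slope_beta=beta,
                     ci=ci, identifiable=identifiable, per_group=per_group)


# ---------------------------------------------------------------------------
# Invasion analysis

@dataclass
class InvasionResult:
    """Rare-mutant invasion fitness at one uncertainty level."""

    mutant_label: str
    resident_label: str
    u: float
    w_mut_res: float
    w_res_res: float
    invasion_fitness: float
    se: float  # Monte-Carlo standard error of the ratio


def heuristic_grim(first_move: float = 0.99) -> Genotype:
    """The most common high-uncertainty strategy: heuristic grim."""
    sub = named_strategy("GRIM", first_move)
    return Genotype(mode=StrategyMode.HEURISTIC, T=0.0,
                    H=sub, C1=sub, C2=sub)


def grim_pavlov_context(T: float = -0.5, first_move_below: float = 0.0,
                        first_move_above: float = 1.0) -> Genotype:
    """The most common low-uncertainty strategy: context-dependent grim/pavlov.

    Below the threshold (interaction perceived as costly) it plays grim
    with a low first move — an absorbing defection regime; at or above
    the threshold it plays the error-correcting pavlov with a high
    first move.  The threshold defaults to -0.5, one of the two evolved
    threshold values.
    """
    below = named_strategy("GRIM", first_move_below)
    above = named_strategy("PAVLOV", first_move_above)
    return Genotype(mode=StrategyMode.CONTEXT_DEPENDENT, T=T,
                    H=above, C1=below, C2=above)


def _lifetime_payoffs(focal: Genotype, partner: Genotype, u: float,
                      cfg: SimulationConfig, n_samples: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Per-lifetime accumulated payoffs of focal against fresh partners.

    Each lifetime is ``cfg.n_interactions`` repeated interactions; every
    interaction draws its own true consequence and private perceptions.
    """
    n = n_samples * cfg.n_interactions
    c = rng.uniform(-3.0, 1.0, n)
    cp_f = perceive_many(c, u, rng)
    cp_p = perceive_many(c, u, rng)

    def expressed(g: Genotype, cp: np.ndarray):
        if g.mode is StrategyMode.HEURISTIC:
            code = np.full(n, g.H.code)
            fm = np.full(n, g.H.first_move)
        else:
            below = cp < g.T if cfg.tie_to_c2 else cp <= g.T
            code = np.where(below, g.C1.code, g.C2.code)
            fm = np.where(below, g.C1.first_move, g.C2.first_move)
        return code, fm

    code_f, fm_f = expressed(focal, cp_f)
    code_p, fm_p = expressed(partner, cp_p)
    pay_f, _, _, _ = play_pairs(code_f, fm_f, code_p, fm_p, c,
                                cfg.b, cfg.epsilon, cfg.n_rounds, rng)
    return pay_f.reshape(n_samples, cfg.n_interactions).sum(axis=1)


def invasion_fitness(mutant: Genotype, resident: Genotype, u: float,
                     cfg: SimulationConfig | None = None,
                     n_samples: int = 20_000,
                     rng: np.random.Generator | None = None,
                     include_baseline: bool = True) -> InvasionResult:
    """Rare-mutant invasion fitness of ``mutant`` into ``resident``.

    Expected lifetime fitness of the mutant among residents divided by
    the resident's fitness against itself; above 1 the mutant can
    invade.  Fitness includes the baseline (as in the evolutionary
    model) unless ``include_baseline`` is False; the crossing point of
    1 is unaffected by that choice.
    """
    from .evolution import strategy_label

    if cfg is None:
        cfg = SimulationConfig()
    if rng is None:
        rng = np.random.default_rng()
    base = cfg.baseline_fitness if include_baseline else 0.0
    w_mut = base + _lifetime_payoffs(mutant, resident, u, cfg, n_samples, rng)
    w_res = base + _lifetime_payoffs(resident, resident, u, cfg, n_samples, rng)
    mm, mr = float(w_mut.mean()), float(w_res.mean())
    if mr <= 0:
        raise ValueError("resident fitness must be positive")
    ratio = mm / mr
    # delta-method SE of the ratio of two independent means
    se = ratio * np.sqrt(w_mut.var(ddof=1) / (n_samples * mm ** 2)
                         + w_res.var(ddof=1) / (n_samples * mr ** 2))
    return InvasionResult(mutant_label=strategy_label(mutant),
                          resident_label=strategy_label(resident),
                          u=float(u), w_mut_res=mm, w_res_res=mr,
                          invasion_fitness=ratio, se=float(se))
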