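import numpy as np
import pytest

from heurevo.game_core import Action
from heurevo.genotype import (
    Genotype,
    StrategyMode,
    generate_mutation_matrix,
    named_strategy,
)
from heurevo.evolution import (
    SimulationConfig,
    initial_population,
    pair_population,
    play_generation,
    play_interaction,
    run_experiment,
    run_fixed_c_simulation,
    run_simulation,
    select_reproduce,
    strategy_label,
)


def homogeneous(name, fm, mode=StrategyMode.HEURISTIC, N=10, T=0.0):
    sub = named_strategy(name, fm)
    return [Genotype(mode=mode, T=T, H=sub, C1=sub, C2=sub) for _ in range(N)]


# ---------------------------------------------------------------------------
# Pairing

def test_two_individuals_form_single_pair(rng):
    pairs = pair_population(2, rng)
    assert pairs in ([(0, 1)], [(1, 0)])


def test_pairing_is_perfect_matching(rng):
    pairs = pair_population(1000, rng)
    flat = [i for p in pairs for i in p]
    assert len(pairs) == 500 and sorted(flat) == list(range(1000))


def test_pairing_uniform_partners(rng):
    counts = {k: 0 for k in range(1, 6)}
    n = 10_000
    for _ in range(n):
        for i, j in pair_population(6, rng):
            if i == 0:
                counts[j] += 1
            elif j == 0:
                counts[i] += 1
    for k in counts:
        assert counts[k] / n == pytest.approx(1 / 5, abs=0.015)


def test_odd_population_rejected(rng):
    with pytest.raises(ValueError):
        pair_population(7, rng)


# ---------------------------------------------------------------------------
# Interactions

def test_alld_pair_gets_zero(rng):
    cfg = SimulationConfig(N=2, epsilon=0.0, u=0.0, generations=1)
    a, b = homogeneous("ALLD", 0.0, N=2)
    rec = play_interaction(a, b, cfg, rng)
    assert rec.payoff_a == 0.0 and rec.payoff_b == 0.0
    assert rec.n_cooperations == 0


def test_allc_pair_payoff_arithmetic(rng):
    cfg = SimulationConfig(N=2, epsilon=0.0, u=0.0, generations=1)
    a, b = homogeneous("ALLC", 1.0, N=2)
    for _ in range(20):
        rec = play_interaction(a, b, cfg, rng)
        assert rec.payoff_a == pytest.approx(10 * (2.0 + rec.c))
        assert rec.n_cooperations == 20


def test_perceptions_private_and_in_range(rng):
    cfg = SimulationConfig(N=2, u=0.8, generations=1)
    a, b = homogeneous("TFT", 1.0, N=2)
    recs = [play_interaction(a, b, cfg, rng) for _ in range(50)]
    assert all(-3 <= r.c_p_a <= 1 and -3 <= r.c_p_b <= 1 for r in recs)
    assert any(r.c_p_a != r.c_p_b for r in recs)  # independent private draws


# ---------------------------------------------------------------------------
# Generations

def test_generation_conservation_and_baseline(rng):
    cfg = SimulationConfig(N=20, epsilon=0.0, u=0.0, generations=1)
    pop = homogeneous("ALLD", 0.0, N=20)
    fitness, stats = play_generation(pop, cfg, rng)
    np.testing.assert_allclose(fitness, 100.0)   # baseline only, no payoffs
    assert stats.cooperation_level == 0.0
    assert sum(stats.strategy_census.values()) == 20


def test_error_rate_sets_cooperation_floor(rng):
    cfg = SimulationConfig(N=40, epsilon=0.01, u=0.0, generations=1)
    pop = homogeneous("ALLD", 0.0, N=40)
    coops = [play_generation(pop, cfg, rng)[1].cooperation_level
             for _ in range(10)]
    assert np.mean(coops) == pytest.approx(0.01, abs=0.004)


def test_grim_monoculture_matches_exact_chain(rng):
    # cross-engine check against the exact Markov-chain value 0.8901
    cfg = SimulationConfig(N=100, epsilon=0.01, u=0.0, generations=1)
    pop = homogeneous("GRIM", 0.99, N=100)
    coops = [play_generation(pop, cfg, rng)[1].cooperation_level
             for _ in range(20)]
    se = np.std(coops) / np.sqrt(len(coops))
    assert abs(np.mean(coops) - 0.89005) < 4 * max(se, 1e-4)


def test_roulette_degenerate_wheel(rng):
    cfg = SimulationConfig(N=10, mu=0.0, generations=1)
    pop = initial_population(10, rng)
    fitness = np.zeros(10)
    fitness[3] = 100.0
    M = generate_mutation_matrix(rng)
    offspring = select_reproduce(pop, fitness, M, cfg, rng)
    assert all(g == pop[3] for g in offspring)


def test_roulette_proportionality(rng):
    cfg = SimulationConfig(N=200, mu=0.0, generations=1)
    pop = homogeneous("ALLC", 1.0, N=100) + homogeneous("ALLD", 0.0, N=100)
    fitness = np.array([200.0] * 100 + [100.0] * 100)
    M = generate_mutation_matrix(rng)
    share = np.mean([
        sum(g.H.response_string == "CCCC"
            for g in select_reproduce(pop, fitness, M, cfg, rng)) / 200
        for _ in range(50)])
    assert share == pytest.approx(2 / 3, abs=0.02)


def test_monomorphic_fixed_point_without_noise(rng):
    # with eps=0 and mu=0 a monomorphic population maps to itself
    cfg = SimulationConfig(N=12, epsilon=0.0, mu=0.0, u=0.3, generations=1)
    pop = homogeneous("GRIM", 1.0, N=12)
    M = generate_mutation_matrix(rng)
    fitness, _ = play_generation(pop, cfg, rng)
    new = select_reproduce(pop, fitness, M, cfg, rng)
    assert all(g == pop[0] for g in new)


def test_neutral_drift_unbiased(rng):
    # equal fitness: heuristic fraction drifts without direction
    cfg = SimulationConfig(N=50, mu=0.0, generations=1)
    M = generate_mutation_matrix(rng)
    drifts = []
    for _ in range(60):
        pop = initial_population(50, rng)
        before = sum(g.mode is StrategyMode.HEURISTIC for g in pop) / 50
        for _ in range(15):
            pop = select_reproduce(pop, np.full(50, 100.0), M, cfg, rng)
        after = sum(g.mode is StrategyMode.HEURISTIC for g in pop) / 50
        drifts.append(after - before)
    se = np.std(drifts) / np.sqrt(len(drifts))
    assert abs(np.mean(drifts)) < 3 * se + 1e-9


# ---------------------------------------------------------------------------
# Full simulations

def test_zero_generations_returns_founders():
    res = run_simulation(SimulationConfig(N=600, generations=0, seed=5))
    assert len(res.final_population) == 600
    assert res.final_stats.heuristic_fraction == pytest.approx(0.5, abs=0.07)
    assert all(g.T == 0.0 for g in res.final_population)


@pytest.mark.parametrize("engine", ["numba", "python"])
def test_seed_determinism(engine):
    cfg = SimulationConfig(N=20, generations=15, u=0.4, seed=99)
    r1 = run_simulation(cfg, engine=engine)
    r2 = run_simulation(cfg, engine=engine)
    np.testing.assert_array_equal(r1.cooperation, r2.cooperation)
    np.testing.assert_array_equal(r1.heuristic_fraction, r2.heuristic_fraction)
    assert r1.final_population == r2.final_population


def test_trajectory_aligns_with_final_population():
    res = run_simulation(SimulationConfig(N=40, generations=30, u=0.2, seed=7))
    heur = sum(g.mode is StrategyMode.HEURISTIC
               for g in res.final_population) / 40
    assert heur == pytest.approx(res.heuristic_fraction[-1])


def test_experiment_rows_and_seed_independence():
    cfg = SimulationConfig(N=20, generations=5, seed=11)
    df = run_experiment([0.5], 1, 2, cfg)
    assert len(df) == 2
    assert df["seed"].nunique() == 2
    assert set(df.columns) >= {"u", "matrix_id", "replicate", "cooperation",
                               "heuristic_fraction", "dominant"}


def test_fixed_c_extremes():
    cfg = SimulationConfig(N=100, generations=400, seed=21)
    high = run_fixed_c_simulation(1.0, cfg)
    low = run_fixed_c_simulation(-3.0, cfg)
    assert high.tail_mean(100) > 0.85        # cooperation dominant
    assert low.tail_mean(100) < 0.05         # near the error floor


def test_strategy_label_convention():
    g = homogeneous("GRIM", 0.99)[0]
    assert strategy_label(g) == "H:CDDD"
    x = Genotype(mode=StrategyMode.CONTEXT_DEPENDENT, T=-0.5,
                 H=named_strategy("ALLD", 0.0),
                 C1=named_strategy("GRIM", 0.0),
                 C2=named_strategy("PAVLOV", 1.0))
    assert strategy_label(x) == "X:CDDD/CDDC"
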