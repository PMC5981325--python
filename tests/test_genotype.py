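import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from heurevo.game_core import Action, Outcome
from heurevo.genotype import (
    Genotype,
    MutationMatrix,
    StrategyMode,
    Substrategy,
    active_substrategy,
    decide,
    decode_response,
    generate_mutation_matrix,
    genotype_from_dict,
    genotype_to_dict,
    mutate,
    named_strategy,
    random_genotype,
    response_code,
    substrategy_from_string,
)

C, D = Action.COOPERATE, Action.DEFECT


# ---------------------------------------------------------------------------
# Codes and named strategies

def test_response_code_bijection():
    for code in range(16):
        assert response_code(decode_response(code)) == code


def test_code_conventions():
    assert substrategy_from_string("DDDD").code == 0
    assert named_strategy("GRIM", 0.5).code == 8      # CC is the MSB
    assert named_strategy("TFT", 0.5).code == 10
    assert named_strategy("PAVLOV", 0.5).code == 9


@pytest.mark.parametrize("name, table", [
    ("GRIM", {Outcome.CC: C, Outcome.CD: D, Outcome.DC: D, Outcome.DD: D}),
    ("TFT", {Outcome.CC: C, Outcome.CD: D, Outcome.DC: C, Outcome.DD: D}),
    ("PAVLOV", {Outcome.CC: C, Outcome.CD: D, Outcome.DC: D, Outcome.DD: C}),
    ("ALLC", {o: C for o in Outcome}),
    ("ALLD", {o: D for o in Outcome}),
])
def test_named_strategy_truth_tables(name, table):
    sub = named_strategy(name, 0.5)
    for outcome, action in table.items():
        assert sub.response[outcome] is action


def test_unknown_name_rejected():
    with pytest.raises(KeyError):
        named_strategy("TF2T", 0.5)


# ---------------------------------------------------------------------------
# Decision logic

def _context_genotype(T=0.0):
    return Genotype(mode=StrategyMode.CONTEXT_DEPENDENT, T=T,
                    H=named_strategy("ALLD", 0.0),
                    C1=named_strategy("GRIM", 0.1),
                    C2=named_strategy("PAVLOV", 0.9))


def test_heuristic_ignores_perception():
    g = Genotype(mode=StrategyMode.HEURISTIC, T=0.0,
                 H=named_strategy("TFT", 1.0),
                 C1=named_strategy("ALLD", 0.0),
                 C2=named_strategy("ALLC", 1.0))
    for cp in (-3.0, -0.1, 0.9):
        assert active_substrategy(g, cp) is g.H


def test_context_switch_and_tie():
    g = _context_genotype(T=0.0)
    assert active_substrategy(g, -1.0) is g.C1
    assert active_substrategy(g, 0.5) is g.C2
    assert active_substrategy(g, 0.0) is g.C2          # tie -> "otherwise"
    assert active_substrategy(g, 0.0, tie_to_c2=False) is g.C1


def test_decide_response_and_errors(rng):
    grim = named_strategy("GRIM", 0.5)
    assert decide(grim, Outcome.CC, 0.0, rng) is C
    assert decide(grim, Outcome.DC, 0.0, rng) is D
    # certain error inverts every intended action
    assert decide(grim, Outcome.CC, 1.0, rng) is D
    assert decide(grim, Outcome.DD, 1.0, rng) is C


def test_decide_first_move_lottery(rng):
    sub = named_strategy("ALLD", 0.7)
    acts = [decide(sub, None, 0.0, rng) for _ in range(5000)]
    frac = sum(a is C for a in acts) / len(acts)
    assert frac == pytest.approx(0.7, abs=0.03)


# ---------------------------------------------------------------------------
# Mutation matrices

@given(st.integers(min_value=0, max_value=10_000))
def test_mutation_matrix_invariants(seed):
    M = generate_mutation_matrix(np.random.default_rng(seed))
    P = M.probs
    np.testing.assert_allclose(P.sum(axis=1), 1.0)
    assert np.all(np.diag(P) == 0.0)
    assert np.all((P == 0.0) | (P == 0.25))
    assert np.all((P > 0).sum(axis=1) == 4)


def test_matrix_generation_deterministic():
    a = generate_mutation_matrix(np.random.default_rng(42))
    b = generate_mutation_matrix(np.random.default_rng(42))
    np.testing.assert_array_equal(a.targets, b.targets)


def test_marginal_cell_occupancy(rng):
    # each off-diagonal cell is chosen with probability 4/15
    hits = np.zeros((16, 16))
    n = 3000
    for _ in range(n):
        M = generate_mutation_matrix(rng)
        hits += M.probs > 0
    off = ~np.eye(16, dtype=bool)
    assert hits[off].mean() / n == pytest.approx(4 / 15, abs=0.01)


def test_from_probs_roundtrip_and_validation(rng):
    M = generate_mutation_matrix(rng)
    M2 = MutationMatrix.from_probs(M.probs)
    np.testing.assert_array_equal(np.sort(M.targets, axis=1),
                                  np.sort(M2.targets, axis=1))
    bad = M.probs.copy()
    bad[0, 0] = 0.25   # self-mutation forbidden
    with pytest.raises(ValueError):
        MutationMatrix.from_probs(bad)


# ---------------------------------------------------------------------------
# Mutation operator

def test_mutate_mu_zero_is_identity(rng):
    g = random_genotype(rng)
    M = generate_mutation_matrix(rng)
    assert mutate(g, 0.0, M, rng=rng) == g


def test_mutate_never_same_code(rng):
    M = generate_mutation_matrix(rng)
    g = random_genotype(rng)
    for _ in range(200):
        g2 = mutate(g, 1.0, M, rng=rng)
        for old, new in zip((g.H, g.C1, g.C2), (g2.H, g2.C1, g2.C2)):
            assert new.code != old.code
        assert g2.mode is not g.mode  # mu=1 always flips the switch


def test_mutation_kernel_sd(rng):
    M = generate_mutation_matrix(rng)
    g = random_genotype(rng)
    dT = np.array([mutate(g, 1.0, M, rng=rng).T - g.T for _ in range(10_000)])
    assert dT.std() == pytest.approx(0.1, rel=0.05)
    assert dT.mean() == pytest.approx(0.0, abs=0.005)


def test_first_move_clamped(rng):
    M = generate_mutation_matrix(rng)
    g = Genotype(mode=StrategyMode.HEURISTIC, T=0.0,
                 H=named_strategy("GRIM", 1.0),
                 C1=named_strategy("GRIM", 0.0),
                 C2=named_strategy("GRIM", 1.0))
    for _ in range(300):
        g2 = mutate(g, 1.0, M, rng=rng)
        for sub in (g2.H, g2.C1, g2.C2):
            assert 0.0 <= sub.first_move <= 1.0


def test_expected_mutated_units(rng):
    # 8 lotteries per offspring at rate mu -> about 8*mu changes expected
    M = generate_mutation_matrix(rng)
    g = random_genotype(rng)
    mu, n = 0.05, 20_000

    def n_changes(g2):
        c = int(g2.mode is not g.mode) + int(g2.T != g.T)
        for old, new in zip((g.H, g.C1, g.C2), (g2.H, g2.C1, g2.C2)):
            c += int(old.first_move != new.first_move)
            c += int(old.code != new.code)
        return c

    total = sum(n_changes(mutate(g, mu, M, rng=rng)) for _ in range(n))
    assert total / n == pytest.approx(8 * mu, rel=0.05)


# ---------------------------------------------------------------------------
# Founders and serialisation

def test_random_genotype_initialisation(rng):
    gs = [random_genotype(rng) for _ in range(8000)]
    assert all(g.T == 0.0 for g in gs)
    heur = sum(g.mode is StrategyMode.HEURISTIC for g in gs) / len(gs)
    assert heur == pytest.approx(0.5, abs=0.02)
    codes = np.array([g.H.code for g in gs])
    freq = np.bincount(codes, minlength=16) / len(gs)
    np.testing.assert_allclose(freq, 1 / 16, atol=0.012)


@given(st.integers(min_value=0, max_value=10_000))
def test_serialisation_roundtrip(seed):
    g = random_genotype(np.random.default_rng(seed))
    assert genotype_from_dict(genotype_to_dict(g)) == g
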