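"""17-gene strategy genotypes and the mutation machinery.

A genotype carries a switch locus S (heuristic vs. context-dependent
behaviour), a perception threshold T, and three memory-one substrategies:
H (played unconditionally by heuristics) and C1/C2 (played by
context-dependent individuals below/at-or-above the threshold).  Each
substrategy has a continuous first-move cooperation probability and four
Boolean response genes over the previous-round outcomes CC, CD, DC, DD —
17 genes in total.

Mutation of the four response genes is constrained by a 16x16
row-stochastic mutation matrix in which every substrategy can mutate
into exactly four others (probability 0.25 each, never into itself);
S flips, while T and the first moves receive Gaussian perturbations.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np

from .game_core import Action, Outcome

N_CODES = 16
MUTATION_FANOUT = 4
DEFAULT_MUTATION_RATE = 0.001
DEFAULT_MUTATION_SD = 0.1


class StrategyMode(enum.Enum):
    """Value of the switch locus S.

    Stored symbolically; the numeric file encoding follows the
    convention 0 = heuristic, 1 = context-dependent.
    """

    HEURISTIC = "heuristic"
    CONTEXT_DEPENDENT = "context_dependent"


@dataclass(frozen=True)
class Substrategy:
    """One memory-one substrategy: first-move probability + response map."""

    first_move: float
    response: tuple[Action, Action, Action, Action]  # indexed by Outcome

    def __post_init__(self) -> None:
        if not 0.0 <= self.first_move <= 1.0:
            raise ValueError(f"first_move={self.first_move} outside [0, 1]")
        if len(self.response) != 4:
            raise ValueError("response map must cover CC, CD, DC, DD")

    @property
    def code(self) -> int:
        return response_code(self)

    @property
    def response_string(self) -> str:
        """Four-letter C/D string in outcome order CC, CD, DC, DD."""
        return "".join("C" if a is Action.COOPERATE else "D" for a in self.response)


def response_code(sub: Substrategy) -> int:
    """Encode the four response genes as an integer 0..15, CC as MSB."""
    code = 0
    for o in Outcome:
        code = (code << 1) | sub.response[o].value
    return code


def decode_response(code: int, first_move: float = 0.0) -> Substrategy:
    """Inverse of :func:`response_code`."""
    if not 0 <= code < N_CODES:
        raise ValueError(f"code {code} outside 0..15")
    resp = tuple(Action((code >> (3 - o)) & 1) for o in Outcome)
    return Substrategy(first_move=first_move, response=resp)


def substrategy_from_string(s: str, first_move: float = 0.0) -> Substrategy:
    """Parse a four-letter C/D string such as ``"CDDD"`` (grim)."""
    if len(s) != 4 or set(s.upper()) - {"C", "D"}:
        raise ValueError(f"invalid response string {s!r}")
    resp = tuple(Action.COOPERATE if ch == "C" else Action.DEFECT
                 for ch in s.upper())
    return Substrategy(first_move=first_move, response=resp)


class NamedStrategy(enum.Enum):
    GRIM = "CDDD"
    TFT = "CDCD"
    PAVLOV = "CDDC"
    ALLC = "CCCC"
    ALLD = "DDDD"


def named_strategy(name: NamedStrategy | str, first_move: float) -> Substrategy:
    """A classic memory-one substrategy by name.

    GRIM cooperates only after mutual cooperation; TFT copies the
    partner's previous action; PAVLOV (win-stay-lose-shift) cooperates
    after CC and DD.
    """
    if isinstance(name, str):
        name = NamedStrategy[name.upper()]
    return substrategy_from_string(name.value, first_move)


@dataclass(frozen=True)
class Genotype:
    """Full 17-gene strategy genotype."""

    mode: StrategyMode
    T: float
    H: Substrategy
    C1: Substrategy
    C2: Substrategy


def active_substrategy(g: Genotype, c_p: float,
                       tie_to_c2: bool = True) -> Substrategy:
    """Substrategy implemented for perceived consequence ``c_p``.

    Heuristics always play H.  Context-dependent individuals play C1
    when c_p < T and C2 otherwise; ``tie_to_c2=False`` flips the
    comparison direction (the two descriptions of the switch rule in
    the source model disagree on ties and orientation; labels are
    symmetric so dynamics are unaffected).
    """
    if g.mode is StrategyMode.HEURISTIC:
        return g.H
    below = c_p < g.T if tie_to_c2 else c_p <= g.T
    return g.C1 if below else g.C2


def decide(sub: Substrategy, prev: Outcome | None, epsilon: float,
           rng: np.random.Generator) -> Action:
    """One action: first-move lottery or response gene, with ε error flip."""
    if prev is None:
        intended = (Action.COOPERATE if rng.random() < sub.first_move
                    else Action.DEFECT)
    else:
        intended = sub.response[prev]
    if epsilon > 0.0 and rng.random() < epsilon:
        return Action.DEFECT if intended is Action.COOPERATE else Action.COOPERATE
    return intended


# ---------------------------------------------------------------------------
# Mutation

@dataclass(frozen=True)
class MutationMatrix:
    """16x16 row-stochastic matrix over response codes.

    Each row holds exactly four nonzero entries of 0.25 (the four codes
    the row's substrategy can mutate into); the diagonal is zero.
    ``targets`` stores the same information as a (16, 4) index table
    used for sampling.
    """

    targets: np.ndarray  # (16, 4) int array of target codes

    def __post_init__(self) -> None:
        t = np.asarray(self.targets)
        if t.shape != (N_CODES, MUTATION_FANOUT):
            raise ValueError("targets must have shape (16, 4)")
        for row in range(N_CODES):
            vals = set(int(x) for x in t[row])
            if len(vals) != MUTATION_FANOUT or row in vals:
                raise ValueError(f"row {row} targets invalid: {sorted(vals)}")
            if not all(0 <= v < N_CODES for v in vals):
                raise ValueError(f"row {row} targets out of range")

    @property
    def probs(self) -> np.ndarray:
        """Dense (16, 16) probability matrix."""
        P = np.zeros((N_CODES, N_CODES))
        for row in range(N_CODES):
            P[row, self.targets[row]] = 1.0 / MUTATION_FANOUT
        return P

    @classmethod
    def from_probs(cls, P: np.ndarray) -> "MutationMatrix":
        P = np.asarray(P, dtype=float)
        if P.shape != (N_CODES, N_CODES):
            raise ValueError("probability matrix must be 16x16")
        targets = np.empty((N_CODES, MUTATION_FANOUT), dtype=np.int64)
        for row in range(N_CODES):
            nz = np.flatnonzero(P[row] > 0)
            if len(nz) != MUTATION_FANOUT or not np.allclose(P[row, nz], 0.25):
                raise ValueError(f"row {row} is not four entries of 0.25")
            targets[row] = nz
        return cls(targets=targets)

    def sample_target(self, code: int, rng: np.random.Generator) -> int:
        return int(self.targets[code, rng.integers(MUTATION_FANOUT)])


def generate_mutation_matrix(rng: np.random.Generator) -> MutationMatrix:
    """Random mutation matrix: per row, 4 of the other 15 codes, each 0.25."""
    targets = np.empty((N_CODES, MUTATION_FANOUT), dtype=np.int64)
    for row in range(N_CODES):
        others = np.array([x for x in range(N_CODES) if x != row])
        targets[row] = np.sort(rng.choice(others, MUTATION_FANOUT, replace=False))
    return MutationMatrix(targets=targets)


def mutate(g: Genotype, mu: float, M: MutationMatrix,
           sigma: float = DEFAULT_MUTATION_SD,
           rng: np.random.Generator | None = None) -> Genotype:
    """Mutated copy of ``g`` (the parent is never modified).

    Eight independent mutation lotteries at rate ``mu``: the switch
    locus S flips; T and each of the three first moves get a N(0, sigma)
    perturbation (first moves clamped to [0, 1], T unbounded — behaviour
    saturates outside the perception support anyway); each substrategy's
    4-bit response block is redrawn from the mutation matrix row of its
    current code, which never returns the same code.
    """
    if rng is None:
        raise ValueError("an explicit rng is required")
    mode = g.mode
    if rng.random() < mu:
        mode = (StrategyMode.CONTEXT_DEPENDENT if mode is StrategyMode.HEURISTIC
                else StrategyMode.HEURISTIC)
    T = g.T
    if rng.random() < mu:
        T = T + rng.normal(0.0, sigma)

    def mutate_sub(sub: Substrategy) -> Substrategy:
        fm = sub.first_move
        if rng.random() < mu:
            fm = float(np.clip(fm + rng.normal(0.0, sigma), 0.0, 1.0))
        code = sub.code
        if rng.random() < mu:
            code = M.sample_target(code, rng)
        return decode_response(code, first_move=fm)

    return replace(g, mode=mode, T=T, H=mutate_sub(g.H),
                   C1=mutate_sub(g.C1), C2=mutate_sub(g.C2))


def random_genotype(rng: np.random.Generator) -> Genotype:
    """Founder genotype: S fair coin, T = 0, uniform first moves and codes."""
    mode = (StrategyMode.HEURISTIC if rng.random() < 0.5
            else StrategyMode.CONTEXT_DEPENDENT)
    subs = [decode_response(int(rng.integers(N_CODES)),
                            first_move=float(rng.random()))
            for _ in range(3)]
    return Genotype(mode=mode, T=0.0, H=subs[0], C1=subs[1], C2=subs[2])


# ---------------------------------------------------------------------------
# Text codec (used by CSV output and the strategy census)

def genotype_to_dict(g: Genotype) -> dict:
    """Serialise all 17 genes; S uses 0 = heuristic, 1 = context-dependent."""
    d: dict = {"S": 0 if g.mode is StrategyMode.HEURISTIC else 1, "T": g.T}
    for label, sub in (("H", g.H), ("C1", g.C1), ("C2", g.C2)):
        d[f"{label}_first_move"] = sub.first_move
        d[f"{label}_response"] = sub.response_string
    return d


def genotype_from_dict(d: dict) -> Genotype:
    mode = StrategyMode.HEURISTIC if int(d["S"]) == 0 else StrategyMode.CONTEXT_DEPENDENT
    subs = {label: substrategy_from_string(d[f"{label}_response"],
                                           first_move=float(d[f"{label}_first_move"]))
            for label in ("H", "C1", "C2")}
    return Genotype(mode=mode, T=float(d["T"]), H=subs["H"],
                    C1=subs["C1"], C2=subs["C2"])
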