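"""One-parameter family of symmetric 2x2 cooperation games.

A cooperating individual pays a variable consequence ``c`` (from a severe
cost of -3 up to a direct benefit of 1) and confers a fixed benefit ``b``
(default 2) on the partner.  Depending on ``c`` the stage game is a
harmony game, a prisoner's dilemma, or a spiteful game in which even
mutual cooperation is worse than mutual defection.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

C_LO: float = -3.0
C_HI: float = 1.0
DEFAULT_BENEFIT: float = 2.0


class Action(enum.Enum):
    COOPERATE = 1
    DEFECT = 0


class Outcome(enum.IntEnum):
    """Joint outcome of one round, focal individual's action first.

    The integer values index the four response genes in the canonical
    order CC, CD, DC, DD (CC is the most significant bit of a response
    code).
    """

    CC = 0
    CD = 1
    DC = 2
    DD = 3

    @property
    def mirrored(self) -> "Outcome":
        """The same round seen from the partner's perspective."""
        return _MIRROR[self]

    @staticmethod
    def from_actions(own: Action, other: Action) -> "Outcome":
        return Outcome((1 - own.value) * 2 + (1 - other.value))


_MIRROR = {Outcome.CC: Outcome.CC, Outcome.CD: Outcome.DC,
           Outcome.DC: Outcome.CD, Outcome.DD: Outcome.DD}


class GameClass(enum.Enum):
    SPITE_REGION = "spite"
    PRISONERS_DILEMMA = "prisoners_dilemma"
    HARMONY = "harmony"


@dataclass(frozen=True)
class GameContext:
    """True payoff environment of one repeated interaction.

    Parameters
    ----------
    c
        Consequence of cooperating to the actor, in [-3, 1].
    b
        Benefit conferred on the partner, positive (default 2).
    """

    c: float
    b: float = DEFAULT_BENEFIT

    def __post_init__(self) -> None:
        if not (C_LO <= self.c <= C_HI):
            raise ValueError(f"c={self.c} outside [{C_LO}, {C_HI}]")
        if self.b <= 0:
            raise ValueError(f"b={self.b} must be positive")


def payoff(own: Action, other: Action, ctx: GameContext) -> float:
    """Stage-game payoff to the focal individual.

    Additive: cooperating adds ``c`` to one's own payoff, and a
    cooperating partner adds ``b``; hence b+c for CC, c for CD, b for
    DC and 0 for DD.
    """
    return ctx.b * other.value + ctx.c * own.value


def classify_game(c: float) -> GameClass:
    """Classify the stage game induced by consequence ``c``.

    Defection dominates for c < 0; below c = -2 mutual defection also
    beats mutual cooperation (spite region); above c = 0 cooperation
    dominates (harmony).  The measure-zero boundaries c = -2 and c = 0
    are assigned to the prisoner's-dilemma region.
    """
    if not (C_LO <= c <= C_HI):
        raise ValueError(f"c={c} outside [{C_LO}, {C_HI}]")
    if c < -2.0:
        return GameClass.SPITE_REGION
    if c <= 0.0:
        return GameClass.PRISONERS_DILEMMA
    return GameClass.HARMONY
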