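"""Core definitions for the 2x2 chicken game.

The chicken game is an anti-coordination game: each player either *avoids*
(concedes, taking a small loss if the other rushes) or *rushes* (wins only if
the other avoids; mutual rushing is the crash, the worst joint outcome).

Payoffs are stored per (self, opponent) *role*, not per seat: every cell of
:class:`PayoffMatrix` answers "if I take row-action and the other takes
column-action, what do I get and what do they get?".  The engine maps seats
onto roles, so the same matrix object serves both players of a symmetric game.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import IntEnum
from typing import NamedTuple


class Action(IntEnum):
    """The two actions, serialized with the conventional codes rush=0, avoid=1."""

    RUSH = 0
    AVOID = 1

    @classmethod
    def from_code(cls, code: int) -> "Action":
        if code not in (0, 1):
            raise ValueError(f"invalid action code {code!r}: must be 0 (rush) or 1 (avoid)")
        return cls(code)


class JointOutcome(NamedTuple):
    """A realized joint action, from the deciding player's perspective."""

    self_action: Action
    opponent_action: Action

    @property
    def code(self) -> str:
        """Two-letter code, self first: AA, AR, RA or RR."""
        letter = {Action.AVOID: "A", Action.RUSH: "R"}
        return letter[self.self_action] + letter[self.opponent_action]


#: the four joint outcomes in canonical order
OUTCOMES = (
    JointOutcome(Action.AVOID, Action.AVOID),
    JointOutcome(Action.AVOID, Action.RUSH),
    JointOutcome(Action.RUSH, Action.AVOID),
    JointOutcome(Action.RUSH, Action.RUSH),
)


class PayoffMatrixError(ValueError):
    """Raised for incomplete or non-finite payoff matrices."""


@dataclass(frozen=True)
class PayoffMatrix:
    """Bimatrix of the 2x2 game: each cell is (payoff to self, payoff to opponent).

    Cell names follow the joint-outcome code with the self's action first:
    ``aa`` both avoid, ``ar`` self avoids / opponent rushes, ``ra`` self
    rushes / opponent avoids, ``rr`` both rush.  Payoffs are real-valued so
    rescaled matrices are admissible; the default is the standard integer
    scale (see :data:`CHICKEN_DEFAULT`).
    """

    aa: tuple[float, float]
    ar: tuple[float, float]
    ra: tuple[float, float]
    rr: tuple[float, float]

    def __post_init__(self) -> None:
        for name in ("aa", "ar", "ra", "rr"):
            cell = getattr(self, name)
            if cell is None or len(cell) != 2:
                raise PayoffMatrixError(f"cell {name!r} must be a pair of numbers")
            if not all(math.isfinite(float(v)) for v in cell):
                raise PayoffMatrixError(f"cell {name!r} has non-finite payoffs: {cell}")
            object.__setattr__(self, name, (float(cell[0]), float(cell[1])))

    def payoff(self, outcome: JointOutcome) -> tuple[float, float]:
        """Payoff pair for a joint outcome, self's payoff first."""
        return getattr(self, outcome.code.lower())

    def swapped(self) -> "PayoffMatrix":
        """The same game viewed from the other player's role.

        For a player-symmetric matrix (like the default) this is a no-op.
        """
        return PayoffMatrix(
            aa=(self.aa[1], self.aa[0]),
            ar=(self.ra[1], self.ra[0]),
            ra=(self.ar[1], self.ar[0]),
            rr=(self.rr[1], self.rr[0]),
        )

    def is_player_symmetric(self) -> bool:
        return self == self.swapped()

    def to_dict(self) -> dict[str, list[float]]:
        return {name: list(getattr(self, name)) for name in ("aa", "ar", "ra", "rr")}

    @classmethod
    def from_dict(cls, cells: dict) -> "PayoffMatrix":
        missing = {"aa", "ar", "ra", "rr"} - set(cells)
        if missing:
            raise PayoffMatrixError(f"payoff matrix missing cells: {sorted(missing)}")
        return cls(
            aa=tuple(cells["aa"]),
            ar=tuple(cells["ar"]),
            ra=tuple(cells["ra"]),
            rr=tuple(cells["rr"]),
        )


#: Default chicken-game reward scale: avoiding against a rusher costs 300,
#: rushing against an avoider wins 300, and the crash costs both players 1000.
CHICKEN_DEFAULT = PayoffMatrix(
    aa=(0.0, 0.0),
    ar=(-300.0, 300.0),
    ra=(300.0, -300.0),
    rr=(-1000.0, -1000.0),
)

#: named built-in matrices, addressable from config files
BUILTIN_MATRICES = {"chicken_default": CHICKEN_DEFAULT}


def payoff(outcome: JointOutcome, matrix: PayoffMatrix) -> tuple[float, float]:
    """Payoffs for a joint outcome, self first."""
    return matrix.payoff(outcome)


def opponent_payoff_bounds(
    self_action: Action, matrix: PayoffMatrix
) -> tuple[float, float]:
    """Max and min payoff the opponent can receive given the self's fixed action.

    These bounds are the building blocks of the kindness measure: fixing my
    action, how well or badly can the other player come out depending on
    their own choice?
    """
    payoffs = [
        matrix.payoff(JointOutcome(self_action, opp))[1]
        for opp in (Action.AVOID, Action.RUSH)
    ]
    return max(payoffs), min(payoffs)
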