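"""The self-concept fairness decision model.

A player tracks a running *fairness* ledger for both themselves and their
opponent.  Each realized action has a *kindness* — a normalized measure of
how generous that action is toward the other player's payoff prospects — and
fairness is an exponentially retained aggregate of kindness history.  The
(possibly asymmetric) difference of the two fairness values is the
*reciprocity* r, which scales how much the opponent's prospective wealth
enters the player's utility.  The utility difference between avoiding and
rushing passes through a sigmoid to yield p(avoid), from which the action is
drawn as a Bernoulli sample.

Pipeline per iteration::

    kindness f  ->  fairness ledger (F_self, F_opp)  ->  reciprocity r
        ->  utility u(avoid), u(rush)  ->  p(avoid) = sigmoid(u_avoid - u_rush)
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .game import Action, JointOutcome, PayoffMatrix, opponent_payoff_bounds

__all__ = [
    "ModelParams",
    "FairnessState",
    "PRESETS",
    "preset_params",
    "kindness_per_action",
    "update_fairness",
    "reciprocity",
    "expected_payoffs",
    "signed_power",
    "utility",
    "avoid_probability",
]

#: default learning rate, chosen so one kindness step of 0.6 moves fairness by 0.5
DEFAULT_ETA = 5.0 / 6.0


class DegenerateMatrixError(ValueError):
    """The recipient's payoff does not depend on anything: kindness undefined."""


@dataclass(frozen=True)
class ModelParams:
    """The five scalars of the fairness model.

    alpha : convexity of the utility in wealth, 0 < alpha <= 1.  Smaller
        values strengthen the preference for equal (r>0) or unequal (r<0)
        payoff distributions; alpha=1 is linear.
    beta : intrinsic benevolence, added to the opponent's fairness update
        every iteration.  Positive means the player habitually perceives the
        opponent as kinder than their actions warrant; negative, as more
        selfish.  Unbounded.
    gamma : fairness retention rate, 0 <= gamma <= 1.  How much of the ledger
        survives an iteration; gamma < 1 makes fairness volatile and bounded.
    theta : weight on the opponent's fairness in reciprocity, 0 <= theta <= 1.
        theta = 0.5 is the unbiased case where reciprocity reduces to
        F_opp - F_self.
    eta : learning rate of the fairness update, eta > 0 (default 5/6).
    """

    alpha: float
    beta: float
    gamma: float
    theta: float
    eta: float = DEFAULT_ETA

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must be in [0, 1], got {self.gamma}")
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError(f"theta must be in [0, 1], got {self.theta}")
        if not self.eta > 0.0:
            raise ValueError(f"eta must be > 0, got {self.eta}")
        for name in ("alpha", "beta", "gamma", "theta", "eta"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def to_dict(self) -> dict[str, float]:
        return {
            "alpha": self.alpha,
            "beta": self.beta,
            "gamma": self.gamma,
            "theta": self.theta,
            "eta": self.eta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**{k: float(v) for k, v in d.items()})


#: Optimized parameter presets producing the two target behavioral styles:
#: "mutual_exchange" alternates one-sided outcomes with the opponent,
#: "rush" rushes consistently (note the strongly negative benevolence).
PRESETS: dict[str, ModelParams] = {
    "mutual_exchange": ModelParams(alpha=0.986, beta=0.069, gamma=0.110, theta=0.710),
    "rush": ModelParams(alpha=0.863, beta=-0.739, gamma=0.673, theta=0.696),
}


def preset_params(name: str) -> ModelParams:
    """Look up a named parameter preset.

    Raises KeyError naming the available presets for an unknown name.
    """
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available presets: {sorted(PRESETS)}"
        ) from None


@dataclass(frozen=True)
class FairnessState:
    """The fairness ledger: self's and opponent's running fairness, both 0 at start."""

    f_self: float = 0.0
    f_opp: float = 0.0


def kindness_per_action(
    action: Action,
    matrix: PayoffMatrix,
    role: str = "self_to_opponent",
) -> float:
    """Normalized kindness of an action toward the other player.

    For the actor's action a, kindness is::

        f(a) = (pi_max(a) - E[pi_max]) / E[pi_max - pi_min]

    where pi_max(a) / pi_min(a) are the best / worst payoff the *recipient*
    can receive given the actor plays a, and E[.] is the unweighted mean over
    the actor's two actions.  The normalization makes kindness invariant to
    positive rescaling of the matrix and to constant shifts of the
    recipient's payoffs.

    ``role`` selects whose kindness: ``"self_to_opponent"`` evaluates the
    matrix as given, ``"opponent_to_self"`` evaluates it from the opponent's
    role (for a player-symmetric matrix the two coincide).
    """
    if role == "self_to_opponent":
        m = matrix
    elif role == "opponent_to_self":
        m = matrix.swapped()
    else:
        raise ValueError(f"unknown role {role!r}")

    bounds = {a: opponent_payoff_bounds(a, m) for a in (Action.AVOID, Action.RUSH)}
    mean_max = (bounds[Action.AVOID][0] + bounds[Action.RUSH][0]) / 2.0
    mean_range = (
        (bounds[Action.AVOID][0] - bounds[Action.AVOID][1])
        + (bounds[Action.RUSH][0] - bounds[Action.RUSH][1])
    ) / 2.0
    if mean_range <= 0.0:
        raise DegenerateMatrixError(
            "recipient's payoff is independent of both players' actions; "
            "kindness is undefined for this matrix"
        )
    return (bounds[action][0] - mean_max) / mean_range


def update_fairness(
    state: FairnessState,
    self_action: Action,
    opp_action: Action,
    params: ModelParams,
    matrix: PayoffMatrix,
) -> FairnessState:
    """One fairness-ledger update after a realized joint action.

    F_self' = gamma*F_self + eta*f_self(a_self)
    F_opp'  = gamma*F_opp  + eta*f_opp(a_opp) + beta

    The benevolence bias beta enters only the opponent's update: it shifts
    how kind the opponent is *perceived* to be, not the self's own record.
    """
    f_self = kindness_per_action(self_action, matrix, "self_to_opponent")
    f_opp = kindness_per_action(opp_action, matrix, "opponent_to_self")
    return FairnessState(
        f_self=params.gamma * state.f_self + params.eta * f_self,
        f_opp=params.gamma * state.f_opp + params.eta * f_opp + params.beta,
    )


def reciprocity(state: FairnessState, theta: float) -> float:
    """r = 2*(theta*F_opp - (1-theta)*F_self).

    The factor 2 makes r equal F_opp - F_self exactly at theta = 0.5.
    Positive r: the opponent is perceived as the kinder party, so their
    wealth enters the utility with positive weight.
    """
    if not 0.0 <= theta <= 1.0:
        raise ValueError(f"theta must be in [0, 1], got {theta}")
    return 2.0 * (theta * state.f_opp - (1.0 - theta) * state.f_self)


def expected_payoffs(
    self_action: Action, matrix: PayoffMatrix
) -> tuple[float, float]:
    """Expected (self, opponent) payoff of an action, uniform over the opponent's reply.

    The opponent's two actions are weighted equally — the same convention
    that normalizes kindness.
    """
    cells = [
        matrix.payoff(JointOutcome(self_action, opp))
        for opp in (Action.AVOID, Action.RUSH)
    ]
    return (
        (cells[0][0] + cells[1][0]) / 2.0,
        (cells[0][1] + cells[1][1]) / 2.0,
    )


def signed_power(x: float, alpha: float) -> float:
    """sign(x)*|x|**alpha — the odd extension of the power to negative wealth.

    Cumulative scores can go strongly negative during a session; the signed
    power keeps the utility monotone in wealth and equals the plain power
    for x >= 0.
    """
    return math.copysign(abs(x) ** alpha, x) if x != 0.0 else 0.0


def utility(
    self_action: Action,
    cum_self: float,
    cum_opp: float,
    r: float,
    params: ModelParams,
    matrix: PayoffMatrix,
) -> float:
    """Utility of an action given both players' cumulative wealth and reciprocity r.

    u(a) = (1/alpha) * [ s(cum_self + E_self(a))^alpha
                         + r * s(cum_opp + E_opp(a))^alpha ]

    with s(.)^alpha the signed power.  At alpha=1, r=0 this is just the
    self's expected wealth after the action.
    """
    e_self, e_opp = expected_payoffs(self_action, matrix)
    a = params.alpha
    return (
        signed_power(cum_self + e_self, a) + r * signed_power(cum_opp + e_opp, a)
    ) / a


def avoid_probability(u_avoid: float, u_rush: float) -> float:
    """p(avoid) = sigmoid(u_avoid - u_rush), saturating-safe.

    The utility difference enters raw (no temperature): because utilities
    grow with cumulative wealth, the sigmoid can saturate in long sessions.
    The result is clamped to the open interval (0, 1) at float resolution.
    """
    if not (math.isfinite(u_avoid) and math.isfinite(u_rush)):
        raise ValueError("utilities must be finite")
    p = float(expit(u_avoid - u_rush))
    tiny = np.nextafter(0.0, 1.0)
    return float(min(max(p, tiny), 1.0 - np.finfo(float).eps / 2))
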