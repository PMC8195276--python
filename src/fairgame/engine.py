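"""Session engine: the fairness agent's decide/observe loop, opponents, phases, logging.

A session is an ordered list of phases; within each phase the agent's model
parameters are fixed, and at a phase boundary they are swapped out while the
fairness ledger and both cumulative scores persist (only the parameters are
said to change; the analysis window, by contrast, restarts — see
:mod:`fairgame.patterns`).

Both players act simultaneously each trial: neither sees the other's
current-trial choice before committing.  The agent and any scripted opponent
draw from independent, separately seeded random streams so either side is
replayable in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .game import Action, CHICKEN_DEFAULT, JointOutcome, PayoffMatrix
from .model import (
    FairnessState,
    ModelParams,
    avoid_probability,
    preset_params,
    reciprocity,
    update_fairness,
    utility,
)

__all__ = [
    "FairnessAgent",
    "PhaseSpec",
    "SessionConfig",
    "TrialRecord",
    "SessionLog",
    "run_session",
    "scripted_policy",
    "AlwaysAvoid",
    "AlwaysRush",
    "RandomBernoulli",
    "FixedSequence",
    "experiment_default_config",
]


class FairnessAgent:
    """A player following the self-concept fairness model.

    State: model parameters, the fairness ledger (starts at zero), both
    players' cumulative payoffs (start at the endowment), and a private RNG
    stream for the Bernoulli action draw.
    """

    def __init__(
        self,
        params: ModelParams,
        matrix: PayoffMatrix = CHICKEN_DEFAULT,
        endowment: float = 20_000.0,
        rng: Optional[np.random.Generator] = None,
    ) -> None:
        self.params = params
        self.matrix = matrix
        self.fairness = FairnessState()
        self.cum_self = float(endowment)
        self.cum_opp = float(endowment)
        self.rng = rng if rng is not None else np.random.default_rng()

    def set_params(self, params: ModelParams) -> None:
        """Switch parameters (phase boundary); ledger and scores persist."""
        self.params = params

    def action_probability(self) -> float:
        """p(avoid) from the current ledger and cumulative scores."""
        r = reciprocity(self.fairness, self.params.theta)
        u_avoid = utility(
            Action.AVOID, self.cum_self, self.cum_opp, r, self.params, self.matrix
        )
        u_rush = utility(
            Action.RUSH, self.cum_self, self.cum_opp, r, self.params, self.matrix
        )
        return avoid_probability(u_avoid, u_rush)

    def decide(self) -> tuple[Action, float]:
        """Compute p(avoid) and draw the action as a Bernoulli sample."""
        p = self.action_probability()
        action = Action.AVOID if self.rng.random() < p else Action.RUSH
        return action, p

    def observe(self, self_action: Action, opp_action: Action) -> None:
        """End-of-trial update: kindness -> fairness ledger -> cumulative scores."""
        self.fairness = update_fairness(
            self.fairness, self_action, opp_action, self.params, self.matrix
        )
        pay_self, pay_opp = self.matrix.payoff(JointOutcome(self_action, opp_action))
        self.cum_self += pay_self
        self.cum_opp += pay_opp


# ---------------------------------------------------------------------------
# opponent policies


class Policy:
    """An opponent: produces one action per trial, may observe the outcome."""

    def decide(self) -> tuple[Action, Optional[float]]:
        raise NotImplementedError

    def observe(self, self_action: Action, opp_action: Action) -> None:
        pass

    def set_params(self, params: ModelParams) -> None:
        """Phase-boundary hook; scripted policies ignore it."""
        pass


class AlwaysAvoid(Policy):
    def decide(self) -> tuple[Action, Optional[float]]:
        return Action.AVOID, None


class AlwaysRush(Policy):
    def decide(self) -> tuple[Action, Optional[float]]:
        return Action.RUSH, None


class RandomBernoulli(Policy):
    """iid avoid with probability p, from the policy's own stream."""

    def __init__(self, p: float, rng: Optional[np.random.Generator] = None) -> None:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p must be in [0, 1], got {p}")
        self.p = p
        self.rng = rng if rng is not None else np.random.default_rng()

    def decide(self) -> tuple[Action, Optional[float]]:
        return (Action.AVOID if self.rng.random() < self.p else Action.RUSH), self.p


class FixedSequence(Policy):
    """Replays a predetermined action sequence."""

    def __init__(self, actions: Sequence[Action]) -> None:
        self.actions = [Action(a) for a in actions]
        self._i = 0

    def decide(self) -> tuple[Action, Optional[float]]:
        if self._i >= len(self.actions):
            raise IndexError(
                f"fixed sequence exhausted after {len(self.actions)} actions"
            )
        a = self.actions[self._i]
        self._i += 1
        return a, None


class AgentPolicy(Policy):
    """Wraps a FairnessAgent as an opponent (self-play)."""

    def __init__(self, agent: FairnessAgent) -> None:
        self.agent = agent

    def decide(self) -> tuple[Action, Optional[float]]:
        return self.agent.decide()

    def observe(self, self_action: Action, opp_action: Action) -> None:
        self.agent.observe(self_action, opp_action)

    def set_params(self, params: ModelParams) -> None:
        self.agent.set_params(params)


def scripted_policy(
    kind: str,
    *,
    p: Optional[float] = None,
    sequence: Optional[Sequence[Action]] = None,
    rng: Optional[np.random.Generator] = None,
) -> Policy:
    """Build a scripted opponent by name.

    kind is one of ``always_avoid``, ``always_rush``, ``random_bernoulli``
    (requires p), ``fixed_sequence`` (requires sequence).
    """
    if kind == "always_avoid":
        return AlwaysAvoid()
    if kind == "always_rush":
        return AlwaysRush()
    if kind == "random_bernoulli":
        if p is None:
            raise ValueError("random_bernoulli requires p")
        return RandomBernoulli(p, rng=rng)
    if kind == "fixed_sequence":
        if sequence is None:
            raise ValueError("fixed_sequence requires a sequence of actions")
        return FixedSequence(sequence)
    raise ValueError(
        f"unknown policy kind {kind!r}; expected one of "
        "always_avoid, always_rush, random_bernoulli, fixed_sequence"
    )


# ---------------------------------------------------------------------------
# session configuration and log


@dataclass(frozen=True)
class PhaseSpec:
    """A contiguous block of trials with one fixed parameter set."""

    n_iterations: int
    params: ModelParams

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("phase must have at least one iteration")

    @classmethod
    def from_preset(cls, n_iterations: int, name: str) -> "PhaseSpec":
        return cls(n_iterations, preset_params(name))


@dataclass(frozen=True)
class SessionConfig:
    phases: tuple[PhaseSpec, ...]
    matrix: PayoffMatrix = CHICKEN_DEFAULT
    endowment: float = 20_000.0
    seed: int = 0
    opponent: dict = field(default_factory=lambda: {"kind": "random_bernoulli", "p": 0.5})

    def __post_init__(self) -> None:
        if len(self.phases) < 1:
            raise ValueError("session needs at least one phase")
        object.__setattr__(self, "phases", tuple(self.phases))

    @property
    def n_iterations(self) -> int:
        return sum(ph.n_iterations for ph in self.phases)

    @property
    def phase_lengths(self) -> list[int]:
        return [ph.n_iterations for ph in self.phases]


@dataclass(frozen=True)
class TrialRecord:
    """One row of the session log; cum columns are running sums from the endowment."""

    iteration: int  # 1-based
    phase: int  # 1-based
    agent_action: Action
    opponent_action: Action
    agent_payoff: float
    opponent_payoff: float
    agent_cum: float
    opponent_cum: float
    p_avoid: float
    decision_time: Optional[float] = None  # seconds in [0, 3]; None when no key press


@dataclass
class SessionLog:
    """A complete recorded session: config echo, trial records, final scores."""

    config: SessionConfig
    records: list[TrialRecord] = field(default_factory=list)
    aborted: bool = False

    def __len__(self) -> int:
        return len(self.records)

    @property
    def final_scores(self) -> tuple[float, float]:
        if not self.records:
            return (self.config.endowment, self.config.endowment)
        last = self.records[-1]
        return (last.agent_cum, last.opponent_cum)

    def actions(self) -> np.ndarray:
        """(n, 2) int array of action codes, agent column first."""
        return np.array(
            [[int(r.agent_action), int(r.opponent_action)] for r in self.records],
            dtype=np.int64,
        ).reshape(-1, 2)

    def to_frame(self):
        """The log as a pandas DataFrame in the canonical CSV column order."""
        import pandas as pd

        return pd.DataFrame(
            {
                "iteration": [r.iteration for r in self.records],
                "phase": [r.phase for r in self.records],
                "agent_action": [int(r.agent_action) for r in self.records],
                "opponent_action": [int(r.opponent_action) for r in self.records],
                "agent_payoff": [r.agent_payoff for r in self.records],
                "opponent_payoff": [r.opponent_payoff for r in self.records],
                "agent_cum": [r.agent_cum for r in self.records],
                "opponent_cum": [r.opponent_cum for r in self.records],
                "p_avoid": [r.p_avoid for r in self.records],
                "decision_time": [r.decision_time for r in self.records],
            }
        )


def _build_opponent(spec: dict, rng: np.random.Generator, config: "SessionConfig") -> Policy:
    kind = spec.get("kind")
    if kind == "fairness_agent":
        params = spec.get("params")
        if isinstance(params, str):
            params = preset_params(params)
        elif isinstance(params, dict):
            params = ModelParams.from_dict(params)
        elif params is None:
            raise ValueError("fairness_agent opponent requires 'params' (preset name or dict)")
        agent = FairnessAgent(
            params, config.matrix.swapped(), endowment=config.endowment, rng=rng
        )
        return AgentPolicy(agent)
    kwargs = {k: v for k, v in spec.items() if k != "kind"}
    if "sequence" in kwargs:
        kwargs["sequence"] = [Action.from_code(int(a)) for a in kwargs["sequence"]]
    return scripted_policy(kind, rng=rng, **kwargs)


def run_session(
    config: SessionConfig, opponent: Optional[Policy] = None
) -> SessionLog:
    """Run a full phase-scheduled session of the iterated chicken game.

    The agent's seed and the opponent's seed are spawned deterministically
    from ``config.seed``.  If ``opponent`` is omitted it is built from
    ``config.opponent`` (a descriptor dict with a ``kind`` key, or
    ``{"kind": "fairness_agent", "params": <preset|dict>}`` for self-play).
    At each phase boundary both players' ``set_params`` hooks fire with the
    new phase's parameters; ledger and cumulative scores carry over.
    """
    agent_seq, opp_seq = np.random.SeedSequence(config.seed).spawn(2)
    agent = FairnessAgent(
        config.phases[0].params,
        config.matrix,
        endowment=config.endowment,
        rng=np.random.default_rng(agent_seq),
    )
    if opponent is None:
        opponent = _build_opponent(
            config.opponent, np.random.default_rng(opp_seq), config
        )

    log = SessionLog(config=config)
    iteration = 0
    for phase_idx, phase in enumerate(config.phases, start=1):
        agent.set_params(phase.params)
        opponent.set_params(phase.params)
        for _ in range(phase.n_iterations):
            iteration += 1
            # simultaneous moves: both commit before either observes
            agent_action, p_avoid = agent.decide()
            opp_action, _ = opponent.decide()
            agent.observe(agent_action, opp_action)
            opponent.observe(opp_action, agent_action)
            pay_a, pay_o = config.matrix.payoff(JointOutcome(agent_action, opp_action))
            log.records.append(
                TrialRecord(
                    iteration=iteration,
                    phase=phase_idx,
                    agent_action=agent_action,
                    opponent_action=opp_action,
                    agent_payoff=pay_a,
                    opponent_payoff=pay_o,
                    agent_cum=agent.cum_self,
                    opponent_cum=agent.cum_opp,
                    p_avoid=p_avoid,
                    decision_time=None,
                )
            )
    return log


def experiment_default_config(seed: int = 0) -> SessionConfig:
    """The three-phase reference design: 50/50/50 trials, exchange -> rush -> exchange
    presets, default matrix, 20,000-point endowment, random-play opponent."""
    return SessionConfig(
        phases=(
            PhaseSpec.from_preset(50, "mutual_exchange"),
            PhaseSpec.from_preset(50, "rush"),
            PhaseSpec.from_preset(50, "mutual_exchange"),
        ),
        matrix=CHICKEN_DEFAULT,
        endowment=20_000.0,
        seed=seed,
    )
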