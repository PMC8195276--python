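# fairgame

Simulation and analysis of the **iterated chicken game** played by an
artificial agent driven by a **self-concept fairness model** — an account of
social decision-making in which a player tracks the fairness of both
themselves and their opponent and lets their *reciprocity* (the weighted gap
between the two) decide how much the opponent's wealth matters to them.

The package is for computational behavioral scientists who want a reusable,
seeded, scriptable version of this class of agent: to generate opponent
behavior for human experiments, to study the model's dynamics in self-play,
or to re-analyze recorded sessions with the standard bilateral
behavioral-pattern statistics.

## The game and the model

Each trial both players simultaneously **avoid** (A, code 1) or **rush**
(R, code 0). The default reward scale (points, self's payoff first):

|            | opp. avoids | opp. rushes |
|------------|-------------|-------------|
| self avoids| (0, 0)      | (−300, 300) |
| self rushes| (300, −300) | (−1000, −1000) |

The agent's decision chain, per iteration *k*:

1. **Kindness** of an action *a*:
   `f(a) = (π_j^max(a) − E[π_j^max]) / E[π_j^max − π_j^min]`,
   where π_j^max/min are the best/worst payoff the recipient can get given
   the actor plays *a*, and E[·] averages uniformly over the actor's two
   actions. Under the default matrix, f(avoid) = 0.6, f(rush) = −0.6.
2. **Fairness ledger** (starts at zero):
   `F_i(k+1) = γ F_i(k) + η f_i(a_i(k))`,
   `F_j(k+1) = γ F_j(k) + η f_j(a_j(k)) + β`,
   with retention γ, learning rate η (default 5/6) and intrinsic
   benevolence β applied to the opponent's perceived fairness only.
3. **Reciprocity**: `r = 2(θ F_j − (1−θ) F_i)`; at θ = 0.5 this is simply
   F_j − F_i.
4. **Utility** of action *a* given cumulative wealth Σπ:
   `u(a) = (1/α)[(Σπ_i + E[π_i^a])^α + r (Σπ_j + E[π_j^a])^α]`
   (signed power for negative wealth).
5. **Choice**: `p(avoid) = 1/(1+e^−z)`, `z = u(avoid) − u(rush)`; the action
   is a Bernoulli draw.

Two shipped parameter presets produce the two canonical behavioral styles:
`mutual_exchange` (α=0.986, β=0.069, γ=0.110, θ=0.710) alternates one-sided
outcomes with its opponent, and `rush` (α=0.863, β=−0.739, γ=0.673, θ=0.696)
rushes consistently.

Recorded sessions are analyzed with a **3-trial sliding window** (step 1,
restarted at phase boundaries) classifying each window as *mutual avoid*,
*mutual rush*, *exchange*, *unfair* or *undefined*, plus per-phase score
slopes. See `docs/methods.md` for the exact windowing rule and its exact
expected frequencies under random play.

## Worked example

```python
from fairgame import (Action, CHICKEN_DEFAULT, FairnessState, preset_params,
                      update_fairness, reciprocity, avoid_probability)

params = preset_params("mutual_exchange")
state = update_fairness(FairnessState(), Action.AVOID, Action.RUSH,
                        params, CHICKEN_DEFAULT)
print(state)                          # FairnessState(f_self=0.5, f_opp=-0.431)
print(reciprocity(state, theta=0.5))  # -0.931
print(avoid_probability(1781.7, 1778.9))  # 0.9426758241011287
```

After one trial in which the self avoided and the opponent rushed, the
self's fairness rises to 0.5 and the opponent's falls to −0.431 (their
kindness −0.5 plus the benevolence 0.069); the reciprocity magnitude 0.931
then tilts the utilities, and a 2.8-point utility edge for avoiding maps
through the sigmoid to p(avoid) ≈ 0.9427.

A full phase-scheduled session from the command line:

```bash
fairgame simulate --seed 1 --out session.csv   # 150 trials, 50/50/50 phases
fairgame analyze session.csv                   # per-phase counts + slopes
fairgame montecarlo --seed 1                   # random-play validation
fairgame presets                               # list the parameter presets
```

`fairgame simulate` uses the bundled three-phase design (exchange → rush →
exchange, 50 trials each, 20,000-point endowment) unless `--config` points
at your own YAML/JSON; `fairgame play` runs the same session interactively.

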