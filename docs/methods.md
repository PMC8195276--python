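# Methods

## The decision model

The agent plays the 2×2 chicken game by maintaining a two-entry *fairness
ledger* — its own fairness F_i and its opponent's F_j — and converting the
ledger into an avoid probability each trial. The chain is: per-action
kindness → ledger update → reciprocity → utility of each action → sigmoid →
Bernoulli draw. All five steps are pure functions in `fairgame.model`; the
ledger, cumulative scores and RNG stream live in
`fairgame.engine.FairnessAgent`.

Assumptions worth stating explicitly:

- **Kindness is matrix-relative and normalized.** The numerator compares the
  recipient's best attainable payoff under the chosen action with its mean
  over the actor's two actions; the denominator is the mean payoff range.
  Kindness is therefore invariant to positive rescaling of the matrix and to
  constant shifts of the recipient's payoffs (property-tested). It is
  undefined for matrices in which the recipient's payoff depends on nothing;
  these raise `DegenerateMatrixError`.
- **Expectations are uniform.** Wherever an expectation over the other
  player's action appears (kindness normalization, the E[π^a] terms of the
  utility), it is an unweighted mean over the two actions, not a
  belief-weighted one. This is the same convention on both sides of the
  model, and it reproduces the reference kindness values (±0.6) exactly.
  The reference description's two printed utilities (1,781.7 / 1,778.9) are
  *not* reproducible under this or any uniform-family convention we tried
  (we obtain ≈1,768.3 for the avoid utility in the same regime); only their
  difference feeds the choice step, so the sigmoid is validated on the
  printed pair directly and the utilities themselves are not treated as
  ground truth.
- **Benevolence is one-sided.** β enters only the opponent's ledger update —
  it models a perception bias about the other, not about oneself.
- **Reciprocity sign.** The formula r = 2(θF_j − (1−θ)F_i) is implemented as
  written. In the canonical one-step example (self avoids, opponent rushes)
  it yields −0.9311, while the accompanying narrative calls the value
  positive; we follow the formula and, where the example is used as a check,
  compare magnitudes.
- **Negative wealth.** Cumulative scores go far below zero in rush-heavy
  sessions, and the utility raises wealth to a fractional power α. We use
  the signed power sign(x)·|x|^α: odd, monotone in wealth, and identical to
  the plain power for x ≥ 0 (the regime of the canonical example). This is
  a design choice the source model leaves open.
- **No temperature.** z = u(avoid) − u(rush) enters the sigmoid raw. Since
  utilities scale with cumulative wealth (endowment 20,000 by default), z
  routinely saturates the sigmoid; probabilities are clamped to the open
  interval (0, 1) at float resolution so the Bernoulli draw never becomes
  literally impossible by rounding.

### Parameters

| name  | meaning                               | bounds      | default |
|-------|---------------------------------------|-------------|---------|
| α     | convexity of utility in wealth        | 0 < α ≤ 1   | preset  |
| β     | intrinsic benevolence (kindness units)| unbounded   | preset  |
| γ     | fairness retention per trial          | 0 ≤ γ ≤ 1   | preset  |
| θ     | weight on opponent's fairness         | 0 ≤ θ ≤ 1   | preset  |
| η     | ledger learning rate                  | η > 0       | 5/6     |

η = 5/6 makes one kindness step of 0.6 move the ledger by exactly 0.5. The
two presets, `mutual_exchange` (0.986, 0.069, 0.110, 0.710) and `rush`
(0.863, −0.739, 0.673, 0.696), are the published optimized configurations
for the two target behavioral styles. With γ < 1 the ledger is bounded:
|F_i| ≤ ηK/(1−γ) and |F_j| ≤ (ηK+|β|)/(1−γ) with K = 0.6 the kindness
extreme — asserted in tests after 10,000 adversarial updates.

## Sessions, phases, state

A session is an ordered list of phases (length + parameter set). The
reference design is 50/50/50 trials with presets exchange → rush → exchange,
endowment 20,000 for both players. At a phase boundary the agent's
*parameters* are swapped; the fairness ledger and both cumulative scores
persist, while the analysis window restarts. The persistence choice is a
documented assumption: only the parameters are described as changing, and
resetting the ledger would discontinuously erase the relationship history
the model is about. The endowment is included in the Σπ terms of the
utility (configurable), since the canonical example's "sum of reward =
1,000" is reproducible by setting the endowment accordingly.

Moves are simultaneous: the engine collects both decisions before either
player observes anything (verified by counterfactual replay — changing the
opponent's trial-k action cannot change any p(avoid) up to trial k). Agent
and opponent draw from independent streams spawned from the session seed,
so either side is replayable in isolation. The first trial's probability is
computed from the zero ledger (r = 0), not hard-coded.

Interactive play (`fairgame play`) keeps the 3-second response window of
the original task in text form: typing the avoid key within the window
records an avoid with its decision time; anything else is a rush with the
decision time absent. The animated graphical display of the original task
is not reproduced.

## Pattern classification

Windows of 3 consecutive joint outcomes (step 1, restarted per phase) are
labeled by the consecutive pairs they contain: (AA,AA) defines *mutual
avoid*, (RR,RR) *mutual rush*, (AR,RA)/(RA,AR) *exchange*, (AR,AR)/(RA,RA)
*unfair*. A window is labeled P iff it contains a defining pair for P and
for no other pattern — ambiguous windows are *undefined*, not resolved by
precedence — and a mutual-avoid (mutual-rush) window is additionally voided
by any RR (AA) row. The verbal definitions the rule reconstructs
("exchanged avoid/rush over at least two iterations", "kept rushing … over
at least two iterations") do not pin these tie-breaks down; this rule is
the unique player-symmetric choice we found whose exact expectations match
the published random-play means for three of the four patterns, and it is
the hard default (`classify_window` is a plain function, so alternative
rules can be swapped in for research use).

Brute-force enumeration of all 64 windows gives exact per-window label
probabilities under iid uniform play: 5/64 mutual avoid, 5/64 mutual rush,
10/64 exchange, 10/64 unfair, 34/64 undefined — expected counts 3.75 /
3.75 / 7.5 / 7.5 per 48 windows. The published random-play means are
3.7 / 3.8 / 7.5 / **6.7**: the first three agree with the symmetric
expectations to within Monte-Carlo noise, but the unfair mean corresponds
to 9/64 and is inconsistent with every player-symmetric rule we considered
(any such rule must count (AR,AR) and (RA,RA) histories identically, and
6.7 would require them not to be). The unfair category is therefore
excluded from numeric validation; this remains an open discrepancy.

Score analysis: the trace is the running sum from the endowment, and the
per-phase slope is (last − first score of the phase) / phase length — the
divisor is the full phase length (50), not the number of differences (49),
matching the published definition, so 50 consecutive crashes give
−1000·49/50 = −980 points/iteration.

## Monte-Carlo validation and the synthetic generator

`fairgame.synth.random_session` draws iid Bernoulli actions per player per
trial (p(avoid) = 0.5 each by default) — the random-play null used to check
that 3-trial windowing does not under-count multi-trial patterns.
`run_montecarlo` repeats this 10,000 × 50 trials (the reference design),
counts patterns per replicate via the same 64-entry lookup table that backs
`count_patterns`, and reports per-label means and SDs. Replicate seeds are
spawned from the master seed by a fixed counter scheme, so results are
independent of batching. What this emulates is memoryless play only: it
validates the *counting machinery*, not the agent, and says nothing about
serially correlated human behavior.

## Numerical choices and problem sizes

- Sigmoid via `scipy.special.expit` (no overflow), clamped to (0, 1) open.
- Per-replicate counting is vectorized through the label lookup table; the
  full 10,000-replicate validation runs in under a second.
- Test problem sizes: 64-window exhaustive enumeration (exact), 10,000
  ledger updates for boundedness, 100,000 draws for Bernoulli frequency
  checks, 20 seeded 200-trial sessions for the preset-direction property.
- Session CSV round-trips use `float_precision="round_trip"` on read so
  logged probabilities survive bit-exactly.

## Limitations

- The two printed reference utilities cannot be regenerated (see above);
  any analysis depending on absolute utility scales should treat them as
  model-internal quantities.
- The unfair-pattern expectation disagrees with the published random-play
  mean; comparisons on that category are not supported.
- No inferential statistics on human cohorts are included: the per-phase
  count and slope tables are designed to feed external stats tools.
- Sigmoid saturation at realistic endowments makes the agent nearly
  deterministic once |z| exceeds ~40; this is faithful to the raw-difference
  choice rule, not a numerical artifact.
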