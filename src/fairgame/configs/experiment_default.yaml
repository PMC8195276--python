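# Reference three-phase experiment design: the agent plays to exchange
# rewards for 50 trials, switches to consistent rushing for 50, then back to
# exchange for the final 50.  Both players start with a 20,000-point
# endowment; the opponent slot defaults to iid random play (replace with
# {kind: fairness_agent, params: <preset>} for self-play).
matrix: chicken_default
endowment: 20000
seed: 0
opponent:
  kind: random_bernoulli
  p: 0.5
phases:
  - n_iterations: 50
    preset: mutual_exchange
  - n_iterations: 50
    preset: rush
  - n_iterations: 50
    preset: mutual_exchange
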