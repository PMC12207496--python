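# cooptom

Evolution of cooperation with a recursive Bayesian theory of mind.

Classic accounts of reciprocity rest on behavioral automata (tit-for-tat,
win-stay-lose-shift, ...) that are hard-wired to a single repeated game.
Human cooperation is more general: we decide from the payoffs of each new
situation, we infer the *motives* behind other people's actions, and we
cooperate conditionally with those we judge to be cooperators.  `cooptom`
implements a computational model of that capacity — the **Bayesian
Reciprocator** — together with the environments and evolutionary machinery
needed to study when it can evolve.  It is aimed at researchers in
evolutionary game theory, social cognition and multi-agent systems.

## The model

A game `G` is a set of actions `a` with a payoff `R_i(a)` for every player.
Utility-based players pick the action with the highest (expected) subjective
utility, ties broken at random:

    a* = argmax_{a in G} U_i(a)                                   (action)

The Bayesian Reciprocator's utility weights every other player's payoff by
the belief that that player shares its own utility function:

    U_i = R_i + Σ_{j≠i} R_j · B_ij(U_j = U_i)                     (utility)

With `B → 1` it treats the other as itself (Altruistic behavior); with
`B → 0` it is Selfish.  Beliefs are updated by Bayes' rule from observed
actions,

    B_ij^t(U | a_j^t, G^t) ∝ P(a_j^t | U_j, G^t, B_{j∩i}^t) · B_ij^{t-1}

where the likelihood gives mass `1 − ε` to the action the hypothesized type
would choose and `ε/|G|` to every other action (`ε` is the trembling-hand
rate; only executed actions are observable).  The recursion — the actor's
own beliefs — is resolved with the *common knowledge* of each observer
subset: because the common observations of `{i, j}` are one object,
`B_{j∩i} = B_{i∩j}`, and no infinite belief hierarchy is needed.  Beliefs
start from a same-type prior of 0.5 with the remainder spread over the
other types in the tournament.

The package provides:

* `cooptom.game_generator` — a generative process over unique
  resource-transfer games (Poisson costs, Exponential benefits, Poisson
  option counts, shuffled unlabeled actions) plus per-generation matching;
* `cooptom.agents` — Selfish, Altruistic and Bayesian Reciprocator players
  and all memory-1 IPD automata (AllD, AllC, TFT, GTFT, WSLS, Forgiver,
  Extort2, and the 16 deterministic strategies);
* `cooptom.btom` — the recursive belief engine (observer-subset tables,
  likelihoods, Bayes updates, perception error);
* `cooptom.ipd` — simultaneous and sequential donation-game IPD bridging
  automata and utility-based agents;
* `cooptom.evolution` — Moran-process steady states: a composition-space
  chain with mutation, and a low-mutation pairwise-fixation chain;
* `cooptom.experiments` / `cooptom.cli` — belief-trajectory probes,
  steady-state parameter scans, result writers, and the `cooptom` command.

## Worked example

Infer a stranger's type from one observed action in the 2-player Give-Keep
game (pay 1 to deliver 3, or do nothing):

```python
import numpy as np
from cooptom import BR, SELFISH, ALTRUISTIC, give_keep_game
from cooptom.btom import BeliefBank, InteractionRecord, belief_query

bank = BeliefBank("bob", (BR, SELFISH, ALTRUISTIC))
game = give_keep_game(1, 3, "alice", "bob")
keep = next(o for o in game.options if o.is_zero)
bank.observe(InteractionRecord(game, "alice", keep,
                               frozenset(("alice", "bob"))), epsilon=0.025)
print(belief_query(bank, ("alice", "bob"), "alice").as_dict())
```

prints (names abbreviated)

```
{BayesianReciprocator: 0.025, Selfish: 0.963, Altruistic: 0.012}
```

— keeping with no provocation is strong evidence of a Selfish type, since
both of the cooperative types would have given at their prior beliefs.

In the iterated prisoner's dilemma the same agent plays without
modification; against a pure defector it pays one exploratory cost and then
withholds:

```python
from cooptom.agents import ALLD
from cooptom.ipd import IPDConfig, play_ipd_match

cfg = IPDConfig(benefit=3, cost=1, game_length=20, epsilon=0.0)
pa, pb, hist = play_ipd_match(BR, ALLD, cfg, np.random.default_rng(0))
print(hist.rounds[:4], pa, pb)
# [('C', 'D'), ('D', 'D'), ('D', 'D'), ('D', 'D')] -1.0 3.0
```

Steady states from the shell, e.g. the repeated private environment:

```
cooptom evolve --env gg --types br,selfish,altruistic --n 10 \
    --delta 0.001 --s 2 --game-length 9 --epsilon 0.025 --b 5 --c 1 \
    --reps 20 --seed 7 --out steady.json
```

reports per-type steady-state abundances, the stationary vector over the 66
population compositions, and the estimated payoff table.

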