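"""Iterated prisoner's dilemma (donation-game form) for automata and
utility-based agents.

Each round, cooperation means paying a cost ``c`` so the partner gains a
benefit ``b`` (``b > c > 0``); defection transfers nothing.  In the
*simultaneous* variant both players commit before either action is revealed;
in the *sequential* variant actions are visible as soon as they are made and
the mover order alternates between rounds.  Rounds are subject to the same
trembling hand as every other game: with probability ``eps`` the realized
action is the opposite of the intended one.

The Bayesian Reciprocator plays the IPD without modification: every round
is cast as a two-option transfer game, automata in the tournament roster are
hypotheses in its prior, and beliefs update at the variant's reveal times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .agents import (ALLC, ALLD, BR, COOPERATE, DEFECT, EXTORT2, FORGIVER,
                     GTFT, TFT, WSLS, BayesianReciprocator, Memory1Strategy,
                     PlayerType, apply_tremble, choose_action,
                     memory1_action, subjective_utility)
from .btom import BeliefBank, InteractionRecord, PriorView, \
    predict_action_distribution
from .game_generator import Game, PayoffOption

__all__ = [
    "IPDConfig", "IPDHistory", "AUTOMATA_ROSTER",
    "play_ipd_match", "br_ipd_policy", "cooperation_rate",
]

AUTOMATA_ROSTER = (ALLD, ALLC, TFT, GTFT, WSLS, FORGIVER, EXTORT2)


@dataclass(frozen=True)
class IPDConfig:
    """Donation-game IPD parameters."""

    benefit: float = 3.0
    cost: float = 1.0
    game_length: int = 50
    epsilon: float = 0.0
    variant: str = "simultaneous"  # or "sequential"

    def __post_init__(self):
        if not self.benefit > self.cost > 0:
            raise ValueError("need benefit > cost > 0 for a dilemma")
        if self.game_length < 1:
            raise ValueError("game_length must be >= 1")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must lie in [0, 1]")
        if self.variant not in ("simultaneous", "sequential"):
            raise ValueError("variant must be simultaneous or sequential")


@dataclass
class IPDHistory:
    """Realized joint actions and running payoff totals of one match."""

    rounds: list = field(default_factory=list)  # [(action_A, action_B), ...]
    payoff_A: float = 0.0
    payoff_B: float = 0.0


def _donation_round(config: IPDConfig, donor, receiver) -> Game:
    """One player's half of an IPD round as a two-option transfer game.
    Option 0 = cooperate (pay c, deliver b), option 1 = defect (nothing)."""
    return Game(
        participants=(donor, receiver),
        deciders=(donor,),
        options=[
            PayoffOption(label=0, payoffs=(-config.cost, config.benefit)),
            PayoffOption(label=1, payoffs=(0.0, 0.0)),
        ],
    )


def br_ipd_policy(bank: BeliefBank, config: IPDConfig, game: Game,
                  rng: np.random.Generator) -> PayoffOption:
    """The Bayesian Reciprocator's intended move for one IPD round.

    Sequential play maximizes the reciprocal utility directly.  Simultaneous
    play maximizes *expected* utility, marginalizing the opponent's action
    over the posterior-weighted predictions of every hypothesis type; in the
    additive donation game this coincides with the direct rule, but the
    marginalization is carried out in full.
    """
    me = game.deciders[0]
    other = next(p for p in game.participants if p != me)
    beliefs = bank.decision_beliefs(game)
    if config.variant == "sequential":
        return choose_action(bank.br_type, game, rng, beliefs=beliefs)

    # predicted opponent action distribution under the common view
    opp_game = _donation_round(config, other, me)
    key = frozenset((me, other))
    cover = bank._smallest_covering(key)
    view = bank.tables[cover] if cover is not None \
        else PriorView(bank.prior_same_type)
    posterior = bank.tables[frozenset((me,))].dists.get(other,
                                                        bank.prior.probs)
    opp_coop = 0.0
    for w, hyp in zip(posterior, bank.roster):
        if w == 0.0:
            continue
        dist = predict_action_distribution(hyp, opp_game, view,
                                           config.epsilon, actor=other)
        opp_coop += w * dist[0]
    # expected utility of each own option over the opponent's action
    utils = []
    for opt in game.options:
        u = 0.0
        for p_opp, opp_opt in ((opp_coop, opp_game.options[0]),
                               (1.0 - opp_coop, opp_game.options[1])):
            if p_opp == 0.0:
                continue
            joint = (opt.payoffs[0] + opp_opt.payoffs[1],
                     opt.payoffs[1] + opp_opt.payoffs[0])
            u += p_opp * subjective_utility(bank.br_type, beliefs, joint, 0)
        utils.append(u)
    best = max(utils)
    ties = [i for i, u in enumerate(utils) if u >= best - 1e-12]
    pick = ties[0] if len(ties) == 1 else ties[rng.integers(len(ties))]
    return game.options[pick]


def _intended_move(ptype, bank, config, game, last_own, last_opp, rng):
    if isinstance(ptype, Memory1Strategy):
        move = memory1_action(ptype, last_own, last_opp, rng)
        return game.options[0] if move == COOPERATE else game.options[1]
    if isinstance(ptype, BayesianReciprocator):
        return br_ipd_policy(bank, config, game, rng)
    beliefs = bank.decision_beliefs(game) if bank is not None else None
    return choose_action(ptype, game, rng, beliefs=beliefs)


def play_ipd_match(type_A: PlayerType, type_B: PlayerType,
                   config: IPDConfig, rng: np.random.Generator,
                   roster=None):
    """Play one match of ``game_length`` rounds; returns
    ``(payoff_A, payoff_B, history)``.

    ``roster`` is the hypothesis space handed to any Bayesian Reciprocator
    in the match (defaults to the reciprocator plus the seven named
    automata).  Memory-1 players condition on their own last realized action
    and the opponent's most recently *observed* action, so in the sequential
    variant the second mover reacts to the current round's first move.
    """
    ids = ("A", "B")
    types = {"A": type_A, "B": type_B}
    banks = {}
    for pid in ids:
        if isinstance(types[pid], BayesianReciprocator):
            if roster is None:
                roster = (BR,) + AUTOMATA_ROSTER
            banks[pid] = BeliefBank(pid, roster, br_type=types[pid])
    games = {"A": _donation_round(config, "A", "B"),
             "B": _donation_round(config, "B", "A")}
    last = {"A": None, "B": None}  # last realized/observed action per player
    history = IPDHistory()
    observers = frozenset(ids)

    for rnd in range(config.game_length):
        if config.variant == "simultaneous":
            realized = {}
            for pid, opp in (("A", "B"), ("B", "A")):
                intended = _intended_move(types[pid], banks.get(pid), config,
                                          games[pid], last[pid], last[opp],
                                          rng)
                realized[pid] = apply_tremble(intended, games[pid],
                                              config.epsilon, rng)
            records = [InteractionRecord(games[pid], pid, realized[pid],
                                         observers) for pid in ids]
            for bank in banks.values():
                bank.observe_simultaneous(records, config.epsilon)
            moves = {pid: DEFECT if realized[pid].is_zero else COOPERATE
                     for pid in ids}
            last.update(moves)
        else:  # sequential, alternating first mover
            order = ids if rnd % 2 == 0 else ids[::-1]
            moves = {}
            realized = {}
            for pid in order:
                opp = "B" if pid == "A" else "A"
                intended = _intended_move(types[pid], banks.get(pid), config,
                                          games[pid], last[pid], last[opp],
                                          rng)
                realized[pid] = apply_tremble(intended, games[pid],
                                              config.epsilon, rng)
                record = InteractionRecord(games[pid], pid, realized[pid],
                                           observers)
                for bank in banks.values():
                    bank.observe(record, config.epsilon)
                moves[pid] = DEFECT if realized[pid].is_zero else COOPERATE
                last[pid] = moves[pid]

        for pid, opp in (("A", "B"), ("B", "A")):
            if moves[pid] == COOPERATE:
                if pid == "A":
                    history.payoff_A -= config.cost
                    history.payoff_B += config.benefit
                else:
                    history.payoff_B -= config.cost
                    history.payoff_A += config.benefit
        history.rounds.append((moves["A"], moves["B"]))

    return history.payoff_A, history.payoff_B, history


def cooperation_rate(history: IPDHistory) -> dict:
    """Fraction of realized actions that are cooperate, per player and
    jointly."""
    if not history.rounds:
        raise ValueError("history is empty")
    n = len(history.rounds)
    coop_a = sum(1 for a, _ in history.rounds if a == COOPERATE)
    coop_b = sum(1 for _, b in history.rounds if b == COOPERATE)
    return {"A": coop_a / n, "B": coop_b / n,
            "joint": (coop_a + coop_b) / (2 * n)}
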