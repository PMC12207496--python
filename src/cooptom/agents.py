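"""Player types: utility-based agents and memory-1 automata.

Utility-based players choose the option with the highest subjective utility
(ties broken uniformly at random) and then execute it through a trembling
hand.  Three utility functions are studied:

* Selfish          ``U_i = R_i``
* Altruistic       ``U_i = R_i + sum_j R_j``
* Bayesian Reciprocator
                   ``U_i = R_i + sum_j R_j * B_ij(U_j = U_i)``

where ``B_ij(U_j = U_i)`` is i's posterior belief that j shares i's utility
function.  With beliefs at 1 the Bayesian Reciprocator is behaviourally
Altruistic; with beliefs at 0 it is Selfish.

Memory-1 automata are strategies for the two-action iterated prisoner's
dilemma, defined by cooperation probabilities conditioned on the previous
round's joint action, ``(p_cc, p_cd, p_dc, p_dd)``, plus a first move.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PlayerType", "Selfish", "Altruistic", "BayesianReciprocator",
    "Memory1Strategy", "Player",
    "SELFISH", "ALTRUISTIC", "BR",
    "ALLD", "ALLC", "TFT", "GTFT", "WSLS", "FORGIVER", "EXTORT2",
    "COOPERATE", "DEFECT",
    "subjective_utility", "choose_action", "apply_tremble",
    "memory1_action", "enumerate_deterministic_memory1",
    "STRATEGY_REGISTRY", "resolve_type",
]

COOPERATE = "C"
DEFECT = "D"


@dataclass(frozen=True, slots=True)
class PlayerType:
    """Base marker; concrete types below are hashable and usable as
    hypothesis-space elements."""

    name: str = "type"

    @property
    def is_utility_based(self) -> bool:
        return True

    def __str__(self):  # pragma: no cover - cosmetic
        return self.name


@dataclass(frozen=True, slots=True)
class Selfish(PlayerType):
    name: str = "Selfish"


@dataclass(frozen=True, slots=True)
class Altruistic(PlayerType):
    name: str = "Altruistic"


@dataclass(frozen=True, slots=True)
class BayesianReciprocator(PlayerType):
    """Conditional cooperator; decision-making needs a belief bank."""

    name: str = "BayesianReciprocator"
    prior_same_type: float = 0.5


@dataclass(frozen=True, slots=True)
class Memory1Strategy(PlayerType):
    """IPD strategy (p_cc, p_cd, p_dc, p_dd) with an explicit first move."""

    name: str = "m1"
    p_cc: float = 0.0
    p_cd: float = 0.0
    p_dc: float = 0.0
    p_dd: float = 0.0
    first_move: str = DEFECT

    def __post_init__(self):
        for p in (self.p_cc, self.p_cd, self.p_dc, self.p_dd):
            if not 0.0 <= p <= 1.0:
                raise ValueError("memory-1 entries must lie in [0, 1]")
        if self.first_move not in (COOPERATE, DEFECT):
            raise ValueError("first_move must be 'C' or 'D'")

    @property
    def is_utility_based(self) -> bool:
        return False

    @property
    def vector(self):
        return (self.p_cc, self.p_cd, self.p_dc, self.p_dd)

    def cooperate_probability(self, last_own, last_opp) -> float:
        """Cooperation probability given the conditioning pair of actions;
        ``None`` history means the first move."""
        if last_own is None or last_opp is None:
            return 1.0 if self.first_move == COOPERATE else 0.0
        idx = {( COOPERATE, COOPERATE): self.p_cc,
               (COOPERATE, DEFECT): self.p_cd,
               (DEFECT, COOPERATE): self.p_dc,
               (DEFECT, DEFECT): self.p_dd}
        return idx[(last_own, last_opp)]


SELFISH = Selfish()
ALTRUISTIC = Altruistic()
BR = BayesianReciprocator()

ALLD = Memory1Strategy("AllD", 0, 0, 0, 0, DEFECT)
ALLC = Memory1Strategy("AllC", 1, 1, 1, 1, COOPERATE)
TFT = Memory1Strategy("TFT", 1, 0, 1, 0, COOPERATE)
GTFT = Memory1Strategy("GTFT", 1, 0.66, 1, 0.66, COOPERATE)
WSLS = Memory1Strategy("WSLS", 1, 0, 0, 1, COOPERATE)
FORGIVER = Memory1Strategy("Forgiver", 1, 0, 1, 1, COOPERATE)
EXTORT2 = Memory1Strategy("Extort2", 0.85, 0.5, 0.35, 0, DEFECT)


@dataclass(slots=True)
class Player:
    """A concrete participant: an id, a type, an optional belief bank
    (Bayesian Reciprocators only) and a running cumulative payoff."""

    id: object
    type: PlayerType
    bank: object = None
    cumulative_payoff: float = 0.0


def subjective_utility(player_type: PlayerType, beliefs, payoffs,
                       self_index: int) -> float:
    """Subjective value of a payoff vector to ``player_type``.

    ``beliefs`` maps participant position -> probability that the player in
    that position shares the evaluator's type; it is consulted only by the
    Bayesian Reciprocator, and only for positions with nonzero payoff.
    """
    r_self = payoffs[self_index]
    if isinstance(player_type, Selfish):
        return r_self
    if isinstance(player_type, Altruistic):
        return r_self + sum(p for i, p in enumerate(payoffs)
                            if i != self_index)
    if isinstance(player_type, BayesianReciprocator):
        total = r_self
        for i, p in enumerate(payoffs):
            if i == self_index or p == 0:
                continue
            if beliefs is None or i not in beliefs:
                raise ValueError(
                    f"missing same-type belief for affected participant {i}")
            total += p * beliefs[i]
        return total
    raise TypeError(f"{player_type} has no subjective utility")


def _argmax_ties(utilities, tol=1e-12):
    best = max(utilities)
    return [i for i, u in enumerate(utilities) if u >= best - tol]


def choose_action(player_type: PlayerType, game, rng: np.random.Generator,
                  beliefs=None, decider=None):
    """Eq.-1 action selection: maximize subjective utility, ties uniform.

    ``decider`` defaults to the game's single decider.  Returns the intended
    :class:`~cooptom.game_generator.PayoffOption`.
    """
    if game.n_options == 0:
        raise ValueError("game has no options")
    if decider is None:
        decider = game.deciders[0]
    self_idx = game.index_of(decider)
    utils = [subjective_utility(player_type, beliefs, opt.payoffs, self_idx)
             for opt in game.options]
    ties = _argmax_ties(utils)
    pick = ties[0] if len(ties) == 1 else ties[rng.integers(len(ties))]
    return game.options[pick]


def apply_tremble(intended, game, epsilon: float, rng: np.random.Generator):
    """Trembling hand: with probability ``epsilon`` a uniformly drawn *other*
    option is executed.  With a single option there is no alternative."""
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError("epsilon must lie in [0, 1]")
    n = game.n_options
    if n <= 1 or epsilon == 0.0 or rng.random() >= epsilon:
        return intended
    others = [opt for opt in game.options if opt is not intended]
    return others[rng.integers(len(others))]


def memory1_action(strategy: Memory1Strategy, last_own, last_opp,
                   rng: np.random.Generator) -> str:
    """Sample the automaton's move given the conditioning actions."""
    p = strategy.cooperate_probability(last_own, last_opp)
    if p >= 1.0:
        return COOPERATE
    if p <= 0.0:
        return DEFECT
    return COOPERATE if rng.random() < p else DEFECT


def enumerate_deterministic_memory1():
    """All 16 deterministic memory-1 strategies.

    First-move convention: cooperate iff ``p_cc == 1`` (so TFT, WSLS, AllC
    and Forgiver open cooperatively, AllD-like strategies open defecting).
    """
    out = []
    for bits in range(16):
        v = [(bits >> (3 - i)) & 1 for i in range(4)]
        fm = COOPERATE if v[0] == 1 else DEFECT
        out.append(Memory1Strategy(f"m1-{v[0]}{v[1]}{v[2]}{v[3]}",
                                   *[float(x) for x in v], fm))
    return out


STRATEGY_REGISTRY = {
    "alld": ALLD, "allc": ALLC, "tft": TFT, "gtft": GTFT, "wsls": WSLS,
    "forgiver": FORGIVER, "extort2": EXTORT2,
    "selfish": SELFISH, "altruistic": ALTRUISTIC, "br": BR,
}


def resolve_type(name: str) -> PlayerType:
    """Look up a type by registry name, or parse ``m1:pcc,pcd,pdc,pdd[:c|d]``."""
    key = name.strip().lower()
    if key in STRATEGY_REGISTRY:
        return STRATEGY_REGISTRY[key]
    if key.startswith("m1:"):
        parts = key.split(":")
        probs = [float(x) for x in parts[1].split(",")]
        if len(probs) != 4:
            raise ValueError("memory-1 spec needs four probabilities")
        fm = COOPERATE
        if len(parts) > 2:
            fm = COOPERATE if parts[2] == "c" else DEFECT
        elif probs[0] < 1.0:
            fm = DEFECT
        return Memory1Strategy(f"m1:{parts[1]}", *probs, fm)
    raise KeyError(f"unknown player type {name!r}")
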