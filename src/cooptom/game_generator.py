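"""Generative resource-allocation games and per-generation match scheduling.

The game sampler produces one-decider transfer games from a probabilistic
template: a Poisson number of cost-benefit "choice types", each with a
Poisson-distributed cost ``c`` and an Exponential-distributed benefit ``b``.
For every choice type and every potential receiver, the decider may pay ``c``
so that the receiver gains ``c + b``; a do-nothing option (all payoffs zero)
is always available.  Because benefits are continuous, no two sampled games
are ever identical, and options carry no semantic labels -- their order is
shuffled so agents must reason from payoffs alone.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GeneratorParams",
    "PayoffOption",
    "Game",
    "MatchSchedule",
    "sample_game",
    "give_keep_game",
    "sample_match_schedule",
]


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the game-sampling process and the interaction regime.

    Parameters
    ----------
    mean_cost : float
        Mean of the Poisson cost distribution (``C``); costs are sometimes 0.
    mean_benefit : float
        Mean of the Exponential benefit distribution (``B``); strictly > 0,
        so a receiver's gain ``c + b`` always exceeds the decider's cost.
    mean_choice_types : float
        Mean of the Poisson count of cost-benefit choice types per game.
    player_counts : dict[int, float]
        Support of the group-size distribution, size -> probability.
    epsilon : float
        Action-error ("trembling hand") probability: with probability
        ``epsilon`` a uniformly drawn *other* option is executed instead of
        the intended one.  Only the executed action is observable.
    omega : float
        Probability that an interaction is observed by the whole population
        rather than only by its participants.
    perception_error : float
        Probability that a non-acting observer privately misperceives the
        executed option (drawn uniformly among the other options).
    game_length : int
        Number of games each matched group plays together per generation.
    seed : int or None
        Convenience seed recorded with configurations.
    """

    mean_cost: float = 1.0
    mean_benefit: float = 5.0
    mean_choice_types: float = 2.0
    player_counts: dict = field(default_factory=lambda: {2: 0.5, 3: 0.5})
    epsilon: float = 0.025
    omega: float = 0.0
    perception_error: float = 0.0
    game_length: int = 1
    seed: int | None = None

    def __post_init__(self):
        if self.mean_cost < 0:
            raise ValueError("mean_cost must be nonnegative")
        if self.mean_benefit <= 0:
            raise ValueError("mean_benefit must be positive")
        if self.mean_choice_types <= 0:
            raise ValueError("mean_choice_types must be positive")
        if self.game_length < 1:
            raise ValueError("game_length must be >= 1")
        for p in (self.epsilon, self.omega, self.perception_error):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if not self.player_counts:
            raise ValueError("player_counts support must be nonempty")
        total = sum(self.player_counts.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("player_counts probabilities must sum to 1")
        if any(k < 2 for k in self.player_counts):
            raise ValueError("group sizes must be >= 2")


@dataclass(frozen=True, slots=True)
class PayoffOption:
    """One selectable option: an opaque label and a payoff per participant."""

    label: int
    payoffs: tuple

    @property
    def is_zero(self) -> bool:
        return all(x == 0 for x in self.payoffs)


@dataclass(slots=True)
class Game:
    """A one-decider (or simultaneous two-decider) choice problem.

    ``payoffs`` in each option are indexed by position in ``participants``.
    """

    participants: tuple
    deciders: tuple
    options: list
    mode: str = "single_decider"  # or "simultaneous"

    @property
    def n_options(self) -> int:
        return len(self.options)

    def index_of(self, player) -> int:
        return self.participants.index(player)

    def zero_option(self) -> PayoffOption:
        for opt in self.options:
            if opt.is_zero:
                return opt
        raise ValueError("game has no all-zero option")

    def to_record(self) -> dict:
        """JSON-serializable form for fixtures and regression logs."""
        return {
            "participants": list(self.participants),
            "deciders": list(self.deciders),
            "mode": self.mode,
            "options": [list(opt.payoffs) for opt in self.options],
        }


@dataclass(slots=True)
class MatchSchedule:
    """Groups to be matched for one generation, each playing
    ``interactions_per_group`` sampled games."""

    groups: list
    interactions_per_group: int


def sample_game(params: GeneratorParams, group, rng: np.random.Generator,
                decider=None) -> Game:
    """Draw one game for ``group`` from the generative template.

    A decider is chosen uniformly from the group (or forced via ``decider``
    so repeated matches can rotate it).  ``k ~ Poisson(mean_choice_types)``
    cost-benefit types are drawn, each with ``c ~ Poisson(mean_cost)`` and
    ``b ~ Exponential(mean_benefit)``; for every type and every non-decider
    there is an option where the decider pays ``c`` and that receiver gains
    ``c + b``.  A do-nothing option is appended and the order is shuffled.
    """
    group = tuple(group)
    if len(group) == 0:
        raise ValueError("group must be nonempty")
    if len(group) not in params.player_counts:
        raise ValueError(
            f"group size {len(group)} outside player_counts support "
            f"{sorted(params.player_counts)}"
        )
    if decider is None:
        decider = group[rng.integers(len(group))]
    elif decider not in group:
        raise ValueError("forced decider must belong to the group")
    dec_idx = group.index(decider)

    k = int(rng.poisson(params.mean_choice_types))
    payoff_rows = []
    costs = rng.poisson(params.mean_cost, k) if k else ()
    benefits = rng.exponential(params.mean_benefit, k) if k else ()
    for c, b in zip(costs, benefits):
        c = float(c)
        b = float(b)
        for r_idx in range(len(group)):
            if r_idx == dec_idx:
                continue
            payoffs = [0.0] * len(group)
            payoffs[dec_idx] = -c
            payoffs[r_idx] = c + b
            payoff_rows.append(tuple(payoffs))
    payoff_rows.append(tuple([0.0] * len(group)))  # "Pay 0"

    order = rng.permutation(len(payoff_rows))
    options = [PayoffOption(label=i, payoffs=payoff_rows[j])
               for i, j in enumerate(order)]
    return Game(participants=group, deciders=(decider,), options=options)


def give_keep_game(cost: float, benefit: float, donor, receiver) -> Game:
    """The two-option worked example: give = (-cost, +benefit), keep = (0, 0).

    Requires ``benefit > cost >= 0`` so that giving creates a genuine
    cooperation dilemma (the transfer enlarges the pie).
    """
    if cost < 0:
        raise ValueError("cost must be nonnegative")
    if benefit <= cost:
        raise ValueError("benefit must exceed cost for a cooperation dilemma")
    options = [
        PayoffOption(label=0, payoffs=(-float(cost), float(benefit))),
        PayoffOption(label=1, payoffs=(0.0, 0.0)),
    ]
    return Game(participants=(donor, receiver), deciders=(donor,),
                options=options)


def sample_match_schedule(population, params: GeneratorParams,
                          rng: np.random.Generator) -> MatchSchedule:
    """Build one generation's matching.

    Every unordered pair of living players is matched exactly once (in a
    shuffled order), so all players face a comparable number of interactions.
    When the group-size support puts mass on sizes above two, each scheduled
    pair is independently upgraded to that size by adjoining uniformly drawn
    additional players.  Each group then plays ``game_length`` sampled games.
    """
    population = list(population)
    if not population:
        raise ValueError("population must be nonempty")
    sizes = sorted(params.player_counts)
    if len(population) < sizes[0]:
        raise ValueError("population smaller than the smallest group size")
    size_vals = np.array(sizes)
    size_probs = np.array([params.player_counts[s] for s in sizes])

    pairs = list(itertools.combinations(population, 2))
    order = rng.permutation(len(pairs))
    groups = []
    for idx in order:
        pair = pairs[idx]
        size = int(size_vals[rng.choice(len(size_vals), p=size_probs)]) \
            if len(size_vals) > 1 else int(size_vals[0])
        group = list(pair)
        if size > 2:
            others = [p for p in population if p not in pair]
            if len(others) >= size - 2:
                extra = rng.choice(len(others), size=size - 2, replace=False)
                group.extend(others[i] for i in np.atleast_1d(extra))
            # else: population too small for the upgrade; keep the pair
        groups.append(tuple(group))
    return MatchSchedule(groups=groups,
                         interactions_per_group=params.game_length)
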