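"""Recursive Bayesian theory of mind over common-knowledge observer subsets.

A Bayesian Reciprocator infers the latent player type (utility function or
automaton) behind observed actions.  Beliefs are kept per *observer subset*:
the set of players who all witnessed a given interaction.  Because the
common knowledge of {i, j} is the same object as that of {j, i}, recursive
"i believes j believes ..." chains collapse to one shared table per subset
instead of an unbounded hierarchy.  The update is Bayes' rule,

    B_t(U | a, G)  ∝  P(a | U, G, B_common) * B_{t-1}(U),

where the likelihood of an action is 1 - eps for the option the hypothesized
type would choose (ties split uniformly) and eps/|G| for every other option,
renormalized across hypotheses.  The recursion in the likelihood -- the
actor's own beliefs about its receivers -- is resolved with the common
subset's beliefs.

Subsets are created lazily when they first occur, initialized from the
smallest tracked superset; each bank additionally keeps its owner's private
view (the singleton subset), conditioned on everything the owner perceived.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .agents import (BR, COOPERATE, DEFECT, Altruistic, BayesianReciprocator,
                     Memory1Strategy, PlayerType, Selfish)
from .game_generator import Game

__all__ = [
    "TypeDistribution", "InteractionRecord", "BeliefBank", "PriorView",
    "ImpossibleObservationError",
    "init_prior", "predict_action_distribution", "update_beliefs",
    "belief_query", "apply_perception_error",
]

_FLOOR = 1e-12


class ImpossibleObservationError(RuntimeError):
    """Raised when every hypothesis assigns zero likelihood (only possible
    with action error eps = 0)."""


class TypeDistribution:
    """A normalized probability vector over the hypothesis roster."""

    __slots__ = ("types", "probs")

    def __init__(self, types, probs, validate: bool = True):
        self.types = tuple(types)
        self.probs = list(float(p) for p in probs)
        if validate:
            if len(self.types) != len(self.probs):
                raise ValueError("types and probs must align")
            if any(p < 0 for p in self.probs):
                raise ValueError("probabilities must be nonnegative")
            if abs(sum(self.probs) - 1.0) > 1e-12:
                raise ValueError("probabilities must sum to 1")

    def __getitem__(self, ptype: PlayerType) -> float:
        return self.probs[self.types.index(ptype)]

    def as_dict(self) -> dict:
        return {t: p for t, p in zip(self.types, self.probs)}

    def __repr__(self):  # pragma: no cover - cosmetic
        inner = ", ".join(f"{t.name}: {p:.4f}"
                          for t, p in zip(self.types, self.probs))
        return f"TypeDistribution({inner})"


def init_prior(roster, prior_same_type: float = 0.5,
               br_type: PlayerType = BR) -> TypeDistribution:
    """Prior over the tournament roster: ``prior_same_type`` on the
    reciprocator's own type, remainder split equally over the others."""
    roster = tuple(roster)
    if br_type not in roster:
        raise ValueError("roster must contain the reciprocator's own type")
    others = [t for t in roster if t != br_type]
    if not others:
        raise ValueError("roster needs at least one alternative type")
    if not 0.0 <= prior_same_type <= 1.0:
        raise ValueError("prior_same_type must lie in [0, 1]")
    rest = (1.0 - prior_same_type) / len(others)
    probs = [prior_same_type if t == br_type else rest for t in roster]
    return TypeDistribution(roster, probs)


@dataclass(slots=True)
class InteractionRecord:
    """One executed action: the game, who acted, what happened, who saw it,
    and what each observer perceived (after perception error)."""

    game: Game
    actor: object
    realized: object  # PayoffOption actually executed
    observers: frozenset
    perceived: dict = field(default_factory=dict)

    def perceived_by(self, observer):
        return self.perceived.get(observer, self.realized)


def apply_perception_error(record: InteractionRecord, eta: float,
                           rng: np.random.Generator) -> InteractionRecord:
    """Each non-acting observer independently misperceives the executed
    option with probability ``eta`` (uniform over the other options).  The
    actor always perceives its own executed action correctly."""
    if not 0.0 <= eta <= 1.0:
        raise ValueError("eta must lie in [0, 1]")
    game = record.game
    if eta > 0.0 and game.n_options > 1:
        others = [o for o in game.options if o is not record.realized]
        for obs in record.observers:
            if obs == record.actor:
                continue
            if rng.random() < eta:
                record.perceived[obs] = others[rng.integers(len(others))]
    return record


class PriorView:
    """Belief view with no data: prior same-type beliefs, no history."""

    __slots__ = ("prior_same",)

    def __init__(self, prior_same: float):
        self.prior_same = prior_same

    def same_type_belief(self, target) -> float:
        return self.prior_same

    def last_action(self, target):
        return None


class _SubsetTable:
    """Beliefs (and commonly-observed memory-1 history) held by one
    observer subset about each target player."""

    __slots__ = ("dists", "last_actions", "bank")

    def __init__(self, bank):
        self.bank = bank
        self.dists = {}         # target -> list of probs (roster order)
        self.last_actions = {}  # target -> 'C' / 'D' / None

    def clone(self):
        t = _SubsetTable(self.bank)
        t.dists = {k: list(v) for k, v in self.dists.items()}
        t.last_actions = dict(self.last_actions)
        return t

    # view protocol -----------------------------------------------------
    def same_type_belief(self, target) -> float:
        d = self.dists.get(target)
        if d is None:
            return self.bank.prior_same_type
        return d[self.bank.br_index]

    def last_action(self, target):
        return self.last_actions.get(target)


def predict_action_distribution(hyp_type: PlayerType, game: Game, view,
                                epsilon: float, actor=None):
    """Probability of each option being *observed* if the actor has
    ``hyp_type``, under the printed likelihood model.

    The hypothesized type's intended choice is simulated with the view's
    (common-knowledge) beliefs and history; the intended option(s) carry
    mass ``1 - eps`` (split over exact ties) and every other option
    ``eps/|G|``.  The result is unnormalized across options by design;
    Bayes' rule renormalizes across hypotheses.
    """
    if actor is None:
        actor = game.deciders[0]
    n = game.n_options
    intended = [0.0] * n
    if isinstance(hyp_type, Memory1Strategy):
        if len(game.participants) != 2 or n != 2:
            raise ValueError("memory-1 hypotheses apply to two-player, "
                             "two-option (donation-round) games only")
        other = next(p for p in game.participants if p != actor)
        q = hyp_type.cooperate_probability(view.last_action(actor),
                                           view.last_action(other))
        for i, opt in enumerate(game.options):
            intended[i] = (1.0 - q) if opt.is_zero else q
    else:
        a_idx = game.index_of(actor)
        utils = []
        if isinstance(hyp_type, Selfish):
            for opt in game.options:
                utils.append(opt.payoffs[a_idx])
        elif isinstance(hyp_type, Altruistic):
            for opt in game.options:
                utils.append(sum(opt.payoffs))
        elif isinstance(hyp_type, BayesianReciprocator):
            for opt in game.options:
                u = opt.payoffs[a_idx]
                for i, p in enumerate(opt.payoffs):
                    if i != a_idx and p != 0.0:
                        u += p * view.same_type_belief(game.participants[i])
                utils.append(u)
        else:
            raise TypeError(f"cannot predict actions for {hyp_type}")
        best = max(utils)
        ties = [i for i, u in enumerate(utils) if u >= best - 1e-12]
        share = 1.0 / len(ties)
        for i in ties:
            intended[i] = share
    miss = epsilon / n
    return [p * (1.0 - epsilon) + (1.0 - p) * miss for p in intended]


class BeliefBank:
    """All belief tables owned by one Bayesian Reciprocator.

    ``tables`` maps canonical observer subsets (frozensets of player ids) to
    per-target type distributions.  The singleton subset ``{owner}`` -- the
    owner's private posterior over every other player, conditioned on all
    observations the owner perceived -- is created eagerly and drives the
    owner's own decisions.
    """

    def __init__(self, owner, roster, prior_same_type: float = 0.5,
                 br_type: PlayerType = BR):
        self.owner = owner
        self.roster = tuple(roster)
        self.br_type = br_type
        self.prior_same_type = float(prior_same_type)
        self.prior = init_prior(self.roster, self.prior_same_type, br_type)
        self.br_index = self.roster.index(br_type)
        self.has_memory1 = any(isinstance(t, Memory1Strategy)
                               for t in self.roster)
        self.tables = {frozenset((owner,)): _SubsetTable(self)}

    # -- subset bookkeeping ---------------------------------------------
    def _ensure_table(self, subset: frozenset) -> _SubsetTable:
        table = self.tables.get(subset)
        if table is not None:
            return table
        supersets = [k for k in self.tables if k > subset]
        if supersets:
            src = min(supersets, key=lambda k: (len(k), sorted(map(str, k))))
            table = self.tables[src].clone()
        else:
            table = _SubsetTable(self)
        self.tables[subset] = table
        return table

    def _smallest_covering(self, subset: frozenset):
        """Smallest tracked subset containing ``subset`` (deterministic
        tie-break), or None."""
        covers = [k for k in self.tables if k >= subset]
        if not covers:
            return None
        return min(covers, key=lambda k: (len(k), sorted(map(str, k))))

    # -- queries ---------------------------------------------------------
    def same_type_belief(self, target) -> float:
        """The owner's own belief that ``target`` shares its type (Eq.-2
        weight); from the private singleton view."""
        return self.tables[frozenset((self.owner,))].same_type_belief(target)

    def decision_beliefs(self, game: Game) -> dict:
        """Position-indexed same-type beliefs for every participant, ready
        for :func:`cooptom.agents.subjective_utility`."""
        return {i: self.same_type_belief(p)
                for i, p in enumerate(game.participants) if p != self.owner}

    # -- updates ----------------------------------------------------------
    def _likelihood(self, record: InteractionRecord, view, perceived_idx):
        if not self.has_memory1:
            return self._likelihood_utility(record, view, perceived_idx)
        raw = []
        for hyp in self.roster:
            dist = predict_action_distribution(hyp, record.game, view,
                                               self._epsilon, record.actor)
            raw.append(dist[perceived_idx])
        return raw

    def _likelihood_utility(self, record, view, idx):
        """Single-pass likelihoods for rosters of utility types only: the
        per-option utilities of all hypotheses are computed together and
        only the perceived option's mass is assembled."""
        game = record.game
        parts = game.participants
        a_idx = parts.index(record.actor)
        bel = [view.same_type_belief(p) if i != a_idx else 0.0
               for i, p in enumerate(parts)]
        eps = self._epsilon
        n = game.n_options
        miss = eps / n
        hit_gain = 1.0 - eps - miss  # hit prob minus miss prob
        stats = {}  # class-key -> [best, tie_count, idx_is_tie]
        keys = []
        for hyp in self.roster:
            if isinstance(hyp, Selfish):
                keys.append("s")
            elif isinstance(hyp, Altruistic):
                keys.append("a")
            elif isinstance(hyp, BayesianReciprocator):
                keys.append("b")
            else:
                raise TypeError(f"cannot predict actions for {hyp}")
        need = set(keys)
        tol = 1e-12
        for k in need:
            stats[k] = [-float("inf"), 0, False]
        for opt_i, opt in enumerate(game.options):
            pays = opt.payoffs
            r_self = pays[a_idx]
            if "s" in need:
                u = r_self
                st = stats["s"]
                if u > st[0] + tol:
                    stats["s"] = [u, 1, opt_i == idx]
                elif u >= st[0] - tol:
                    st[1] += 1
                    st[2] = st[2] or opt_i == idx
            if "a" in need or "b" in need:
                tot = r_self
                ub = r_self
                for i, p in enumerate(pays):
                    if i != a_idx and p != 0.0:
                        tot += p
                        ub += p * bel[i]
                if "a" in need:
                    st = stats["a"]
                    if tot > st[0] + tol:
                        stats["a"] = [tot, 1, opt_i == idx]
                    elif tot >= st[0] - tol:
                        st[1] += 1
                        st[2] = st[2] or opt_i == idx
                if "b" in need:
                    st = stats["b"]
                    if ub > st[0] + tol:
                        stats["b"] = [ub, 1, opt_i == idx]
                    elif ub >= st[0] - tol:
                        st[1] += 1
                        st[2] = st[2] or opt_i == idx
        like = {}
        for k in need:
            _, ties, at_idx = stats[k]
            p_int = (1.0 / ties) if at_idx else 0.0
            like[k] = miss + p_int * hit_gain
        return [like[k] for k in keys]

    def observe(self, record: InteractionRecord, epsilon: float):
        """Bayes-update every tracked subset contained in the record's
        observer set, then advance commonly-observed automata histories."""
        self._apply([record], epsilon)

    def observe_simultaneous(self, records, epsilon: float):
        """Joint update for simultaneously revealed actions: likelihoods for
        all records use pre-round hypothesis states, then states advance."""
        self._apply(list(records), epsilon)

    def _apply(self, records, epsilon: float):
        owner = self.owner
        records = [r for r in records if owner in r.observers]
        if not records:
            return
        self._epsilon = float(epsilon)
        plans = []
        for record in records:
            obs_set = frozenset(record.observers)
            self._ensure_table(obs_set)
            perceived = record.perceived_by(owner)
            p_idx = perceived.label
            targets = [k for k in self.tables if k <= obs_set]
            # Likelihoods depend only on the recursive view; cache per view.
            by_view = {}
            for key in targets:
                view_key = key if record.actor in key else \
                    self._smallest_covering(key | {record.actor})
                by_view.setdefault(view_key, []).append(key)
            for view_key, keys in by_view.items():
                view = self.tables[view_key] if view_key is not None \
                    else PriorView(self.prior_same_type)
                raw = self._likelihood(record, view, p_idx)
                plans.append((record, keys, raw, perceived))
        # apply all posterior multiplications, then advance histories
        for record, keys, raw, _ in plans:
            if max(raw) <= 0.0:
                raise ImpossibleObservationError(
                    f"action by {record.actor} has zero likelihood under "
                    f"every hypothesis")
            for key in keys:
                table = self.tables[key]
                d = table.dists.get(record.actor)
                if d is None:
                    d = list(self.prior.probs)
                post = [max(w * lk, _FLOOR) for w, lk in zip(d, raw)]
                z = sum(post)
                table.dists[record.actor] = [w / z for w in post]
        if self.has_memory1:
            for record, keys, _, perceived in plans:
                move = DEFECT if perceived.is_zero else COOPERATE
                for key in keys:
                    self.tables[key].last_actions[record.actor] = move

    # -- serialization ----------------------------------------------------
    def to_json(self) -> dict:
        out = {}
        for key, table in self.tables.items():
            skey = "|".join(sorted(str(m) for m in key))
            out[skey] = {
                str(t): {ty.name: p for ty, p in
                         zip(self.roster, probs)}
                for t, probs in table.dists.items()
            }
        return out


# -- module-level operation wrappers --------------------------------------

def update_beliefs(bank: BeliefBank, record: InteractionRecord,
                   epsilon: float) -> BeliefBank:
    """Apply one observation to ``bank`` (in place; returned for chaining)."""
    bank.observe(record, epsilon)
    return bank


def belief_query(bank: BeliefBank, subset, target) -> TypeDistribution:
    """Distribution the observer subset holds about ``target``: the tracked
    table if present, else lazily the smallest tracked superset's view, else
    the global prior."""
    key = frozenset(subset) if subset else frozenset((bank.owner,))
    cover = bank._smallest_covering(key)
    if cover is not None:
        d = bank.tables[cover].dists.get(target)
        if d is not None:
            return TypeDistribution(bank.roster, d, validate=False)
    return TypeDistribution(bank.roster, bank.prior.probs, validate=False)
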