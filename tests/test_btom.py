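"""Belief machinery: priors, likelihoods, Bayes updates, observer subsets.

The two-round oracle tests recompute posteriors with explicit hand
arithmetic (prior x printed likelihoods, renormalized) independently of the
bank's update path.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cooptom.agents import ALTRUISTIC, BR, SELFISH
from cooptom.btom import (BeliefBank, ImpossibleObservationError,
                          InteractionRecord, PriorView,
                          apply_perception_error, belief_query, init_prior,
                          predict_action_distribution, update_beliefs)
from cooptom.game_generator import GeneratorParams, give_keep_game, \
    sample_game

ROSTER3 = (BR, SELFISH, ALTRUISTIC)


def _record(game, actor, option, observers=None):
    obs = frozenset(observers if observers is not None
                    else game.participants)
    return InteractionRecord(game, actor, option, obs)


def _give(game):
    return next(o for o in game.options if not o.is_zero)


def _keep(game):
    return next(o for o in game.options if o.is_zero)


class TestPrior:
    def test_three_type_roster(self):
        d = init_prior(ROSTER3, 0.5)
        assert d.as_dict() == {BR: 0.5, SELFISH: 0.25, ALTRUISTIC: 0.25}

    def test_degenerate_prior(self):
        d = init_prior(ROSTER3, 1.0)
        assert d[BR] == 1.0 and d[SELFISH] == 0.0

    def test_two_type_roster(self):
        d = init_prior((BR, SELFISH), 0.5)
        assert d[SELFISH] == 0.5

    def test_roster_errors(self):
        with pytest.raises(ValueError):
            init_prior((SELFISH, ALTRUISTIC))  # no reciprocator type
        with pytest.raises(ValueError):
            init_prior((BR,))  # no alternatives


class TestPredictedActions:
    def test_selfish_hypothesis_keeps(self):
        g = give_keep_game(1, 3, "a", "b")
        dist = predict_action_distribution(SELFISH, g, PriorView(0.5), 0.0,
                                           "a")
        assert dist[g.options.index(_keep(g))] == 1.0

    def test_altruistic_hypothesis_gives(self):
        g = give_keep_game(1, 3, "a", "b")
        dist = predict_action_distribution(ALTRUISTIC, g, PriorView(0.5),
                                           0.0, "a")
        assert dist[g.options.index(_give(g))] == 1.0

    def test_printed_likelihood_masses(self):
        """Two options, eps = 0.025: chosen action 0.975, other eps/|G| =
        0.0125 (unnormalized by design)."""
        g = give_keep_game(1, 3, "a", "b")
        for hyp in ROSTER3:
            dist = predict_action_distribution(hyp, g, PriorView(0.5),
                                               0.025, "a")
            assert sorted(dist) == pytest.approx([0.0125, 0.975])

    def test_fast_path_matches_generic_prediction(self, rng):
        """The single-pass utility-roster likelihood equals the per-
        hypothesis prediction route."""
        params = GeneratorParams()
        bank = BeliefBank("w", ROSTER3)
        for _ in range(50):
            size = 2 if rng.random() < 0.5 else 3
            group = tuple(f"p{i}" for i in range(size - 1)) + ("w",)
            game = sample_game(params, group, rng)
            actor = game.deciders[0]
            opt = game.options[rng.integers(game.n_options)]
            rec = _record(game, actor, opt)
            view = PriorView(0.5)
            bank._epsilon = 0.05
            fast = bank._likelihood_utility(rec, view, opt.label)
            slow = [predict_action_distribution(h, game, view, 0.05,
                                                actor)[opt.label]
                    for h in ROSTER3]
            assert fast == pytest.approx(slow)


class TestPosteriorOrderings:
    """Posterior shifts after short give-keep interactions: the same action
    is interpreted differently depending on what preceded it."""

    def _bob_bank(self):
        return BeliefBank("bob", ROSTER3)

    def test_unconditional_keep_suggests_selfish(self):
        bank = self._bob_bank()
        g = give_keep_game(1, 3, "alice", "bob")
        bank.observe(_record(g, "alice", _keep(g)), 0.025)
        post = belief_query(bank, {"alice", "bob"}, "alice")
        assert post[SELFISH] > 0.25  # above its prior mass
        assert post[SELFISH] == max(post.probs)

    def test_keep_after_keep_reads_as_reciprocation(self):
        bank_a = self._bob_bank()
        g = give_keep_game(1, 3, "alice", "bob")
        bank_a.observe(_record(g, "alice", _keep(g)), 0.025)
        unconditional = belief_query(bank_a, {"alice", "bob"}, "alice")

        bank_b = self._bob_bank()
        g_bob = give_keep_game(1, 3, "bob", "alice")
        bank_b.observe(_record(g_bob, "bob", _keep(g_bob)), 0.025)
        bank_b.observe(_record(g, "alice", _keep(g)), 0.025)
        conditioned = belief_query(bank_b, {"alice", "bob"}, "alice")

        assert conditioned[SELFISH] < unconditional[SELFISH]
        assert conditioned[BR] > unconditional[BR]

    def test_give_lowers_selfish(self):
        bank = self._bob_bank()
        g = give_keep_game(1, 3, "alice", "bob")
        bank.observe(_record(g, "alice", _give(g)), 0.025)
        post = belief_query(bank, {"alice", "bob"}, "alice")
        assert post[SELFISH] < 0.25
        assert post[BR] > 0.5

    def test_give_after_keep_reads_as_altruistic(self):
        bank = self._bob_bank()
        g_bob = give_keep_game(1, 3, "bob", "alice")
        bank.observe(_record(g_bob, "bob", _keep(g_bob)), 0.025)
        g = give_keep_game(1, 3, "alice", "bob")
        bank.observe(_record(g, "alice", _give(g)), 0.025)
        post = belief_query(bank, {"alice", "bob"}, "alice")
        assert post[ALTRUISTIC] == max(post.probs)

    def test_flat_likelihood_preserves_prior(self):
        """A single-option game is uninformative about the actor."""
        from cooptom.game_generator import Game, PayoffOption
        g = Game(participants=("alice", "bob"), deciders=("alice",),
                 options=[PayoffOption(0, (0.0, 0.0))])
        bank = self._bob_bank()
        bank.observe(_record(g, "alice", g.options[0]), 0.025)
        post = belief_query(bank, {"alice", "bob"}, "alice")
        assert post.probs == pytest.approx(bank.prior.probs)


class TestTwoRoundOracle:
    """Posterior after two observed give-keep rounds equals explicit Bayes
    arithmetic over the printed likelihoods, including the recursive
    reinterpretation of the second action."""

    EPS = 0.1
    HIT, MISS = 1 - EPS, EPS / 2  # 0.9 and 0.05

    def test_same_actor_twice(self):
        prior = {"br": 0.5, "s": 0.5}
        # Reciprocator-hypothesis intends give while the common belief
        # about the receiver stays at 0.5 (-1 + 0.5*3 > 0).
        like = {"give": {"br": self.HIT, "s": self.MISS},
                "keep": {"br": self.MISS, "s": self.HIT}}
        for seq in (("give", "give"), ("give", "keep"),
                    ("keep", "give"), ("keep", "keep")):
            w = dict(prior)
            for a in seq:
                w = {k: w[k] * like[a][k] for k in w}
                z = sum(w.values())
                w = {k: v / z for k, v in w.items()}

            bank = BeliefBank("bob", (BR, SELFISH))
            g = give_keep_game(1, 3, "alice", "bob")
            for a in seq:
                opt = _give(g) if a == "give" else _keep(g)
                bank.observe(_record(g, "alice", opt), self.EPS)
            post = belief_query(bank, {"alice", "bob"}, "alice")
            assert post[BR] == pytest.approx(w["br"], abs=1e-9)
            assert post[SELFISH] == pytest.approx(w["s"], abs=1e-9)

    def test_reciprocal_reinterpretation_after_observer_acted(self):
        """After Bob keeps, keeping becomes the reciprocator-consistent
        reply: the hypothesis's intended action flips with the updated
        common belief about Bob."""
        # Bob's keep updates the pair's belief about *Bob*:
        b_bob = (0.5 * self.MISS) / (0.5 * self.MISS + 0.5 * self.HIT)
        assert b_bob < 1 / 3  # give utility -1 + 3*b < 0 -> intends keep
        like_alice = {"give": {"br": self.MISS, "s": self.MISS},
                      "keep": {"br": self.HIT, "s": self.HIT}}
        for a in ("give", "keep"):
            w = {"br": 0.5 * like_alice[a]["br"],
                 "s": 0.5 * like_alice[a]["s"]}
            z = sum(w.values())
            w = {k: v / z for k, v in w.items()}

            bank = BeliefBank("bob", (BR, SELFISH))
            g_bob = give_keep_game(1, 3, "bob", "alice")
            bank.observe(_record(g_bob, "bob", _keep(g_bob)), self.EPS)
            g = give_keep_game(1, 3, "alice", "bob")
            opt = _give(g) if a == "give" else _keep(g)
            bank.observe(_record(g, "alice", opt), self.EPS)
            post = belief_query(bank, {"alice", "bob"}, "alice")
            assert post[BR] == pytest.approx(w["br"], abs=1e-9)


class TestUpdateMechanics:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1), eps=st.floats(0.01, 0.3))
    def test_posteriors_stay_normalized(self, seed, eps):
        rng = np.random.default_rng(seed)
        params = GeneratorParams()
        bank = BeliefBank(0, ROSTER3)
        for _ in range(10):
            group = (0, 1) if rng.random() < 0.5 else (0, 1, 2)
            game = sample_game(params, group, rng)
            opt = game.options[rng.integers(game.n_options)]
            bank.observe(_record(game, game.deciders[0], opt), eps)
        for table in bank.tables.values():
            for dist in table.dists.values():
                assert min(dist) >= 0
                assert sum(dist) == pytest.approx(1.0, abs=1e-9)

    def test_subset_key_symmetry(self):
        """i-and-j and j-and-i address one stored object."""
        bank = BeliefBank("i", ROSTER3)
        g = give_keep_game(1, 3, "j", "i")
        bank.observe(_record(g, "j", _keep(g)), 0.025)
        assert frozenset(("i", "j")) in bank.tables
        a = belief_query(bank, ("i", "j"), "j")
        b = belief_query(bank, ("j", "i"), "j")
        assert a.probs == b.probs

    def test_convergence_on_selfish_partner(self):
        bank = BeliefBank("bob", ROSTER3)
        g = give_keep_game(1, 3, "alice", "bob")
        for _ in range(10):
            bank.observe(_record(g, "alice", _keep(g)), 0.025)
        assert bank.same_type_belief("alice") < 0.01
        post = belief_query(bank, {"alice", "bob"}, "alice")
        assert post[SELFISH] > 0.99

    def test_impossible_observation_without_error(self):
        bank = BeliefBank("bob", (BR, ALTRUISTIC))
        g = give_keep_game(1, 3, "alice", "bob")
        with pytest.raises(ImpossibleObservationError):
            bank.observe(_record(g, "alice", _keep(g)), 0.0)

    def test_module_level_update_wrapper(self):
        bank = BeliefBank("bob", ROSTER3)
        g = give_keep_game(1, 3, "alice", "bob")
        out = update_beliefs(bank, _record(g, "alice", _give(g)), 0.025)
        assert out is bank
        assert bank.same_type_belief("alice") > 0.5

    def test_untouched_subsets_stay_untouched(self):
        """An interaction between a pair does not move beliefs held with a
        third player."""
        bank = BeliefBank("i", ROSTER3)
        g_ik = give_keep_game(1, 3, "k", "i")
        bank.observe(_record(g_ik, "k", _keep(g_ik)), 0.025)
        before = belief_query(bank, ("i", "k"), "k").probs
        g_ij = give_keep_game(1, 3, "j", "i")
        bank.observe(_record(g_ij, "j", _give(g_ij)), 0.025)
        assert belief_query(bank, ("i", "k"), "k").probs == before


class TestObserverSubsets:
    def test_lazy_query_falls_back_to_prior(self):
        bank = BeliefBank("i", ROSTER3)
        d = belief_query(bank, ("i", "x"), "x")
        assert d.probs == pytest.approx(bank.prior.probs)

    def test_private_interactions_scale_linearly(self):
        bank = BeliefBank(0, ROSTER3)
        for j in range(1, 6):
            g = give_keep_game(1, 3, j, 0)
            bank.observe(_record(g, j, _keep(g)), 0.025)
        # singleton plus one pair table per partner
        assert len(bank.tables) == 1 + 5

    def test_public_interactions_need_one_subset(self):
        bank = BeliefBank(0, ROSTER3)
        everyone = frozenset(range(6))
        for j in range(1, 6):
            g = give_keep_game(1, 3, j, 0)
            bank.observe(_record(g, j, _keep(g), observers=everyone), 0.025)
        assert len(bank.tables) == 2  # singleton + full population

    def test_pair_subset_inits_from_tracked_superset(self):
        """A newly occurring pair inherits what the larger subset already
        commonly established."""
        bank = BeliefBank(0, ROSTER3)
        everyone = frozenset(range(4))
        g = give_keep_game(1, 3, 1, 0)
        for _ in range(5):
            bank.observe(_record(g, 1, _keep(g), observers=everyone), 0.025)
        public = belief_query(bank, everyone, 1)[SELFISH]
        bank.observe(_record(g, 1, _keep(g), observers=(0, 1)), 0.025)
        pair = belief_query(bank, (0, 1), 1)[SELFISH]
        assert pair >= public  # inherited, then sharpened privately


class TestPerceptionError:
    def test_zero_rate_is_identity(self, rng):
        g = give_keep_game(1, 3, "a", "b")
        rec = _record(g, "a", _give(g), observers=("a", "b", "c"))
        apply_perception_error(rec, 0.0, rng)
        assert rec.perceived == {}

    def test_certain_error_flips_everyone_but_actor(self, rng):
        g = give_keep_game(1, 3, "a", "b")
        rec = _record(g, "a", _give(g), observers=("a", "b", "c"))
        apply_perception_error(rec, 1.0, rng)
        assert rec.perceived_by("a") is _give(g)
        assert rec.perceived_by("b").is_zero
        assert rec.perceived_by("c").is_zero

    def test_empirical_misperception_rate(self, rng):
        g = give_keep_game(1, 3, "a", "b")
        n = 10_000
        mis = 0
        for _ in range(n):
            rec = _record(g, "a", _give(g))
            apply_perception_error(rec, 0.075, rng)
            if rec.perceived_by("b").is_zero:
                mis += 1
        assert abs(mis / n - 0.075) < 3 * np.sqrt(0.075 * 0.925 / n)
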