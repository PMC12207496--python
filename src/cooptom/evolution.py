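"""Moran-process steady states for the generative-game and IPD tournaments.

Two evolutionary analyses are supported:

* A *composition-space* chain with mutation: for every composition of player
  types in a population of size ``N``, per-type expected cumulative payoffs
  are estimated by simulating whole generations; a softmax (selection
  strength ``s``) of those payoffs gives copy probabilities; the resulting
  birth-death transition matrix over compositions is solved for its
  stationary distribution.

* A *low-mutation* chain over homogeneous populations: pairwise expected
  payoffs feed the classic fixation-probability product formula, giving an
  M x M chain between single-type states.

Both stationary distributions are the leading-eigenvector fixed point of the
corresponding stochastic matrix, computed by a direct linear solve and
verified to residual 1e-10.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components

from .agents import BayesianReciprocator, Player, apply_tremble, \
    choose_action
from .btom import BeliefBank, InteractionRecord, apply_perception_error
from .game_generator import GeneratorParams, sample_game, \
    sample_match_schedule
from .ipd import IPDConfig, play_ipd_match

__all__ = [
    "PayoffEstimate", "SteadyState", "GameGeneratorEnvironment",
    "enumerate_compositions", "estimate_expected_payoffs",
    "copy_probabilities", "composition_transition_matrix",
    "low_mutation_transition_matrix", "stationary_distribution",
    "abundance_summary", "estimate_pairwise_payoffs",
    "gg_steady_state", "ipd_steady_state",
]


# ---------------------------------------------------------------------------
# generation simulation (Game Generator environment)
# ---------------------------------------------------------------------------

class GameGeneratorEnvironment:
    """Simulates one generation of generative-game matches for a given
    population composition.

    Players are matched by :func:`~cooptom.game_generator.sample_match_schedule`;
    each group plays ``game_length`` sampled games with the decider drawn
    uniformly per game.  Bayesian Reciprocators start each generation with
    fresh belief banks whose hypothesis space is the tournament roster.
    """

    def __init__(self, params: GeneratorParams, roster):
        self.params = params
        self.roster = tuple(roster)

    def run_generation(self, counts, rng: np.random.Generator):
        """One generation at composition ``counts`` (aligned with the
        roster).  Returns (per-type mean cumulative payoff dict, population
        mean payoff)."""
        params = self.params
        players = []
        pid = 0
        for ptype, k in zip(self.roster, counts):
            for _ in range(int(k)):
                bank = None
                if isinstance(ptype, BayesianReciprocator):
                    bank = BeliefBank(pid, self.roster, br_type=ptype)
                players.append(Player(pid, ptype, bank))
                pid += 1
        by_id = {p.id: p for p in players}
        all_ids = [p.id for p in players]
        br_players = [p for p in players if p.bank is not None]
        eps, omega, eta = params.epsilon, params.omega, params.perception_error

        schedule = sample_match_schedule(all_ids, params, rng)
        for group in schedule.groups:
            for _ in range(schedule.interactions_per_group):
                game = sample_game(params, group, rng)
                decider = game.deciders[0]
                dec = by_id[decider]
                if dec.bank is not None:
                    intended = choose_action(
                        dec.type, game, rng,
                        beliefs=dec.bank.decision_beliefs(game))
                else:
                    intended = choose_action(dec.type, game, rng)
                realized = apply_tremble(intended, game, eps, rng)
                for i, pay in enumerate(realized.payoffs):
                    if pay != 0.0:
                        by_id[game.participants[i]].cumulative_payoff += pay
                if omega > 0.0 and rng.random() < omega:
                    observers = frozenset(all_ids)
                else:
                    observers = frozenset(group)
                record = InteractionRecord(game, decider, realized,
                                           observers)
                if eta > 0.0:
                    apply_perception_error(record, eta, rng)
                if len(observers) > len(group):
                    for p in br_players:
                        p.bank.observe(record, eps)
                else:
                    for member in group:
                        b = by_id[member].bank
                        if b is not None:
                            b.observe(record, eps)

        per_type = {}
        for ptype in self.roster:
            mine = [p.cumulative_payoff for p in players if p.type == ptype]
            if mine:
                per_type[ptype] = float(np.mean(mine))
        pop_mean = float(np.mean([p.cumulative_payoff for p in players]))
        return per_type, pop_mean


# ---------------------------------------------------------------------------
# payoff estimation
# ---------------------------------------------------------------------------

@dataclass
class PayoffEstimate:
    """Empirical per-type expected cumulative payoffs at one composition."""

    counts: tuple
    payoffs: dict          # PlayerType -> mean cumulative payoff
    population_mean: float
    reps: int


def enumerate_compositions(N: int, M: int):
    """All M-type compositions of a population of N, lexicographic."""
    out = []
    for cut in itertools.combinations_with_replacement(range(M), N):
        counts = [0] * M
        for t in cut:
            counts[t] += 1
        out.append(tuple(counts))
    return sorted(set(out), reverse=True)


def estimate_expected_payoffs(counts, environment, reps: int,
                              rng: np.random.Generator) -> PayoffEstimate:
    """Average per-type cumulative payoffs over ``reps`` independent
    generations (fresh belief banks each).  Types absent from the
    composition have no estimate."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    sums = {}
    pop_sum = 0.0
    for _ in range(reps):
        per_type, pop_mean = environment.run_generation(counts, rng)
        pop_sum += pop_mean
        for t, v in per_type.items():
            sums[t] = sums.get(t, 0.0) + v
    payoffs = {t: v / reps for t, v in sums.items()}
    return PayoffEstimate(tuple(counts), payoffs, pop_sum / reps, reps)


# ---------------------------------------------------------------------------
# chains
# ---------------------------------------------------------------------------

def copy_probabilities(payoffs, s: float):
    """Softmax of expected cumulative payoffs with selection strength ``s``
    (max-subtracted for stability)."""
    arr = np.asarray(payoffs, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("payoffs must be finite")
    z = s * arr
    z -= z.max()
    e = np.exp(z)
    return e / e.sum()


def composition_transition_matrix(estimates, N: int, M: int, delta: float,
                                  s: float, roster=None):
    """Birth-death chain over compositions.

    ``estimates``: dict composition -> PayoffEstimate.  For neighbours
    differing by one birth (type b) and one death (type d):
    ``p_ij = (delta/M + (1-delta)*mu_b) * (pop_d/N)`` where ``mu`` is the
    softmax copy probability among the types present in the source
    composition (absent types can only arrive by mutation).
    """
    comps = sorted(estimates.keys(), reverse=True)
    index = {c: i for i, c in enumerate(comps)}
    C = len(comps)
    p = np.zeros((C, C))
    for comp in comps:
        i = index[comp]
        est = estimates[comp]
        present = [t for t, k in enumerate(comp) if k > 0]
        if roster is not None:
            pay = [est.payoffs[roster[t]] for t in present]
        else:
            pay = [est.payoffs[t] for t in present]
        mu_present = copy_probabilities(pay, s)
        mu = np.zeros(M)
        for t, m in zip(present, mu_present):
            mu[t] = m
        for d in present:
            for b in range(M):
                if b == d:
                    continue
                target = list(comp)
                target[b] += 1
                target[d] -= 1
                j = index[tuple(target)]
                prob = (delta / M + (1.0 - delta) * mu[b]) * comp[d] / N
                if prob < 0:
                    raise RuntimeError("negative transition probability")
                p[i, j] = prob
        p[i, i] = 1.0 - p[i].sum()
        if p[i, i] < -1e-12:
            raise RuntimeError("row overflow in transition matrix")
        p[i, i] = max(p[i, i], 0.0)
    return p, comps


def _log_fitness_printed(k, N, s, pii, pij):
    # k players of the focal type; both partner counts reduced by one,
    # exactly as printed.
    w = ((k - 1) * pii + (N - k - 1) * pij) / (N - 1)
    return s * w


def _log_fitness_standard(k, N, s, pii, pij):
    # k players of the focal type; N - k partners of the other type.
    w = ((k - 1) * pii + (N - k) * pij) / (N - 1)
    return s * w


def fixation_probability(pi_ii, pi_ij, pi_jj, pi_ji, N: int, s: float,
                         exponent_form: str = "printed") -> float:
    """Probability that a single j-mutant fixes in an i-resident population,
    via the product formula, evaluated in log space.

    ``exponent_form='printed'`` uses partner weights (k-1)/(N-1) and
    (N-k-1)/(N-1) for both types; ``'standard'`` uses the usual Moran
    weights where the cross-partner count is not reduced.
    """
    if s < 0:
        raise ValueError("selection strength must be nonnegative")
    lf = _log_fitness_printed if exponent_form == "printed" else \
        _log_fitness_standard
    if exponent_form not in ("printed", "standard"):
        raise ValueError("exponent_form must be 'printed' or 'standard'")
    # log gamma_k = log mu_i^k - log mu_j^k at k i-players, N-k j-players
    log_gammas = []
    for k in range(1, N):
        li = lf(k, N, s, pi_ii, pi_ij)
        ljj = lf(N - k, N, s, pi_jj, pi_ji)
        log_gammas.append(li - ljj)
    cum = np.cumsum(log_gammas)
    m = max(cum.max(), 0.0)
    denom = math.exp(-m) + np.exp(cum - m).sum()
    rho = math.exp(-m) / denom
    # rho is mathematically positive; floor it above the underflow limit so
    # strongly disfavored invasions do not disconnect the chain
    return max(rho, 1e-300)


def low_mutation_transition_matrix(pairwise, types, N: int, s: float,
                                   exponent_form: str = "printed"):
    """M x M chain over homogeneous populations in the low-mutation limit.

    ``pairwise[(a, b)]`` is the expected payoff of a type-``a`` player
    paired with a type-``b`` player.  Off-diagonal entries are the fixation
    probability of a lone mutant scaled by the uniform mutant-introduction
    factor 1/(M-1); the stationary distribution is invariant to that scale.
    """
    M = len(types)
    p = np.zeros((M, M))
    for i, ti in enumerate(types):
        for j, tj in enumerate(types):
            if i == j:
                continue
            rho = fixation_probability(
                pairwise[(ti, ti)], pairwise[(ti, tj)],
                pairwise[(tj, tj)], pairwise[(tj, ti)],
                N, s, exponent_form)
            p[i, j] = rho / (M - 1)
        p[i, i] = 1.0 - p[i].sum()
    return p


@dataclass
class SteadyState:
    """Stationary distribution of an evolutionary chain."""

    frequencies: np.ndarray
    states: list = field(default_factory=list)
    residual: float = 0.0


def stationary_distribution(p: np.ndarray, states=None,
                            tol: float = 1e-10) -> SteadyState:
    """Left-stationary vector of a row-stochastic matrix via linear solve,
    with residual check ``||x p - x||_inf < tol``."""
    p = np.asarray(p, dtype=float)
    n = p.shape[0]
    if p.shape != (n, n) or np.any(p < -1e-12):
        raise ValueError("transition matrix must be square and nonnegative")
    if np.max(np.abs(p.sum(axis=1) - 1.0)) > 1e-8:
        raise ValueError("transition matrix rows must sum to 1")
    # irreducibility check on the directed support graph
    support = (p > 0).astype(int)
    ncomp, _ = connected_components(support, directed=True,
                                    connection="strong")
    if ncomp > 1:
        raise ValueError(
            f"chain is reducible ({ncomp} strongly connected components); "
            "stationary distribution is not unique")
    a = p.T - np.eye(n)
    a[-1, :] = 1.0
    rhs = np.zeros(n)
    rhs[-1] = 1.0
    x = np.linalg.solve(a, rhs)
    x = np.clip(x, 0.0, None)
    x /= x.sum()
    residual = float(np.max(np.abs(x @ p - x)))
    if residual >= tol:
        raise RuntimeError(f"stationary residual {residual:.2e} >= {tol}")
    return SteadyState(frequencies=x, states=list(states) if states
                       is not None else list(range(n)), residual=residual)


def abundance_summary(steady: SteadyState, compositions, N: int):
    """Per-type steady-state abundance: (1/N) sum_i counts_i * x*_i."""
    comps = np.asarray(compositions, dtype=float)
    freq = steady.frequencies @ comps / N
    total = freq.sum()
    if total > 0:
        freq = freq / total
    return freq


# ---------------------------------------------------------------------------
# end-to-end drivers
# ---------------------------------------------------------------------------

@dataclass
class GGSteadyStateResult:
    roster: tuple
    compositions: list
    payoff_table: dict
    transition: np.ndarray
    steady: SteadyState
    abundances: np.ndarray
    population_payoff: float  # steady-state-weighted mean cumulative payoff


def gg_steady_state(params: GeneratorParams, roster, N: int = 10,
                    delta: float = 0.001, s: float = 2.0, reps: int = 20,
                    seed: int = 0) -> GGSteadyStateResult:
    """Composition-space Moran steady state of the generative-game
    environment: estimate payoffs per composition, build the chain, solve.

    Seeds are split per composition with a spawned stream so the estimate is
    reproducible and compositions are independent.
    """
    roster = tuple(roster)
    M = len(roster)
    env = GameGeneratorEnvironment(params, roster)
    comps = enumerate_compositions(N, M)
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(comps))
    estimates = {}
    for comp, child in zip(comps, children):
        rng = np.random.default_rng(child)
        estimates[comp] = estimate_expected_payoffs(comp, env, reps, rng)
    p, comps = composition_transition_matrix(estimates, N, M, delta, s,
                                             roster=roster)
    steady = stationary_distribution(p, states=comps)
    abundances = abundance_summary(steady, comps, N)
    pop = float(sum(x * estimates[c].population_mean
                    for x, c in zip(steady.frequencies, comps)))
    return GGSteadyStateResult(roster, comps, estimates, p, steady,
                               abundances, pop)


def estimate_pairwise_payoffs(types, config: IPDConfig, reps: int,
                              seed: int = 0, roster=None):
    """Expected per-match payoffs pi[(a, b)] for every ordered type pair,
    averaged over ``reps`` matches per unordered pair."""
    types = tuple(types)
    pairwise = {}
    root = np.random.SeedSequence(seed)
    pairs = [(i, j) for i in range(len(types)) for j in range(i, len(types))]
    children = root.spawn(len(pairs))
    for (i, j), child in zip(pairs, children):
        rng = np.random.default_rng(child)
        ta, tb = types[i], types[j]
        tot_a = tot_b = 0.0
        for _ in range(reps):
            pa, pb, _ = play_ipd_match(ta, tb, config, rng, roster=roster)
            tot_a += pa
            tot_b += pb
        if i == j:
            pairwise[(ta, tb)] = (tot_a + tot_b) / (2 * reps)
        else:
            pairwise[(ta, tb)] = tot_a / reps
            pairwise[(tb, ta)] = tot_b / reps
    return pairwise


@dataclass
class IPDSteadyStateResult:
    roster: tuple
    pairwise: dict
    transition: np.ndarray
    steady: SteadyState
    abundances: np.ndarray
    population_payoff: float  # per-round per-player, normalized to [0, 1]


def ipd_steady_state(roster, config: IPDConfig, N: int = 100, s: float = 1.0,
                     reps: int = 1000, seed: int = 0,
                     exponent_form: str = "printed") -> IPDSteadyStateResult:
    """Low-mutation-limit steady state of the IPD tournament."""
    roster = tuple(roster)
    pairwise = estimate_pairwise_payoffs(roster, config, reps, seed)
    p = low_mutation_transition_matrix(pairwise, roster, N, s, exponent_form)
    steady = stationary_distribution(p, states=list(roster))
    abundances = steady.frequencies
    per_round = sum(x * pairwise[(t, t)] for x, t in zip(abundances, roster))
    norm = per_round / (config.game_length * (config.benefit - config.cost))
    norm = min(max(norm, 0.0), 1.0)
    return IPDSteadyStateResult(roster, pairwise, p, steady, abundances,
                                norm)
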