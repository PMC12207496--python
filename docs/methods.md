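# Methods

## Agents and decision rule

Three utility functions are studied on arbitrary payoff vectors: Selfish
(`U = R_self`), Altruistic (`U = R_self + Σ R_other`), and the Bayesian
Reciprocator (`U = R_self + Σ R_other · B(same type)`), plus memory-1
automata for the two-action IPD.  Utility players maximize subjective
utility with exact ties (tolerance 1e-12) broken uniformly with the run's
seeded generator.  Execution passes through a trembling hand: with
probability `ε` a uniformly drawn *other* option is executed.  Intentions
are never observable.

The reciprocator is parochial by construction: it weights another player's
payoff by the posterior probability that the player shares *its own*
utility function.  A partner known with certainty to be an unconditional
cooperator (AllC) therefore receives weight 0, not 1 — the weight tracks
type identity, not niceness.  (With `ε = 0` this situation cannot arise
from behavior alone, since AllC and a reciprocator generate identical
histories.)

## Belief representation

Beliefs live in per-observer-subset tables: the subset of players who all
witnessed an interaction shares one table, so "I believe you believe ..."
chains collapse (the common knowledge of `{i, j}` is a single object).
Tables are created lazily when a subset first occurs and are initialized
from the smallest tracked superset.  Each bank also keeps its owner's
private (singleton) view — everything the owner has perceived — which
drives the owner's own decisions; with groups larger than two, the same
target can be observed under incomparable subsets, and the singleton view
is the only table guaranteed to condition on all of it.

The update multiplies the tracked distribution over the actor's type by the
likelihood of the *perceived* action and renormalizes.  The likelihood is
the printed form `1 − ε` for the hypothesized type's intended action
(split over ties) and `ε/|G|` for each other option; it sums to less than
one across options by design, and Bayes renormalization across hypotheses
absorbs the deficit.  The hypothesized reciprocator's intended action is
simulated with the *common* subset's beliefs about the receivers — for an
updated subset `S` and actor `a`, the view is the smallest tracked subset
containing `S ∪ {a}`.  Posterior weights are floored at 1e-12 before
renormalization so small-`ε` runs cannot lock a hypothesis at exactly zero;
if every hypothesis assigns zero likelihood (possible only at `ε = 0`) an
impossible-observation error is raised.  Memory-1 hypotheses carry
per-subset history state (the last commonly observed action of each
player), advanced after the round's distributions are updated; in
simultaneous play both actions are revealed at once and both updates use
the pre-round state.

Perception error `η` makes each non-acting observer independently perceive
a uniformly drawn other option.  Every observer updates its own bank with
its own percept while believing the data are common — this is what
produces divergent beliefs.  Participants and third-party observers are
treated alike.

## The game generator

Each sample draws `k ~ Poisson(2)` cost-benefit choice types, each with
cost `c ~ Poisson(C)` and benefit `b ~ Exponential(B)`; for every type and
every non-decider there is an option in which the decider pays `c` and
that receiver gains `c + b` (benefit always exceeds cost), plus one
do-nothing option.  Option order is shuffled and labels carry no
semantics.  Defaults follow the studied conditions: `C = 1`, `B = 5`,
group sizes 2 or 3 with equal probability for evolutionary runs (pairs
only for the learning probes), `ε = 0.025`.

A generation matches every unordered pair of players once, in shuffled
order; when size-3 groups have positive probability a scheduled pair is
upgraded by adjoining a uniformly drawn third player.  Each group plays
`game_length` samples with the decider drawn uniformly per sample.  The
pairing volume is a design choice the underlying generative story does not
pin down; round-robin gives every player the same expected interaction
count and is what the steady-state scans below use.  Public observation
happens per interaction with probability `ω`; otherwise only the group
observes.

## Evolutionary analyses

Composition-space chain (resource-transfer environment): for every
composition of `N = 10` players over the type roster, per-type expected
cumulative payoffs are estimated by simulating independent generations
with fresh belief banks (20 at desk scale; 200 at full scale).  A softmax with selection strength `s = 2` over the payoffs
of the *present* types gives copy probabilities; with mutation
`δ = 0.001`, neighbor transitions are
`p_ij = (δ/M + (1 − δ)μ_b) · pop_d/N`.  The stationary distribution is the
fixed point of the row-stochastic matrix, computed by direct linear solve
with an irreducibility check and residual verified below 1e-10; per-type
abundances are stationary-weighted mean type fractions.

Low-mutation chain (IPD): pairwise expected match payoffs (desk scale 30+
matches per ordered pair; 1,000 at full scale) feed the standard fixation
product formula in log space, at `N = 100`, `s = 1`.  The printed fitness
exponent reduces *both* partner counts by one — weights `(k−1)/(N−1)` and
`(N−k−1)/(N−1)`, which do not sum to 1; this form is the default and the
conventional Moran weighting is available via
`exponent_form="standard"`.  Off-diagonal entries carry a uniform
mutant-introduction factor `1/(M−1)`, to which the stationary distribution
is invariant.

Seeding: one root seed spawns independent child streams per composition
(or per type pair), so runs are bit-reproducible and compositions
independent.

## Sequential IPD conventions

Rounds are donation games (cooperate = pay `c`, deliver `b`).  In the
sequential variant the first mover alternates by round and actions are
visible immediately; memory-1 automata condition on their own last action
and the opponent's most recently *observed* action, so a second mover
reacts to the current round's first move, while a first round without own
history falls back to the strategy's first move.  The reciprocator casts
each round as a two-option transfer game; in simultaneous play it
maximizes expected utility, marginalizing the opponent's action over the
posterior-weighted predictions of every hypothesis.

## Desk scale, and what the tests do and do not show

Deterministic results (WSLS's 50% cooperation against AllD, the belief
orderings of the Give-Keep vignettes, the two-round posterior oracle) are
exact.  The IPD tournament structure — WSLS most prevalent in the
simultaneous variant and Forgiver in the sequential variant without the
reciprocator, and the reciprocator most prevalent when added — reproduces
at 30 matches per pair.

The composition-space thresholds are sensitive to the per-generation
pairing volume.  Under round-robin matching, cumulative payoffs are large
enough that the softmax at `s = 2` acts as a near-argmax on expected
payoffs, and the reciprocator's expected-payoff margin over Selfish at the
pivotal mixed compositions stays positive well past the nominal threshold
regions: at desk scale the direct-reciprocity transition to reciprocator
dominance occurs at game length 2, dominance persists to action-error
rates beyond 0.35 (game length 9), and the Selfish takeover under
perception error does not occur on the grid up to 0.1.  Threshold scans
therefore report the first grid point crossing their criterion, or one
step beyond the grid when the crossing lies outside it.  A further
dilution is specific to multi-option games: a misperceived transfer
usually looks like a different transfer rather than like defection, so
only roughly `1/|G|` of perception errors read as selfish behavior.

The synthetic environment also idealizes real interaction in ways that
bound what green tests imply: types are stationary within a generation,
the hypothesis space is closed and correct (the true generating types are
always in the prior's support), payoffs are perfectly observed by whoever
observes at all, and populations are well mixed with no assortment.

## Known limitations

* Inequality-averse and other richer utility functions, learned or
  hierarchical priors, nonparametric type discovery, and explicit costly
  punishment are out of scope.
* K-level nested-belief approximations are deliberately absent; the
  common-knowledge subset representation replaces them.
* With partial observability (`0 < ω < 1`) the number of distinct observer
  subsets can grow combinatorially in the worst case; the implementation
  tracks only subsets that occur.
* Memory-1 hypotheses are only defined for two-player, two-option rounds;
  automata cannot play the generative resource-transfer games.
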