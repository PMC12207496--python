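"""Reproducible experiment drivers: belief-trajectory probes, steady-state
parameter scans for direct and indirect reciprocity, IPD tournaments, and
result writers.

Scans default to desk scale (tens of replicate generations per composition
and coarse grids); the full-scale replicate counts (200
generations per composition, 1,000 matches per pair) are available by
raising ``reps``.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .agents import ALTRUISTIC, BR, SELFISH, BayesianReciprocator, \
    PlayerType, resolve_type
from .btom import BeliefBank, InteractionRecord, apply_perception_error
from .evolution import gg_steady_state, ipd_steady_state
from .game_generator import GeneratorParams, sample_game, \
    sample_match_schedule
from .ipd import AUTOMATA_ROSTER, IPDConfig
from .agents import apply_tremble, choose_action

__all__ = [
    "ExperimentConfig", "DEFAULT_GG_ROSTER",
    "belief_trajectory_probe", "run_direct_scan", "run_indirect_scan",
    "run_ipd_scan", "write_results", "read_results",
]

DEFAULT_GG_ROSTER = (BR, SELFISH, ALTRUISTIC)


@dataclass
class ExperimentConfig:
    """Round-trippable experiment configuration (YAML/JSON)."""

    experiment: str = "direct"
    B: float = 5.0
    C: float = 1.0
    mean_choice_types: float = 2.0
    player_counts: dict = field(default_factory=lambda: {2: 0.5, 3: 0.5})
    epsilon: float = 0.025
    omega: float = 0.0
    perception_error: float = 0.0
    game_length: int = 1
    N: int = 10
    delta: float = 0.001
    s: float = 2.0
    reps: int = 20
    seed: int = 0
    grids: dict = field(default_factory=dict)
    roster: list = field(default_factory=lambda: ["br", "selfish",
                                                  "altruistic"])
    out: str | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        clean = {k: v for k, v in d.items() if k in known}
        if "player_counts" in clean:
            clean["player_counts"] = {int(k): float(v) for k, v in
                                      clean["player_counts"].items()}
        return cls(**clean)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def generator_params(self, **overrides) -> GeneratorParams:
        base = dict(mean_cost=self.C, mean_benefit=self.B,
                    mean_choice_types=self.mean_choice_types,
                    player_counts=dict(self.player_counts),
                    epsilon=self.epsilon, omega=self.omega,
                    perception_error=self.perception_error,
                    game_length=self.game_length, seed=self.seed)
        base.update(overrides)
        return GeneratorParams(**base)

    def resolve_roster(self):
        return tuple(resolve_type(n) for n in self.roster)


# ---------------------------------------------------------------------------
# belief-trajectory probes
# ---------------------------------------------------------------------------

def belief_trajectory_probe(partner_type: PlayerType,
                            n_interactions: int = 20, trials: int = 100,
                            env: str = "pair",
                            params: GeneratorParams | None = None,
                            roster=DEFAULT_GG_ROSTER,
                            rng: np.random.Generator | None = None
                            ) -> pd.DataFrame:
    """Monitor a probe Bayesian Reciprocator's posterior during interaction.

    ``env='pair'`` pairs the probe with a single partner of
    ``partner_type`` for ``n_interactions`` two-player games (the decider
    rotates at random).  ``env='population'`` embeds the probe in a 10-player
    population (4 reciprocators, 3 Selfish, 3 Altruistic) where every
    one-shot interaction is publicly observed, and logs the probe's beliefs
    about every other player after each observation; ``partner_type`` is
    ignored there.

    Returns a long table with one row per (trial, step, target): the
    target's true type and the probe's posterior over every hypothesis.
    Step 0 rows hold the prior.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    roster = tuple(roster)
    rows = []
    if env == "pair":
        if params is None:
            params = GeneratorParams(player_counts={2: 1.0})
        for trial in range(trials):
            probe = BeliefBank(0, roster)
            partner_bank = BeliefBank(1, roster) \
                if isinstance(partner_type, BayesianReciprocator) else None
            banks = {0: probe, 1: partner_bank}
            types = {0: BR, 1: partner_type}

            def log(step):
                d = probe.tables[frozenset((0,))].dists.get(
                    1, probe.prior.probs)
                row = {"trial": trial, "step": step, "target": 1,
                       "target_type": partner_type.name}
                row.update({t.name: p for t, p in zip(roster, d)})
                rows.append(row)

            log(0)
            for step in range(1, n_interactions + 1):
                game = sample_game(params, (0, 1), rng)
                decider = game.deciders[0]
                bank = banks[decider]
                beliefs = bank.decision_beliefs(game) if bank else None
                intended = choose_action(types[decider], game, rng,
                                         beliefs=beliefs)
                realized = apply_tremble(intended, game, params.epsilon, rng)
                record = InteractionRecord(game, decider, realized,
                                           frozenset((0, 1)))
                for b in banks.values():
                    if b is not None:
                        b.observe(record, params.epsilon)
                log(step)
    elif env == "population":
        if params is None:
            params = GeneratorParams(player_counts={2: 1.0}, omega=1.0,
                                     game_length=1)
        pop_types = [BR] * 4 + [SELFISH] * 3 + [ALTRUISTIC] * 3
        ids = list(range(10))
        for trial in range(trials):
            banks = {i: BeliefBank(i, roster) if isinstance(t,
                     BayesianReciprocator) else None
                     for i, t in zip(ids, pop_types)}
            probe = banks[0]

            def log(step):
                table = probe.tables[frozenset((0,))]
                for tgt in ids[1:]:
                    d = table.dists.get(tgt, probe.prior.probs)
                    row = {"trial": trial, "step": step, "target": tgt,
                           "target_type": pop_types[tgt].name}
                    row.update({t.name: p for t, p in zip(roster, d)})
                    rows.append(row)

            log(0)
            schedule = sample_match_schedule(ids, params, rng)
            step = 0
            for group in schedule.groups:
                game = sample_game(params, group, rng)
                decider = game.deciders[0]
                bank = banks[decider]
                beliefs = bank.decision_beliefs(game) if bank else None
                intended = choose_action(pop_types[decider], game, rng,
                                         beliefs=beliefs)
                realized = apply_tremble(intended, game, params.epsilon, rng)
                record = InteractionRecord(game, decider, realized,
                                           frozenset(ids))
                if params.perception_error > 0:
                    apply_perception_error(record, params.perception_error,
                                           rng)
                for b in banks.values():
                    if b is not None:
                        b.observe(record, params.epsilon)
                step += 1
                log(step)
    else:
        raise ValueError("env must be 'pair' or 'population'")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# steady-state scans
# ---------------------------------------------------------------------------

def _gg_scan(grid, config: ExperimentConfig) -> pd.DataFrame:
    """Run the composition-space steady state at every parameter point of
    ``grid`` (list of dicts of GeneratorParams overrides)."""
    roster = config.resolve_roster()
    rows = []
    results = []
    for point in grid:
        params = config.generator_params(**point)
        res = gg_steady_state(params, roster, N=config.N,
                              delta=config.delta, s=config.s,
                              reps=config.reps, seed=config.seed)
        results.append((point, res))
    pop_max = max(res.population_payoff for _, res in results)
    for point, res in results:
        ab = res.abundances
        winner_idx = int(np.argmax(ab))
        is_tie = np.sum(np.isclose(ab, ab[winner_idx])) > 1
        row = {"experiment": config.experiment, **point,
               "game_length": point.get("game_length", config.game_length),
               "epsilon": point.get("epsilon", config.epsilon),
               "omega": point.get("omega", config.omega),
               "perception_error": point.get("perception_error",
                                             config.perception_error),
               "N": config.N, "delta": config.delta, "s": config.s,
               "reps": config.reps, "seed": config.seed,
               "winner": "tie" if is_tie else roster[winner_idx].name,
               "population_payoff": res.population_payoff,
               "normalized_payoff": min(max(
                   res.population_payoff / pop_max, 0.0), 1.0)
               if pop_max > 0 else 0.0}
        for t, a in zip(roster, ab):
            row[f"abundance_{t.name}"] = float(a)
        rows.append(row)
    return pd.DataFrame(rows)


def run_direct_scan(config: ExperimentConfig | None = None,
                    game_lengths=None, epsilons=None, **overrides
                    ) -> pd.DataFrame:
    """Direct reciprocity: repeated private interactions (omega = 0).

    The grid is the product of ``game_lengths`` and ``epsilons`` (each
    defaulting to the single configured value).  Returns one row per grid
    point with steady-state abundances, the most prevalent type, and the
    scan-normalized population payoff.
    """
    if config is None:
        config = ExperimentConfig(experiment="direct", omega=0.0,
                                  game_length=9, **overrides)
    lengths = list(game_lengths or
                   config.grids.get("game_length", [config.game_length]))
    eps_grid = list(epsilons or config.grids.get("epsilon",
                                                 [config.epsilon]))
    grid = [{"game_length": int(gl), "epsilon": float(e), "omega": 0.0}
            for gl, e in itertools.product(lengths, eps_grid)]
    return _gg_scan(grid, config)


def run_indirect_scan(config: ExperimentConfig | None = None,
                      omegas=None, epsilons=None, etas=None, **overrides
                      ) -> pd.DataFrame:
    """Indirect reciprocity: one-shot interactions (game length 1) with a
    probability ``omega`` that each action is publicly observed."""
    if config is None:
        config = ExperimentConfig(experiment="indirect", omega=1.0,
                                  game_length=1, **overrides)
    om = list(omegas or config.grids.get("omega", [config.omega]))
    eps_grid = list(epsilons or config.grids.get("epsilon",
                                                 [config.epsilon]))
    eta_grid = list(etas or config.grids.get("perception_error",
                                             [config.perception_error]))
    grid = [{"game_length": 1, "omega": float(o), "epsilon": float(e),
             "perception_error": float(h)}
            for o, e, h in itertools.product(om, eps_grid, eta_grid)]
    return _gg_scan(grid, config)


def run_ipd_scan(variant: str = "simultaneous", game_lengths=(10, 50),
                 epsilons=(0.025,), benefits=(3.0,), cost: float = 1.0,
                 include_br: bool = True, roster=None, N: int = 100,
                 s: float = 1.0, reps: int = 50, seed: int = 0,
                 exponent_form: str = "printed") -> pd.DataFrame:
    """IPD tournament steady states over a grid of game length, action
    error and benefit/cost ratio, with or without the Bayesian
    Reciprocator in the roster."""
    if roster is None:
        roster = AUTOMATA_ROSTER
    roster = tuple(roster)
    if include_br and not any(isinstance(t, BayesianReciprocator)
                              for t in roster):
        roster = (BR,) + roster
    rows = []
    for gl, eps, b in itertools.product(game_lengths, epsilons, benefits):
        cfg = IPDConfig(benefit=float(b), cost=cost, game_length=int(gl),
                        epsilon=float(eps), variant=variant)
        res = ipd_steady_state(roster, cfg, N=N, s=s, reps=reps, seed=seed,
                               exponent_form=exponent_form)
        ab = res.abundances
        widx = int(np.argmax(ab))
        row = {"variant": variant, "game_length": int(gl),
               "epsilon": float(eps), "benefit": float(b), "cost": cost,
               "b_over_c": float(b) / cost, "include_br": include_br,
               "N": N, "s": s, "reps": reps, "seed": seed,
               "winner": roster[widx].name,
               "normalized_payoff": res.population_payoff}
        for t, a in zip(roster, ab):
            row[f"abundance_{t.name}"] = float(a)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# result I/O
# ---------------------------------------------------------------------------

def write_results(table: pd.DataFrame, path, fmt: str = "csv",
                  metadata: dict | None = None) -> Path:
    """Write a result table with run metadata.

    CSV output is plain RFC-4180 rows (metadata goes to a ``.meta.json``
    sidecar); JSON output embeds ``{"metadata": ..., "rows": [...]}`` in one
    file.  Tables must be nonempty.
    """
    if table.empty:
        raise ValueError("refusing to write an empty result table")
    path = Path(path)
    meta = {"package_version": _pkg_version, "schema_version": 1}
    meta.update(metadata or {})
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "csv":
        table.to_csv(path, index=False, lineterminator="\r\n")
        with open(path.with_suffix(path.suffix + ".meta.json"), "w") as fh:
            json.dump(meta, fh, indent=2, default=str)
    elif fmt == "json":
        payload = {"metadata": meta,
                   "rows": json.loads(table.to_json(orient="records"))}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=str)
    else:
        raise ValueError("fmt must be 'csv' or 'json'")
    return path


def read_results(path, fmt: str = "csv") -> pd.DataFrame:
    """Round-trip reader for :func:`write_results` output."""
    path = Path(path)
    if fmt == "csv":
        return pd.read_csv(path)
    with open(path) as fh:
        payload = json.load(fh)
    return pd.DataFrame(payload["rows"])
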