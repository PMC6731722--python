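"""Evolutionary transitions in individuality as Bayesian model comparison.

A hierarchy structure (the model M) is scored by its evidence — which,
under the evolution/inference dictionary, is the population's average
fitness.  Competing structures are evaluated counterfactually on a
*shared* sampled environment window (common random numbers), each by
running its own replicator trajectory and averaging the log per-step
evidence; a transition in individuality happens exactly when a grouped
structure out-scores the ungrouped incumbent.

Structure moves mirror the two transition routes: a new node added at
the top of the network (``add_top_level``: a nascent collective at a new
level, coexisting with a distinguished "free" value holding ungrouped
units) or a new value added to an existing variable (``add_value``).
Link deletion/restoration expresses conditional-independence changes.
Moves conserve total mass exactly and touch only the participating part
of the network; everything else keeps its parameters.

Greedy search accepts the best candidate only when it beats the
incumbent by more than a margin ``delta``; ties and sub-margin gains
keep the incumbent, and ranking ties break toward fewer levels, then
fewer total types, then lexicographic structure id — a deterministic
simplicity-first rule (the automatic Occam's razor made explicit).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .dynamics import FitnessTable, freeze_level, replicator_step
from .environment import FREE_LABEL, EnvironmentProcess, group_label
from .errors import (
    ExtinctionError,
    InvalidMoveError,
    ShapeMismatchError,
)
from .hierarchy import (
    ENV_NODE,
    HierarchyStructure,
    Level,
    MultilevelDistribution,
)

MOVE_KINDS = ("add_top_level", "add_value", "merge_value",
              "delete_link", "restore_link")


def evidence(dist: MultilevelDistribution, w: FitnessTable) -> float:
    """Model evidence of one observation: sum over configurations of w·f.

    Identical, by the duality, to the average fitness the replicator
    step normalizes by; the same correctly-rounded summation is used so
    the two agree exactly.
    """
    if w.structure.shape != dist.structure.shape:
        raise ShapeMismatchError("fitness table and distribution shapes differ")
    return math.fsum(np.multiply(w.values, dist.values).ravel().tolist())


@dataclass(frozen=True)
class ModelState:
    """A candidate model: structure, population state and fitness tables."""

    structure: HierarchyStructure
    distribution: MultilevelDistribution
    tables: Mapping[str, FitnessTable]

    def __post_init__(self):
        if self.distribution.structure != self.structure:
            raise ShapeMismatchError("distribution structure differs from state structure")
        for state, tab in self.tables.items():
            if tab.structure.shape != self.structure.shape:
                raise ShapeMismatchError(f"table for {state!r} has wrong shape")
        object.__setattr__(self, "tables", dict(self.tables))

    @property
    def structure_id(self) -> str:
        return self.structure.structure_id


def initial_state(env: EnvironmentProcess,
                  structure: HierarchyStructure,
                  distribution: MultilevelDistribution | None = None) -> ModelState:
    """Convenience constructor: uniform population unless one is given."""
    if distribution is None:
        n = int(np.prod(structure.shape))
        distribution = MultilevelDistribution(
            structure, np.full(structure.shape, 1.0 / n))
    return ModelState(structure, distribution, env.tables_for(structure))


@dataclass(frozen=True)
class StructureMove:
    """A single edit of the hierarchy structure.

    ``kind`` selects the payload fields that matter:

    * ``add_top_level`` — ``level`` (new level name), ``label`` (nascent
      collective), ``grouping`` (top-level label -> membership weight in
      [0, 1]), ``epsilon`` (fraction of weighted mass moved into the
      collective; the rest stays in the "free" value), optional
      ``fitness_factors`` (env state -> {label: factor} for the new axis).
    * ``add_value`` — ``level``, ``label`` (new value), ``donors``
      (labels whose mass seeds it), ``epsilon`` (fraction moved).
    * ``merge_value`` — ``level``, ``label`` (value removed), ``into``
      (label absorbing its mass); inverse of a single-donor add_value.
    * ``delete_link`` / ``restore_link`` — ``link`` = (child, conditioner).
    """

    kind: str
    level: str | None = None
    label: str | None = None
    grouping: Mapping[str, float] | None = None
    donors: tuple[str, ...] | None = None
    into: str | None = None
    epsilon: float | None = None
    link: tuple[str, str] | None = None
    fitness_factors: Mapping[str, Mapping[str, float]] | None = None

    def __post_init__(self):
        if self.kind not in MOVE_KINDS:
            raise InvalidMoveError(f"unknown move kind {self.kind!r}")
        if self.grouping is not None:
            object.__setattr__(self, "grouping", dict(self.grouping))
        if self.donors is not None:
            object.__setattr__(self, "donors", tuple(self.donors))
        if self.link is not None:
            object.__setattr__(self, "link", tuple(self.link))

    def describe(self) -> str:
        if self.kind == "add_top_level":
            grouped = sorted(k for k, v in (self.grouping or {}).items() if v > 0)
            return (f"add_top_level({self.level}: {self.label} over "
                    f"{grouped}, eps={self.epsilon})")
        if self.kind == "add_value":
            return f"add_value({self.level}: {self.label} from {self.donors}, eps={self.epsilon})"
        if self.kind == "merge_value":
            return f"merge_value({self.level}: {self.label} -> {self.into})"
        return f"{self.kind}{self.link}"


def _require(cond: bool, msg: str):
    if not cond:
        raise InvalidMoveError(msg)


def apply_move(state: ModelState, move: StructureMove,
               env: EnvironmentProcess | None = None) -> ModelState:
    """Apply a structure move; mass is conserved exactly.

    Untouched entries keep their mass bit-for-bit.  Fitness entries for
    newly created configurations come from, in order of precedence, the
    environment's parametric synergy rule (``add_top_level`` only), the
    move's ``fitness_factors``, or the neutral default (factor 1 for a
    new axis value, a copy of the first donor's slice for a new value).
    """
    s = state.structure
    vals = state.distribution.values

    if move.kind == "add_top_level":
        _require(move.level is not None and move.label is not None,
                 "add_top_level needs a level name and a collective label")
        _require(move.level not in s.names and move.level != ENV_NODE,
                 f"level name {move.level!r} collides")
        _require(move.label != FREE_LABEL, f"label {FREE_LABEL!r} is reserved")
        eps = move.epsilon if move.epsilon is not None else 0.5
        _require(0.0 < eps < 1.0, "epsilon must lie in (0, 1)")
        grouping = move.grouping or {}
        top = s.top
        for lab, wgt in grouping.items():
            _require(lab in top.types, f"grouping label {lab!r} not at top level")
            _require(0.0 <= wgt <= 1.0, "grouping weights must lie in [0, 1]")

        new_level = Level(move.level, (move.label, FREE_LABEL))
        new_structure = HierarchyStructure(s.levels + (new_level,), s.deleted_links)

        g = np.array([grouping.get(lab, 0.0) for lab in top.types])
        g = g.reshape((1,) * (vals.ndim - 1) + (-1,))
        moved = eps * g * vals
        new_vals = np.stack([moved, vals - moved], axis=-1)
        new_dist = MultilevelDistribution(new_structure, new_vals)

        new_tables: dict[str, FitnessTable] = {}
        synergy = env.synergy if env is not None else None
        for env_state, tab in state.tables.items():
            if synergy is not None:
                fac_grp = synergy.synergy_factor(env_state, move.label)
                fac_free = synergy.synergy_factor(env_state, FREE_LABEL)
            else:
                factors = (move.fitness_factors or {}).get(env_state, {})
                fac_grp = float(factors.get(move.label, 1.0))
                fac_free = float(factors.get(FREE_LABEL, 1.0))
            new_w = np.stack([tab.values * fac_grp, tab.values * fac_free], axis=-1)
            new_tables[env_state] = FitnessTable(new_structure, env_state, new_w)
        return ModelState(new_structure, new_dist, new_tables)

    if move.kind == "add_value":
        _require(move.level is not None and move.label is not None and move.donors,
                 "add_value needs a level, a new label and donors")
        ax = s.axis(move.level)
        lv = s.levels[ax]
        _require(move.label not in lv.types, f"label {move.label!r} collides")
        eps = move.epsilon if move.epsilon is not None else 0.5
        _require(0.0 < eps < 1.0, "epsilon must lie in (0, 1)")
        donor_idx = [s.type_index(move.level, d) for d in move.donors]

        new_level = Level(lv.name, lv.types + (move.label,))
        new_structure = HierarchyStructure(
            s.levels[:ax] + (new_level,) + s.levels[ax + 1:], s.deleted_links)

        new_vals = np.concatenate(
            [vals, np.zeros_like(np.take(vals, [0], axis=ax))], axis=ax)
        mover = np.zeros_like(np.take(vals, 0, axis=ax))
        idx: list = [slice(None)] * new_vals.ndim
        for d in donor_idx:
            idx[ax] = d
            donated = eps * new_vals[tuple(idx)]
            new_vals[tuple(idx)] = new_vals[tuple(idx)] - donated
            mover = mover + donated
        idx[ax] = len(lv.types)
        new_vals[tuple(idx)] = mover
        new_dist = MultilevelDistribution(new_structure, new_vals)

        new_tables = {}
        for env_state, tab in state.tables.items():
            factors = (move.fitness_factors or {}).get(env_state)
            if factors is not None and move.label in factors:
                new_slice = np.full_like(np.take(tab.values, 0, axis=ax),
                                         float(factors[move.label]))
            else:  # inherit the first donor's fitness
                new_slice = np.take(tab.values, donor_idx[0], axis=ax)
            new_w = np.concatenate(
                [tab.values, np.expand_dims(new_slice, ax)], axis=ax)
            new_tables[env_state] = FitnessTable(new_structure, env_state, new_w)
        return ModelState(new_structure, new_dist, new_tables)

    if move.kind == "merge_value":
        _require(move.level is not None and move.label is not None and move.into,
                 "merge_value needs a level, a label to remove and a target")
        ax = s.axis(move.level)
        lv = s.levels[ax]
        _require(lv.cardinality > 1, "cannot remove the only value of a level")
        src = s.type_index(move.level, move.label)
        dst = s.type_index(move.level, move.into)
        _require(src != dst, "source and target labels must differ")

        keep = [i for i in range(lv.cardinality) if i != src]
        new_level = Level(lv.name, tuple(lv.types[i] for i in keep))
        new_structure = HierarchyStructure(
            s.levels[:ax] + (new_level,) + s.levels[ax + 1:], s.deleted_links)

        merged = np.take(vals, keep, axis=ax).copy()
        dst_new = keep.index(dst)
        idx = [slice(None)] * merged.ndim
        idx[ax] = dst_new
        merged[tuple(idx)] = merged[tuple(idx)] + np.take(vals, src, axis=ax)
        new_dist = MultilevelDistribution(new_structure, merged)

        new_tables = {
            env_state: FitnessTable(new_structure, env_state,
                                    np.take(tab.values, keep, axis=ax))
            for env_state, tab in state.tables.items()
        }
        return ModelState(new_structure, new_dist, new_tables)

    if move.kind in ("delete_link", "restore_link"):
        _require(move.link is not None, f"{move.kind} needs a (child, conditioner) pair")
        links = set(s.deleted_links)
        if move.kind == "delete_link":
            _require(move.link not in links, f"link {move.link} already deleted")
            links.add(move.link)
        else:
            _require(move.link in links, f"link {move.link} is not deleted")
            links.discard(move.link)
        try:
            new_structure = s.with_deleted_links(links)
        except ValueError as err:
            raise InvalidMoveError(str(err)) from None
        new_dist = MultilevelDistribution(new_structure, vals)
        new_tables = {
            env_state: FitnessTable(new_structure, env_state, tab.values)
            for env_state, tab in state.tables.items()
        }
        # a freshly frozen level must actually be frozen in the tables
        if move.kind == "delete_link" and move.link[0] == ENV_NODE:
            new_tables = {
                env_state: freeze_level(tab, move.link[1])
                for env_state, tab in new_tables.items()
            }
        return ModelState(new_structure, new_dist, new_tables)

    raise InvalidMoveError(f"unknown move kind {move.kind!r}")  # pragma: no cover


@dataclass(frozen=True)
class ModelScore:
    """Evidence score of one model over a shared evaluation window.

    Scores are comparable only across equal windows: same environment
    sample sequence, same length, same seed.  An extinct model scores
    ``-inf``.
    """

    structure_id: str
    mean_log_evidence: float
    per_step_log_evidence: tuple[float, ...]
    window: int
    seed: int
    rank: int | None = None

    @property
    def per_step_evidence(self) -> tuple[float, ...]:
        return tuple(math.exp(x) for x in self.per_step_log_evidence)


def _score_state(state: ModelState, sequence: Sequence[str],
                 seed: int) -> ModelScore:
    dist = state.distribution
    logs: list[float] = []
    for env_state in sequence:
        try:
            dist, avg = replicator_step(dist, state.tables[env_state])
        except ExtinctionError:
            return ModelScore(state.structure_id, float("-inf"),
                              tuple(logs), len(sequence), seed)
        logs.append(math.log(avg))
    mean = math.fsum(logs) / len(logs)
    return ModelScore(state.structure_id, mean, tuple(logs), len(sequence), seed)


def _rank_key(state: ModelState, score: ModelScore):
    return (-score.mean_log_evidence, state.structure.n_levels,
            state.structure.total_types, score.structure_id)


def compare_models(states: Sequence[ModelState], env: EnvironmentProcess,
                   T: int, seed: int) -> list[ModelScore]:
    """Score every model on one shared environment window.

    Each model runs its own replicator trajectory along the *same*
    sampled sequence ``e(1..T)`` (common random numbers) and is scored
    by its mean log per-step evidence.  Returned scores align with the
    input order; ``rank`` is 0 for the best model, with ties broken
    toward fewer levels, then fewer total types, then structure id.
    """
    sequence = env.sample_sequence(T, seed)
    scores = [_score_state(st, sequence, seed) for st in states]
    order = sorted(range(len(states)),
                   key=lambda i: _rank_key(states[i], scores[i]))
    ranked = list(scores)
    for rank, i in enumerate(order):
        ranked[i] = replace(scores[i], rank=rank)
    return ranked


def default_move_generator(state: ModelState) -> list[StructureMove]:
    """Default candidate set: pairwise groupings plus single-value splits.

    Proposes one ``add_top_level`` move per unordered pair of current
    top-level types (nascent collective named by its members, half the
    pair's mass moved in) and one ``add_value`` split per existing type.
    """
    moves: list[StructureMove] = []
    s = state.structure
    next_level = f"C{s.n_levels}"
    top = s.top
    for a, b in itertools.combinations(top.types, 2):
        moves.append(StructureMove(
            kind="add_top_level", level=next_level,
            label=group_label((a, b)), grouping={a: 1.0, b: 1.0}, epsilon=0.5))
    for lv in s.levels:
        for lab in lv.types:
            new_lab = f"{lab}'"
            if new_lab in lv.types:
                continue
            moves.append(StructureMove(
                kind="add_value", level=lv.name, label=new_lab,
                donors=(lab,), epsilon=0.5))
    return moves


@dataclass(frozen=True)
class SearchEvent:
    """One round of greedy structure search."""

    round: int
    move: StructureMove | None
    structure_id: str
    mean_log_evidence: float
    incumbent_mean_log_evidence: float
    accepted: bool


def _round_seed(seed: int, round_index: int) -> int:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(round_index,))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def greedy_search(initial: ModelState, env: EnvironmentProcess,
                  move_generator: Callable[[ModelState], Iterable[StructureMove]]
                  = default_move_generator,
                  window: int = 24, max_rounds: int = 5, seed: int = 0,
                  delta: float = 1e-6) -> tuple[ModelState, list[SearchEvent]]:
    """Greedy hill climb over hierarchy structures by model evidence.

    Each round samples a fresh shared window (seed derived from the run
    seed and the round index), scores the incumbent and all candidates
    with :func:`compare_models`, and accepts the best candidate iff its
    mean log evidence exceeds the incumbent's by more than ``delta``.
    Ties and sub-margin improvements keep the incumbent, so structure
    that buys no fitness is never adopted.  Stops at ``max_rounds`` or
    at the first round with no accepted move; every accepted move is a
    transition event in the returned log.
    """
    state = initial
    events: list[SearchEvent] = []
    for rnd in range(1, max_rounds + 1):
        candidates = list(move_generator(state))
        cand_states = [apply_move(state, m, env) for m in candidates]
        scores = compare_models([state] + cand_states, env,
                                window, _round_seed(seed, rnd))
        inc_score = scores[0]
        best_i = None
        if candidates:
            best_i = min(range(len(candidates)),
                         key=lambda i: _rank_key(cand_states[i], scores[i + 1]))
        if (best_i is not None
                and scores[best_i + 1].mean_log_evidence
                > inc_score.mean_log_evidence + delta):
            state = cand_states[best_i]
            events.append(SearchEvent(
                round=rnd, move=candidates[best_i],
                structure_id=state.structure_id,
                mean_log_evidence=scores[best_i + 1].mean_log_evidence,
                incumbent_mean_log_evidence=inc_score.mean_log_evidence,
                accepted=True))
        else:
            events.append(SearchEvent(
                round=rnd, move=None, structure_id=state.structure_id,
                mean_log_evidence=inc_score.mean_log_evidence,
                incumbent_mean_log_evidence=inc_score.mean_log_evidence,
                accepted=False))
            break
    return state, events
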