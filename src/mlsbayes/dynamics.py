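"""Discrete replicator dynamics and its Bayesian dual.

The discrete replicator update

    f(x; t+1) = w(x; t) f(x; t) / sum_x w(x; t) f(x; t)

over multilevel configurations ``x = (I_i, C1_j, ...)`` is algebraically
identical to the Bayesian update

    P(x | e(t)) = P(e(t) | x) P(x) / sum_x P(e(t) | x) P(x)

once relative abundance is read as the prior, fitness as the likelihood
of the observed environment state ``e(t)``, the next abundance as the
posterior and the average fitness as the model evidence.  Both updates
are implemented here as genuinely independent codepaths — numpy
elementwise arithmetic versus a pure-Python accumulation in reversed
cell order — so that :func:`assert_duality` is a real check rather than
a tautology.  Both normalizers go through :func:`math.fsum`, which is
correctly rounded and therefore insensitive to cell order and to
zero-mass cells introduced by structure moves.

Fitness bookkeeping follows the same dictionary: the fitness of a
collective is the composition-weighted average fitness of its members,
``P(e|C_j) = sum_i P(e|I_i, C_j) P(I_i|C_j)``, and a level is *frozen*
when its units' fitness is fully determined by the collectives
containing them (the table is constant along that level's axis), in
which case within-collective composition at that level is exactly
invariant under selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

from .errors import (
    EmptyCollectiveError,
    ExtinctionError,
    NegativeEntryError,
    ShapeMismatchError,
)
from .hierarchy import ENV_NODE, HierarchyStructure, MultilevelDistribution

if TYPE_CHECKING:  # pragma: no cover
    from .environment import EnvironmentProcess


@dataclass(frozen=True)
class FitnessTable:
    """Per-environment-state fitness array, read as a likelihood table.

    ``values`` has one axis per level (same shape as the distribution);
    entry ``w(I_i in C1_j in ...; e)`` is identified with
    ``P(e | I_i, C1_j, ...)`` for the environment state ``env_state``.
    """

    structure: HierarchyStructure
    env_state: str
    values: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.values, dtype=float)
        if arr.shape != self.structure.shape:
            raise ShapeMismatchError(
                f"fitness shape {arr.shape} != structure shape {self.structure.shape}")
        if np.any(arr < 0):
            raise NegativeEntryError("fitness values must be non-negative")
        arr = arr.copy()
        arr.flags.writeable = False
        object.__setattr__(self, "values", arr)

    def is_constant_along(self, level: str, tol: float = 0.0) -> bool:
        """True iff the table does not vary along ``level``'s axis."""
        ax = self.structure.axis(level)
        ref = np.take(self.values, 0, axis=ax)
        dev = np.abs(self.values - np.expand_dims(ref, ax)).max()
        return float(dev) <= tol


def frozen_link_violation(table: FitnessTable) -> float:
    """Max deviation of the table from its structure's frozen constraints.

    For every deleted link ``(e, V)`` the table must be constant along
    level ``V``'s axis.  Returns 0.0 when all constraints hold (or none
    are declared).
    """
    worst = 0.0
    for child, cond in table.structure.deleted_links:
        if child != ENV_NODE:
            continue
        ax = table.structure.axis(cond)
        ref = np.take(table.values, 0, axis=ax)
        dev = float(np.abs(table.values - np.expand_dims(ref, ax)).max())
        worst = max(worst, dev)
    return worst


def replicator_step(dist: MultilevelDistribution,
                    w: FitnessTable) -> tuple[MultilevelDistribution, float]:
    """One generation of the discrete replicator equation.

    Returns the next-generation distribution and the average fitness
    ``sum w·f``.  Raises :class:`ExtinctionError` when the average
    fitness is zero (the update is undefined; renormalizing silently
    would fabricate dynamics).
    """
    if w.structure.shape != dist.structure.shape:
        raise ShapeMismatchError("fitness table and distribution shapes differ")
    weighted = np.multiply(w.values, dist.values)
    avg = math.fsum(weighted.ravel().tolist())
    if avg <= 0.0:
        raise ExtinctionError("average fitness is zero; population annihilated")
    return MultilevelDistribution(dist.structure, weighted / avg), avg


def bayes_update(prior: MultilevelDistribution,
                 likelihood: FitnessTable) -> tuple[MultilevelDistribution, float]:
    """Bayes' rule over the joint configuration space; dual of the replicator.

    Independent codepath: pure-Python cell loop, evidence accumulated
    over the *reversed* flat cell order.  Returns the posterior and the
    model evidence ``sum P(e|x) P(x)``.
    """
    if likelihood.structure.shape != prior.structure.shape:
        raise ShapeMismatchError("likelihood and prior shapes differ")
    flat_prior = prior.values.ravel().tolist()
    flat_lik = likelihood.values.ravel().tolist()
    unnormalized = [p * l for p, l in zip(flat_prior, flat_lik)]
    evidence = math.fsum(reversed(unnormalized))
    if evidence <= 0.0:
        raise ExtinctionError("model evidence is zero")
    posterior_flat = [u / evidence for u in unnormalized]
    posterior = np.array(posterior_flat, dtype=float).reshape(prior.values.shape)
    return MultilevelDistribution(prior.structure, posterior), evidence


def collective_fitness(dist: MultilevelDistribution, w: FitnessTable,
                       level: str, label: str) -> float:
    """Fitness of one collective: mean member fitness weighted by composition.

    Implements ``P(e|C_j) = sum_i P(e|I_i, C_j) P(I_i|C_j)`` summed over
    all member configurations.  Works at any level, including the
    individual level (where it conditions on the individual type).
    """
    s = dist.structure
    ax = s.axis(level)
    j = s.type_index(level, label)
    f_sub = np.take(dist.values, j, axis=ax)
    w_sub = np.take(w.values, j, axis=ax)
    mass = math.fsum(f_sub.ravel().tolist())
    if mass <= 0.0:
        raise EmptyCollectiveError(
            f"collective {label!r} at level {level!r} has zero marginal mass")
    return math.fsum(np.multiply(w_sub, f_sub).ravel().tolist()) / mass


def freeze_level(w: FitnessTable, level: str) -> FitnessTable:
    """Make a level evolutionarily frozen: fitness constant along its axis.

    Each slice along the level's axis is replaced by the axis mean, so
    units at that level have fitness fully determined by the collectives
    containing them.  The output satisfies the frozen constraint exactly
    and is a fixed point of this operation.
    """
    ax = w.structure.axis(level)
    mean = w.values.mean(axis=ax, keepdims=True)
    frozen = np.broadcast_to(mean, w.values.shape).copy()
    return FitnessTable(w.structure, w.env_state, frozen)


@dataclass(frozen=True)
class DualityReport:
    """Agreement between the replicator and Bayesian codepaths on one instance."""

    max_posterior_diff: float
    evidence_diff: float
    tol: float

    @property
    def passed(self) -> bool:
        return self.max_posterior_diff <= self.tol and self.evidence_diff <= self.tol


def assert_duality(dist: MultilevelDistribution, w: FitnessTable,
                   tol: float = 1e-12) -> DualityReport:
    """Run both codepaths on the same instance and report their deviation."""
    post_r, avg = replicator_step(dist, w)
    post_b, ev = bayes_update(dist, w)
    max_diff = float(np.abs(post_r.values - post_b.values).max())
    return DualityReport(max_diff, abs(avg - ev), tol)


@dataclass(frozen=True)
class StepRecord:
    """One time step of a trajectory."""

    t: int
    env_state: str
    avg_fitness: float
    log_evidence_increment: float
    cum_log_evidence: float
    distribution: np.ndarray | None = None

    def __eq__(self, other):
        if not isinstance(other, StepRecord):
            return NotImplemented
        same_dist = ((self.distribution is None and other.distribution is None)
                     or (self.distribution is not None
                         and other.distribution is not None
                         and np.array_equal(self.distribution, other.distribution)))
        return (self.t == other.t and self.env_state == other.env_state
                and self.avg_fitness == other.avg_fitness
                and self.log_evidence_increment == other.log_evidence_increment
                and self.cum_log_evidence == other.cum_log_evidence
                and same_dist)


@dataclass
class TrajectoryRecord:
    """Time-stamped log of a run: per-step evidence and structure events.

    The cumulative log evidence is the exact prefix sum of the per-step
    increments ``log w̄(t)``; accumulating in log space avoids the
    underflow a product of hundreds of per-step evidences would hit.
    """

    steps: list[StepRecord] = field(default_factory=list)
    events: list = field(default_factory=list)
    final_distribution: MultilevelDistribution | None = None

    @property
    def cum_log_evidence(self) -> float:
        return self.steps[-1].cum_log_evidence if self.steps else 0.0


def run_trajectory(dist0: MultilevelDistribution, env: "EnvironmentProcess",
                   T: int, seed: int,
                   record_snapshots: bool = True) -> TrajectoryRecord:
    """Iterate the replicator update along a sampled environment sequence.

    The environment states ``e(1), ..., e(T)`` are drawn from ``env``
    with the given seed (all randomness lives in the environment; the
    update itself is deterministic in frequencies).  Extinction at step
    ``t`` raises :class:`ExtinctionError` carrying that step index.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    sequence = env.sample_sequence(T, seed)
    tables = env.tables_for(dist0.structure)
    record = TrajectoryRecord()
    dist = dist0
    cum = 0.0
    for t, state in enumerate(sequence, start=1):
        try:
            dist, avg = replicator_step(dist, tables[state])
        except ExtinctionError as err:
            raise ExtinctionError(str(err), step=t) from None
        inc = math.log(avg)
        cum += inc
        record.steps.append(StepRecord(
            t=t, env_state=state, avg_fitness=avg,
            log_evidence_increment=inc, cum_log_evidence=cum,
            distribution=dist.values if record_snapshots else None))
    record.final_distribution = dist
    return record
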