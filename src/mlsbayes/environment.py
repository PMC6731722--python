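"""Synthetic stochastic environments and parametric fitness tables.

The environment process emits a stream of discrete states
``e(1), e(2), ...`` (i.i.d. or first-order Markov) and supplies one
fitness/likelihood table per state.  Tables are either given explicitly
or generated from a :class:`SynergySpec`: each individual type carries a
base fitness ``b(I_i; e)`` and each collective type a synergy factor
``s(C_j; e) >= 0``, combined multiplicatively,

    w(I_i in C1_j in ...; e) = b(I_i; e) * s(C1_j; e) * s(C2_k; e) * ...

With ``s == 1`` everywhere the fitness factorizes over individuals —
the exact no-synergy null in which grouping can never raise average
fitness.  Synergy attached to a *set* of individual types (co-membership
synergy) is resolved through deterministic group labels of the form
``"g:I1+I2"``, which is how collectives created by grouping moves in the
structure-learning module advertise their members.

All sampling consumes an explicit seed; equal seeds give identical
streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .dynamics import FitnessTable
from .errors import (
    InvalidStochasticMatrixError,
    MissingSpecError,
    ShapeMismatchError,
)
from .hierarchy import HierarchyStructure, MultilevelDistribution

GROUP_PREFIX = "g:"

#: Distinguished collective value holding units not (yet) grouped into
#: any collective at that level; always synergy-neutral (s = 1).
FREE_LABEL = "free"

_STOCHASTIC_TOL = 1e-12


def group_label(members) -> str:
    """Deterministic label for a collective grouping the given member types."""
    return GROUP_PREFIX + "+".join(sorted(members))


def group_members(label: str) -> frozenset | None:
    """Inverse of :func:`group_label`; None for non-group labels."""
    if not label.startswith(GROUP_PREFIX):
        return None
    return frozenset(label[len(GROUP_PREFIX):].split("+"))


@dataclass(frozen=True)
class SynergySpec:
    """Parametric fitness rule: per-individual base times per-collective synergy.

    ``base[e][label]`` is the base fitness of an individual type under
    environment state ``e`` (must cover every individual type).
    ``synergy[e][label]`` is the synergy factor of a collective type
    (default 1 when absent).  ``group_synergy[e]`` maps frozensets of
    member labels to factors, resolved through group labels; it is how
    "these types do better together" is expressed without enumerating
    collective labels in advance.
    """

    base: Mapping[str, Mapping[str, float]]
    synergy: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    group_synergy: Mapping[str, Mapping[frozenset, float]] = field(default_factory=dict)

    def base_fitness(self, env_state: str, label: str) -> float:
        try:
            return float(self.base[env_state][label])
        except KeyError:
            raise MissingSpecError(
                f"no base fitness for individual {label!r} under {env_state!r}") from None

    def synergy_factor(self, env_state: str, label: str) -> float:
        """Synergy of a collective label under one environment state.

        Lookup order: explicit per-label table, then co-membership table
        via the label's member set, then the neutral default 1.  The
        ``free`` value is always neutral.
        """
        if label == FREE_LABEL:
            return 1.0
        per_label = self.synergy.get(env_state, {})
        if label in per_label:
            return float(per_label[label])
        members = group_members(label)
        if members is not None:
            return float(self.group_synergy.get(env_state, {}).get(members, 1.0))
        return 1.0


def build_fitness_tables(spec: SynergySpec,
                         structure: HierarchyStructure) -> dict[str, FitnessTable]:
    """Materialize one fitness table per environment state for a structure.

    Axis 0 (the individual level) gets base fitnesses; every higher axis
    multiplies in per-label synergy factors.  With ``s == 1`` everywhere
    each table is constant along all collective axes given the
    individual type.
    """
    tables: dict[str, FitnessTable] = {}
    individual = structure.levels[0]
    for env_state in spec.base:
        arr = np.ones(structure.shape, dtype=float)
        b = np.array([spec.base_fitness(env_state, lab) for lab in individual.types])
        arr *= b.reshape((-1,) + (1,) * (structure.n_levels - 1))
        for ax in range(1, structure.n_levels):
            lv = structure.levels[ax]
            s = np.array([spec.synergy_factor(env_state, lab) for lab in lv.types])
            shape = [1] * structure.n_levels
            shape[ax] = lv.cardinality
            arr *= s.reshape(shape)
        tables[env_state] = FitnessTable(structure, env_state, arr)
    return tables


@dataclass(frozen=True)
class EnvironmentProcess:
    """Stochastic generator of environment states and their fitness tables.

    ``kind`` is ``"iid"`` (states drawn independently with
    ``probabilities``) or ``"markov"`` (first-order chain with row-
    stochastic ``transition_matrix``; the initial state is drawn from the
    stationary distribution so empirical frequencies converge to it).
    Fitness comes from explicit ``tables`` or from a parametric
    ``synergy`` spec evaluated on whatever structure is asked for.
    """

    env_states: tuple[str, ...]
    kind: str = "iid"
    probabilities: tuple[float, ...] | None = None
    transition_matrix: tuple[tuple[float, ...], ...] | None = None
    tables: Mapping[str, FitnessTable] | None = None
    synergy: SynergySpec | None = None

    def __post_init__(self):
        object.__setattr__(self, "env_states", tuple(self.env_states))
        n = len(self.env_states)
        if n < 1:
            raise ValueError("need at least one environment state")
        if self.kind == "iid":
            p = self.probabilities
            if p is None:
                p = tuple(1.0 / n for _ in range(n))
            p = tuple(float(x) for x in p)
            if len(p) != n or any(x < 0 for x in p) or abs(math.fsum(p) - 1.0) > _STOCHASTIC_TOL:
                raise InvalidStochasticMatrixError(
                    "state probabilities must be a length-matched distribution")
            object.__setattr__(self, "probabilities", p)
        elif self.kind == "markov":
            m = self.transition_matrix
            if m is None:
                raise InvalidStochasticMatrixError("markov kind needs a transition matrix")
            m = tuple(tuple(float(x) for x in row) for row in m)
            if len(m) != n or any(len(row) != n for row in m):
                raise InvalidStochasticMatrixError("transition matrix must be n x n")
            for row in m:
                if any(x < 0 for x in row) or abs(math.fsum(row) - 1.0) > _STOCHASTIC_TOL:
                    raise InvalidStochasticMatrixError(
                        f"transition row {row} is not a probability distribution")
            object.__setattr__(self, "transition_matrix", m)
        else:
            raise ValueError(f"unknown environment kind {self.kind!r}")

    def stationary_distribution(self) -> np.ndarray:
        """Long-run state frequencies (the probabilities themselves for i.i.d.)."""
        if self.kind == "iid":
            return np.array(self.probabilities)
        P = np.array(self.transition_matrix)
        n = P.shape[0]
        # solve pi (P - I) = 0 with sum(pi) = 1
        A = np.vstack([(P.T - np.eye(n)), np.ones(n)])
        b = np.zeros(n + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(A, b, rcond=None)
        pi = np.clip(pi, 0.0, None)
        return pi / pi.sum()

    def sample_sequence(self, T: int, seed: int) -> list[str]:
        """Draw ``e(1), ..., e(T)``; deterministic given the seed."""
        if T < 1:
            raise ValueError("T must be >= 1")
        rng = np.random.default_rng(seed)
        n = len(self.env_states)
        if self.kind == "iid":
            idx = rng.choice(n, size=T, p=np.array(self.probabilities))
        else:
            P = np.array(self.transition_matrix)
            idx = np.empty(T, dtype=int)
            state = rng.choice(n, p=self.stationary_distribution())
            for t in range(T):
                idx[t] = state
                state = rng.choice(n, p=P[state])
        return [self.env_states[i] for i in idx]

    def tables_for(self, structure: HierarchyStructure) -> dict[str, FitnessTable]:
        """Fitness tables for a structure, from the spec or the explicit tables."""
        if self.synergy is not None:
            return build_fitness_tables(self.synergy, structure)
        if self.tables is not None:
            for state, tab in self.tables.items():
                if tab.structure.shape != structure.shape:
                    raise ShapeMismatchError(
                        f"explicit table for {state!r} does not match the structure")
            return dict(self.tables)
        raise MissingSpecError("environment has neither tables nor a synergy spec")


def make_fig3_fixture() -> tuple[HierarchyStructure, MultilevelDistribution]:
    """Toy two-level population: three individual types in two collectives.

    A fixed bivariate abundance table (package-defined constants, so
    tests are bit-reproducible) with deliberately unequal collective
    compositions: collective ``A`` is dominated by ``I2``, collective
    ``B`` by ``I3``, and neither composition matches the individual-level
    marginal.  Exercises every marginal/conditional operation.
    """
    structure = HierarchyStructure.from_levels(
        [("I", ("I1", "I2", "I3")), ("C1", ("A", "B"))])
    values = np.array([
        [0.10, 0.05],
        [0.20, 0.15],
        [0.10, 0.40],
    ])
    return structure, MultilevelDistribution(structure, values)


def two_state_synergy_environment(s: float = 4.0,
                                  probabilities: tuple[float, float] = (0.5, 0.5),
                                  ) -> EnvironmentProcess:
    """Standard two-state study environment with co-membership synergy.

    Three individual types; base fitness favours ``I1`` under ``e1`` and
    ``I2`` under ``e2`` (``I3`` is the neutral bystander); grouping
    ``{I1, I2}`` into one collective multiplies their fitness by ``s``
    under both states.  ``s = 1`` is the exact no-synergy null.
    """
    members = frozenset({"I1", "I2"})
    spec = SynergySpec(
        base={
            "e1": {"I1": 1.5, "I2": 0.8, "I3": 1.0},
            "e2": {"I1": 0.8, "I2": 1.5, "I3": 1.0},
        },
        group_synergy={
            "e1": {members: float(s)},
            "e2": {members: float(s)},
        },
    )
    return EnvironmentProcess(env_states=("e1", "e2"), kind="iid",
                              probabilities=probabilities, synergy=spec)
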