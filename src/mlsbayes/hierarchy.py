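"""Multilevel populations as multivariate discrete distributions.

A multilevel population — individuals nested in collectives, collectives
nested in higher-level collectives — is encoded as a joint probability
table: the relative abundance ``f(I_i in C1_j in C2_k in ...)`` of
individuals of type ``I_i`` inside collectives of type ``C1_j`` inside
``C2_k`` ... is identified with the joint probability
``P(I_i, C1_j, C2_k, ...)``.  Under this identification,

* per-level abundance distributions are **marginals**,
* collective **composition** and individual **membership** distributions
  are the two conditional readings of the same joint entries,
* structural simplifications of selection correspond to
  **conditional-independence (CI)** relations, i.e. deleted links of the
  belief network that factorizes the joint as
  ``P(e|I,C1,...) P(I|C1,...) ... P(C^L)``.

Storage is a dense numpy array, one axis per level, lowest level first.
Structures here are desk-scale (at most a few thousand cells), so dense
enumeration keeps every operation trivially checkable against a
loop-over-all-index-tuples oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    AllZeroError,
    EmptyCollectiveError,
    NegativeEntryError,
    NormalizationError,
    ShapeMismatchError,
    UnknownLevelError,
    UnknownTypeError,
)

#: Name of the observed environment node in the belief network.  It is not
#: a population level; it appears only as the child of deleted links that
#: express "frozen" levels (fitness independent of that level).
ENV_NODE = "e"

#: Entries of a distribution must sum to one within this tolerance
#: (accumulated float error over long trajectories).
NORMALIZATION_TOL = 1e-9


@dataclass(frozen=True)
class Level:
    """One level of the hierarchy: a name and its ordered type labels."""

    name: str
    types: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "types", tuple(self.types))
        if len(self.types) < 1:
            raise ValueError(f"level {self.name!r} needs at least one type")
        if len(set(self.types)) != len(self.types):
            raise ValueError(f"duplicate type labels at level {self.name!r}")

    @property
    def cardinality(self) -> int:
        return len(self.types)


@dataclass(frozen=True)
class HierarchyStructure:
    """The model M: ordered levels plus the set of deleted belief-network links.

    ``levels`` are ordered lowest first (individuals ``I``, then ``C1``,
    ``C2``, ...).  ``deleted_links`` is a set of ordered pairs
    ``(child, conditioner)`` removed from the full chain factorization;
    the child may be any level or the environment node ``"e"``, and the
    conditioner must be a strictly higher level than the child.

    Two structures are equal iff their levels, labels and deleted links
    are equal, which is what model-comparison bookkeeping requires.
    """

    levels: tuple[Level, ...]
    deleted_links: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "levels", tuple(self.levels))
        object.__setattr__(self, "deleted_links", frozenset(
            (str(c), str(v)) for c, v in self.deleted_links))
        names = [lv.name for lv in self.levels]
        if len(set(names)) != len(names):
            raise ValueError("level names must be unique")
        if ENV_NODE in names:
            raise ValueError(f"{ENV_NODE!r} is reserved for the environment node")
        order = {n: i for i, n in enumerate(names)}
        for child, cond in self.deleted_links:
            if cond not in order:
                raise ValueError(f"deleted link conditioner {cond!r} is not a level")
            if child == ENV_NODE:
                continue
            if child not in order:
                raise ValueError(f"deleted link child {child!r} is not a level")
            if order[child] >= order[cond]:
                raise ValueError(
                    f"deleted link ({child!r}, {cond!r}): conditioner must be "
                    "a strictly higher level than the child")

    # -- lookups -----------------------------------------------------------

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(lv.name for lv in self.levels)

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(lv.cardinality for lv in self.levels)

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def total_types(self) -> int:
        return sum(lv.cardinality for lv in self.levels)

    @property
    def top(self) -> Level:
        return self.levels[-1]

    def axis(self, name: str) -> int:
        """Array axis of a level (lowest level is axis 0)."""
        for i, lv in enumerate(self.levels):
            if lv.name == name:
                return i
        raise UnknownLevelError(f"no level named {name!r}")

    def level(self, name: str) -> Level:
        return self.levels[self.axis(name)]

    def type_index(self, level_name: str, label: str) -> int:
        lv = self.level(level_name)
        try:
            return lv.types.index(label)
        except ValueError:
            raise UnknownTypeError(
                f"no type {label!r} at level {level_name!r}") from None

    def with_deleted_links(self, links) -> "HierarchyStructure":
        """Copy of this structure with ``deleted_links`` replaced."""
        return HierarchyStructure(self.levels, frozenset(tuple(l) for l in links))

    @property
    def structure_id(self) -> str:
        """Canonical, sortable identifier used in score tables and logs."""
        lvl = "|".join(f"{lv.name}[{','.join(lv.types)}]" for lv in self.levels)
        links = ";".join(f"{c}<-{v}" for c, v in sorted(self.deleted_links))
        return f"{lvl}||{links}"

    @classmethod
    def from_levels(cls, levels, deleted_links=()) -> "HierarchyStructure":
        """Build from ``[(name, [labels...]), ...]`` pairs, lowest level first."""
        return cls(tuple(Level(n, tuple(t)) for n, t in levels),
                   frozenset(tuple(l) for l in deleted_links))


@dataclass(frozen=True)
class MultilevelDistribution:
    """Joint relative-abundance array; the population state / Bayesian prior.

    ``values[i, j, k, ...] = f(I_i in C1_j in C2_k in ...)``, non-negative
    and summing to one.  The array is stored read-only.
    """

    structure: HierarchyStructure
    values: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.values, dtype=float)
        if arr.shape != self.structure.shape:
            raise ShapeMismatchError(
                f"values shape {arr.shape} != structure shape {self.structure.shape}")
        if np.any(arr < 0):
            raise NegativeEntryError("distribution entries must be non-negative")
        total = math.fsum(arr.ravel().tolist())
        if abs(total - 1.0) > NORMALIZATION_TOL:
            raise NormalizationError(
                f"entries sum to {total!r}, not 1 within {NORMALIZATION_TOL}")
        arr = arr.copy()
        arr.flags.writeable = False
        object.__setattr__(self, "values", arr)

    def __eq__(self, other):
        if not isinstance(other, MultilevelDistribution):
            return NotImplemented
        return (self.structure == other.structure
                and np.array_equal(self.values, other.values))

    def __hash__(self):
        return hash((self.structure, self.values.tobytes()))


def normalize(raw, structure: HierarchyStructure) -> MultilevelDistribution:
    """Turn raw non-negative abundances into a distribution summing to one.

    Abundances are always measured relative to the total abundance of
    individuals, so any non-negative array with at least one positive
    entry defines a valid population state.
    """
    arr = np.asarray(raw, dtype=float)
    if arr.shape != structure.shape:
        raise ShapeMismatchError(
            f"raw shape {arr.shape} != structure shape {structure.shape}")
    if np.any(arr < 0):
        raise NegativeEntryError("raw abundances must be non-negative")
    total = math.fsum(arr.ravel().tolist())
    if total == 0.0:
        raise AllZeroError("all abundances are zero")
    return MultilevelDistribution(structure, arr / total)


def marginal(dist: MultilevelDistribution, level: str) -> np.ndarray:
    """Abundance distribution of types at one level: sum over all other axes.

    Returns a vector aligned with ``dist.structure.level(level).types``.
    """
    ax = dist.structure.axis(level)
    axes = tuple(a for a in range(dist.values.ndim) if a != ax)
    return dist.values.sum(axis=axes) if axes else dist.values.copy()


def composition(dist: MultilevelDistribution, collective_level: str,
                collective_type: str, member_level: str) -> np.ndarray:
    """Composition of a collective: P(member type | collective type).

    ``member_level`` must lie strictly below ``collective_level``.  Raises
    :class:`EmptyCollectiveError` when the collective has zero marginal
    mass (the conditional is undefined; no NaNs are returned).
    """
    s = dist.structure
    c_ax = s.axis(collective_level)
    m_ax = s.axis(member_level)
    if m_ax >= c_ax:
        raise ValueError(
            f"member level {member_level!r} must be strictly below "
            f"collective level {collective_level!r}")
    j = s.type_index(collective_level, collective_type)
    sub = np.take(dist.values, j, axis=c_ax)
    mass = float(sub.sum())
    if mass <= 0.0:
        raise EmptyCollectiveError(
            f"collective {collective_type!r} at level {collective_level!r} "
            "has zero marginal mass")
    axes = tuple(a for a in range(sub.ndim) if a != m_ax)
    vec = sub.sum(axis=axes) if axes else sub
    return vec / mass


def membership(dist: MultilevelDistribution, member_level: str,
               member_type: str, collective_level: str) -> np.ndarray:
    """Membership distribution of a member type: P(collective | member type).

    The symmetric conditional reading of the same joint entries as
    :func:`composition`, conditioning on the lower-level type instead.
    """
    s = dist.structure
    c_ax = s.axis(collective_level)
    m_ax = s.axis(member_level)
    if m_ax >= c_ax:
        raise ValueError(
            f"member level {member_level!r} must be strictly below "
            f"collective level {collective_level!r}")
    i = s.type_index(member_level, member_type)
    sub = np.take(dist.values, i, axis=m_ax)
    mass = float(sub.sum())
    if mass <= 0.0:
        raise EmptyCollectiveError(
            f"member type {member_type!r} at level {member_level!r} "
            "has zero marginal mass")
    c_sub = c_ax - 1  # collective axis after removing the lower member axis
    axes = tuple(a for a in range(sub.ndim) if a != c_sub)
    vec = sub.sum(axis=axes) if axes else sub
    return vec / mass


@dataclass(frozen=True)
class CIReport:
    """Result of a conditional-independence check.

    ``max_violation`` is the largest max-norm deviation between the
    child's conditionals across positive-mass values of the conditioner
    (holding every other higher level fixed).  ``vacuous`` is true when
    no conditioning event with at least two positive-mass conditioner
    values exists, or the conditioner is absent from the structure.
    """

    satisfied: bool
    max_violation: float
    vacuous: bool = False


def check_ci(dist: MultilevelDistribution, child: str, conditioner: str,
             tol: float = 1e-12) -> CIReport:
    """Check ``P(child | levels above child)`` invariance to the conditioner.

    The deleted link ``(child, conditioner)`` asserts that the
    composition of units at the child's level does not depend on which
    conditioner-level collective they belong to, given all other higher
    levels.  Conditionals are compared only where the conditioning event
    has positive mass; an absent or everywhere-degenerate conditioner
    counts as (vacuously) satisfied.
    """
    s = dist.structure
    if conditioner not in s.names:
        return CIReport(True, 0.0, vacuous=True)
    c_ax = s.axis(child)
    v_ax = s.axis(conditioner)
    if v_ax <= c_ax:
        raise ValueError("conditioner must be a strictly higher level than child")

    arr = dist.values
    below = tuple(range(c_ax))
    if below:
        arr = arr.sum(axis=below)
    # arr axes: 0 = child, 1.. = levels above child, in structure order.
    v_pos = (v_ax - c_ax - 1) + 1
    other_axes = [a for a in range(1, arr.ndim) if a != v_pos]
    other_shape = [arr.shape[a] for a in other_axes]

    max_viol = 0.0
    any_comparison = False
    for idx in np.ndindex(*other_shape):
        sl: list = [slice(None)] * arr.ndim
        for a, i in zip(other_axes, idx):
            sl[a] = i
        sub = arr[tuple(sl)]            # (child card, conditioner card)
        masses = sub.sum(axis=0)
        pos = masses > 0.0
        if int(pos.sum()) < 2:
            continue
        conds = sub[:, pos] / masses[pos]
        viol = float((conds.max(axis=1) - conds.min(axis=1)).max())
        any_comparison = True
        if viol > max_viol:
            max_viol = viol
    return CIReport(max_viol <= tol, max_viol, vacuous=not any_comparison)


def project_ci(dist: MultilevelDistribution,
               structure_with_links: HierarchyStructure) -> MultilevelDistribution:
    """Project a distribution onto the CI constraints of a link-deleted structure.

    Rebuilds the chain factorization ``P(I|...) P(C1|...) ... P(C^L)``
    from the distribution's own conditionals, replacing each deleted
    link's conditional by the conditional marginalized over the deleted
    conditioner (the standard information-projection choice for this
    factorization).  Links whose child is the environment node constrain
    fitness tables, not the distribution, and are ignored here.

    Where a retained-parent configuration has zero mass the conditional
    is undefined; it is filled uniformly over the child axis (the filled
    value only receives mass the projection itself fabricates).  With no
    deleted latent-latent links the input is returned unchanged.
    """
    s = dist.structure
    t = structure_with_links
    if s.levels != t.levels:
        raise ShapeMismatchError("structures have different levels/labels")
    latent = {(c, v) for c, v in t.deleted_links if c != ENV_NODE}
    if not latent:
        return MultilevelDistribution(t, dist.values)

    vals = dist.values
    n = vals.ndim
    result = np.ones_like(vals)
    for ax in range(n):
        name = t.names[ax]
        parents = set(range(ax + 1, n))
        deleted = {t.axis(v) for c, v in latent if c == name}
        retained = parents - deleted
        keep = {ax} | retained
        joint = vals.sum(axis=tuple(a for a in range(n) if a not in keep),
                         keepdims=True) if keep != set(range(n)) else vals
        parent_axes = tuple(a for a in range(n) if a not in retained)
        parent = vals.sum(axis=parent_axes, keepdims=True)
        safe = np.where(parent > 0.0, parent, 1.0)
        cond = np.where(parent > 0.0, joint / safe, 1.0 / vals.shape[ax])
        result = result * cond
    total = math.fsum(result.ravel().tolist())
    return MultilevelDistribution(t, result / total)
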