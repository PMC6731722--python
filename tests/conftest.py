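import numpy as np
import pytest

from mlsbayes import (
    FitnessTable,
    HierarchyStructure,
    MultilevelDistribution,
)


@pytest.fixture
def ex1_structure():
    """Two individual types in two collectives (the worked example)."""
    return HierarchyStructure.from_levels([("I", ("I1", "I2")), ("C1", ("A", "B"))])


@pytest.fixture
def ex1_dist(ex1_structure):
    """f(I1 in A)=0.2, f(I2 in A)=0.2, f(I1 in B)=0.5, f(I2 in B)=0.1."""
    return MultilevelDistribution(
        ex1_structure, np.array([[0.2, 0.5], [0.2, 0.1]]))


@pytest.fixture
def ex1_table(ex1_structure):
    """w(I1 in A)=2, w(I2 in A)=2, w(I1 in B)=1, w(I2 in B)=3."""
    return FitnessTable(ex1_structure, "e",
                        np.array([[2.0, 1.0], [2.0, 3.0]]))


@pytest.fixture
def chain3():
    """Three-level distribution built as P(C2) P(C1|C2) P(I|C1).

    By construction I is conditionally independent of C2 given C1.
    """
    structure = HierarchyStructure.from_levels(
        [("I", ("I1", "I2")), ("C1", ("A", "B")), ("C2", ("X", "Y"))])
    p_c2 = np.array([0.3, 0.7])
    p_c1_given_c2 = np.array([[0.6, 0.2],    # rows: C1 value, cols: C2 value
                              [0.4, 0.8]])
    p_i_given_c1 = np.array([[0.9, 0.25],    # rows: I value, cols: C1 value
                             [0.1, 0.75]])
    values = np.einsum("ij,jk,k->ijk", p_i_given_c1, p_c1_given_c2, p_c2)
    return MultilevelDistribution(structure, values)


@pytest.fixture
def ci_counterexample():
    """Three levels where the I-composition depends on C2.

    C1 has a single value; given C2=X the I-composition is (0.8, 0.2),
    given C2=Y it is (0.3, 0.7), so the max conditional difference is 0.5.
    """
    structure = HierarchyStructure.from_levels(
        [("I", ("I1", "I2")), ("C1", ("A",)), ("C2", ("X", "Y"))])
    values = np.array([[[0.40, 0.15]], [[0.10, 0.35]]])
    return MultilevelDistribution(structure, values)


def random_distribution(rng, structure, positive=True):
    raw = rng.random(structure.shape)
    if positive:
        raw = raw + 1e-9
    return MultilevelDistribution(structure, raw / raw.sum())


def random_structure(rng, max_levels=4, max_types=5):
    n_levels = int(rng.integers(1, max_levels + 1))
    levels = []
    for i in range(n_levels):
        card = int(rng.integers(1, max_types + 1))
        name = "I" if i == 0 else f"C{i}"
        levels.append((name, tuple(f"{name}t{j}" for j in range(card))))
    return HierarchyStructure.from_levels(levels)
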