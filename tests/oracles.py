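"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plain-Python loops over explicit index
tuples, deliberately sharing no arithmetic path with the package.
"""

import itertools
import math

import numpy as np


def all_indices(shape):
    return itertools.product(*(range(n) for n in shape))


def naive_marginal(values, axis):
    """Sum over all other indices with an explicit loop."""
    out = [0.0] * values.shape[axis]
    for idx in all_indices(values.shape):
        out[idx[axis]] += float(values[idx])
    return np.array(out)


def naive_conditional(values, target_axis, given_axis, given_index):
    """P(target | given) by explicit restricted summation."""
    num = [0.0] * values.shape[target_axis]
    den = 0.0
    for idx in all_indices(values.shape):
        if idx[given_axis] != given_index:
            continue
        num[idx[target_axis]] += float(values[idx])
        den += float(values[idx])
    if den == 0.0:
        raise ZeroDivisionError("conditioning event has zero mass")
    return np.array(num) / den


def naive_posterior(f, w):
    """Selection update by explicit loops, third arithmetic path."""
    total = 0.0
    for idx in all_indices(f.shape):
        total += float(f[idx]) * float(w[idx])
    out = np.empty_like(np.asarray(f, dtype=float))
    for idx in all_indices(f.shape):
        out[idx] = float(f[idx]) * float(w[idx]) / total
    return out, total


def naive_collective_fitness(f, w, axis, index):
    """Composition-weighted member fitness by restricted double loop."""
    num = 0.0
    den = 0.0
    for idx in all_indices(f.shape):
        if idx[axis] != index:
            continue
        num += float(w[idx]) * float(f[idx])
        den += float(f[idx])
    return num / den


def product_evidence_log(f0, tables_by_state, sequence):
    """log of the T-fold sequential evidence product, by full enumeration.

    Runs the selection update step by step with plain loops and returns
    ``log prod_t wbar_t`` (computed as a sum of logs to dodge underflow,
    which for T <= 20 matches the direct product to float precision).
    """
    f = np.asarray(f0, dtype=float).copy()
    logs = []
    for state in sequence:
        f, avg = naive_posterior(f, tables_by_state[state])
        logs.append(math.log(avg))
    return sum(logs)


def random_instance(rng, max_levels=4, max_types=5, positive=True):
    """Random (values, fitness) pair on a random small shape."""
    n_levels = int(rng.integers(1, max_levels + 1))
    shape = tuple(int(rng.integers(1, max_types + 1)) for _ in range(n_levels))
    raw = rng.random(shape)
    if positive:
        raw = raw + 1e-9
    f = raw / raw.sum()
    w = rng.random(shape) * 3.0
    return f, w
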