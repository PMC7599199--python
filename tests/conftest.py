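import numpy as np
import pytest

from polikst import (
    Domain,
    LevelSet,
    PolimParameters,
    PolytomousStructure,
)

# Worked 4-level example tables: delta1 is called a distance function but
# violates the triangle inequality (d(a,d)=5 > d(a,b)+d(b,d)=4); the
# checkers treat it as a general dissimilarity.
DELTA1_4 = np.array([
    [0, 1, 3, 5],
    [1, 0, 2, 3],
    [3, 2, 0, 1],
    [5, 3, 1, 0],
], dtype=float)

F1_4 = np.array([
    [20, 18, 10, 5],
    [10, 40, 5, 8],
    [7, 8, 15, 4],
    [1, 2, 3, 4],
], dtype=float)

# 3-level order-respecting metrics distinguishing delta-monotonicity.
DELTA1_3 = np.array([[0, 1, 3], [1, 0, 2], [3, 2, 0]], dtype=float)
DELTA2_3 = np.array([[0, 3, 4], [3, 0, 2], [4, 2, 0]], dtype=float)

# Worked half-monotone error row built from the decay rates
# upsilon(2,0)=2/10, upsilon(2,1)=1/10, omega(2,3)=3/10, omega(2,4)=5/10.
WORKED_ROW = np.array([2, 10, 100, 30, 15], dtype=float) / 157.0


@pytest.fixture
def chain4():
    return LevelSet(("a", "b", "c", "d"))


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def small_structure():
    """A 3-item, 3-level structure with bottom and top."""
    domain = Domain(("q1", "q2", "q3"))
    levels = LevelSet.from_count(3)
    states = [(0, 0, 0), (1, 0, 0), (1, 1, 0), (2, 1, 1), (2, 2, 2)]
    return PolytomousStructure(domain, levels, states)


@pytest.fixture
def recovery_params():
    """A well-identified 5-item, 3-level, 12-state model with strong
    diagonals, suitable for large-sample recovery checks."""
    from polikst import random_structure

    structure = random_structure(5, 3, 12, seed=4)
    gen = np.random.default_rng(1)
    L, Q, S = 3, 5, 12
    eps = gen.dirichlet(np.ones(L), size=(Q, L))
    eps = 0.15 * eps + 0.85 * np.eye(L)[None, :, :]
    eps /= eps.sum(axis=2, keepdims=True)
    pi = gen.dirichlet(np.ones(S) * 5)
    return PolimParameters(structure, eps, pi)


@pytest.fixture
def small_params(small_structure, rng):
    """Random valid parameters on the small structure."""
    Q, L, S = (small_structure.n_items, small_structure.n_levels,
               small_structure.n_states)
    eps = rng.dirichlet(np.ones(L), size=(Q, L))
    # tilt toward the diagonal so simulated data carry signal
    eps = 0.3 * eps + 0.7 * np.eye(L)[None, :, :]
    eps /= eps.sum(axis=2, keepdims=True)
    pi = rng.dirichlet(np.ones(S) * 5)
    return PolimParameters(small_structure, eps, pi)
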