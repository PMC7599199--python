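"""Level metrics, monotonicity conditions, and the rate reparameterization.

For an item with error matrix ``E_q``, several "monotonicity" restrictions
tie the conditional probabilities ``eps_q(i, j)`` to the distance between
levels ``i`` and ``j``:

* *modality*: the true level is modal in its row (Hamming monotonicity);
* *delta-monotonicity*: ``delta(i,j) < delta(i,k)  <=>  f(i,j) > f(i,k)``
  for all level triples, for a level metric ``delta``;
* *delta-half-monotonicity*: the same biconditional restricted to triples
  where ``j`` and ``k`` lie on the same side of ``i`` in the level order;
* *overall error*: each diagonal entry exceeds the sum of its row's
  off-diagonal entries (hence exceeds 1/2).

Half-monotone rows admit an exact reparameterization into overrate/underrate
decay rates in (0, 1): each off-diagonal entry is the neighbouring entry one
step closer to the diagonal times a rate, and the diagonal follows from row
normalization.  This turns the inequality-constrained model into a
box-constrained one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .structures import LevelSet

__all__ = [
    "LevelMetric",
    "PairFunction",
    "RateParameters",
    "hamming_metric",
    "manhattan_metric",
    "check_metric_axioms",
    "is_order_respecting",
    "restricted_triples",
    "is_delta_monotone",
    "is_delta_half_monotone",
    "check_modality",
    "check_overall_error",
    "column_view",
    "rates_to_epsilon",
    "epsilon_to_rates",
]


@dataclass
class LevelMetric:
    """Symmetric nonnegative distance table over level codes.

    The triangle inequality and the order-respecting condition are *not*
    construction invariants (useful dissimilarities may violate them); they
    are checked on demand by :func:`check_metric_axioms` and
    :func:`is_order_respecting`.
    """

    dist: np.ndarray
    name: str = "custom"

    def __post_init__(self):
        d = np.asarray(self.dist, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance table must be square")
        if not np.allclose(d, d.T):
            raise ValueError("distance table must be symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("distances must be zero on the diagonal")
        off = d[~np.eye(d.shape[0], dtype=bool)]
        if np.any(off <= 0):
            raise ValueError("off-diagonal distances must be positive")
        self.dist = d

    @property
    def n_levels(self) -> int:
        return self.dist.shape[0]

    def __call__(self, i: int, j: int) -> float:
        return float(self.dist[i, j])


def hamming_metric(levels: LevelSet | int) -> LevelMetric:
    """0 on the diagonal, 1 everywhere else (the discrete metric)."""
    n = levels if isinstance(levels, int) else len(levels)
    d = 1.0 - np.eye(n)
    return LevelMetric(d, name="hamming")


def manhattan_metric(levels: LevelSet | int) -> LevelMetric:
    """Discrete Manhattan distance ``|i - j|`` on a chain of levels.

    Equals the size of the symmetric difference of the two levels' down
    sets, i.e. the number of chain steps separating them.
    """
    n = levels if isinstance(levels, int) else len(levels)
    idx = np.arange(n)
    d = np.abs(idx[:, None] - idx[None, :]).astype(float)
    return LevelMetric(d, name="manhattan")


def check_metric_axioms(metric: LevelMetric) -> dict:
    """Exhaustive check of symmetry, identity and the triangle inequality.

    Returns a report dict with booleans and witness triples/pairs for every
    failed axiom (symmetry and identity hold by construction here, but are
    re-verified so externally built tables can be audited uniformly).
    """
    d = metric.dist
    n = d.shape[0]
    report = {"symmetry": True, "identity": True, "triangle": True,
              "witnesses": []}
    if not np.allclose(d, d.T):
        report["symmetry"] = False
    if np.any(np.diag(d) != 0):
        report["identity"] = False
    for x in range(n):
        for y in range(n):
            for z in range(n):
                if d[x, z] > d[x, y] + d[y, z]:
                    report["triangle"] = False
                    report["witnesses"].append((x, y, z))
    return report


def is_order_respecting(metric: LevelMetric) -> tuple[bool, list]:
    """``i < j < k  =>  delta(i,k) > max(delta(i,j), delta(j,k))``.

    Returns the verdict and the list of violating increasing triples.
    """
    d = metric.dist
    n = d.shape[0]
    bad = []
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(j + 1, n):
                if not d[i, k] > max(d[i, j], d[j, k]):
                    bad.append((i, j, k))
    return (not bad), bad


def restricted_triples(levels: LevelSet | int) -> list[tuple[int, int, int]]:
    """Triples ``(i, j, k)`` with ``j`` and ``k`` on one side of ``i``.

    The side condition is ``i <= min(j, k)`` or ``max(j, k) < i`` (the upper
    bound reflexive, the lower strict); this one-strict reading reproduces
    the count of 44 such triples out of 64 on a 4-level chain.
    """
    n = levels if isinstance(levels, int) else len(levels)
    out = []
    for i in range(n):
        for j in range(n):
            for k in range(n):
                if (i <= min(j, k)) or (max(j, k) < i):
                    out.append((i, j, k))
    return out


class PairFunction:
    """A possibly partial real-valued function on ordered level pairs."""

    def __init__(self, values: dict[tuple[int, int], float], n_levels: int):
        self.values = {(int(i), int(j)): float(v) for (i, j), v in values.items()}
        self.n_levels = int(n_levels)
        for (i, j) in self.values:
            if not (0 <= i < n_levels and 0 <= j < n_levels):
                raise ValueError(f"pair ({i}, {j}) outside 0..{n_levels - 1}")

    @classmethod
    def from_matrix(cls, mat) -> "PairFunction":
        m = np.asarray(mat, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("pair-function matrix must be square")
        vals = {(i, j): m[i, j] for i in range(m.shape[0]) for j in range(m.shape[1])
                if np.isfinite(m[i, j])}
        return cls(vals, m.shape[0])

    def get(self, i: int, j: int):
        return self.values.get((i, j))

    def transpose(self) -> "PairFunction":
        return PairFunction({(j, i): v for (i, j), v in self.values.items()},
                            self.n_levels)


def _as_pair_function(f) -> PairFunction:
    if isinstance(f, PairFunction):
        return f
    return PairFunction.from_matrix(np.asarray(f, dtype=float))


def _check_triples(f: PairFunction, metric: LevelMetric,
                   triples: Iterable[tuple[int, int, int]]):
    """Test the monotonicity biconditional on the given triples.

    Triples where either needed value of ``f`` is undefined are skipped and
    counted.  Returns (verdict, violations, n_skipped).
    """
    d = metric.dist
    violations = []
    skipped = 0
    for (i, j, k) in triples:
        fij = f.get(i, j)
        fik = f.get(i, k)
        if fij is None or fik is None:
            skipped += 1
            continue
        if (d[i, j] < d[i, k]) != (fij > fik):
            violations.append((i, j, k))
    return (not violations), violations, skipped


def is_delta_monotone(f, metric: LevelMetric) -> tuple[bool, list]:
    """delta-monotonicity over all ``|L|^3`` triples; ties violate.

    ``f`` may be a matrix, a :class:`PairFunction`, or an
    :class:`~polikst.model.ErrorMatrix` (its ``probs`` are used).
    """
    f = _coerce(f)
    n = metric.n_levels
    triples = ((i, j, k) for i in range(n) for j in range(n) for k in range(n))
    ok, bad, _ = _check_triples(f, metric, triples)
    return ok, bad


def is_delta_half_monotone(f, metric: LevelMetric) -> tuple[bool, list]:
    """delta-monotonicity confined to same-side (restricted) triples."""
    f = _coerce(f)
    ok, bad, _ = _check_triples(f, metric, restricted_triples(metric.n_levels))
    return ok, bad


def _coerce(f) -> PairFunction:
    probs = getattr(f, "probs", None)
    if probs is not None:
        return PairFunction.from_matrix(probs)
    return _as_pair_function(f)


def check_modality(E) -> bool:
    """True iff every diagonal entry is the strict row maximum."""
    m = _matrix_of(E)
    n = m.shape[0]
    for i in range(n):
        for j in range(n):
            if j != i and not m[i, i] > m[i, j]:
                return False
    return True


def check_overall_error(E) -> bool:
    """True iff ``eps(i,i) > sum_{j != i} eps(i,j)`` for every row."""
    m = _matrix_of(E)
    diag = np.diag(m)
    off = m.sum(axis=1) - diag
    return bool(np.all(diag > off))


def _matrix_of(E) -> np.ndarray:
    probs = getattr(E, "probs", None)
    return np.asarray(probs if probs is not None else E, dtype=float)


def column_view(E) -> PairFunction:
    """Transposed accessor ``f(i, j) = eps(j, i)``.

    Feeding this to any row checker yields the corresponding column
    monotonicity condition.
    """
    return PairFunction.from_matrix(_matrix_of(E).T)


# ---------------------------------------------------------------------------
# overrate/underrate decay-rate reparameterization
# ---------------------------------------------------------------------------

@dataclass
class RateParameters:
    """Decay rates of one item's error-matrix rows.

    For row ``i`` (the latent level), ``upsilon[i, j]`` with ``j < i`` is the
    underrate decay ``eps(i, j) / eps(i, j+1)`` and ``omega[i, j]`` with
    ``j > i`` is the overrate decay ``eps(i, j) / eps(i, j-1)`` — each ratio
    steps one column further from the diagonal.  Entries outside their
    triangle are NaN.  All defined rates must lie strictly in (0, 1) for the
    row to be half-monotone.
    """

    item: object
    omega: np.ndarray
    upsilon: np.ndarray

    def __post_init__(self):
        self.omega = np.asarray(self.omega, dtype=float)
        self.upsilon = np.asarray(self.upsilon, dtype=float)
        n = self.omega.shape[0]
        if self.omega.shape != (n, n) or self.upsilon.shape != (n, n):
            raise ValueError("omega and upsilon must be square and equal-sized")

    @property
    def n_levels(self) -> int:
        return self.omega.shape[0]

    def defined_rates(self) -> np.ndarray:
        """All defined rates as a flat array (row by row, upsilon then omega)."""
        vals = []
        n = self.n_levels
        for i in range(n):
            vals.extend(self.upsilon[i, j] for j in range(i))
            vals.extend(self.omega[i, j] for j in range(i + 1, n))
        return np.array(vals)

    def in_open_unit_interval(self) -> bool:
        r = self.defined_rates()
        return bool(np.all((r > 0) & (r < 1)))

    @classmethod
    def from_flat(cls, item, values, n_levels: int) -> "RateParameters":
        """Inverse of :meth:`defined_rates`."""
        values = np.asarray(values, dtype=float)
        n = n_levels
        if values.shape != (n * (n - 1),):
            raise ValueError(f"expected {n * (n - 1)} rates, got {values.shape}")
        omega = np.full((n, n), np.nan)
        upsilon = np.full((n, n), np.nan)
        pos = 0
        for i in range(n):
            for j in range(i):
                upsilon[i, j] = values[pos]
                pos += 1
            for j in range(i + 1, n):
                omega[i, j] = values[pos]
                pos += 1
        return cls(item, omega, upsilon)


def rates_to_epsilon(rates: RateParameters):
    """Row-stochastic error matrix generated by decay rates in (0, 1).

    Row ``i`` is built outward from an unnormalized diagonal of 1:
    ``t_j = t_{j+1} * upsilon[i, j]`` going down, ``t_j = t_{j-1} *
    omega[i, j]`` going up; normalizing makes the diagonal
    ``(1 + sum of the off-diagonal products)^{-1}``.  Every row is
    half-monotone by construction.
    """
    from .model import ErrorMatrix  # local import to avoid cycle

    n = rates.n_levels
    r = rates.defined_rates()
    if np.any(~((r > 0) & (r < 1))):
        raise ValueError("all rates must lie strictly in (0, 1)")
    probs = np.empty((n, n))
    for i in range(n):
        t = np.empty(n)
        t[i] = 1.0
        for j in range(i - 1, -1, -1):
            t[j] = t[j + 1] * rates.upsilon[i, j]
        for j in range(i + 1, n):
            t[j] = t[j - 1] * rates.omega[i, j]
        probs[i] = t / t.sum()
    return ErrorMatrix(rates.item, probs)


def epsilon_to_rates(E) -> RateParameters:
    """Exact inverse of :func:`rates_to_epsilon` on positive matrices.

    The recovered rates lie in (0, 1) iff each row is strictly unimodal
    about its diagonal (the half-monotone shape); otherwise some rate falls
    outside and the caller may flag the row.
    """
    m = _matrix_of(E)
    if np.any(m <= 0):
        raise ValueError("epsilon_to_rates requires strictly positive entries")
    n = m.shape[0]
    omega = np.full((n, n), np.nan)
    upsilon = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i):
            upsilon[i, j] = m[i, j] / m[i, j + 1]
        for j in range(i + 1, n):
            omega[i, j] = m[i, j] / m[i, j - 1]
    return RateParameters(getattr(E, "item", None), omega, upsilon)
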