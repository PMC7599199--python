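"""Minimum-discrepancy (MD) estimation of PoLIM parameters.

MD replaces the EM's posterior with the much stronger assumption that a
response pattern can only be generated by the states at *minimum distance*
from it, the distance being the per-item sum of a level metric (Hamming or
Manhattan).  Each observed pattern spreads its frequency uniformly over its
minimum-distance states; the parameter estimates then follow from the same
closed-form count ratios as the complete-data maximizer.  No iteration is
involved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model import PolimParameters
from .monotonicity import LevelMetric
from .structures import PolytomousStructure, ResponseData

__all__ = [
    "MinDistanceAssignment",
    "pattern_state_distance",
    "distance_matrix",
    "min_distance_states",
    "md_fit",
]


def pattern_state_distance(R, K, metric: LevelMetric) -> float:
    """Additive discrepancy ``sum_q metric(R(q), K(q))`` between two points of L^Q."""
    a = np.asarray(R, dtype=np.int64)
    b = np.asarray(K, dtype=np.int64)
    if a.shape != b.shape:
        raise ValueError("pattern and state have different lengths")
    return float(metric.dist[a, b].sum())


def distance_matrix(patterns, states, metric: LevelMetric) -> np.ndarray:
    """All pairwise pattern-state discrepancies, shape (P, S)."""
    pats = np.asarray(patterns, dtype=np.int64)
    sts = np.asarray(states, dtype=np.int64)
    out = np.zeros((pats.shape[0], sts.shape[0]))
    for q in range(pats.shape[1]):
        out += metric.dist[pats[:, q][:, None], sts[:, q][None, :]]
    return out


@dataclass
class MinDistanceAssignment:
    """Minimum-distance states of one pattern (ties all retained)."""

    state_indices: np.ndarray
    distance: float


def min_distance_states(R, structure: PolytomousStructure,
                        metric: LevelMetric) -> MinDistanceAssignment:
    """Exhaustive scan of the structure for the nearest states to ``R``."""
    d = distance_matrix(np.asarray(R)[None, :], structure.states, metric)[0]
    dmin = d.min()
    return MinDistanceAssignment(np.flatnonzero(d == dmin), float(dmin))


def md_fit(data: ResponseData, structure: PolytomousStructure,
           metric: LevelMetric) -> PolimParameters:
    """Closed-form MD estimates under uniform weighting of tied states.

    With ``u(K|R)`` uniform over the minimum-distance set of ``R``:

    * ``pi_K = sum_R n_R u(K|R) / N``
    * ``eps_q(i,j) = [sum_R n_R sum_{K: K(q)=i, R(q)=j} u(K|R)]
      / [sum_R n_R sum_{K: K(q)=i} u(K|R)]``

    Error-matrix rows whose latent level receives no mass fall back to the
    uniform row ``1/|L|`` and are reported via a warning.
    """
    if data.patterns.shape[1] != structure.n_items:
        raise ValueError("data and structure have different numbers of items")
    D = distance_matrix(data.patterns, structure.states, metric)
    is_min = D == D.min(axis=1, keepdims=True)
    U = is_min / is_min.sum(axis=1, keepdims=True)
    W = data.frequencies[:, None] * U
    pi = W.sum(axis=0) / data.n

    L, Q = structure.n_levels, structure.n_items
    eps = np.empty((Q, L, L))
    eye = np.eye(L)
    fallback_rows = []
    for q in range(Q):
        s1h = eye[structure.states[:, q]]
        p1h = eye[data.patterns[:, q]]
        counts = (p1h.T @ (W @ s1h)).T  # rows = latent level i
        row_tot = counts.sum(axis=1)
        for i in range(L):
            if row_tot[i] > 0:
                eps[q, i] = counts[i] / row_tot[i]
            else:
                eps[q, i] = 1.0 / L
                fallback_rows.append((structure.domain.items[q], i))
    if fallback_rows:
        warnings.warn(
            "uniform fallback for error rows with no minimum-distance mass: "
            f"{fallback_rows}", stacklevel=2,
        )
    return PolimParameters(structure, eps, pi)
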