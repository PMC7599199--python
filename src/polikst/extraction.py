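"""Data-driven extraction of polytomous structures by k-median clustering.

Candidate structures are grown by an ordinal k-median: observed response
patterns are assigned to their nearest centroid under the per-item Manhattan
sum, and each centroid is replaced by the component-wise (lower) median of
its assigned patterns, iterated to a fixed point.  Among candidates the best
structure is the one minimizing the larger of the two asymmetric
discrepancies between a validation sample ``D2`` and the structure ``K``:
the respondent-averaged distance from each pattern to its nearest state, and
the state-averaged distance from each state to its nearest observed pattern
(the minimax criterion).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .md import distance_matrix
from .monotonicity import manhattan_metric
from .structures import PolytomousStructure, ResponseData

__all__ = [
    "SplitPlan",
    "ExtractionResult",
    "split_data",
    "kmedian_extract",
    "discrepancy_data_to_structure",
    "discrepancy_structure_to_data",
    "minimax_select",
    "extraction_pipeline",
]


@dataclass
class SplitPlan:
    """Disjoint exhaustive respondent indices for extraction/validation/test."""

    extraction: np.ndarray
    validation: np.ndarray
    test: np.ndarray
    seed: int | None = None


def split_data(data: ResponseData, seed: int | np.random.Generator,
               test_size: int = 0,
               validation_fraction: float = 1 / 3) -> SplitPlan:
    """Random respondent-level partition into D1 (extraction), D2, D0."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = data.n
    if not 0 <= test_size < n:
        raise ValueError("test_size must lie in [0, N)")
    perm = rng.permutation(n)
    test = perm[:test_size]
    rest = perm[test_size:]
    n_val = int(round(len(rest) * validation_fraction))
    if n_val == 0 or n_val == len(rest):
        raise ValueError("validation split would be empty or exhaustive")
    return SplitPlan(extraction=np.sort(rest[n_val:]),
                     validation=np.sort(rest[:n_val]), test=np.sort(test))


def _weighted_lower_median(values: np.ndarray, weights: np.ndarray) -> int:
    """Lower median of an integer multiset given by values/weights."""
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cum = np.cumsum(w)
    total = cum[-1]
    target = (total + 1) // 2  # position of the lower median, 1-based
    return int(v[np.searchsorted(cum, target)])


def kmedian_extract(data: ResponseData, initial_centroids,
                    max_iter: int = 100) -> PolytomousStructure:
    """Ordinal k-median clustering of response patterns.

    Alternates pattern classification (nearest centroid under the Manhattan
    sum, ties to the lowest-index centroid) and centroid adjustment
    (component-wise weighted lower median of the assigned patterns, an exact
    coordinate-wise minimizer of the within-cluster Manhattan discrepancy).
    Empty clusters are dropped; stops at a fixed point or ``max_iter``.
    Returns the distinct final centroids as a structure.
    """
    if data.n_patterns == 0:
        raise ValueError("empty data")
    cents = np.asarray(initial_centroids, dtype=np.int64)
    n_lv = (len(data.levels) if data.levels is not None
            else int(max(data.patterns.max(), cents.max())) + 1)
    metric = manhattan_metric(n_lv)
    if cents.ndim != 2 or cents.shape[1] != data.patterns.shape[1]:
        raise ValueError("centroids must conform to the data's items")
    pats, freqs = data.patterns, data.frequencies
    prev_assign = None
    for _ in range(max_iter):
        D = distance_matrix(pats, cents, metric)
        assign = D.argmin(axis=1)  # argmin takes the lowest index on ties
        new_cents = []
        for c in range(cents.shape[0]):
            mask = assign == c
            if not mask.any():
                continue  # empty cluster dropped
            new_cents.append([
                _weighted_lower_median(pats[mask, q], freqs[mask])
                for q in range(pats.shape[1])
            ])
        new_cents = np.asarray(new_cents, dtype=np.int64)
        if (new_cents.shape == cents.shape and np.array_equal(new_cents, cents)
                and prev_assign is not None
                and np.array_equal(assign, prev_assign)):
            break
        cents, prev_assign = new_cents, assign
    distinct = np.unique(cents, axis=0)
    from .structures import LevelSet
    return PolytomousStructure(data.domain, LevelSet.from_count(n_lv),
                               distinct)


def discrepancy_data_to_structure(D: ResponseData,
                                  structure: PolytomousStructure) -> float:
    """Frequency-weighted mean over respondents of the min Manhattan distance to K."""
    metric = manhattan_metric(structure.n_levels)
    dm = distance_matrix(D.patterns, structure.states, metric)
    return float((D.frequencies @ dm.min(axis=1)) / D.n)


def discrepancy_structure_to_data(structure: PolytomousStructure,
                                  D: ResponseData) -> float:
    """Mean over states of the min Manhattan distance to a distinct observed pattern."""
    metric = manhattan_metric(structure.n_levels)
    dm = distance_matrix(D.patterns, structure.states, metric)
    return float(dm.min(axis=0).mean())


@dataclass
class ExtractionResult:
    """Candidate structures with their discrepancy pairs and the minimax pick."""

    structures: list[PolytomousStructure]
    discrepancies: list[tuple[float, float]]  # (delta(D2, K), delta(K, D2))
    selected: int
    z: float

    @property
    def selected_structure(self) -> PolytomousStructure:
        return self.structures[self.selected]


def minimax_select(candidates, D2: ResponseData) -> ExtractionResult:
    """Pick the candidate minimizing ``max(delta(D2,K), delta(K,D2))``.

    Ties are broken by smaller structure size, then by input order.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("at least one candidate structure is required")
    pairs = []
    for K in candidates:
        pairs.append((discrepancy_data_to_structure(D2, K),
                      discrepancy_structure_to_data(K, D2)))
    keys = [(max(p), len(K)) for p, K in zip(pairs, candidates)]
    selected = min(range(len(candidates)), key=lambda i: keys[i])
    return ExtractionResult(candidates, pairs, selected,
                            z=float(max(pairs[selected])))


def extraction_pipeline(data: ResponseData, n_partitions: int,
                        centroid_sizes, seed: int,
                        test_size: int = 0,
                        validation_fraction: float = 1 / 3,
                        max_iter: int = 100) -> ExtractionResult:
    """Full extract-and-select pipeline.

    For each random partition and each initial-centroid cardinality, sample
    initial centroids without replacement from the distinct observed
    patterns of the extraction set, run k-median, and score the result on
    that partition's validation set; the minimax winner over the whole grid
    is returned.  Fully seeded.
    """
    rng = np.random.default_rng(seed)
    centroid_sizes = [int(s) for s in centroid_sizes]
    candidates: list[PolytomousStructure] = []
    pairs: list[tuple[float, float]] = []
    for _ in range(int(n_partitions)):
        plan = split_data(data, rng, test_size=test_size,
                          validation_fraction=validation_fraction)
        d1 = data.subset(plan.extraction)
        d2 = data.subset(plan.validation)
        for size in centroid_sizes:
            if size > d1.n_patterns:
                raise ValueError(
                    f"centroid size {size} exceeds the {d1.n_patterns} "
                    "distinct patterns of the extraction set"
                )
            pick = rng.choice(d1.n_patterns, size=size, replace=False)
            K = kmedian_extract(d1, d1.patterns[pick], max_iter=max_iter)
            candidates.append(K)
            pairs.append((discrepancy_data_to_structure(d2, K),
                          discrepancy_structure_to_data(K, d2)))
    keys = [(max(p), len(K)) for p, K in zip(pairs, candidates)]
    selected = min(range(len(candidates)), key=lambda i: keys[i])
    return ExtractionResult(candidates, pairs, selected,
                            z=float(max(pairs[selected])))
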