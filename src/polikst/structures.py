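"""Items, ordered level sets, polytomous states and structures.

A polytomous knowledge (or belief) state assigns to every item ``q`` of a
domain ``Q`` a response level drawn from a finite chain ``L``; it is a point
of the product lattice ``L^Q``.  A polytomous structure is a finite nonempty
set of such states.  States are stored as integer vectors of 0-based level
codes; arbitrary ordered level labels are mapped to codes on read.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "LevelSet",
    "Domain",
    "PolytomousStructure",
    "ResponseData",
    "pointwise_leq",
    "enumerate_patterns",
    "random_structure",
    "state_to_string",
    "state_from_string",
]

#: Largest |L|^|Q| that enumerate_patterns will materialize by default.
DEFAULT_ENUMERATION_CAP = 2_000_000


@dataclass(frozen=True)
class LevelSet:
    """A finite chain of response levels, coded internally as ``0..n``.

    Parameters
    ----------
    labels : tuple
        Ordered level identifiers ``l_0 < l_1 < ... < l_n``.  At least two
        levels are required and labels must be distinct.
    """

    labels: tuple

    def __post_init__(self):
        object.__setattr__(self, "labels", tuple(self.labels))
        if len(self.labels) < 2:
            raise ValueError("a level set needs at least 2 levels")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("level labels must be distinct")

    @classmethod
    def from_count(cls, n_levels: int) -> "LevelSet":
        """Level set ``0, 1, ..., n_levels-1`` with integer labels."""
        return cls(tuple(range(int(n_levels))))

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def codes(self) -> range:
        return range(len(self.labels))

    def code_of(self, label) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown level label {label!r}") from None


@dataclass(frozen=True)
class Domain:
    """An ordered, nonempty sequence of distinct item identifiers."""

    items: tuple

    def __post_init__(self):
        object.__setattr__(self, "items", tuple(self.items))
        if not self.items:
            raise ValueError("domain must be nonempty")
        if len(set(self.items)) != len(self.items):
            raise ValueError("item identifiers must be distinct")

    @classmethod
    def from_count(cls, n_items: int) -> "Domain":
        return cls(tuple(f"q{i + 1}" for i in range(int(n_items))))

    def __len__(self) -> int:
        return len(self.items)

    def index_of(self, item) -> int:
        try:
            return self.items.index(item)
        except ValueError:
            raise KeyError(f"unknown item {item!r}") from None


def _as_state_array(state, n_items: int, n_levels: int) -> np.ndarray:
    arr = np.asarray(state, dtype=np.int64)
    if arr.shape != (n_items,):
        raise ValueError(
            f"state has {arr.shape} entries, domain has {n_items} items"
        )
    if arr.min(initial=0) < 0 or arr.max(initial=0) >= n_levels:
        raise ValueError(f"state levels must lie in 0..{n_levels - 1}: {arr}")
    return arr


def pointwise_leq(k1, k2) -> bool:
    """Pointwise order on ``L^Q``: ``k1 ⊑ k2`` iff ``k1(q) <= k2(q)`` for all q."""
    a = np.asarray(k1, dtype=np.int64)
    b = np.asarray(k2, dtype=np.int64)
    if a.shape != b.shape:
        raise ValueError(f"states live on different domains: {a.shape} vs {b.shape}")
    return bool(np.all(a <= b))


def state_to_string(state: Sequence[int], n_levels: int) -> str:
    """Serialize a state; digit string when codes fit one digit, else CSV."""
    codes = [int(c) for c in state]
    if n_levels <= 10:
        return "".join(str(c) for c in codes)
    return ",".join(str(c) for c in codes)


def state_from_string(s: str, n_items: int, n_levels: int) -> tuple:
    if "," in s:
        codes = tuple(int(t) for t in s.split(","))
    else:
        codes = tuple(int(ch) for ch in s)
    if len(codes) != n_items:
        raise ValueError(f"state string {s!r} does not match {n_items} items")
    if any(c < 0 or c >= n_levels for c in codes):
        raise ValueError(f"state string {s!r} has levels outside 0..{n_levels - 1}")
    return codes


class PolytomousStructure:
    """A finite nonempty set of polytomous states over a shared domain.

    Attributes
    ----------
    domain : Domain
    levels : LevelSet
    states : ndarray of shape (|K|, |Q|)
        Distinct state vectors, stored in the order given.
    """

    def __init__(self, domain: Domain, levels: LevelSet, states: Iterable):
        self.domain = domain
        self.levels = levels
        rows = [
            _as_state_array(s, len(domain), len(levels)) for s in states
        ]
        if not rows:
            raise ValueError("a structure must contain at least one state")
        arr = np.vstack(rows)
        tuples = [tuple(r) for r in arr]
        if len(set(tuples)) != len(tuples):
            raise ValueError("states in a structure must be pairwise distinct")
        self.states = arr
        self._index = {t: i for i, t in enumerate(tuples)}

    @property
    def n_states(self) -> int:
        return self.states.shape[0]

    @property
    def n_items(self) -> int:
        return len(self.domain)

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def __len__(self) -> int:
        return self.n_states

    def __contains__(self, state) -> bool:
        return tuple(int(c) for c in np.asarray(state)) in self._index

    def index_of(self, state) -> int:
        key = tuple(int(c) for c in np.asarray(state))
        if key not in self._index:
            raise KeyError(f"state {key} not in structure")
        return self._index[key]

    def state_strings(self) -> list[str]:
        return [state_to_string(s, self.n_levels) for s in self.states]

    def __repr__(self) -> str:
        return (
            f"PolytomousStructure(|Q|={self.n_items}, |L|={self.n_levels}, "
            f"|K|={self.n_states})"
        )


class ResponseData:
    """Aggregated response patterns with nonnegative integer frequencies."""

    def __init__(self, patterns, frequencies, domain: Domain | None = None,
                 levels: LevelSet | None = None):
        pats = np.asarray(patterns, dtype=np.int64)
        if pats.ndim != 2:
            raise ValueError("patterns must be a 2-d array (pattern x item)")
        freqs = np.asarray(frequencies, dtype=np.int64)
        if freqs.shape != (pats.shape[0],):
            raise ValueError("one frequency per pattern required")
        if np.any(freqs < 0):
            raise ValueError("frequencies must be nonnegative")
        tuples = [tuple(r) for r in pats]
        if len(set(tuples)) != len(tuples):
            raise ValueError("patterns must be distinct (aggregate first)")
        if freqs.sum() < 1:
            raise ValueError("total sample size must be at least 1")
        self.patterns = pats
        self.frequencies = freqs
        self.domain = domain if domain is not None else Domain.from_count(pats.shape[1])
        self.levels = levels
        if len(self.domain) != pats.shape[1]:
            raise ValueError("domain size does not match pattern length")

    @classmethod
    def from_responses(cls, responses, domain: Domain | None = None,
                       levels: LevelSet | None = None) -> "ResponseData":
        """Aggregate a respondent-by-item table into distinct patterns."""
        arr = np.asarray(responses, dtype=np.int64)
        if arr.ndim != 2 or arr.shape[0] == 0:
            raise ValueError("responses must be a nonempty 2-d table")
        pats, counts = np.unique(arr, axis=0, return_counts=True)
        return cls(pats, counts, domain=domain, levels=levels)

    @property
    def n(self) -> int:
        """Total number of respondents."""
        return int(self.frequencies.sum())

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[0]

    def expand(self) -> np.ndarray:
        """Respondent-level table (one row per respondent)."""
        return np.repeat(self.patterns, self.frequencies, axis=0)

    def subset(self, respondent_indices) -> "ResponseData":
        """New ResponseData from a selection of (expanded) respondent rows."""
        rows = self.expand()[np.asarray(respondent_indices, dtype=np.int64)]
        return ResponseData.from_responses(rows, domain=self.domain,
                                           levels=self.levels)

    def __repr__(self) -> str:
        return f"ResponseData(N={self.n}, distinct={self.n_patterns})"


def enumerate_patterns(domain: Domain, levels: LevelSet,
                       cap: int = DEFAULT_ENUMERATION_CAP) -> np.ndarray:
    """All ``|L|^|Q|`` patterns in lexicographic order, as an array.

    Refuses (with an explicit error) when the full product would exceed
    ``cap`` rows; brute-force consumers should stay well below it.
    """
    n_items, n_levels = len(domain), len(levels)
    total = n_levels ** n_items
    if total > cap:
        raise ValueError(
            f"|L|^|Q| = {n_levels}^{n_items} = {total} exceeds the "
            f"enumeration cap of {cap}"
        )
    out = np.array(
        list(itertools.product(range(n_levels), repeat=n_items)),
        dtype=np.int64,
    ).reshape(total, n_items)
    return out


def random_structure(num_items: int, num_levels: int, size: int,
                     seed: int | np.random.Generator) -> PolytomousStructure:
    """Random structure containing the bottom and top states.

    Draws ``size - 2`` further states uniformly without replacement from
    ``L^Q \\ {bottom, top}`` by rejection on a seeded stream, so the full
    product is never materialized.  Deterministic given ``seed``.
    """
    num_items, num_levels, size = int(num_items), int(num_levels), int(size)
    total = num_levels ** num_items
    if size < 2 or size > total:
        raise ValueError(
            f"size must satisfy 2 <= size <= |L|^|Q| = {total}, got {size}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    domain = Domain.from_count(num_items)
    levels = LevelSet.from_count(num_levels)
    bottom = (0,) * num_items
    top = (num_levels - 1,) * num_items
    chosen: dict = {bottom: None, top: None}
    target = size
    # Rejection sampling; for nearly-exhaustive sizes fall back to enumeration.
    if size > 0.5 * total:
        all_pats = enumerate_patterns(domain, levels)
        order = rng.permutation(total)
        for idx in order:
            if len(chosen) == target:
                break
            chosen.setdefault(tuple(all_pats[idx]), None)
    else:
        while len(chosen) < target:
            batch = rng.integers(0, num_levels, size=(max(64, target), num_items))
            for row in batch:
                t = tuple(int(c) for c in row)
                if t not in chosen:
                    chosen[t] = None
                    if len(chosen) == target:
                        break
    states = list(chosen.keys())
    return PolytomousStructure(domain, levels, states)
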