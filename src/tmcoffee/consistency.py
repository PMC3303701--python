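"""Constraint library construction and T-Coffee triplet extension.

The primary library is the union, over all unordered profile pairs, of the
residue-pair constraints whose pair-HMM posterior clears the threshold.
Extension relays support through third sequences: the extended weight of
(A,i,B,j) adds, for every other sequence C and position k, the minimum of
the two weights on the legs (A,i,C,k) and (C,k,B,j).
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from typing import Iterable, Mapping

import numpy as np

from .errors import DataError
from .pairhmm import PairHmmParams, extract_constraints, forward_backward


class ConstraintLibrary:
    """Weighted residue-pair constraints between input sequences.

    Weights are non-negative integers; storage is canonical on the order in
    which sequence ids were registered, and lookups are symmetric.
    """

    def __init__(self, lengths: Mapping[str, int]):
        self.lengths: dict[str, int] = dict(lengths)
        self._order = {sid: k for k, sid in enumerate(self.lengths)}
        # (idA, idB) with idA before idB in registration order -> {(i, j): w}
        self._pairs: dict[tuple[str, str], dict[tuple[int, int], int]] = {}

    def _canon(self, a: str, i: int, b: str, j: int):
        if a not in self._order:
            raise DataError(f"unknown sequence id {a!r}")
        if b not in self._order:
            raise DataError(f"unknown sequence id {b!r}")
        if a == b:
            raise DataError(f"self-pair constraint on {a!r}")
        if not (0 <= i < self.lengths[a]):
            raise DataError(f"position {i} outside sequence {a!r}")
        if not (0 <= j < self.lengths[b]):
            raise DataError(f"position {j} outside sequence {b!r}")
        if self._order[a] <= self._order[b]:
            return (a, b), (i, j)
        return (b, a), (j, i)

    def add(self, a: str, i: int, b: str, j: int, weight: int) -> None:
        if weight < 0:
            raise DataError("constraint weights must be non-negative")
        key, pos = self._canon(a, i, b, j)
        self._pairs.setdefault(key, {})[pos] = int(weight)

    def weight(self, a: str, i: int, b: str, j: int) -> int:
        key, pos = self._canon(a, i, b, j)
        return self._pairs.get(key, {}).get(pos, 0)

    def pair_items(self, a: str, b: str) -> list[tuple[int, int, int]]:
        """Constraints between a and b, oriented as (pos_a, pos_b, weight)."""
        key, _ = self._canon(a, 0, b, 0)
        items = self._pairs.get(key, {})
        if key == (a, b):
            return [(i, j, w) for (i, j), w in items.items()]
        return [(j, i, w) for (i, j), w in items.items()]

    def ids(self) -> list[str]:
        return list(self.lengths)

    def n_constraints(self) -> int:
        return sum(len(d) for d in self._pairs.values())

    def copy(self) -> "ConstraintLibrary":
        out = ConstraintLibrary(self.lengths)
        for key, d in self._pairs.items():
            out._pairs[key] = dict(d)
        return out

    def __eq__(self, other) -> bool:
        if not isinstance(other, ConstraintLibrary):
            return NotImplemented
        return (self.lengths == other.lengths
                and {k: v for k, v in self._pairs.items() if v}
                == {k: v for k, v in other._pairs.items() if v})


def pair_score(lib: ConstraintLibrary, idA: str, posA: int,
               idB: str, posB: int) -> int:
    """Stored weight of (idA,posA,idB,posB), or 0 when absent."""
    return lib.weight(idA, posA, idB, posB)


def build_primary_library(profiles: Mapping[str, "object"],
                          params: PairHmmParams | None = None,
                          threshold: float = 0.99,
                          occupancy: bool = True,
                          threads: int = 1) -> ConstraintLibrary:
    """Pair-HMM every unordered profile pair and pool the thresholded
    posterior constraints into one symmetric library."""
    if len(profiles) < 2:
        raise DataError("need at least two profiles to build a library")
    params = params or PairHmmParams.default()
    ids = list(profiles)
    lib = ConstraintLibrary({sid: len(profiles[sid].query) for sid in ids})
    pairs = [(ids[x], ids[y]) for x in range(len(ids))
             for y in range(x + 1, len(ids))]

    def one(pair):
        a, b = pair
        post = forward_backward(profiles[a], profiles[b], params,
                                occupancy=occupancy)
        return extract_constraints(post, a, b, threshold=threshold)

    if threads > 1:
        with ThreadPoolExecutor(max_workers=threads) as ex:
            results = list(ex.map(one, pairs))
    else:
        results = [one(p) for p in pairs]
    for (a, b), constraints in zip(pairs, results):
        for i, j, w in constraints:
            lib.add(a, i, b, j, w)
    return lib


def extended_pair_weights(lib: ConstraintLibrary, idA: str, idB: str
                          ) -> dict[tuple[int, int], int]:
    """Extended weights between two sequences, computed lazily: primary
    weight plus min-weight relays through every third sequence."""
    acc: dict[tuple[int, int], int] = {}
    for i, j, w in lib.pair_items(idA, idB):
        acc[(i, j)] = w
    for mid in lib.ids():
        if mid == idA or mid == idB:
            continue
        left: dict[int, list[tuple[int, int]]] = {}
        for i, k, w in lib.pair_items(idA, mid):
            left.setdefault(k, []).append((i, w))
        if not left:
            continue
        for k, j, w2 in lib.pair_items(mid, idB):
            for i, w1 in left.get(k, ()):
                key = (i, j)
                acc[key] = acc.get(key, 0) + min(w1, w2)
    return acc


def extended_pair_matrix(lib: ConstraintLibrary, idA: str, idB: str
                         ) -> np.ndarray:
    """Dense (lenA x lenB) matrix of extended weights."""
    W = np.zeros((lib.lengths[idA], lib.lengths[idB]), dtype=np.int64)
    for (i, j), w in extended_pair_weights(lib, idA, idB).items():
        W[i, j] = w
    return W


def extend_library(lib: ConstraintLibrary) -> ConstraintLibrary:
    """Eager triplet extension of the whole library (identical by
    construction to the lazy per-pair computation)."""
    out = ConstraintLibrary(lib.lengths)
    ids = lib.ids()
    for x in range(len(ids)):
        for y in range(x + 1, len(ids)):
            a, b = ids[x], ids[y]
            for (i, j), w in extended_pair_weights(lib, a, b).items():
                if w > 0:
                    out.add(a, i, b, j, w)
    return out


def total_pair_weight(lib: ConstraintLibrary, idA: str, idB: str) -> int:
    return sum(w for _, _, w in lib.pair_items(idA, idB))
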