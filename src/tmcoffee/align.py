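"""Guide-tree construction and progressive consistency alignment.

The aligner carries no gap penalty: all positional signal comes from the
extended library weights, as in classic consistency-based progressive
alignment.  Sub-alignment columns are scored by the average extended weight
over the contributing (non-gap) row pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from . import _hmm_core
from .consistency import (ConstraintLibrary, build_primary_library,
                          extended_pair_matrix, total_pair_weight)
from .errors import DataError
from .extension import ExtendedProfile, FilterParams, extend_all
from .formats import GAP, MultipleAlignment, Sequence
from .pairhmm import PairHmmParams

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# guide tree

@dataclass(frozen=True)
class GuideTree:
    """Rooted binary merge tree; leaves are sequence ids."""

    label: str | None = None
    left: "GuideTree | None" = None
    right: "GuideTree | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.label is not None

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        return self.left.leaves() + self.right.leaves()

    def newick(self) -> str:
        def fmt(node):
            if node.is_leaf:
                return node.label
            return f"({fmt(node.left)},{fmt(node.right)})"
        return fmt(self) + ";"


def library_distance(lib: ConstraintLibrary, a: str, b: str) -> float:
    """1 - normalized library score; the normalization divides the summed
    pair weights by 100 x min(lenA, lenB)."""
    norm = 100.0 * min(lib.lengths[a], lib.lengths[b])
    score = total_pair_weight(lib, a, b) / norm
    return 1.0 - min(1.0, score)


def build_guide_tree(lib: ConstraintLibrary,
                     distances: Mapping[tuple[str, str], float] | None = None
                     ) -> GuideTree:
    """UPGMA over library distances with deterministic lexicographic
    tie-breaks (ties merge the lexicographically smallest cluster pair)."""
    ids = lib.ids()
    if len(ids) < 2:
        raise DataError("guide tree needs at least 2 sequences")
    if distances is None:
        distances = {}
        for x in range(len(ids)):
            for y in range(x + 1, len(ids)):
                a, b = ids[x], ids[y]
                distances[(a, b)] = library_distance(lib, a, b)

    def dist(a: str, b: str) -> float:
        if (a, b) in distances:
            return distances[(a, b)]
        return distances[(b, a)]

    # cluster: (lexicographically smallest member, members, node, size)
    clusters: list[tuple[str, GuideTree, list[str]]] = [
        (sid, GuideTree(label=sid), [sid]) for sid in ids]
    d = {(ci[0], cj[0]): dist(ci[0], cj[0])
         for x, ci in enumerate(clusters) for cj in clusters[x + 1:]}
    cd = {}
    for x in range(len(clusters)):
        for y in range(x + 1, len(clusters)):
            a, mbrs_a = clusters[x][0], clusters[x][2]
            b, mbrs_b = clusters[y][0], clusters[y][2]
            cd[frozenset((a, b))] = float(np.mean(
                [dist(p, q) for p in mbrs_a for q in mbrs_b]))

    keys = {c[0] for c in clusters}
    by_key = {c[0]: c for c in clusters}
    while len(keys) > 1:
        best = None
        for ka in sorted(keys):
            for kb in sorted(keys):
                if ka >= kb:
                    continue
                cand = (cd[frozenset((ka, kb))], ka, kb)
                if best is None or cand < best:
                    best = cand
        _, ka, kb = best
        a_key, a_node, a_mbrs = by_key[ka]
        b_key, b_node, b_mbrs = by_key[kb]
        new_key = min(a_key, b_key)
        new_node = GuideTree(left=a_node, right=b_node)
        new_mbrs = a_mbrs + b_mbrs
        keys.discard(ka)
        keys.discard(kb)
        del by_key[ka], by_key[kb]
        # UPGMA average linkage, weighted by cluster sizes
        for other in keys:
            o_mbrs = by_key[other][2]
            da = cd.pop(frozenset((ka, other)))
            db = cd.pop(frozenset((kb, other)))
            new_d = (da * len(a_mbrs) + db * len(b_mbrs)) / len(new_mbrs)
            cd[frozenset((new_key, other))] = new_d
        cd.pop(frozenset((ka, kb)), None)
        keys.add(new_key)
        by_key[new_key] = (new_key, new_node, new_mbrs)
    return by_key[next(iter(keys))][1]


# ---------------------------------------------------------------------------
# library-driven DP over sub-alignment columns

class LibraryScorer:
    """Caches dense extended-weight matrices per sequence pair."""

    def __init__(self, lib: ConstraintLibrary):
        self.lib = lib
        self._cache: dict[tuple[str, str], np.ndarray] = {}

    def matrix(self, a: str, b: str) -> np.ndarray:
        if (a, b) in self._cache:
            return self._cache[(a, b)]
        if (b, a) in self._cache:
            return self._cache[(b, a)].T
        W = extended_pair_matrix(self.lib, a, b)
        self._cache[(a, b)] = W
        return W


def _position_maps(msa: MultipleAlignment):
    """Per row: column -> residue index (-1 at gaps)."""
    pos = {}
    for sid, row in zip(msa.ids, msa.rows):
        p = np.full(len(row), -1, dtype=np.int64)
        k = 0
        for c, ch in enumerate(row):
            if ch != GAP:
                p[c] = k
                k += 1
        pos[sid] = p
    return pos


def column_score_matrix(subA: MultipleAlignment, subB: MultipleAlignment,
                        scorer: LibraryScorer) -> np.ndarray:
    """Average extended weight over contributing row pairs, per column pair."""
    la, lb = subA.ncols, subB.ncols
    total = np.zeros((la, lb))
    count = np.zeros((la, lb))
    posA = _position_maps(subA)
    posB = _position_maps(subB)
    for a in subA.ids:
        pa = posA[a]
        ma = pa >= 0
        ia = np.nonzero(ma)[0]
        for b in subB.ids:
            pb = posB[b]
            ib = np.nonzero(pb >= 0)[0]
            if ia.size == 0 or ib.size == 0:
                continue
            W = scorer.matrix(a, b)
            total[np.ix_(ia, ib)] += W[np.ix_(pa[ia], pb[ib])]
            count[np.ix_(ia, ib)] += 1
    with np.errstate(invalid="ignore"):
        S = np.where(count > 0, total / np.maximum(count, 1), 0.0)
    return S


def _merge(subA: MultipleAlignment, subB: MultipleAlignment,
           path: np.ndarray) -> MultipleAlignment:
    rowsA = [[] for _ in subA.ids]
    rowsB = [[] for _ in subB.ids]
    i = j = 0
    for mv in path:
        if mv == 0:
            for r, row in zip(rowsA, subA.rows):
                r.append(row[i])
            for r, row in zip(rowsB, subB.rows):
                r.append(row[j])
            i += 1
            j += 1
        elif mv == 1:  # consume an A column, gap in B
            for r, row in zip(rowsA, subA.rows):
                r.append(row[i])
            for r in rowsB:
                r.append(GAP)
            i += 1
        else:          # consume a B column, gap in A
            for r in rowsA:
                r.append(GAP)
            for r, row in zip(rowsB, subB.rows):
                r.append(row[j])
            j += 1
    return MultipleAlignment(
        subA.ids + subB.ids,
        tuple("".join(r) for r in rowsA) + tuple("".join(r) for r in rowsB))


def align_pair_of_subalignments(subA: MultipleAlignment,
                                subB: MultipleAlignment,
                                scorer: LibraryScorer | ConstraintLibrary
                                ) -> MultipleAlignment:
    """Merge two sub-alignments by global DP over their columns, maximizing
    summed average library weight; no gap penalty.  Tie-break prefers match
    over gap-in-B over gap-in-A."""
    if set(subA.ids) & set(subB.ids):
        raise DataError("sub-alignments share sequence ids")
    if isinstance(scorer, ConstraintLibrary):
        scorer = LibraryScorer(scorer)
    S = column_score_matrix(subA, subB, scorer)
    _, path = _hmm_core.consistency_dp(S)
    return _merge(subA, subB, np.asarray(path))


def progressive_align(tree: GuideTree,
                      scorer: LibraryScorer | ConstraintLibrary,
                      order: list[str] | None = None) -> MultipleAlignment:
    """Post-order traversal of the guide tree; final rows follow ``order``
    (defaults to the tree's leaf order)."""
    if isinstance(scorer, ConstraintLibrary):
        scorer = LibraryScorer(scorer)
    leaf_rows = getattr(scorer, "leaf_rows", None)
    if leaf_rows is None:
        raise DataError("scorer lacks leaf residue rows; use align_sequences")

    def walk(node: GuideTree) -> MultipleAlignment:
        if node.is_leaf:
            return MultipleAlignment((node.label,), (leaf_rows[node.label],))
        return align_pair_of_subalignments(walk(node.left), walk(node.right),
                                           scorer)

    msa = walk(tree)
    if order is not None:
        msa = msa.reorder(order)
    return msa


def align_sequences(sequences: list[Sequence],
                    lib: ConstraintLibrary,
                    tree: GuideTree | None = None) -> MultipleAlignment:
    """Progressive alignment of full sequences under a constraint library."""
    scorer = LibraryScorer(lib)
    scorer.leaf_rows = {s.id: s.residues for s in sequences}
    if tree is None:
        tree = build_guide_tree(lib)
    return progressive_align(tree, scorer, order=[s.id for s in sequences])


# ---------------------------------------------------------------------------
# scoring and refinement

def total_library_score(msa: MultipleAlignment, scorer: LibraryScorer) -> int:
    """Sum of extended weights over all co-columned residue pairs."""
    pos = _position_maps(msa)
    total = 0
    ids = list(msa.ids)
    for x in range(len(ids)):
        pa = pos[ids[x]]
        for y in range(x + 1, len(ids)):
            pb = pos[ids[y]]
            both = (pa >= 0) & (pb >= 0)
            if not both.any():
                continue
            W = scorer.matrix(ids[x], ids[y])
            total += int(W[pa[both], pb[both]].sum())
    return total


def refine(msa: MultipleAlignment, lib: ConstraintLibrary,
           rounds: int = 0) -> MultipleAlignment:
    """Leave-one-out iterative refinement; a realignment is accepted only if
    the total library score does not decrease.  ``rounds=0`` disables."""
    if rounds <= 0:
        return msa
    scorer = LibraryScorer(lib)
    current = msa
    best_score = total_library_score(current, scorer)
    for _ in range(rounds):
        improved = False
        for sid in sorted(current.ids):
            rest_ids = [s for s in current.ids if s != sid]
            rest = MultipleAlignment(
                tuple(rest_ids), tuple(current.row(s) for s in rest_ids)
            ).drop_all_gap_columns()
            single = MultipleAlignment((sid,),
                                       (current.row(sid).replace(GAP, ""),))
            candidate = align_pair_of_subalignments(rest, single, scorer)
            candidate = candidate.reorder(current.ids)
            score = total_library_score(candidate, scorer)
            # strict improvement only: accepting equal-score shuffles can
            # cycle without converging
            if score > best_score:
                improved = True
                best_score = score
                current = candidate.drop_all_gap_columns()
        if not improved:
            break
    return current


# ---------------------------------------------------------------------------
# end-to-end pipeline

def tmcoffee_align(sequences: list[Sequence], database=None, *,
                   params: PairHmmParams | None = None,
                   filters: FilterParams | None = None,
                   threshold: float = 0.99,
                   occupancy: bool = True,
                   extension: bool = True,
                   refine_rounds: int = 0,
                   threads: int = 1,
                   profiles: Mapping[str, ExtendedProfile] | None = None,
                   return_details: bool = False):
    """Full pipeline: homology extension, primary library, guide tree,
    progressive alignment, optional refinement.

    With ``extension=False`` (or no database) every sequence gets its
    degenerate self-profile and the pipeline reduces to consistency
    alignment of the plain sequences.
    """
    if len(sequences) < 2:
        raise DataError("need at least 2 sequences to align")
    params = params or PairHmmParams.default()
    if profiles is None:
        if extension and database is not None:
            profiles = extend_all(sequences, database, filters)
        else:
            profiles = {s.id: ExtendedProfile.from_sequence(s)
                        for s in sequences}
    kept = sum(p.n_hits for p in profiles.values())
    logger.info("profiles: %d sequences, %d hits kept", len(profiles), kept)
    lib = build_primary_library(profiles, params, threshold=threshold,
                                occupancy=occupancy, threads=threads)
    logger.info("primary library: %d constraints", lib.n_constraints())
    tree = build_guide_tree(lib)
    msa = align_sequences(sequences, lib, tree=tree)
    msa = refine(msa, lib, rounds=refine_rounds)
    logger.info("alignment: %d rows x %d columns", msa.nrows, msa.ncols)
    if return_details:
        return msa, {"profiles": profiles, "library": lib, "tree": tree,
                     "hits_kept": kept}
    return msa
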