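"""Core-region SP/TC scoring and paired significance testing.

A residue participates in scoring iff its (row, reference-column) cell lies
inside a core block of its row and is not a gap.  SP counts reference-core
residue pairs co-columned in the test alignment; TC counts reference core
columns whose core residues all land in a single test column (columns with
fewer than two core residues are not counted).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence as TSeq

import numpy as np
from scipy import stats

from .errors import DataError
from .formats import GAP, CoreAnnotation, MultipleAlignment

logger = logging.getLogger(__name__)


def _check_same_sequences(test: MultipleAlignment, ref: MultipleAlignment):
    if sorted(test.ids) != sorted(ref.ids):
        raise DataError("test and reference alignments have different ids")
    tdg, rdg = test.degapped(), ref.degapped()
    for sid in rdg:
        if tdg[sid] != rdg[sid]:
            raise DataError(
                f"sequence {sid!r} differs between test and reference "
                "after removing gaps")


def _column_of_position(msa: MultipleAlignment) -> dict[str, np.ndarray]:
    """Per row: residue index -> column index."""
    out = {}
    for sid, row in zip(msa.ids, msa.rows):
        cols = [c for c, ch in enumerate(row) if ch != GAP]
        out[sid] = np.asarray(cols, dtype=np.int64)
    return out


def _core_cells(ref: MultipleAlignment, core: CoreAnnotation):
    """Per reference column: list of (row id, residue index) of core,
    non-gap residues."""
    masks = {sid: core.mask(sid, ref.ncols) for sid in ref.ids}
    cells: list[list[tuple[str, int]]] = [[] for _ in range(ref.ncols)]
    for sid, row in zip(ref.ids, ref.rows):
        mask = masks[sid]
        k = 0
        for c, ch in enumerate(row):
            if ch != GAP:
                if mask[c]:
                    cells[c].append((sid, k))
                k += 1
    return cells


def sp_score(test: MultipleAlignment, ref: MultipleAlignment,
             core: CoreAnnotation) -> tuple[float, int]:
    """Fraction of reference-core residue pairs identically aligned in the
    test MSA; returns (SP, pairs counted).  SP is NaN when no pair counts."""
    _check_same_sequences(test, ref)
    test_col = _column_of_position(test)
    cells = _core_cells(ref, core)
    num = den = 0
    for col_cells in cells:
        for x in range(len(col_cells)):
            sid_x, px = col_cells[x]
            cx = test_col[sid_x][px]
            for y in range(x + 1, len(col_cells)):
                sid_y, py = col_cells[y]
                den += 1
                if cx == test_col[sid_y][py]:
                    num += 1
    if den == 0:
        logger.warning("empty core: SP undefined")
        return math.nan, 0
    return num / den, den


def tc_score(test: MultipleAlignment, ref: MultipleAlignment,
             core: CoreAnnotation) -> tuple[float, int]:
    """Fraction of reference core columns reproduced intact in the test MSA;
    returns (TC, columns counted).  TC is NaN when no column counts."""
    _check_same_sequences(test, ref)
    test_col = _column_of_position(test)
    cells = _core_cells(ref, core)
    num = den = 0
    for col_cells in cells:
        if len(col_cells) < 2:
            continue
        den += 1
        target = {test_col[sid][p] for sid, p in col_cells}
        if len(target) == 1:
            num += 1
    if den == 0:
        logger.warning("empty core: TC undefined")
        return math.nan, 0
    return num / den, den


@dataclass
class ScoreReport:
    """Per-family and aggregate SP/TC values (aggregates are unweighted
    arithmetic means over families with non-empty cores)."""

    families: dict[str, dict] = field(default_factory=dict)

    def add(self, name: str, sp: float, pairs: int, tc: float, cols: int):
        self.families[name] = {"SP": sp, "pairs": pairs, "TC": tc,
                               "cols": cols}

    @property
    def scored(self) -> dict[str, dict]:
        return {k: v for k, v in self.families.items()
                if v["pairs"] > 0 or v["cols"] > 0}

    @property
    def avg_sp(self) -> float:
        vals = [v["SP"] for v in self.scored.values() if v["pairs"] > 0]
        return float(np.mean(vals)) if vals else math.nan

    @property
    def avg_tc(self) -> float:
        vals = [v["TC"] for v in self.scored.values() if v["cols"] > 0]
        return float(np.mean(vals)) if vals else math.nan

    @property
    def total_pairs(self) -> int:
        return sum(v["pairs"] for v in self.families.values())

    @property
    def total_cols(self) -> int:
        return sum(v["cols"] for v in self.families.values())

    def to_tsv(self) -> str:
        lines = ["family\tSP\tTC\tpairs\tcols"]
        for name, v in self.families.items():
            lines.append(f"{name}\t{v['SP']:.6f}\t{v['TC']:.6f}"
                         f"\t{v['pairs']}\t{v['cols']}")
        lines.append(f"avg\t{self.avg_sp:.6f}\t{self.avg_tc:.6f}"
                     f"\t{self.total_pairs}\t{self.total_cols}")
        return "\n".join(lines) + "\n"


def score_suite(results: Mapping[str, tuple[MultipleAlignment,
                                            MultipleAlignment,
                                            CoreAnnotation]]) -> ScoreReport:
    """SP/TC per family plus unweighted aggregate means and totals."""
    if not results:
        raise DataError("score_suite needs at least one family")
    report = ScoreReport()
    for name, (test, ref, core) in results.items():
        sp, pairs = sp_score(test, ref, core)
        tc, cols = tc_score(test, ref, core)
        if pairs == 0 and cols == 0:
            logger.warning("family %s has an empty core; excluded from "
                           "aggregates", name)
        report.add(name, sp, pairs, tc, cols)
    return report


# ---------------------------------------------------------------------------
# paired significance test

_EXACT_LIMIT = 20


def paired_test(scoresA: TSeq[float], scoresB: TSeq[float]) -> float:
    """Two-sided exact Wilcoxon signed-rank p-value over per-family paired
    differences; zero differences are dropped and identical vectors give
    p = 1.0.  Ties in |difference| take midranks; the exact null
    distribution is enumerated over sign assignments."""
    if len(scoresA) != len(scoresB):
        raise DataError("paired score vectors differ in length")
    if len(scoresA) < 2:
        raise DataError("paired test needs at least 2 families")
    diffs = np.asarray(scoresA, dtype=float) - np.asarray(scoresB, dtype=float)
    diffs = diffs[diffs != 0.0]
    n = diffs.size
    if n == 0:
        return 1.0
    if n > _EXACT_LIMIT:
        return float(stats.wilcoxon(diffs, zero_method="wilcox",
                                    alternative="two-sided",
                                    method="approx").pvalue)
    ranks = stats.rankdata(np.abs(diffs))
    # integer grid: doubled midranks are whole numbers
    r2 = np.asarray(np.round(ranks * 2), dtype=int)
    w_obs2 = int(np.round(float(ranks[diffs > 0].sum()) * 2))
    # distribution of 2*W+ under random signs, by convolution
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        nxt = counts.copy()
        nxt[r:] += counts[: total + 1 - r]
        counts = nxt
    counts /= counts.sum()
    p_le = float(counts[: w_obs2 + 1].sum())
    p_ge = float(counts[w_obs2:].sum())
    return min(1.0, 2.0 * min(p_le, p_ge))
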