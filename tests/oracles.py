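"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (path enumeration, triple loops,
exhaustive search, set algebra) and shares no code with the package
implementations it checks.
"""

from __future__ import annotations

import numpy as np


def enumerate_match_posteriors(E: np.ndarray, init: np.ndarray,
                               T: np.ndarray) -> tuple[np.ndarray, float]:
    """Posterior match probabilities by explicit enumeration of every
    state-labeled monotone path emitting all of A and B.

    ``E`` holds match-emission values (insert states emit 1); ``init`` and
    ``T`` are the 5-state initial distribution and transition matrix with
    state order (match, shortA, shortB, longA, longB).
    """
    m, n = E.shape
    total = 0.0
    post = np.zeros((m, n))
    consumes = {0: (1, 1), 1: (1, 0), 2: (0, 1), 3: (1, 0), 4: (0, 1)}

    def emission(s, i, j):
        # i, j are counts consumed *after* taking state s's step
        if s == 0:
            return E[i - 1, j - 1]
        return 1.0

    def rec(i, j, s, prob, matches):
        nonlocal total
        if i == m and j == n:
            total += prob
            for cell in matches:
                post[cell] += prob
            return
        for s2 in range(5):
            di, dj = consumes[s2]
            i2, j2 = i + di, j + dj
            if i2 > m or j2 > n:
                continue
            p2 = prob * T[s, s2] * emission(s2, i2, j2)
            if p2 == 0.0:
                continue
            if s2 == 0:
                rec(i2, j2, s2, p2, matches + ((i2 - 1, j2 - 1),))
            else:
                rec(i2, j2, s2, p2, matches)

    for s0 in range(5):
        di, dj = consumes[s0]
        if di > m or dj > n:
            continue
        p0 = init[s0] * emission(s0, di, dj)
        if p0 == 0.0:
            continue
        if s0 == 0:
            rec(di, dj, s0, p0, ((di - 1, dj - 1),))
        else:
            rec(di, dj, s0, p0, ())
    return post / total, total


def brute_extend(lib):
    """Triple-loop triplet extension over a ConstraintLibrary, returning a
    dict {(idA, posA, idB, posB): weight} with idA registered before idB."""
    ids = lib.ids()
    out = {}
    for x in range(len(ids)):
        for y in range(x + 1, len(ids)):
            a, b = ids[x], ids[y]
            for i in range(lib.lengths[a]):
                for j in range(lib.lengths[b]):
                    w = lib.weight(a, i, b, j)
                    for c in ids:
                        if c in (a, b):
                            continue
                        for k in range(lib.lengths[c]):
                            w1 = lib.weight(a, i, c, k)
                            w2 = lib.weight(c, k, b, j)
                            if w1 and w2:
                                w += min(w1, w2)
                    if w:
                        out[(a, i, b, j)] = w
    return out


def exhaustive_best_alignment_score(S: np.ndarray) -> float:
    """Maximum total column score over every monotone interleaving of the
    two column sets (no gap penalty)."""
    la, lb = S.shape
    best = [-np.inf]

    def rec(i, j, score):
        if i == la and j == lb:
            if score > best[0]:
                best[0] = score
            return
        if i < la and j < lb:
            rec(i + 1, j + 1, score + S[i, j])
        if i < la:
            rec(i + 1, j, score)
        if j < lb:
            rec(i, j + 1, score)

    rec(0, 0, 0.0)
    return best[0]


def _residue_columns(rows: dict[str, str]):
    """Per row id: residue index -> column, plus per column the set of
    (row, residue index) placed there."""
    col_of = {}
    cells = {}
    for sid, row in rows.items():
        k = 0
        col_of[sid] = {}
        for c, ch in enumerate(row):
            if ch != "-":
                col_of[sid][k] = c
                cells.setdefault(c, set()).add((sid, k))
                k += 1
    return col_of, cells


def brute_sp_tc(test_rows: dict[str, str], ref_rows: dict[str, str],
                core_masks: dict[str, list[bool]]):
    """Set-based SP and TC on core cells; returns (sp, pairs, tc, cols)
    with NaN scores when nothing counts."""
    tcol, _ = _residue_columns(test_rows)
    rcol, rcells = _residue_columns(ref_rows)
    sp_num = sp_den = tc_num = tc_den = 0
    for c in sorted(rcells):
        core_here = sorted((sid, k) for sid, k in rcells[c]
                           if core_masks[sid][c])
        for x in range(len(core_here)):
            for y in range(x + 1, len(core_here)):
                (sa, ka), (sb, kb) = core_here[x], core_here[y]
                sp_den += 1
                if tcol[sa][ka] == tcol[sb][kb]:
                    sp_num += 1
        if len(core_here) >= 2:
            tc_den += 1
            if len({tcol[s][k] for s, k in core_here}) == 1:
                tc_num += 1
    sp = sp_num / sp_den if sp_den else float("nan")
    tc = tc_num / tc_den if tc_den else float("nan")
    return sp, sp_den, tc, tc_den


def exact_signed_rank_p(diffs) -> float:
    """Two-sided exact Wilcoxon signed-rank p by direct enumeration of all
    sign assignments (midranks for tied |differences|)."""
    import itertools

    d = [x for x in diffs if x != 0]
    if not d:
        return 1.0
    absd = sorted((abs(x), idx) for idx, x in enumerate(d))
    ranks = [0.0] * len(d)
    i = 0
    while i < len(absd):
        j = i
        while j < len(absd) and absd[j][0] == absd[i][0]:
            j += 1
        mid = (i + 1 + j) / 2.0
        for k in range(i, j):
            ranks[absd[k][1]] = mid
        i = j
    w_obs = sum(r for x, r in zip(d, ranks) if x > 0)
    n = len(d)
    le = ge = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        if w <= w_obs + 1e-12:
            le += 1
        if w >= w_obs - 1e-12:
            ge += 1
    scale = 2.0 ** n
    return min(1.0, 2.0 * min(le / scale, ge / scale))
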