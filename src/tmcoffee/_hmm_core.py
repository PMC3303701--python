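"""Numba kernels for the 5-state pair-HMM forward/backward recursions.

State order: 0 = match, 1/2 = short-gap inserts (consume A / consume B),
3/4 = long-gap inserts (consume A / consume B).  Emissions are in odds form:
the match state emits a likelihood ratio, insert states emit 1 (log 0), so
the forward total is the full-model likelihood divided by the null model.
"""

import numpy as np
from numba import njit

NEG_INF = -np.inf


@njit(cache=True)
def forward(logE, lt, linit):
    m, n = logE.shape
    F = np.full((5, m + 1, n + 1), NEG_INF)
    for i in range(m + 1):
        for j in range(n + 1):
            if i > 0 and j > 0:
                # match, consumes (1,1)
                if i == 1 and j == 1:
                    acc = linit[0]
                else:
                    acc = NEG_INF
                    for s in range(5):
                        t = F[s, i - 1, j - 1] + lt[s, 0]
                        acc = np.logaddexp(acc, t)
                F[0, i, j] = acc + logE[i - 1, j - 1]
            if i > 0:
                # insert states consuming A
                for s in (1, 3):
                    if i == 1 and j == 0:
                        acc = linit[s]
                    else:
                        acc = NEG_INF
                    for sp in range(5):
                        t = F[sp, i - 1, j] + lt[sp, s]
                        acc = np.logaddexp(acc, t)
                    F[s, i, j] = acc
            if j > 0:
                # insert states consuming B
                for s in (2, 4):
                    if i == 0 and j == 1:
                        acc = linit[s]
                    else:
                        acc = NEG_INF
                    for sp in range(5):
                        t = F[sp, i, j - 1] + lt[sp, s]
                        acc = np.logaddexp(acc, t)
                    F[s, i, j] = acc
    return F


@njit(cache=True)
def backward(logE, lt):
    m, n = logE.shape
    B = np.full((5, m + 1, n + 1), NEG_INF)
    for s in range(5):
        B[s, m, n] = 0.0
    for i in range(m, -1, -1):
        for j in range(n, -1, -1):
            if i == m and j == n:
                continue
            for s in range(5):
                acc = NEG_INF
                if i < m and j < n:
                    acc = np.logaddexp(
                        acc, lt[s, 0] + logE[i, j] + B[0, i + 1, j + 1])
                if i < m:
                    acc = np.logaddexp(acc, lt[s, 1] + B[1, i + 1, j])
                    acc = np.logaddexp(acc, lt[s, 3] + B[3, i + 1, j])
                if j < n:
                    acc = np.logaddexp(acc, lt[s, 2] + B[2, i, j + 1])
                    acc = np.logaddexp(acc, lt[s, 4] + B[4, i, j + 1])
                B[s, i, j] = acc
    return B


@njit(cache=True)
def total_from_forward(F):
    m = F.shape[1] - 1
    n = F.shape[2] - 1
    acc = NEG_INF
    for s in range(5):
        acc = np.logaddexp(acc, F[s, m, n])
    return acc


@njit(cache=True)
def total_from_backward(B, logE, linit):
    m, n = logE.shape
    acc = NEG_INF
    if m > 0 and n > 0:
        acc = np.logaddexp(acc, linit[0] + logE[0, 0] + B[0, 1, 1])
    if m > 0:
        acc = np.logaddexp(acc, linit[1] + B[1, 1, 0])
        acc = np.logaddexp(acc, linit[3] + B[3, 1, 0])
    if n > 0:
        acc = np.logaddexp(acc, linit[2] + B[2, 0, 1])
        acc = np.logaddexp(acc, linit[4] + B[4, 0, 1])
    return acc


@njit(cache=True)
def match_posteriors(F, B, total):
    m = F.shape[1] - 1
    n = F.shape[2] - 1
    P = np.zeros((m, n))
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            v = F[0, i, j] + B[0, i, j] - total
            if v > 0.0:
                v = 0.0
            P[i - 1, j - 1] = np.exp(v)
    return P


@njit(cache=True)
def consistency_dp(S):
    """Needleman-Wunsch with no gap penalty over a column-score matrix.

    Returns the trace as an array of moves from the start: 0 = match,
    1 = consume A only (gap in B), 2 = consume B only (gap in A).
    Tie-break prefers match, then gap-in-B, then gap-in-A.
    """
    la, lb = S.shape
    dp = np.zeros((la + 1, lb + 1))
    move = np.zeros((la + 1, lb + 1), dtype=np.int8)
    for i in range(1, la + 1):
        dp[i, 0] = dp[i - 1, 0]
        move[i, 0] = 1
    for j in range(1, lb + 1):
        dp[0, j] = dp[0, j - 1]
        move[0, j] = 2
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            diag = dp[i - 1, j - 1] + S[i - 1, j - 1]
            up = dp[i - 1, j]
            left = dp[i, j - 1]
            if diag >= up and diag >= left:
                dp[i, j] = diag
                move[i, j] = 0
            elif up >= left:
                dp[i, j] = up
                move[i, j] = 1
            else:
                dp[i, j] = left
                move[i, j] = 2
    # traceback
    path = np.empty(la + lb, dtype=np.int8)
    k = la + lb
    i, j = la, lb
    while i > 0 or j > 0:
        mv = move[i, j]
        k -= 1
        path[k] = mv
        if mv == 0:
            i -= 1
            j -= 1
        elif mv == 1:
            i -= 1
        else:
            j -= 1
    return dp[la, lb], path[k:]
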