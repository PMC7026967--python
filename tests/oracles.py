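"""Independent naive-formula / brute-force oracles used by the tests.

Each oracle is written straight from the textbook definition (or as a
plain exhaustive computation) and deliberately shares no code with the
package implementations it checks.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter

NEG = float("-inf")


# ----------------------------------------------------------- alignment

def gotoh_oracle(a: str, b: str, match=1.0, mismatch=-1.0, gap_open=-2.0, gap_extend=-1.0):
    """Plain-dict affine-gap global DP with the canonical tie rules
    (diagonal predecessor preferred in order M, X, Y; gap opening
    preferred over extension; final state preferred M, X, Y).  Returns
    (score, distance) where distance = (mismatches + gap columns) /
    columns, terminal gap runs excluded."""
    n, m = len(a), len(b)
    M = {(0, 0): 0.0}
    X, Y = {}, {}
    ptr_m, ptr_x, ptr_y = {}, {}, {}
    for i in range(1, n + 1):
        X[(i, 0)] = gap_open + gap_extend * (i - 1)
        ptr_x[(i, 0)] = "X" if i > 1 else "M"
    for j in range(1, m + 1):
        Y[(0, j)] = gap_open + gap_extend * (j - 1)
        ptr_y[(0, j)] = "Y" if j > 1 else "M"

    def get(d, key):
        return d.get(key, NEG)

    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if (a[i - 1] == b[j - 1] and a[i - 1] in "ACGT") else mismatch
            cands = [
                (get(M, (i - 1, j - 1)), "M"),
                (get(X, (i - 1, j - 1)), "X"),
                (get(Y, (i - 1, j - 1)), "Y"),
            ]
            best = max(cands, key=lambda t: t[0])
            # ties: first in M, X, Y order
            for v, st in cands:
                if v == best[0]:
                    best = (v, st)
                    break
            M[(i, j)] = best[0] + s
            ptr_m[(i, j)] = best[1]
            op_ = get(M, (i - 1, j)) + gap_open
            ex_ = get(X, (i - 1, j)) + gap_extend
            X[(i, j)] = op_ if op_ >= ex_ else ex_
            ptr_x[(i, j)] = "M" if op_ >= ex_ else "X"
            op_ = get(M, (i, j - 1)) + gap_open
            ex_ = get(Y, (i, j - 1)) + gap_extend
            Y[(i, j)] = op_ if op_ >= ex_ else ex_
            ptr_y[(i, j)] = "M" if op_ >= ex_ else "Y"

    finals = [(get(M, (n, m)), "M"), (get(X, (n, m)), "X"), (get(Y, (n, m)), "Y")]
    score = max(v for v, _ in finals)
    state = next(st for v, st in finals if v == score)

    cols = []  # (ca, cb) aligned column characters
    i, j = n, m
    while i > 0 or j > 0:
        if state == "M":
            cols.append((a[i - 1], b[j - 1]))
            state = ptr_m[(i, j)]
            i, j = i - 1, j - 1
        elif state == "X":
            cols.append((a[i - 1], "-"))
            state = ptr_x[(i, j)]
            i -= 1
        else:
            cols.append(("-", b[j - 1]))
            state = ptr_y[(i, j)]
            j -= 1
    cols.reverse()
    lo = 0
    while lo < len(cols) and "-" in cols[lo]:
        lo += 1
    hi = len(cols)
    while hi > lo and "-" in cols[hi - 1]:
        hi -= 1
    core = cols[lo:hi]
    if not core:
        return score, 1.0
    diff = sum(1 for ca, cb in core if ca == "-" or cb == "-" or ca != cb or ca not in "ACGT")
    return score, diff / len(core)


# ------------------------------------------------------ alpha diversity

def chao1_oracle(counts):
    pos = [c for c in counts if c > 0]
    f1 = sum(1 for c in pos if c == 1)
    f2 = sum(1 for c in pos if c == 2)
    return len(pos) + f1 * (f1 - 1) / (2 * (f2 + 1))


def ace_oracle(counts, t=10):
    pos = [c for c in counts if c > 0]
    rare = [c for c in pos if c <= t]
    s_abund = len(pos) - len(rare)
    if not rare:
        return float(s_abund)
    n_rare = sum(rare)
    f = Counter(rare)
    c_ace = 1 - f[1] / n_rare
    if c_ace == 0:
        return float(len(pos))
    g2 = 0.0
    if n_rare > 1:
        top = sum(i * (i - 1) * f[i] for i in range(1, t + 1))
        g2 = max(len(rare) / c_ace * top / (n_rare * (n_rare - 1)) - 1, 0.0)
    return s_abund + len(rare) / c_ace + f[1] / c_ace * g2


def shannon_oracle(counts):
    pos = [c for c in counts if c > 0]
    n = sum(pos)
    return -sum((c / n) * math.log(c / n) for c in pos) if n else 0.0


def simpson_oracle(counts):
    pos = [c for c in counts if c > 0]
    n = sum(pos)
    if n <= 1:
        return 1.0
    return sum(c * (c - 1) for c in pos) / (n * (n - 1))


def coverage_oracle(counts):
    pos = [c for c in counts if c > 0]
    n = sum(pos)
    if n == 0:
        return 0.0
    f1 = sum(1 for c in pos if c == 1)
    return (1 - f1 / n) * 100.0


def bray_curtis_oracle(x, y):
    tot = sum(x) + sum(y)
    if tot == 0:
        return 0.0
    return 1 - 2 * sum(min(a, b) for a, b in zip(x, y)) / tot


# ------------------------------------------------------------- tables

def chi_square_over_n(table):
    """Pearson chi-square of a 2-D table divided by the grand total."""
    rows = [sum(r) for r in table]
    cols = [sum(c) for c in zip(*table)]
    n = sum(rows)
    chi2 = 0.0
    for i, r in enumerate(rows):
        for j, c in enumerate(cols):
            e = r * c / n
            if e > 0:
                chi2 += (table[i][j] - e) ** 2 / e
    return chi2 / n


# ---------------------------------------------------- friedman oracle

def friedman_statistic(matrix):
    """Tie-corrected Friedman chi-square from mid-ranks (independent
    coding of the same definition the implementation uses)."""
    n = len(matrix)
    k = len(matrix[0])
    ranks = []
    for row in matrix:
        order = sorted(range(k), key=lambda j: row[j])
        r = [0.0] * k
        j = 0
        while j < k:
            tied = [order[j]]
            while j + len(tied) < k and row[order[j + len(tied)]] == row[order[j]]:
                tied.append(order[j + len(tied)])
            avg = sum(range(j + 1, j + len(tied) + 1)) / len(tied)
            for idx in tied:
                r[idx] = avg
            j += len(tied)
        ranks.append(r)
    colsums = [sum(r[j] for r in ranks) for j in range(k)]
    num = 12.0 * sum((cs - n * (k + 1) / 2) ** 2 for cs in colsums) / (n * k * (k + 1))
    ties = 0.0
    for r in ranks:
        for _, cnt in Counter(r).items():
            ties += cnt**3 - cnt
    corr = 1.0 - ties / (n * (k**3 - k))
    if corr <= 0:
        return 0.0
    return num / corr


def friedman_permutation_p(matrix):
    """Exact permutation p-value: permute treatments independently
    within every block ((k!)^n arrangements) and count statistics at
    least as extreme as the observed one."""
    observed = friedman_statistic(matrix)
    k = len(matrix[0])
    perms = list(itertools.permutations(range(k)))
    n_ge = 0
    total = 0
    def rec(i, rows):
        nonlocal n_ge, total
        if i == len(matrix):
            total += 1
            if friedman_statistic(rows) >= observed - 1e-12:
                n_ge += 1
            return
        for p in perms:
            rec(i + 1, rows + [[matrix[i][j] for j in p]])
    rec(0, [])
    return n_ge / total
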