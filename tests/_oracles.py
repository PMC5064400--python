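"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive: integer combinatorics for the
hypergeometric tail, a hand-rolled Gotoh dynamic program with full optimal
traceback enumeration for pairwise alignment, exhaustive permutation search
for the one-to-one ortholog assignment, and literal definition checks for
N50 and window recounts.  None of it shares code with the package paths it
verifies.
"""

from __future__ import annotations

import itertools
from math import comb

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")

GAP_OPEN = -12  # first gap position (existence 11 + extension 1)
GAP_EXT = -1

NEG = float("-inf")


def hypergeom_tail_exact(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) by direct summation of integer binomial products."""
    num = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(n, K) + 1))
    return num / comb(N, n)


def hypergeom_pmf_sum(n: int, K: int, N: int) -> float:
    num = sum(comb(K, i) * comb(N - K, n - i) for i in range(0, n + 1))
    return num / comb(N, n)


def _score(a: str, b: str) -> float:
    return float(_B62[a][b])


def gotoh_optimal(a: str, b: str):
    """All optimal global affine-gap alignments of two short sequences.

    Returns (best_score, identities) where ``identities`` is the set of
    identity percentages (identical pairs / columns * 100) achievable by
    an optimal alignment.  End gaps are penalized like internal gaps.
    """
    la, lb = len(a), len(b)
    M = [[NEG] * (lb + 1) for _ in range(la + 1)]
    X = [[NEG] * (lb + 1) for _ in range(la + 1)]  # gap in b (a residue over '-')
    Y = [[NEG] * (lb + 1) for _ in range(la + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(la + 1):
        for j in range(lb + 1):
            if i > 0 and j > 0:
                M[i][j] = _score(a[i - 1], b[j - 1]) + max(
                    M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]
                )
            if i > 0:
                X[i][j] = max(
                    M[i - 1][j] + GAP_OPEN,
                    X[i - 1][j] + GAP_EXT,
                    Y[i - 1][j] + GAP_OPEN,
                )
            if j > 0:
                Y[i][j] = max(
                    M[i][j - 1] + GAP_OPEN,
                    X[i][j - 1] + GAP_OPEN,
                    Y[i][j - 1] + GAP_EXT,
                )
    best = max(M[la][lb], X[la][lb], Y[la][lb])

    # enumerate all optimal paths backwards
    identities: set[float] = set()
    EPS = 1e-9

    def walk(i: int, j: int, state: str, ident: int, cols: int) -> None:
        if i == 0 and j == 0 and state == "M":
            if cols:
                identities.add(100.0 * ident / cols)
            return
        if state == "M":
            if i > 0 and j > 0:
                target = M[i][j]
                inc = _score(a[i - 1], b[j - 1])
                hit = 1 if a[i - 1] == b[j - 1] else 0
                for prev in ("M", "X", "Y"):
                    val = {"M": M, "X": X, "Y": Y}[prev][i - 1][j - 1]
                    if abs(val + inc - target) < EPS:
                        walk(i - 1, j - 1, prev, ident + hit, cols + 1)
        elif state == "X":
            target = X[i][j]
            if i > 0:
                for prev, pen in (("M", GAP_OPEN), ("X", GAP_EXT), ("Y", GAP_OPEN)):
                    val = {"M": M, "X": X, "Y": Y}[prev][i - 1][j]
                    if abs(val + pen - target) < EPS:
                        walk(i - 1, j, prev, ident, cols + 1)
        else:
            target = Y[i][j]
            if j > 0:
                for prev, pen in (("M", GAP_OPEN), ("X", GAP_OPEN), ("Y", GAP_EXT)):
                    val = {"M": M, "X": X, "Y": Y}[prev][i][j - 1]
                    if abs(val + pen - target) < EPS:
                        walk(i, j - 1, prev, ident, cols + 1)

    for state, val in (("M", M[la][lb]), ("X", X[la][lb]), ("Y", Y[la][lb])):
        if abs(val - best) < EPS:
            walk(la, lb, state, 0, 0)
    return best, identities


def best_assignment_count(qualifies) -> int:
    """Max one-to-one qualifying-pair count by exhaustive permutation search.

    ``qualifies`` is a 2D boolean array (query x reference).
    """
    nq = len(qualifies)
    nr = len(qualifies[0]) if nq else 0
    best = 0
    refs = list(range(nr))
    for r in range(min(nq, nr), 0, -1):
        for q_sub in itertools.combinations(range(nq), r):
            for r_perm in itertools.permutations(refs, r):
                if all(qualifies[q][p] for q, p in zip(q_sub, r_perm)):
                    return r
    return 0


def recount_window(anchors, gstart: int, gend: int) -> tuple[int, int]:
    """Independent (k, n) recount for one [gstart, gend) window."""
    n = k = 0
    for a in anchors:
        if gstart <= a.global_pos < gend:
            n += 1
            if a.labeled:
                k += 1
    return k, n


def n50_definition_check(lengths, value: int) -> bool:
    """Check the N50 definition literally: contigs >= value cover half."""
    total = sum(lengths)
    ge = sum(L for L in lengths if L >= value)
    if 2 * ge < total:
        return False
    # value must be attained and be the largest such attained length
    if value not in lengths:
        return False
    for L in sorted(set(lengths), reverse=True):
        if 2 * sum(x for x in lengths if x >= L) >= total:
            return L == value
    return False


def adjacency_breakpoints(ref_order, query_order) -> int:
    """Unordered-adjacency breakpoint count over two id sequences."""
    radj = {frozenset(p) for p in zip(ref_order, ref_order[1:])}
    qadj = {frozenset(p) for p in zip(query_order, query_order[1:])}
    return len(radj - qadj)
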