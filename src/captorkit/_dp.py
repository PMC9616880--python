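"""Numba kernels for unit-cost semi-global alignment and edit distance.

Alignment convention: the *reference* must be consumed end-to-end; the
*query* has free leading and trailing gaps (the adaptor is located inside a
longer read). Moves and costs: diagonal match 0, diagonal mismatch 1,
vertical = reference base absent from the read (deletion, cost 1),
horizontal = extra read base (insertion, cost 1).

Determinism: the alignment endpoint is the smallest query index attaining
the minimal cost; traceback prefers match > mismatch > deletion > insertion
at equal cost. Op codes: 0 match, 1 mismatch, 2 deletion, 3 insertion.
"""

from __future__ import annotations

import numpy as np
from numba import njit

OP_MATCH, OP_MISMATCH, OP_DELETION, OP_INSERTION = 0, 1, 2, 3


@njit(cache=True)
def sg_cost(ref: np.ndarray, query: np.ndarray) -> int:
    """Minimal semi-global edit cost of ref within query (score only)."""
    m, n = len(ref), len(query)
    prev = np.zeros(n + 1, dtype=np.int32)
    curr = np.empty(n + 1, dtype=np.int32)
    for i in range(1, m + 1):
        curr[0] = i
        ri = ref[i - 1]
        for j in range(1, n + 1):
            d = prev[j - 1] + (0 if query[j - 1] == ri else 1)
            u = prev[j] + 1
            l = curr[j - 1] + 1
            c = d
            if u < c:
                c = u
            if l < c:
                c = l
            curr[j] = c
        prev, curr = curr, prev
    best = prev[0]
    for j in range(1, n + 1):
        if prev[j] < best:
            best = prev[j]
    return best


@njit(cache=True)
def _sg_matrix(ref: np.ndarray, query: np.ndarray) -> np.ndarray:
    m, n = len(ref), len(query)
    D = np.empty((m + 1, n + 1), dtype=np.int32)
    for j in range(n + 1):
        D[0, j] = 0
    for i in range(1, m + 1):
        D[i, 0] = i
        ri = ref[i - 1]
        for j in range(1, n + 1):
            d = D[i - 1, j - 1] + (0 if query[j - 1] == ri else 1)
            u = D[i - 1, j] + 1
            l = D[i, j - 1] + 1
            c = d
            if u < c:
                c = u
            if l < c:
                c = l
            D[i, j] = c
    return D


@njit(cache=True)
def sg_align(ref: np.ndarray, query: np.ndarray):
    """Full semi-global alignment with traceback.

    Returns (cost, ref_start, query_start, query_end, ref_pos, read_pos, op)
    where the three arrays describe the alignment path in reference order.
    For insertions ref_pos is the preceding reference position (pileup
    convention) and for deletions read_pos is -1.
    """
    m, n = len(ref), len(query)
    D = _sg_matrix(ref, query)
    end_j = 0
    best = D[m, 0]
    for j in range(1, n + 1):
        if D[m, j] < best:
            best = D[m, j]
            end_j = j
    cost = best
    # worst case path length m + n
    ref_pos = np.empty(m + n, dtype=np.int32)
    read_pos = np.empty(m + n, dtype=np.int32)
    op = np.empty(m + n, dtype=np.uint8)
    k = m + n  # fill backwards
    i, j = m, end_j
    while i > 0:
        here = D[i, j]
        ri = ref[i - 1]
        took = False
        if j > 0:
            sub = 0 if query[j - 1] == ri else 1
            if D[i - 1, j - 1] + sub == here:
                k -= 1
                ref_pos[k] = i - 1
                read_pos[k] = j - 1
                op[k] = OP_MATCH if sub == 0 else OP_MISMATCH
                i -= 1
                j -= 1
                took = True
        if not took and D[i - 1, j] + 1 == here:
            k -= 1
            ref_pos[k] = i - 1
            read_pos[k] = -1
            op[k] = OP_DELETION
            i -= 1
            took = True
        if not took:
            # horizontal: extra read base, attributed to preceding ref pos
            k -= 1
            ref_pos[k] = i - 1
            read_pos[k] = j - 1
            op[k] = OP_INSERTION
            j -= 1
    return cost, 0, j, end_j, ref_pos[k:], read_pos[k:], op[k:]


@njit(cache=True)
def levenshtein(a: np.ndarray, b: np.ndarray) -> int:
    m, n = len(a), len(b)
    prev = np.arange(n + 1, dtype=np.int32)
    curr = np.empty(n + 1, dtype=np.int32)
    for i in range(1, m + 1):
        curr[0] = i
        ai = a[i - 1]
        for j in range(1, n + 1):
            d = prev[j - 1] + (0 if b[j - 1] == ai else 1)
            u = prev[j] + 1
            l = curr[j - 1] + 1
            c = d
            if u < c:
                c = u
            if l < c:
                c = l
            curr[j] = c
        prev, curr = curr, prev
    return int(prev[n])
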