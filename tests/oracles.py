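"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive (exhaustive enumeration, O(n^4)
scans) and shares no code with the package's own algorithms.
"""

from __future__ import annotations

from functools import lru_cache

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def enumerate_semiglobal_cost(ref: str, query: str) -> int:
    """Minimum unit-cost of aligning ref end-to-end into query with free
    query ends, by exhaustive recursion over alignment paths."""

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> int:
        # cost of aligning ref[i:] against query[j:] (suffix may be skipped)
        if i == len(ref):
            return 0  # trailing query bases are free
        options = [best(i + 1, j) + 1]  # delete ref[i]
        if j < len(query):
            options.append(best(i + 1, j + 1)
                           + (0 if ref[i] == query[j] else 1))  # (mis)match
            options.append(best(i, j + 1) + 1)  # insert query[j]
        return min(options)

    # leading query bases are free: try every start
    return min(best(0, j) for j in range(len(query) + 1))


def brute_hairpin(seq: str, min_loop: int = 3) -> int:
    """O(n^4): longest s at i whose reverse complement occurs at j with
    j >= i + |s| + min_loop."""
    n = len(seq)
    best = 0
    for length in range(1, n + 1):
        for i in range(n - length + 1):
            rc = revcomp(seq[i:i + length])
            for j in range(i + length + min_loop, n - length + 1):
                if seq[j:j + length] == rc:
                    best = max(best, length)
    return best


def naive_shared_substring(seq: str, db: dict[str, str]) -> int:
    """Longest exact substring of seq present in db (either strand)."""
    targets = []
    for s in db.values():
        targets.append(s)
        targets.append(revcomp(s))
    best = 0
    for length in range(1, len(seq) + 1):
        found = False
        for i in range(len(seq) - length + 1):
            piece = seq[i:i + length]
            if any(piece in t for t in targets):
                found = True
                break
        if found:
            best = length
        else:
            break
    return best


def py_levenshtein(a: str, b: str) -> int:
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        curr = [i]
        for j, cb in enumerate(b, 1):
            curr.append(min(prev[j - 1] + (ca != cb), prev[j] + 1,
                            curr[-1] + 1))
        prev = curr
    return prev[-1]
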