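"""Independent brute-force oracles used to pin down expected test values.

These deliberately re-derive results by the most transparent route available
(memoized recursion, exact integer enumeration) and share no code with the
implementations they check.
"""

from __future__ import annotations

import sys
from functools import lru_cache
from math import comb


def nw_oracle(a: str, b: str, gap_open: float = 10.0, gap_extend: float = 0.5,
              match: float = 5.0, mismatch: float = -4.0, n_score: float = -2.0
              ) -> tuple[float, int, int]:
    """(score, matches, columns) of the optimal global alignment by plain
    recursion, maximizing score, then matches, then shortness.

    A gap of length g costs ``gap_open + gap_extend * g``; end gaps are
    penalized.  The lexicographic objective is packed into one exact integer
    so path choices cannot influence the result.
    """
    sys.setrecursionlimit(200000)
    n, m = len(a), len(b)
    B = n + m + 1
    A = (min(n, m) + 1) * B

    def csub(x: str, y: str) -> int:
        if "N" in (x, y):
            return int(2 * n_score) * A - 1
        if x == y:
            return int(2 * match) * A + B - 1
        return int(2 * mismatch) * A - 1

    gap_first = -int(2 * (gap_open + gap_extend)) * A - 1
    gap_next = -int(2 * gap_extend) * A - 1

    @lru_cache(maxsize=None)
    def go(i: int, j: int, state: int) -> int:
        if i == n and j == m:
            return 0
        best = -(10 ** 18)
        if i < n and j < m:
            best = max(best, csub(a[i], b[j]) + go(i + 1, j + 1, 0))
        if i < n:
            best = max(best, (gap_next if state == 1 else gap_first) + go(i + 1, j, 1))
        if j < m:
            best = max(best, (gap_next if state == 2 else gap_first) + go(i, j + 1, 2))
        return best

    packed = go(0, 0, 0)
    q, r = divmod(packed, A)
    if r > min(n, m) * B:
        r -= A
        q += 1
    matches = r // B + 1
    columns = matches * B - r
    return q / 2.0, int(matches), int(columns)


def fisher_oracle(a: int, b: int, c: int, d: int, alternative: str) -> float:
    """One-sided Fisher's exact p by exact hypergeometric enumeration.

    The table is [[a, b], [c, d]]; with margins fixed, the top-left count k
    follows a hypergeometric law.  ``greater`` sums P(K >= a), ``less`` sums
    P(K <= a), using exact integer binomial coefficients.
    """
    r1, c1, n = a + b, a + c, a + b + c + d
    denom = comb(n, c1)
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    if alternative == "greater":
        ks = range(a, hi + 1)
    elif alternative == "less":
        ks = range(lo, a + 1)
    else:
        raise ValueError(alternative)
    num = sum(comb(r1, k) * comb(n - r1, c1 - k) for k in ks)
    return num / denom
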