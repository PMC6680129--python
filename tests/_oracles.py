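"""Independent brute-force oracles used only by the test suite."""

from __future__ import annotations

import bisect
from math import comb


def binom_pmf_table(n: int, p: float) -> list[float]:
    return [comb(n, k) * p**k * (1 - p) ** (n - k) for k in range(n + 1)]


def storer_kim_oracle(x1: int, n1: int, x2: int, n2: int, eps: float = 1e-12) -> float:
    """Direct double enumeration of the exact unconditional two-binomial test."""
    p_hat = (x1 + x2) / (n1 + n2)
    d_obs = abs(x1 / n1 - x2 / n2)
    pmf1 = binom_pmf_table(n1, p_hat)
    pmf2 = binom_pmf_table(n2, p_hat)
    total = 0.0
    for y1 in range(n1 + 1):
        for y2 in range(n2 + 1):
            if abs(y1 / n1 - y2 / n2) >= d_obs - eps:
                total += pmf1[y1] * pmf2[y2]
    return min(total, 1.0)


def storer_kim_oracle_grid(n1: int, n2: int, eps: float = 1e-12) -> list[list[float]]:
    """All (x1, x2) p-values by per-pooled-count enumeration with suffix sums.

    Same brute-force definition as storer_kim_oracle (it shares the pmf and
    the |difference| ordering, nothing of the implementation under test),
    organised so the exhaustive sweep over (n1, n2) <= 25 stays fast.
    """
    cells = [(abs(y1 / n1 - y2 / n2), y1, y2) for y1 in range(n1 + 1) for y2 in range(n2 + 1)]
    cells.sort()
    diffs = [c[0] for c in cells]
    out = [[0.0] * (n2 + 1) for _ in range(n1 + 1)]
    for s in range(n1 + n2 + 1):
        p_hat = s / (n1 + n2)
        pmf1 = binom_pmf_table(n1, p_hat)
        pmf2 = binom_pmf_table(n2, p_hat)
        prob_sorted = [pmf1[y1] * pmf2[y2] for _, y1, y2 in cells]
        suffix = [0.0] * (len(cells) + 1)
        for i in range(len(cells) - 1, -1, -1):
            suffix[i] = suffix[i + 1] + prob_sorted[i]
        for x1 in range(max(0, s - n2), min(n1, s) + 1):
            x2 = s - x1
            d = abs(x1 / n1 - x2 / n2)
            idx = bisect.bisect_left(diffs, d - eps)
            out[x1][x2] = min(suffix[idx], 1.0)
    return out


def bh_oracle(pvalues: list[float]) -> list[float]:
    """Textbook Benjamini-Hochberg step-up adjustment."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvalues[i] * m / rank)
        adj[i] = running
    return adj
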