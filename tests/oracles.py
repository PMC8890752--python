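"""Independent brute-force reference implementations used by the tests.

These deliberately avoid the package's chain-based data structures: regions
are enumerated as raw substrings and checked criterion by criterion, so they
provide an oracle that shares no code path with qlckit.detect.
"""

from __future__ import annotations

import math
from collections import Counter


def brute_force_xlc(
    sequence: str,
    target: str = "Q",
    min_fraction: float = 0.25,
    max_gap: int = 17,
    min_length: int = 15,
) -> list[tuple[int, int]]:
    """All qualifying spans by exhaustive substring enumeration, reduced to
    maximal non-overlapping spans by the documented selection rule (keep
    the longest remaining span, ties toward the leftmost start)."""
    n = len(sequence)
    qualifying: list[tuple[int, int]] = []
    for i in range(n):
        if sequence[i] != target:
            continue
        for j in range(i + 1, n + 1):
            if sequence[j - 1] != target:
                continue
            sub = sequence[i:j]
            length = j - i
            if length < min_length:
                continue
            if sub.count(target) / length < min_fraction:
                continue
            runs = [len(run) for run in sub.split(target) if run]
            if runs and max(runs) > max_gap:
                continue
            qualifying.append((i, j))
    maximal = [
        s
        for s in qualifying
        if not any(o != s and o[0] <= s[0] and s[1] <= o[1] for o in qualifying)
    ]
    selected: list[tuple[int, int]] = []
    for span in sorted(maximal, key=lambda s: (-(s[1] - s[0]), s[0])):
        if all(span[1] <= k[0] or span[0] >= k[1] for k in selected):
            selected.append(span)
    return sorted(selected)


def shannon_complexity(window: str, alphabet_size: int = 20) -> float:
    """Direct Shannon-entropy evaluation of window complexity (independent
    of the incremental sliding-window code path)."""
    L = len(window)
    h = 0.0
    for count in Counter(window).values():
        h -= (count / L) * math.log(count / L, alphabet_size)
    return h


def brute_force_jsd(p: list[float], q: list[float]) -> float:
    """Jensen-Shannon divergence from first principles, base 2."""

    def h(dist: list[float]) -> float:
        return -sum(x * math.log2(x) for x in dist if x > 0)

    m = [(a + b) / 2 for a, b in zip(p, q)]
    return h(m) - (h(p) + h(q)) / 2


def pairwise_rg_squared(points) -> float:
    """Rg^2 via the all-pairs identity (1 / (2 N^2)) * sum_ij |r_i - r_j|^2."""
    n = len(points)
    total = 0.0
    for i in range(n):
        for j in range(n):
            total += sum((points[i][k] - points[j][k]) ** 2 for k in range(3))
    return total / (2 * n * n)
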