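"""Independent brute-force oracles for the five entropy measures.

Everything here is written in plain Python with explicit loops and no
shared code with the package, so agreement with the vectorised
implementations is a genuine cross-check.
"""

from __future__ import annotations

import math
from collections import Counter


def _shannon(counts) -> float:
    total = sum(counts)
    return -sum((c / total) * math.log(c / total) for c in counts if c)


def slopen_oracle(x, m, gamma, delta) -> float:
    patterns = Counter()
    for j in range(len(x) - m + 1):
        window = x[j:j + m]
        symbols = []
        for a, b in zip(window, window[1:]):
            d = b - a
            if d > gamma:
                s = 2
            elif d > delta:
                s = 1
            elif abs(d) <= delta:
                s = 0
            elif d >= -gamma:
                s = -1
            else:
                s = -2
            symbols.append(s)
        patterns[tuple(symbols)] += 1
    return _shannon(patterns.values())


def sampen_oracle(x, m, r) -> float:
    n = len(x)
    nt = n - m  # templates that admit an (m+1)-length extension
    a = b = 0
    for i in range(nt):
        for j in range(i + 1, nt):
            dist_m = max(abs(x[i + k] - x[j + k]) for k in range(m))
            if dist_m <= r:
                b += 1
                if max(dist_m, abs(x[i + m] - x[j + m])) <= r:
                    a += 1
    if a == 0 or b == 0:
        return None
    return -math.log(a / b)


def _rank_pattern(window):
    # earlier index ranks lower on ties
    return tuple(sorted(range(len(window)), key=lambda k: (window[k], k)))


def pe_oracle(x, m, tau) -> float:
    patterns = Counter()
    for i in range(len(x) - (m - 1) * tau):
        patterns[_rank_pattern([x[i + k * tau] for k in range(m)])] += 1
    return _shannon(patterns.values())


def wpe_oracle(x, m, tau):
    mass: dict = {}
    total = 0.0
    for i in range(len(x) - (m - 1) * tau):
        window = [x[i + k * tau] for k in range(m)]
        mean = sum(window) / m
        weight = sum((v - mean) ** 2 for v in window) / m
        key = _rank_pattern(window)
        mass[key] = mass.get(key, 0.0) + weight
        total += weight
    if total == 0.0:
        return None
    return -sum((w / total) * math.log(w / total) for w in mass.values() if w > 0)


def _bubble_swaps(window) -> int:
    """Actual bubble sort, counting swaps."""
    arr = list(window)
    swaps = 0
    for top in range(len(arr) - 1, 0, -1):
        for i in range(top):
            if arr[i] > arr[i + 1]:
                arr[i], arr[i + 1] = arr[i + 1], arr[i]
                swaps += 1
    return swaps


def _renyi2(counts) -> float:
    total = sum(counts)
    return -math.log(sum((c / total) ** 2 for c in counts))


def be_oracle(x, m) -> float:
    hs = []
    for size in (m, m + 1):
        counts = Counter(_bubble_swaps(x[i:i + size])
                         for i in range(len(x) - size + 1))
        hs.append(_renyi2(counts.values()))
    return (hs[1] - hs[0]) / math.log((m + 1) / (m - 1))


def ranksum_enumeration_oracle(a, b) -> float:
    """Two-sided exact rank-sum p by explicit enumeration with midranks."""
    import itertools

    pooled = list(a) + list(b)
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        mid = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    na = len(a)
    observed = sum(ranks[:na])
    mean = na * (len(pooled) + 1) / 2
    dev = abs(observed - mean)
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), na):
        total += 1
        if abs(sum(ranks[i] for i in combo) - mean) >= dev - 1e-9:
            hits += 1
    return hits / total
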