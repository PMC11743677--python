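"""Independent brute-force oracles for the nonlinear statistics and AUC.

Deliberately naive implementations (explicit loops, list arithmetic,
string search) kept structurally independent of the package's vectorized
code paths, so agreement is evidence of correctness rather than shared
bugs.
"""

from __future__ import annotations

import math
from itertools import permutations

import numpy as np


def pe_oracle(x, m=3, delay=1):
    """Permutation entropy by explicit pattern counting."""
    x = list(map(float, x))
    n = len(x)
    counts = {}
    n_vec = n - (m - 1) * delay
    if n_vec < 2:
        return float("nan")
    for t in range(n_vec):
        vec = [x[t + k * delay] for k in range(m)]
        # stable ranking: sort positions by (value, position)
        order = tuple(sorted(range(m), key=lambda k: (vec[k], k)))
        counts[order] = counts.get(order, 0) + 1
    total = sum(counts.values())
    return -sum((c / total) * math.log(c / total) for c in counts.values())


def apen_oracle(x, m=2, r=None, r_frac=0.2):
    """Approximate entropy by double loops, self-matches included."""
    x = list(map(float, x))
    n = len(x)
    if r is None:
        mu = sum(x) / n
        r = r_frac * math.sqrt(sum((v - mu) ** 2 for v in x) / n)

    def phi(mm):
        n_t = n - mm + 1
        total = 0.0
        for i in range(n_t):
            count = 0
            for j in range(n_t):
                if max(abs(x[i + k] - x[j + k]) for k in range(mm)) <= r:
                    count += 1
            total += math.log(count / n_t)
        return total / n_t

    return phi(m) - phi(m + 1)


def sampen_oracle(x, m=2, r=None, r_frac=0.2):
    """Sample entropy by double loops over the first n-m templates."""
    x = list(map(float, x))
    n = len(x)
    if r is None:
        mu = sum(x) / n
        r = r_frac * math.sqrt(sum((v - mu) ** 2 for v in x) / n)
    n_t = n - m
    a = b = 0
    for i in range(n_t):
        for j in range(i + 1, n_t):
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                b += 1
                if max(abs(x[i + k] - x[j + k]) for k in range(m + 1)) <= r:
                    a += 1
    if a == 0 or b == 0:
        return float("nan")
    return -math.log(a / b)


def lz76_oracle(bits) -> int:
    """LZ76 component count via the exhaustive-history definition.

    A component grows while it can be copied from the text before its
    last character (self-overlap allowed); the first character that
    breaks reproducibility closes the component.  The terminal
    (possibly still-copyable) component counts as one.
    """
    s = "".join(str(int(b)) for b in bits)
    n = len(s)
    c = 0
    start = 0
    while start < n:
        j = start
        # grow the phrase while s[start:j+1] occurs in s[:j]
        while j < n and s[start : j + 1] in s[:j]:
            j += 1
        c += 1
        start = j + 1 if j < n else n
    return c


def mdcpsr_oracle(x, m=3):
    """Median centroid distance of the delay embedding, step by step.

    Re-derives the delay from the autocorrelation (first zero crossing
    within n/3, 1/e fallback, cap) with plain Python loops.
    """
    x = list(map(float, x))
    n = len(x)
    mu = sum(x) / n
    xc = [v - mu for v in x]
    denom = sum(v * v for v in xc)
    cap = max(1, (n - 1) // (m - 1))
    if denom == 0:
        return 0.0
    acf = [sum(xc[t] * xc[t + lag] for t in range(n - lag)) / denom
           for lag in range(n)]
    tau = None
    for lag in range(1, max(2, n // 3)):
        if acf[lag] <= 0:
            tau = lag
            break
    if tau is None:
        for lag in range(1, n):
            if acf[lag] <= 1.0 / math.e:
                tau = lag
                break
    tau = min(tau if tau is not None else 1, cap)
    n_pts = n - (m - 1) * tau
    if n_pts < 1:
        return float("nan")
    points = [[x[t + k * tau] for k in range(m)] for t in range(n_pts)]
    centroid = [sum(p[k] for p in points) / n_pts for k in range(m)]
    dists = sorted(
        math.sqrt(sum((p[k] - centroid[k]) ** 2 for k in range(m)))
        for p in points
    )
    mid = n_pts // 2
    if n_pts % 2:
        return dists[mid]
    return 0.5 * (dists[mid - 1] + dists[mid])


def auc_oracle(scores, labels):
    """AUC as the concordance probability over all positive-negative pairs."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    if not pos or not neg:
        return float("nan")
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
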