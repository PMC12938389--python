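"""Independent brute-force reference implementations.

Deliberately naive (explicit loops, direct formulas, exhaustive
enumeration); they share conventions with the package estimators but no
code.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.linalg import svdvals


def apen(x: np.ndarray, m: int, r: float) -> float:
    def phi(mm: int) -> float:
        n = len(x) - mm + 1
        templates = [x[i : i + mm] for i in range(n)]
        total = 0.0
        for ti in templates:
            c = sum(1 for tj in templates if np.max(np.abs(ti - tj)) <= r)
            total += math.log(c / n)
        return total / n

    return phi(m) - phi(m + 1)


def sampen(x: np.ndarray, m: int, r: float) -> float:
    n = len(x) - m
    a = b = 0
    for i in range(n):
        for j in range(i + 1, n):
            if np.max(np.abs(x[i : i + m] - x[j : j + m])) <= r:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    if a == 0 or b == 0:
        return float("nan")
    return -math.log(a / b)


def fuzzyen(x: np.ndarray, m: int, r: float, p: float = 2.0) -> float:
    n = len(x) - m

    def phi(mm: int) -> float:
        templates = [x[i : i + mm] - np.mean(x[i : i + mm]) for i in range(n)]
        total = 0.0
        count = 0
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                d = np.max(np.abs(templates[i] - templates[j]))
                total += math.exp(-((d / r) ** p))
                count += 1
        return total / count

    return math.log(phi(m)) - math.log(phi(m + 1))


def permen(x: np.ndarray, m: int, tau: int = 1) -> float:
    counts: dict[tuple, int] = {}
    for i in range(len(x) - (m - 1) * tau):
        window = x[i : i + (m - 1) * tau + 1 : tau]
        # stable ordinal pattern: rank positions sorted by (value, index)
        pattern = tuple(sorted(range(m), key=lambda k: (window[k], k)))
        counts[pattern] = counts.get(pattern, 0) + 1
    total = sum(counts.values())
    return -sum((c / total) * math.log(c / total) for c in counts.values())


def sse(x: np.ndarray, window: int) -> float:
    k = len(x) - window + 1
    traj = np.array([x[i : i + window] for i in range(k)])
    s = svdvals(traj)
    p = s / s.sum()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def envelope_en(x: np.ndarray) -> float:
    # analytic signal by direct FFT construction (positive spectrum doubled)
    n = len(x)
    spec = np.fft.fft(x)
    h = np.zeros(n)
    h[0] = 1.0
    if n % 2 == 0:
        h[n // 2] = 1.0
        h[1 : n // 2] = 2.0
    else:
        h[1 : (n + 1) // 2] = 2.0
    env = np.abs(np.fft.ifft(spec * h))
    p = env / env.sum()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def log_energy(x: np.ndarray) -> float:
    eps = np.finfo(np.float64).tiny
    return float(sum(math.log(v * v + eps) for v in x))


def bh_stepup(p_values: list[float]) -> list[float]:
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p_values[i] * m / rank_from_top)
        adjusted[i] = val
        prev = val
    return adjusted


def ranksum_exact_standardized(a: list[float], b: list[float]) -> float:
    """|W - E[W]| / sqrt(Var[W]) with moments from exhaustive enumeration."""
    pooled = list(a) + list(b)
    n1 = len(a)
    ranks = {}
    # midranks for ties
    vals = sorted(pooled)
    for i in range(len(pooled)):
        v = pooled[i]
        positions = [j + 1 for j, u in enumerate(vals) if u == v]
        ranks[i] = sum(positions) / len(positions)
    w_obs = sum(ranks[i] for i in range(n1))
    # enumerate all assignments of which indices belong to group a
    rank_list = [ranks[i] for i in range(len(pooled))]
    all_w = [sum(rank_list[i] for i in comb)
             for comb in itertools.combinations(range(len(pooled)), n1)]
    mu = float(np.mean(all_w))
    var = float(np.var(all_w))
    return abs(w_obs - mu) / math.sqrt(var)


def auc_pairs(scores: list[float], labels: list[int]) -> float:
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))
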