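"""Numba kernels for the O(N^2) template-matching entropies.

The ApEn/SampEn sweep exploits early termination on the Chebyshev distance
(impossible in a vectorized formulation); the fuzzy-distance sweep is
branch-free so the compiler can vectorize it, leaving the exp to one
batched NumPy call.  Independent brute-force references used for
verification live in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def fuzzy_dists(X: np.ndarray, m: int, r: np.ndarray, out: np.ndarray) -> None:
    """Scaled template distances (d/r) for all pairs of every signal.

    ``out`` has shape (B, 2, n_pairs): Chebyshev distances between
    mean-centered templates of lengths m and m+1 (the same N-m templates at
    both lengths, Chen convention), divided by the per-signal tolerance.
    The inner loops are branch-free so they vectorize; the caller applies
    one exp over the whole buffer.  A zero tolerance maps d = 0 to 0 and
    d > 0 to inf (membership 1 and 0 after exp(-z^p)).
    """
    B, N = X.shape
    n = N - m
    for b in range(B):
        x = X[b]
        rb = r[b]
        inv = 1.0 / rb if rb > 0.0 else np.inf
        for li in range(2):
            mm = m + li
            comps = np.empty((mm, n))
            for i in range(n):
                s = 0.0
                for k in range(mm):
                    s += x[i + k]
                mu = s / mm
                for k in range(mm):
                    comps[k, i] = x[i + k] - mu
            row = out[b, li]
            pos = 0
            if mm == 2:
                c0, c1 = comps[0], comps[1]
                for i in range(n - 1):
                    a0, a1 = c0[i], c1[i]
                    for j in range(i + 1, n):
                        d0 = abs(a0 - c0[j])
                        d1 = abs(a1 - c1[j])
                        row[pos + j - i - 1] = max(d0, d1) * inv
                    pos += n - i - 1
            elif mm == 3:
                c0, c1, c2 = comps[0], comps[1], comps[2]
                for i in range(n - 1):
                    a0, a1, a2 = c0[i], c1[i], c2[i]
                    for j in range(i + 1, n):
                        d0 = abs(a0 - c0[j])
                        d1 = abs(a1 - c1[j])
                        d2 = abs(a2 - c2[j])
                        row[pos + j - i - 1] = max(d0, max(d1, d2)) * inv
                    pos += n - i - 1
            else:
                for i in range(n - 1):
                    for j in range(i + 1, n):
                        d = 0.0
                        for k in range(mm):
                            dk = abs(comps[k, i] - comps[k, j])
                            if dk > d:
                                d = dk
                        row[pos + j - i - 1] = d * inv
                    pos += n - i - 1
        if r[b] == 0.0:  # 0 * inf -> nan; restore the exact-match convention
            for li in range(2):
                row = out[b, li]
                for q in range(row.shape[0]):
                    if np.isnan(row[q]):
                        row[q] = 0.0


@njit(cache=False)
def apen_sampen_one(x: np.ndarray, m: int, r: float) -> tuple[float, float]:
    # One pair sweep serves both estimators: ApEn counts template matches
    # over N-m+1 (length m) / N-m (length m+1) templates with self-matches;
    # SampEn's B is the subset of m-matching pairs among the first N-m
    # templates and its A coincides with ApEn's (m+1)-pair count.
    n1 = x.shape[0] - m + 1
    n2 = n1 - 1
    c1 = np.ones(n1)
    c2 = np.ones(n2)
    a_cnt = 0
    b_cnt = 0
    for i in range(n1 - 1):
        for j in range(i + 1, n1):
            ok = True
            for k in range(m):
                if abs(x[i + k] - x[j + k]) > r:
                    ok = False
                    break
            if ok:
                c1[i] += 1.0
                c1[j] += 1.0
                if j < n2:
                    b_cnt += 1
                    if abs(x[i + m] - x[j + m]) <= r:
                        c2[i] += 1.0
                        c2[j] += 1.0
                        a_cnt += 1
    phi1 = 0.0
    for i in range(n1):
        phi1 += np.log(c1[i] / n1)
    phi2 = 0.0
    for i in range(n2):
        phi2 += np.log(c2[i] / n2)
    apen = phi1 / n1 - phi2 / n2
    sampen = -np.log(a_cnt / b_cnt) if a_cnt > 0 and b_cnt > 0 else np.nan
    return apen, sampen


@njit(cache=False)
def apen_sampen_batch(X: np.ndarray, m: int, r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ap = np.empty(X.shape[0])
    sp = np.empty(X.shape[0])
    for b in range(X.shape[0]):
        ap[b], sp[b] = apen_sampen_one(X[b], m, r[b])
    return ap, sp


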