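"""Independent brute-force reference implementations of the summary
statistics, used as oracles by the unit and acceptance tests.

Everything here is written by direct enumeration (all pairs, explicit
textbook formulas, dictionaries of haplotype strings) and deliberately
shares no code with sweepscan.sumstats.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def pairwise_diff(h1, h2) -> int:
    """Hamming distance over sites where both alleles are called."""
    n = 0
    for a, b in zip(h1, h2):
        if a >= 0 and b >= 0 and a != b:
            n += 1
    return n


def brute_pi(matrix: np.ndarray, accessible_bp: int) -> float:
    """Mean pairwise difference per site by enumerating every haplotype pair,
    each site weighted by its own non-missing pair count."""
    n_hap, n_sites = matrix.shape
    total = 0.0
    for j in range(n_sites):
        col = matrix[:, j]
        called = [a for a in col if a >= 0]
        m = len(called)
        if m < 2:
            continue
        diffs = sum(1 for a, b in itertools.combinations(called, 2) if a != b)
        total += diffs / (m * (m - 1) / 2)
    return total / accessible_bp


def brute_dxy(mat_a: np.ndarray, mat_b: np.ndarray, accessible_bp: int) -> float:
    total = 0.0
    for j in range(mat_a.shape[1]):
        ca = [a for a in mat_a[:, j] if a >= 0]
        cb = [b for b in mat_b[:, j] if b >= 0]
        if not ca or not cb:
            continue
        diffs = sum(1 for a in ca for b in cb if a != b)
        total += diffs / (len(ca) * len(cb))
    return total / accessible_bp


def brute_watterson(matrix: np.ndarray, accessible_bp: int) -> float:
    n = matrix.shape[0]
    s = 0
    for j in range(matrix.shape[1]):
        called = [a for a in matrix[:, j] if a >= 0]
        if 0 < sum(called) < len(called):
            s += 1
    a1 = sum(1.0 / i for i in range(1, n))
    return s / (a1 * accessible_bp)


def brute_tajimas_d(matrix: np.ndarray) -> float:
    """Textbook Tajima (1989) D with the standard constants."""
    n = matrix.shape[0]
    if n < 3:
        return float("nan")
    s = 0
    pi_total = 0.0
    for j in range(matrix.shape[1]):
        called = [a for a in matrix[:, j] if a >= 0]
        m = len(called)
        if m < 2:
            continue
        d = sum(called)
        if 0 < d < m:
            s += 1
        diffs = sum(1 for a, b in itertools.combinations(called, 2) if a != b)
        pi_total += diffs / (m * (m - 1) / 2)
    if s == 0:
        return float("nan")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (pi_total - s / a1) / math.sqrt(e1 * s + e2 * s * (s - 1))


def brute_fay_wu_h(matrix: np.ndarray) -> float:
    """theta_pi - theta_H over segregating sites, derived counts explicit."""
    total = 0.0
    any_site = False
    for j in range(matrix.shape[1]):
        called = [a for a in matrix[:, j] if a >= 0]
        m = len(called)
        d = sum(called)
        if m < 2 or d == 0 or d == m:
            continue
        any_site = True
        theta_pi = 2.0 * d * (m - d) / (m * (m - 1))
        theta_h = 2.0 * d * d / (m * (m - 1))
        total += theta_pi - theta_h
    return total if any_site else float("nan")


def brute_garud(matrix: np.ndarray) -> tuple[float, float, float]:
    """H1/H12/H2H1 by counting haplotype strings in a dictionary (no missing
    data expected)."""
    n = matrix.shape[0]
    counts: dict[tuple, int] = {}
    for i in range(n):
        key = tuple(int(a) for a in matrix[i])
        counts[key] = counts.get(key, 0) + 1
    freqs = sorted((c / n for c in counts.values()), reverse=True)
    h1 = sum(p * p for p in freqs)
    top2 = sum(freqs[:2])
    h12 = top2 * top2 + sum(p * p for p in freqs[2:])
    h2 = h1 - freqs[0] ** 2
    return h1, h12, h2 / h1


def brute_haf(matrix: np.ndarray) -> float:
    """Mean 1-HAF: each haplotype sums the derived counts of the sites where
    it carries the derived allele."""
    counts = matrix.sum(axis=0)
    scores = [
        sum(int(counts[j]) for j in range(matrix.shape[1]) if matrix[i, j] == 1)
        for i in range(matrix.shape[0])
    ]
    return float(np.mean(scores))


def brute_hudson_fst(mat_a: np.ndarray, mat_b: np.ndarray) -> float:
    """Ratio of averages of the Hudson per-site estimator."""
    num_sum = 0.0
    den_sum = 0.0
    for j in range(mat_a.shape[1]):
        ca = [a for a in mat_a[:, j] if a >= 0]
        cb = [b for b in mat_b[:, j] if b >= 0]
        n1, n2 = len(ca), len(cb)
        if n1 < 2 or n2 < 2:
            continue
        p1 = sum(ca) / n1
        p2 = sum(cb) / n2
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
        num_sum += num
        den_sum += den
    return num_sum / den_sum if den_sum != 0 else float("nan")


def brute_gmin(mat_a: np.ndarray, mat_b: np.ndarray) -> float:
    dists = [
        pairwise_diff(mat_a[i], mat_b[j])
        for i in range(mat_a.shape[0])
        for j in range(mat_b.shape[0])
    ]
    mean = float(np.mean(dists))
    return min(dists) / mean if mean > 0 else float("nan")


def brute_ss_h12(mat_a: np.ndarray, mat_b: np.ndarray) -> float:
    """The documented surrogate: pooled H12 magnitude; positive sign iff the
    modal pooled haplotype occurs in both populations at >= half its pooled
    frequency."""
    pooled = np.concatenate([mat_a, mat_b], axis=0)
    n = pooled.shape[0]
    counts: dict[tuple, int] = {}
    for i in range(n):
        key = tuple(int(a) for a in pooled[i])
        counts[key] = counts.get(key, 0) + 1
    # modal class with lexicographic tie-break
    best = min(sorted(counts), key=lambda k: (-counts[k], k))
    freqs = sorted((c / n for c in counts.values()), reverse=True)
    top2 = sum(freqs[:2])
    h12 = top2 * top2 + sum(p * p for p in freqs[2:])
    p_pooled = counts[best] / n
    fa = sum(1 for i in range(mat_a.shape[0]) if tuple(int(x) for x in mat_a[i]) == best) / mat_a.shape[0]
    fb = sum(1 for i in range(mat_b.shape[0]) if tuple(int(x) for x in mat_b[i]) == best) / mat_b.shape[0]
    sign = 1.0 if min(fa, fb) >= 0.5 * p_pooled else -1.0
    return sign * h12
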