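"""Independent brute-force reference implementations used by the tests.

These are deliberately naive (nested loops, exhaustive enumeration, exact
rational arithmetic) and share no code with the package internals they check.
"""

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np


def brute_force_profile(reads, windows, extension, sizes, bin_rule="overlap"):
    """Per-(window, bin, read) triple loop over interval overlaps."""
    counts = np.zeros((len(windows), windows[0].n_bins), dtype=np.int64)
    extended = []
    for chrom, start, end, strand in reads:
        if chrom not in sizes:
            continue
        if strand == "+":
            s, e = start, end + extension
        else:
            s, e = start - extension, end
        s, e = max(0, s), min(sizes[chrom], e)
        extended.append((chrom, s, e))
    for wi, w in enumerate(windows):
        for b in range(w.n_bins):
            bs, be = w.bin_interval(b)
            for chrom, s, e in extended:
                if chrom != w.chrom:
                    continue
                if bin_rule == "overlap":
                    if s < be and e > bs:
                        counts[wi, b] += 1
                else:
                    mid = (s + e) // 2
                    if bs <= mid < be:
                        counts[wi, b] += 1
        for b in w.clipped_bins:
            counts[wi, b] = 0
    return counts


def exhaustive_kmeans2(X):
    """Globally optimal 2-cluster SSE by enumerating all bipartitions."""
    n = len(X)
    best = np.inf
    idx = list(range(n))
    for size in range(1, n // 2 + 1):
        for subset in combinations(idx, size):
            a = np.array(subset)
            b = np.array([i for i in idx if i not in subset])
            sse = 0.0
            for part in (a, b):
                mu = X[part].mean(axis=0)
                sse += ((X[part] - mu) ** 2).sum()
            best = min(best, sse)
    return best


def hypergeom_upper_tail_exact(N, K, n, k):
    """P(X >= k) as an exact rational via binomial coefficients."""
    total = comb(N, n)
    acc = Fraction(0)
    for i in range(k, min(K, n) + 1):
        acc += Fraction(comb(K, i) * comb(N - K, n - i), total)
    return acc


def pca_eigh_variance_ratios(X):
    """Variance ratios from a dense eigendecomposition of the covariance."""
    Xc = X - X.mean(axis=0)
    C = Xc.T @ Xc / 1.0
    vals = np.linalg.eigvalsh(C)[::-1]
    vals = np.clip(vals, 0, None)
    return vals / vals.sum()
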