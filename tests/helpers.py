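"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately written in plain Python (dicts, loops,
``statistics``) with no shared code paths with :mod:`thinpred`, so a test
comparing the two is a genuine dual-route check.
"""

from __future__ import annotations

import math
import statistics
from collections import Counter, defaultdict


def brute_pe(values, d, tau, weighted=False, norm="possible"):
    """Permutation entropy by direct motif enumeration (bits)."""
    values = list(values)
    n_motifs = len(values) - (d - 1) * tau
    assert n_motifs >= 1, "series too short"
    mass: dict = defaultdict(float)
    total = 0.0
    for t in range(n_motifs):
        motif = [values[t + j * tau] for j in range(d)]
        # stable ordinal pattern: sort positions by (value, position)
        pattern = tuple(sorted(range(d), key=lambda j: (motif[j], j)))
        w = statistics.pvariance(motif) if weighted else 1.0
        mass[pattern] += w
        total += w
    assert total > 0, "degenerate: all motifs constant"
    probs = [m / total for m in mass.values() if m > 0]
    h = -sum(p * math.log2(p) for p in probs)
    if norm == "possible":
        return h / math.log2(math.factorial(d))
    if norm == "observed":
        n_obs = sum(1 for m in mass.values() if m > 0)
        return 0.0 if n_obs <= 1 else h / math.log2(n_obs)
    return h


def brute_pe_grid_search(values, d_lo=2, d_hi=5, tau_lo=1, tau_hi=7, weighted=True):
    """Exhaustive re-scan of the PE parameter grid (observed normalization)."""
    best, best_score = None, math.inf
    for d in range(d_lo, d_hi + 1):
        for tau in range(tau_lo, tau_hi + 1):
            if len(values) < (d - 1) * tau + 1:
                continue
            score = brute_pe(values, d, tau, weighted=weighted, norm="observed")
            if score < best_score:
                best, best_score = (d, tau), score
    return best


def brute_mi_bits(xs, ys):
    """Plug-in mutual information over discrete symbol pairs (bits)."""
    assert len(xs) == len(ys)
    n = len(xs)

    def entropy(counter):
        return -sum((c / n) * math.log2(c / n) for c in counter.values())

    return entropy(Counter(xs)) + entropy(Counter(ys)) - entropy(Counter(zip(xs, ys)))


def brute_acf(values, lag):
    """Pearson autocorrelation via the textbook sums."""
    a = list(values[:-lag])
    b = list(values[lag:])
    ma, mb = statistics.fmean(a), statistics.fmean(b)
    num = sum((u - ma) * (v - mb) for u, v in zip(a, b))
    den = math.sqrt(sum((u - ma) ** 2 for u in a) * sum((v - mb) ** 2 for v in b))
    return num / den
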