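"""Independent brute-force oracles used by the test suite.

These are deliberately literal, loop-by-loop transcriptions of the defining
formulas, kept free of any code shared with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np


def fuzzy_entropy_bruteforce(
    x, m: int = 2, r: float = 0.25, n_exp: float = 2.0, relative: bool = True
) -> float:
    """ln(phi_m) - ln(phi_{m+1}) by explicit enumeration of all window pairs.

    Both window lengths use the same K = N - m starting positions; the
    membership of a pair is exp(-(chebyshev/r_eff)^n) and self-pairs are
    excluded from the average.
    """
    x = [float(v) for v in x]
    N = len(x)
    K = N - m
    assert K >= 2, "sequence too short"
    mean = sum(x) / N
    sd = math.sqrt(sum((v - mean) ** 2 for v in x) / N)
    if sd == 0:
        return 0.0
    r_eff = r * sd if relative else r

    def phi(w: int) -> float:
        windows = [x[i : i + w] for i in range(K)]
        total = 0.0
        for i in range(K):
            inner = 0.0
            for j in range(K):
                if j == i:
                    continue
                d = max(abs(a - b) for a, b in zip(windows[i], windows[j]))
                inner += math.exp(-((d / r_eff) ** n_exp))
            total += inner / (K - 1)
        return total / K

    return math.log(phi(m)) - math.log(phi(m + 1))


def relieff_bruteforce(X, y, m_iter: int, k_nn: int, seed: int) -> np.ndarray:
    """Per-column ReliefF weights by explicit per-instance enumeration.

    Columns are min-max scaled to [0,1] (constant columns to zero); for each
    sampled instance the k nearest hits and misses by Euclidean distance
    update every column weight by mean miss-difference minus mean
    hit-difference, averaged over sampled instances.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    Xs = np.zeros_like(X)
    for c in range(p):
        lo, hi = X[:, c].min(), X[:, c].max()
        if hi > lo:
            Xs[:, c] = (X[:, c] - lo) / (hi - lo)
    rng = np.random.default_rng(seed)
    m_eff = min(m_iter, n)
    sampled = rng.choice(n, size=m_eff, replace=False)
    W = np.zeros(p)
    for i in sampled:
        dists = []
        for j in range(n):
            dists.append(math.sqrt(sum((Xs[i, c] - Xs[j, c]) ** 2 for c in range(p))))
        hits = [j for j in sorted(range(n), key=lambda j: dists[j])
                if y[j] == y[i] and j != i][:k_nn]
        misses = [j for j in sorted(range(n), key=lambda j: dists[j])
                  if y[j] != y[i]][:k_nn]
        for c in range(p):
            hit_diff = sum(abs(Xs[i, c] - Xs[j, c]) for j in hits) / len(hits)
            miss_diff = sum(abs(Xs[i, c] - Xs[j, c]) for j in misses) / len(misses)
            W[c] += miss_diff - hit_diff
    return W / m_eff


def band_energy_fractions_fft(signal, fs: float, bands: dict) -> dict:
    """Fraction of spectral energy (rfft periodogram) in each band."""
    sig = np.asarray(signal, dtype=float)
    spec = np.abs(np.fft.rfft(sig)) ** 2
    freqs = np.fft.rfftfreq(len(sig), d=1.0 / fs)
    total = spec.sum()
    out = {}
    for name, (lo, hi) in bands.items():
        out[name] = spec[(freqs >= lo) & (freqs < hi)].sum() / total
    return out
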