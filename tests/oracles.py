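"""Independent brute-force oracles the implementation is checked against.

Everything here is written from the mathematical definition, deliberately
avoiding the code paths (and, where possible, even the numpy routines) used
by the package.
"""

from functools import lru_cache
import math


def dtw_brute(x, y):
    """DTW by plain memoized recursion over the alignment lattice."""
    x = tuple(float(v) for v in x)
    y = tuple(float(v) for v in y)

    @lru_cache(maxsize=None)
    def d(i, j):
        cost = abs(x[i] - y[j])
        if i == 0 and j == 0:
            return cost
        best = math.inf
        if i > 0:
            best = min(best, d(i - 1, j))
        if j > 0:
            best = min(best, d(i, j - 1))
        if i > 0 and j > 0:
            best = min(best, d(i - 1, j - 1))
        return cost + best

    return d(len(x) - 1, len(y) - 1)


def percentile_linear(sorted_vals, q):
    """Linear-interpolation percentile on a pre-sorted list (q in [0,100])."""
    n = len(sorted_vals)
    if n == 1:
        return sorted_vals[0]
    pos = q / 100.0 * (n - 1)
    lo = int(math.floor(pos))
    hi = min(lo + 1, n - 1)
    frac = pos - lo
    return sorted_vals[lo] * (1 - frac) + sorted_vals[hi] * frac


def stats_brute(values):
    """[mean, max, min, population sd, Q1, Q2, Q3] from first principles."""
    vals = [float(v) for v in values]
    n = len(vals)
    mean = sum(vals) / n
    var = sum((v - mean) ** 2 for v in vals) / n
    s = sorted(vals)
    return [mean, max(vals), min(vals), math.sqrt(var),
            percentile_linear(s, 25), percentile_linear(s, 50),
            percentile_linear(s, 75)]


def trapezoid_brute(values, dt):
    """Composite trapezoid rule by explicit summation."""
    vals = [float(v) for v in values]
    return sum((vals[i] + vals[i + 1]) / 2.0 * dt for i in range(len(vals) - 1))


def dft_magnitude_brute(values):
    """One-sided magnitude spectrum (DC included) via the naive O(n^2) DFT."""
    vals = [float(v) for v in values]
    n = len(vals)
    out = []
    for k in range(n // 2 + 1):
        re = sum(v * math.cos(-2 * math.pi * k * i / n)
                 for i, v in enumerate(vals))
        im = sum(v * math.sin(-2 * math.pi * k * i / n)
                 for i, v in enumerate(vals))
        out.append(math.hypot(re, im))
    return out


def lowpass_fft_oracle(x, cutoff_hz, fs):
    """Frequency-domain low-pass: zero every bin at/above the cutoff."""
    import numpy as np
    spec = np.fft.rfft(np.asarray(x, dtype=float))
    freqs = np.fft.rfftfreq(len(x), d=1.0 / fs)
    spec[freqs >= cutoff_hz] = 0.0
    return np.fft.irfft(spec, n=len(x))
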