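"""Independent reference implementations used only to check the package.

Everything here is deliberately naive — pure-Python double loops, direct FFT
masking, two-pass statistics — and shares no code with the implementation
under test.
"""

from __future__ import annotations

import math

import numpy as np


def fuzzyen_bruteforce(
    x,
    m: int = 2,
    n: float = 2.0,
    r_factor: float = 0.2,
    convention: str = "chen",
) -> float:
    """O(N^2) fuzzy entropy enumerating every (s, t) template pair.

    The epoch is divided by its population SD, then the similarity
    exp(-(d)^n / r_factor) of baseline-removed template vectors is averaged
    under the Chebyshev distance, for lengths m and m+1.
    """
    xs = [float(v) for v in x]
    big_n = len(xs)
    mean = sum(xs) / big_n
    sd = math.sqrt(sum((v - mean) ** 2 for v in xs) / big_n)
    if sd == 0.0:
        return 0.0
    z = [v / sd for v in xs]
    z_mean = sum(z) / big_n

    def phi(length: int, count: int, epoch_baseline: bool) -> float:
        vecs = []
        for s in range(count):
            window = z[s : s + length]
            base = z_mean if epoch_baseline else sum(window) / length
            vecs.append([v - base for v in window])
        outer = 0.0
        for s in range(count):
            inner = 0.0
            for t in range(count):
                if t == s:
                    continue
                d = max(abs(a - b) for a, b in zip(vecs[s], vecs[t]))
                inner += math.exp(-(d**n) / r_factor)
            outer += inner / (count - 1)
        return outer / count

    if convention == "chen":
        return math.log(phi(m, big_n - m, False)) - math.log(phi(m + 1, big_n - m, False))
    return math.log(phi(m, big_n - m + 1, True)) - math.log(phi(m + 1, big_n - m, True))


def fft_band_energy(x, fs: float, lo: float, hi: float) -> float:
    """Energy of x restricted to [lo, hi] Hz by zeroing all other FFT bins."""
    spec = np.fft.rfft(np.asarray(x, dtype=float))
    freqs = np.fft.rfftfreq(len(x), d=1.0 / fs)
    spec[(freqs < lo) | (freqs > hi)] = 0.0
    masked = np.fft.irfft(spec, n=len(x))
    return float(np.sum(masked**2))


def energy_direct(x) -> float:
    """Exact sum of squares via compensated summation."""
    return math.fsum(float(v) * float(v) for v in x)


def mean_sd_twopass(values) -> tuple[float, float]:
    """Two-pass mean and sample SD (n-1)."""
    vals = [float(v) for v in values]
    n = len(vals)
    mean = math.fsum(vals) / n
    var = math.fsum((v - mean) ** 2 for v in vals) / (n - 1)
    return mean, math.sqrt(var)


def student_t2_two_sided_p(t: float) -> float:
    """Two-sided p for the t distribution with 2 df, closed form.

    F(t) = 1/2 + t / (2*sqrt(2)*sqrt(1 + t^2/2)).
    """
    cdf = 0.5 + t / (2.0 * math.sqrt(2.0) * math.sqrt(1.0 + t * t / 2.0))
    return 2.0 * (1.0 - cdf)
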