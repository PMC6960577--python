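"""Independent brute-force reference implementations used as test oracles.

These are deliberately written as plain loops / direct convolutions so they
share no code path with the package implementation they check.
"""

import numpy as np


def poincare_bruteforce(rr):
    """Lag-1 Poincaré descriptors by explicit per-point loop."""
    x = [rr[i] for i in range(len(rr) - 1)]
    y = [rr[i + 1] for i in range(len(rr) - 1)]
    n = len(x)
    xc = sum(x) / n
    yc = sum(y) / n
    d1sq = d2sq = 0.0
    for xi, yi in zip(x, y):
        d1 = abs((xi - xc) - (yi - yc)) / np.sqrt(2)
        d2 = abs((xi - xc) + (yi - yc)) / np.sqrt(2)
        d1sq += d1 * d1
        d2sq += d2 * d2
    sd1 = np.sqrt(d1sq / n)
    sd2 = np.sqrt(d2sq / n)
    return sd1, sd2, np.sqrt(xc**2 + yc**2), np.pi * sd1 * sd2


def reference_dwt_step(x, dec_lo, dec_hi):
    """One DWT level by direct convolution: half-sample symmetric extension
    of width L-1 on both sides, full convolution, odd-indexed downsampling."""
    L = len(dec_lo)
    ext = np.concatenate([x[L - 2 :: -1], x, x[:-L:-1]])
    a = np.convolve(ext, dec_lo, mode="valid")[1::2]
    d = np.convolve(ext, dec_hi, mode="valid")[1::2]
    return a, d


def reference_dwt_cascade(x, dec_lo, dec_hi, level):
    """Level-``level`` approximation and detail coefficients."""
    a = np.asarray(x, dtype=float)
    d = None
    for _ in range(level):
        a, d = reference_dwt_step(a, dec_lo, dec_hi)
    return a, d
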