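"""Independent brute-force oracles shared across test modules."""

import math

from scipy.stats import hypergeom


def triangle_oracle(hist):
    """Exhaustive point-to-line-distance Triangle threshold.

    Re-derives the threshold from first principles: build the chord from
    the peak to the farthest non-empty bin as an explicit line Ax+By+C=0,
    evaluate every candidate bin's perpendicular distance with the
    textbook formula, and take the maximum (ties toward the peak).
    """
    hist = list(map(float, hist))
    nonzero = [i for i, h in enumerate(hist) if h > 0]
    peak = max(range(256), key=lambda i: hist[i])
    lo, hi = nonzero[0], nonzero[-1]
    tail = lo if (peak - lo) >= (hi - peak) else hi
    if tail == peak:
        tail = hi if peak == lo else lo
    x1, y1, x2, y2 = peak, hist[peak], tail, hist[tail]
    A, B, C = y2 - y1, -(x2 - x1), (x2 - x1) * y1 - (y2 - y1) * x1
    best_bin, best_dist = None, -1.0
    step = 1 if tail > peak else -1
    for b in range(peak + step, tail, step):
        d = abs(A * b + B * hist[b] + C) / math.hypot(A, B)
        if d > best_dist + 1e-12:
            best_dist, best_bin = d, b
    return peak if best_bin is None else best_bin


def fisher_oracle(table):
    """Two-sided Fisher p by full hypergeometric enumeration."""
    a, b = table[0]
    c, d = table[1]
    row1, col1, N = a + b, a + c, a + b + c + d
    p_obs = hypergeom.pmf(a, N, col1, row1)
    total = 0.0
    for x in range(max(0, row1 + col1 - N), min(row1, col1) + 1):
        p = hypergeom.pmf(x, N, col1, row1)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


def random_histogram(rng):
    """A random 256-bin histogram with a dominant peak plus scattered mass."""
    import numpy as np

    hist = np.zeros(256, dtype=int)
    peak = int(rng.integers(0, 256))
    hist[peak] = int(rng.integers(500, 5000))
    n_extra = int(rng.integers(2, 60))
    bins = rng.integers(0, 256, size=n_extra)
    hist[bins] += rng.integers(1, 400, size=n_extra)
    if np.count_nonzero(hist) < 2:
        hist[(peak + 37) % 256] += 5
    return hist
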