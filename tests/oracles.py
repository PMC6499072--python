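"""Independent brute-force reference implementations used as test oracles.

These deliberately use naive loops / two-pass formulas and share no code with
the package paths they check.
"""

from __future__ import annotations

import math

import numpy as np


def brute_weighted_centroid(weights: np.ndarray) -> tuple[float, ...]:
    """Sum(w * p) / Sum(w) by explicit iteration over every element."""
    total = 0.0
    acc = [0.0] * weights.ndim
    for idx in np.ndindex(weights.shape):
        w = float(weights[idx])
        total += w
        for d, c in enumerate(idx):
            acc[d] += w * c
    return tuple(a / total for a in acc)


def brute_scalar_projection(point, origin, toward) -> float:
    """Signed projection of (point - origin) onto the unit vector toward - origin."""
    ax = [t - o for t, o in zip(toward, origin)]
    norm = math.sqrt(sum(a * a for a in ax))
    ax = [a / norm for a in ax]
    d = [p - o for p, o in zip(point, origin)]
    return sum(di * ai for di, ai in zip(d, ax))


def brute_pearson(x, y) -> float:
    """Two-pass covariance / sigma-sigma Pearson coefficient."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    sx = math.sqrt(sum((a - mx) ** 2 for a in x) / n)
    sy = math.sqrt(sum((b - my) ** 2 for b in y) / n)
    return cov / (sx * sy)


def brute_longest_run(flags) -> tuple[int, int]:
    """(start, length) of the longest contiguous run of truthy values, by
    exhaustive scan over all (start, end) windows."""
    flags = list(bool(f) for f in flags)
    best = (-1, 0)
    for i in range(len(flags)):
        for j in range(i, len(flags)):
            if all(flags[i : j + 1]) and (j - i + 1) > best[1]:
                best = (i, j - i + 1)
    return best


def brute_disc_pixel_count(shape, center, radius) -> int:
    """Number of pixel centers strictly within ``radius`` of ``center``."""
    count = 0
    for yx in np.ndindex(shape):
        if sum((c - cc) ** 2 for c, cc in zip(yx, center)) <= radius**2:
            count += 1
    return count
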