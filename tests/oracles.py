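"""Independent brute-force oracles used by the tests.

Deliberately written with explicit Python loops and lists, independent of
the vectorised implementations they check.
"""

import math


def pb_pairwise_slopes_oracle(x, y):
    """Explicit enumeration of usable pairwise slopes and the offset K."""
    slopes = []
    n = len(x)
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[j] - x[i]
            dy = y[j] - y[i]
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                s = math.inf if dy > 0 else -math.inf
            else:
                s = dy / dx
            if s == -1.0:
                continue
            slopes.append(s)
    slopes.sort()
    k = sum(1 for s in slopes if s < -1.0)
    return slopes, k


def pb_slope_oracle(x, y):
    """Shifted median over explicitly enumerated pairs; None if degenerate."""
    slopes, k = pb_pairwise_slopes_oracle(x, y)
    n = len(slopes)
    if n < 2:
        return None

    def order_stat(rank):
        return slopes[min(max(rank - 1 + k, 0), n - 1)]

    if n % 2 == 1:
        return order_stat((n + 1) // 2)
    return 0.5 * (order_stat(n // 2) + order_stat(n // 2 + 1))


def ols_line_oracle(x, y):
    """Closed-form normal equations for the straight line y = a + b*x."""
    n = len(x)
    sx = sum(x)
    sy = sum(y)
    sxx = sum(v * v for v in x)
    sxy = sum(u * v for u, v in zip(x, y))
    b = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    a = (sy - b * sx) / n
    return a, b
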