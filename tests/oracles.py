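"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths of the package: quantiles are
built from explicit order-statistic interpolation, volume integrals from
exact piecewise-linear geometry over the sorted heights, the two-sample
trimmed-means test from scipy building blocks, and Cliff's delta from
pair enumeration.
"""

import math

import numpy as np
from scipy import stats
from scipy.stats.mstats import winsorize


def zeta_oracle(heights, p):
    """Inverse material ratio: type-7 quantile at 1 − p/100, by hand."""
    a = np.sort(np.asarray(heights, dtype=float).ravel())
    n = a.size
    q = 1.0 - p / 100.0
    pos = (n - 1) * q
    i = int(math.floor(pos))
    if i >= n - 1:
        return float(a[-1])
    frac = pos - i
    return float(a[i] + frac * (a[i + 1] - a[i]))


def _integral_zeta(heights, x):
    """∫₀ˣ ζ(r) dr for the piecewise-linear quantile function (exact)."""
    b = np.sort(np.asarray(heights, dtype=float).ravel())[::-1]
    n = b.size
    knots = 100.0 * np.arange(n) / (n - 1)
    total = 0.0
    for k in range(n - 1):
        p0, p1 = knots[k], knots[k + 1]
        if p1 <= x:
            total += 0.5 * (b[k] + b[k + 1]) * (p1 - p0)
        elif p0 < x < p1:
            zx = b[k] + (b[k + 1] - b[k]) * (x - p0) / (p1 - p0)
            total += 0.5 * (b[k] + zx) * (x - p0)
            break
        else:
            break
    return total


def vm_oracle(heights, x):
    """Material volume Vm(x) = (1/100)·∫₀ˣ [ζ(r) − ζ(x)] dr, exact."""
    return (_integral_zeta(heights, x) - x * zeta_oracle(heights, x)) / 100.0


def vv_oracle(heights, x):
    """Void volume Vv(x) = (1/100)·∫ₓ¹⁰⁰ [ζ(x) − ζ(r)] dr, exact."""
    full = _integral_zeta(heights, 100.0)
    tail = full - _integral_zeta(heights, x)
    return ((100.0 - x) * zeta_oracle(heights, x) - tail) / 100.0


def yuen_oracle(x, y, gamma):
    """Two-sample trimmed-means test from scipy building blocks."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)

    def d_of(v):
        n = v.size
        g = int(math.floor(gamma * n))
        h = n - 2 * g
        sw2 = np.var(winsorize(np.sort(v), (gamma, gamma)), ddof=1)
        return (n - 1) * sw2 / (h * (h - 1)), stats.trim_mean(v, gamma), h

    dx, mx, hx = d_of(x)
    dy, my, hy = d_of(y)
    t = abs(mx - my) / math.sqrt(dx + dy)
    df = (dx + dy) ** 2 / (dx**2 / (hx - 1) + dy**2 / (hy - 1))
    p = 2.0 * stats.t.sf(t, df)
    return t, df, p


def cliff_delta_oracle(x, y):
    """Cliff's delta by explicit enumeration of all pairs."""
    gt = sum(1 for xi in x for yj in y if xi > yj)
    lt = sum(1 for xi in x for yj in y if xi < yj)
    return (gt - lt) / (len(x) * len(y))
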