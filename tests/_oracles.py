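"""Independent brute-force oracles, deliberately written without any of
the package's interpolation or summary code paths."""

import numpy as np


def natural_spline_oracle(knot_x, knot_y, eval_x):
    """Natural cubic spline by direct solve of the classical tridiagonal
    system for the knot second derivatives (zero at the boundaries),
    followed by the textbook piecewise-cubic evaluation. Only valid for
    eval_x within [knot_x[0], knot_x[-1]]."""
    x = np.asarray(knot_x, float)
    y = np.asarray(knot_y, float)
    n = x.size
    h = np.diff(x)
    A = np.zeros((n, n))
    b = np.zeros(n)
    A[0, 0] = 1.0
    A[-1, -1] = 1.0
    for i in range(1, n - 1):
        A[i, i - 1] = h[i - 1]
        A[i, i] = 2.0 * (h[i - 1] + h[i])
        A[i, i + 1] = h[i]
        b[i] = 6.0 * ((y[i + 1] - y[i]) / h[i] - (y[i] - y[i - 1]) / h[i - 1])
    M = np.linalg.solve(A, b)  # knot second derivatives

    eval_x = np.atleast_1d(np.asarray(eval_x, float))
    out = np.empty_like(eval_x)
    for k, xv in enumerate(eval_x):
        i = min(max(np.searchsorted(x, xv, side="right") - 1, 0), n - 2)
        hi = h[i]
        t0, t1 = x[i + 1] - xv, xv - x[i]
        out[k] = (M[i] * t0 ** 3 / (6 * hi) + M[i + 1] * t1 ** 3 / (6 * hi)
                  + (y[i] / hi - M[i] * hi / 6) * t0
                  + (y[i + 1] / hi - M[i + 1] * hi / 6) * t1)
    return out


def percentile_type7_oracle(values, q):
    """Type-7 percentile from first principles: sort, then linearly
    interpolate between the order statistics at rank (n-1) * q/100."""
    v = np.sort(np.asarray(values, float))
    pos = (v.size - 1) * q / 100.0
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    frac = pos - lo
    return v[lo] * (1 - frac) + v[hi] * frac


def band_users_oracle(profile_p, counts, lo, hi):
    """Band user total by explicit per-age loop."""
    total = 0.0
    for a in range(lo, hi + 1):
        total += counts[a] * profile_p[a]
    return total
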