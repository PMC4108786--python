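"""Independent reference implementations used to validate the fast paths."""

import math

import numpy as np

from slgraph.sl import embed


def sl_pair_bruteforce(x, y, params):
    """Exhaustive recurrence enumeration straight from the definition.

    For every reference time i, each channel's critical squared distance is
    the ceil(p_ref * n_candidates)-th smallest squared distance to the
    candidates in the (w1, w2] annulus; recurrences are candidates at or
    below it.  SL is the coincidence fraction averaged over references and
    symmetrized over the two conditioning directions.
    """
    ex = embed(np.asarray(x, float), params.m, params.lag)
    ey = embed(np.asarray(y, float), params.m, params.lag)
    n = ex.shape[0]
    total, used = 0.0, 0
    for i in range(n):
        cand = [j for j in range(n) if params.w1 < abs(i - j) <= params.w2]
        if not cand:
            continue
        k = max(1, math.ceil(params.p_ref * len(cand)))
        dx = {j: float(np.sum((ex[i] - ex[j]) ** 2)) for j in cand}
        dy = {j: float(np.sum((ey[i] - ey[j]) ** 2)) for j in cand}
        rx_crit = sorted(dx.values())[k - 1]
        ry_crit = sorted(dy.values())[k - 1]
        rx = {j for j in cand if dx[j] <= rx_crit}
        ry = {j for j in cand if dy[j] <= ry_crit}
        both = len(rx & ry)
        total += 0.5 * (both / len(rx) + both / len(ry))
        used += 1
    return total / used


def ar1(rng, n, phi=0.95):
    """Stationary AR(1) surrogate with burn-in."""
    e = rng.standard_normal(n + 200)
    x = np.empty(n + 200)
    x[0] = e[0]
    for i in range(1, n + 200):
        x[i] = phi * x[i - 1] + e[i]
    return x[200:]
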