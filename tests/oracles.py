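"""Independent brute-force oracles used by the test-suite.

These deliberately avoid the package's own algorithms: visit detection by
dense 1-second resampling of each segment, and the KS statistic by direct
ECDF evaluation on a grid of pooled values.
"""

import numpy as np


def dense_visits(t, x, y, cx, cy, radius, min_away_s, step_s=1.0):
    """Visits of a piecewise-linear track to a circle, by dense resampling.

    Every segment is sampled at ``step_s`` resolution, in/out runs are
    scanned directly, and runs separated by less than ``min_away_s``
    outside time are merged.  Returns (entries, exits) in seconds.
    """
    ts = [np.asarray([t[0]])]
    xs = [np.asarray([x[0]])]
    ys = [np.asarray([y[0]])]
    for i in range(len(t) - 1):
        dt = t[i + 1] - t[i]
        n = max(int(np.ceil(dt / step_s)), 1)
        s = (np.arange(1, n + 1) / n)
        ts.append(t[i] + s * dt)
        xs.append(x[i] + s * (x[i + 1] - x[i]))
        ys.append(y[i] + s * (y[i + 1] - y[i]))
    tt = np.concatenate(ts)
    xx = np.concatenate(xs)
    yy = np.concatenate(ys)
    inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius * radius
    if not inside.any():
        return np.empty(0), np.empty(0)
    padded = np.concatenate(([False], inside, [False]))
    changes = np.flatnonzero(np.diff(padded.astype(np.int8)))
    entries = tt[changes[0::2]]
    exits = tt[np.minimum(changes[1::2], len(tt)) - 1]
    # merge runs with outside gaps shorter than min_away_s
    me, mx = [entries[0]], [exits[0]]
    for e, o in zip(entries[1:], exits[1:]):
        if e - mx[-1] < min_away_s:
            mx[-1] = max(mx[-1], o)
        else:
            me.append(e)
            mx.append(o)
    return np.asarray(me), np.asarray(mx)


def random_walk(rng, n=300, step_sd=300.0, fix_interval_s=600.0):
    """A plain Gaussian random walk trajectory for oracle comparisons."""
    t = np.arange(n) * fix_interval_s
    x = np.cumsum(rng.normal(0, step_sd, n))
    y = np.cumsum(rng.normal(0, step_sd, n))
    return t, x, y


def ks_D_grid(a, b):
    """KS statistic by direct ECDF evaluation at all pooled values."""
    grid = np.concatenate([a, b])
    fa = np.array([(a <= g).mean() for g in grid])
    fb = np.array([(b <= g).mean() for g in grid])
    return float(np.abs(fa - fb).max())
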