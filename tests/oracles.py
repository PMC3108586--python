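"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's linear-algebra fitting path: the
cosinor oracle is an exhaustive grid search over (mesor, amplitude,
acrophase); the ANOVA oracle computes between/within sums of squares
directly; the Fisher oracle enumerates the hypergeometric distribution.
"""

import math

import numpy as np


def grid_search_cosinor(t, y, period=24.0, frac_step=0.01, phi_step=0.01):
    """Exhaustive SSE minimisation on a (M, A, phi) grid.

    M spans the data range and A spans [0, range], both at ``frac_step`` of
    the range; phi spans [0, period) at ``phi_step`` hours. Returns
    ``(best_sse, (M, A, phi))``. Uses the sufficient-statistic expansion of
    the SSE so the full grid is evaluated exactly but cheaply.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    lo, hi = y.min(), y.max()
    rng_y = hi - lo
    if rng_y == 0.0:
        return 0.0, (float(lo), 0.0, float("nan"))
    ms = np.arange(lo, hi + 0.5 * frac_step * rng_y, frac_step * rng_y)
    amps = np.arange(0.0, rng_y + 0.5 * frac_step * rng_y, frac_step * rng_y)
    phis = np.arange(0.0, period, phi_step)
    w = 2.0 * np.pi / period
    n = len(y)
    syy, sy = float(y @ y), float(y.sum())

    best_sse = math.inf
    best = None
    for start in range(0, len(phis), 200):
        chunk = phis[start:start + 200]
        cosmat = np.cos(w * (t[None, :] - chunk[:, None]))  # (k, n)
        s_c = cosmat.sum(axis=1)
        s_cc = (cosmat * cosmat).sum(axis=1)
        s_yc = cosmat @ y
        m = ms[None, :, None]
        a = amps[None, None, :]
        sse = (syy - 2.0 * m * sy + n * m * m
               - 2.0 * a * s_yc[:, None, None]
               + 2.0 * m * a * s_c[:, None, None]
               + a * a * s_cc[:, None, None])
        k = int(np.argmin(sse))
        if sse.flat[k] < best_sse:
            best_sse = float(sse.flat[k])
            ki, mi, ai = np.unravel_index(k, sse.shape)
            best = (float(ms[mi]), float(amps[ai]), float(chunk[ki]))
    return best_sse, best


def oneway_anova_f(groups):
    """Textbook between/within one-way ANOVA F from a list of 1-d arrays."""
    all_y = np.concatenate(groups)
    grand = all_y.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(float(((g - g.mean()) ** 2).sum()) for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_y) - len(groups)
    return (ss_between / df_b) / (ss_within / df_w), df_b, df_w


def fisher_two_sided_p(table):
    """Two-sided Fisher exact p by exhaustive hypergeometric enumeration."""
    (a, b), (c, d) = table
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def pmf(k):
        return (math.comb(row1, k) * math.comb(row2, col1 - k)
                / math.comb(n, col1))

    p_obs = pmf(a)
    lo = max(0, col1 - row2)
    hi = min(col1, row1)
    return sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs * (1 + 1e-12))
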