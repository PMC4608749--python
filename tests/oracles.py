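"""Independent brute-force oracles for the pixel-wise fits.

Dense 1-D grid search over the relaxation time with the amplitude solved in
closed form per grid node — deliberately naive so it shares nothing with the
nonlinear path it cross-checks.
"""

import numpy as np


def grid_search_monoexp(t, y, t_grid):
    """Best (A, T) for S = A*exp(-t/T) over an explicit T grid.

    For fixed T the optimal amplitude is the linear projection
    A = sum(y*e) / sum(e*e) with e = exp(-t/T).
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    best = (np.inf, np.nan, np.nan)
    for T in t_grid:
        e = np.exp(-t / T)
        a = float(y @ e) / float(e @ e)
        ssr = float(np.sum((a * e - y) ** 2))
        if ssr < best[0]:
            best = (ssr, a, T)
    return best[1], best[2]


def grid_search_ir_magnitude(ti, y, t_grid):
    """Best (A, T1) for |A*(1 - 2*exp(-TI/T1))| against magnitude data.

    For fixed T1 and A > 0 the model magnitude is A*|m| with
    m = 1 - 2*exp(-TI/T1), so A projects linearly onto |m|.
    """
    ti = np.asarray(ti, float)
    y = np.asarray(y, float)
    best = (np.inf, np.nan, np.nan)
    for T1 in t_grid:
        m = np.abs(1.0 - 2.0 * np.exp(-ti / T1))
        denom = float(m @ m)
        if denom == 0:
            continue
        a = max(float(y @ m) / denom, 0.0)
        ssr = float(np.sum((a * m - y) ** 2))
        if ssr < best[0]:
            best = (ssr, a, T1)
    return best[1], best[2]
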