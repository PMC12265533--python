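"""Independent brute-force oracles shared by the detector test modules.

These loop explicitly over every sliding window / sample and stay
deliberately independent of the vectorized implementations they check.
"""

import numpy as np


def oracle_step(x, win, step, thr):
    """Half-window mean-difference step detector on one signal."""
    half = win // 2
    for start in range(0, len(x) - win + 1, step):
        w = x[start : start + win]
        if abs(w[half : 2 * half].mean() - w[:half].mean()) > thr:
            return True
    return False


def oracle_p2p(x, win, step, thr):
    for start in range(0, len(x) - win + 1, step):
        w = x[start : start + win]
        if w.max() - w.min() > thr:
            return True
    return False


def oracle_abs(x, thr):
    return bool((np.abs(np.asarray(x)) > thr).any())


def oracle_drift(x, thr, min_r2):
    n = len(x)
    t = np.arange(n)
    slope, intercept = np.polyfit(t, x, 1)
    fitted = slope * t + intercept
    ss_res = ((x - fitted) ** 2).sum()
    ss_tot = ((x - x.mean()) ** 2).sum()
    r2 = 1 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return abs(slope * (n - 1)) > thr and r2 >= min_r2


def oracle_flatline(x):
    return bool(np.var(np.asarray(x)) == 0.0)
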