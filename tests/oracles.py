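"""Independent reference implementations used to cross-check the package."""

import math

import numpy as np


def brute_force_loess(x, y, span):
    """Reference loess: explicit per-point tricube weighted least squares.

    Selects the ceil(span*n) nearest neighbours of each point by sorting
    distances, builds the tricube weights, and solves the local degree-1
    weighted regression with lstsq — no shared code with the smoother it
    checks.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    k = math.ceil(span * n)
    out = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        nbr = np.argsort(d, kind="stable")[:k]
        dmax = d[nbr].max()
        u = d[nbr] / dmax if dmax > 0 else np.zeros(k)
        w = np.clip(1 - u**3, 0, None) ** 3
        design = np.column_stack([np.ones(k), x[nbr] - x[i]])
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(design * sw[:, None], y[nbr] * sw, rcond=None)
        out[i] = beta[0]
    return out
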