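"""Independent reference implementations used as test oracles.

These are deliberately literal, scalar re-implementations written from the
model definitions, kept separate from the package code paths they check.
"""

from __future__ import annotations

import math

import numpy as np


def chill_portions_literal(
    temps,
    slp: float = 1.6,
    tetmlt: float = 277.0,
    a0: float = 1.395e5,
    a1: float = 2.567e18,
    e0: float = 4153.5,
    e1: float = 12888.8,
):
    """Hour-by-hour Dynamic Model recurrence, plain Python floats."""
    x = 0.0
    out = []
    for t in temps:
        tk = float(t) + 273.0
        ftmprt = slp * tetmlt * (tk - tetmlt) / tk
        sr = math.exp(ftmprt)
        xi = sr / (1.0 + sr)
        xs = (a0 / a1) * math.exp((e1 - e0) / tk)
        ak1 = a1 * math.exp(-e1 / tk)
        x = xs - (xs - x) * math.exp(-ak1)
        if x >= 1.0:
            delta = x * xi
            out.append(delta)
            x -= delta
        else:
            out.append(0.0)
    return np.asarray(out)


def nipals_pls_coefficients(X, y, n_components: int):
    """Literal NIPALS PLS1: regression coefficients for centred X, centred y.

    Power-iteration weights, X- and y-deflation per component, coefficients
    mapped through B = W (P'W)^{-1} q.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    Xk = X - X.mean(axis=0)
    yk = y - y.mean()
    Ws, Ps, qs = [], [], []
    for _ in range(n_components):
        w = Xk.T @ yk
        w = w / np.linalg.norm(w)
        t = Xk @ w
        tt = float(t @ t)
        p = Xk.T @ t / tt
        q = float(yk @ t) / tt
        Xk = Xk - np.outer(t, p)
        yk = yk - q * t
        Ws.append(w)
        Ps.append(p)
        qs.append(q)
    W = np.column_stack(Ws)
    P = np.column_stack(Ps)
    return W @ np.linalg.solve(P.T @ W, np.asarray(qs))


def moving_average_literal(x, window: int):
    """Brute-force centred moving average with edge truncation."""
    x = np.asarray(x, float)
    half = window // 2
    return np.array(
        [x[max(0, i - half): i + half + 1].mean() for i in range(len(x))]
    )
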