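"""Independent brute-force oracles used only by the tests.

Each function recomputes a statistic by the most literal possible method
(double loops, exhaustive pair enumeration, ray casting) so the package
implementations can be checked against code that shares nothing with
them.
"""

import numpy as np


def auc_pair_counting(scores, labels) -> float:
    """AUC as (concordant + 0.5 * tied) / (n1 * n0) over all pairs."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos = s[y == 1]
    neg = s[y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def morans_i_double_sum(W, values) -> float:
    """Textbook Moran's I by explicit double summation over a dense W."""
    W = np.asarray(W, dtype=float)
    x = np.asarray(values, dtype=float)
    n = len(x)
    z = x - x.mean()
    num = 0.0
    s0 = 0.0
    for i in range(n):
        for j in range(n):
            num += W[i, j] * z[i] * z[j]
            s0 += W[i, j]
    return (n / s0) * num / (z**2).sum()


def autocovariate_double_loop(coords, response, radius) -> np.ndarray:
    """Inverse-distance weighted neighbor mean by explicit loops."""
    coords = np.asarray(coords, dtype=float)
    y = np.asarray(response, dtype=float)
    n = len(y)
    out = np.empty(n)
    for i in range(n):
        num = den = 0.0
        for j in range(n):
            if i == j:
                continue
            d = float(np.hypot(*(coords[i] - coords[j])))
            if 0 < d <= radius:
                num += y[j] / d
                den += 1.0 / d
        out[i] = num / den
    return out


def point_in_polygon_raycast(px, py, vertices) -> bool:
    """Even-odd ray casting with an explicit on-edge check (edges inside)."""
    vx = [v[0] for v in vertices]
    vy = [v[1] for v in vertices]
    n = len(vertices)
    for k in range(n):
        x1, y1 = vx[k], vy[k]
        x2, y2 = vx[(k + 1) % n], vy[(k + 1) % n]
        cross = (x2 - x1) * (py - y1) - (y2 - y1) * (px - x1)
        if abs(cross) < 1e-9:
            if min(x1, x2) - 1e-9 <= px <= max(x1, x2) + 1e-9 and \
               min(y1, y2) - 1e-9 <= py <= max(y1, y2) + 1e-9:
                return True
    inside = False
    j = n - 1
    for k in range(n):
        if (vy[k] > py) != (vy[j] > py):
            x_int = vx[k] + (py - vy[k]) * (vx[j] - vx[k]) / (vy[j] - vy[k])
            if px < x_int:
                inside = not inside
        j = k
    return inside


def check_loss(y, yhat, tau) -> float:
    """Quantile-regression check loss."""
    r = np.asarray(y, dtype=float) - np.asarray(yhat, dtype=float)
    return float(np.sum(np.where(r >= 0, tau * r, (tau - 1) * r)))
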