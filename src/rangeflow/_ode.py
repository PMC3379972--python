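"""Numba kernels for the GeoSSE pruning likelihood.

The three-state (A, B, AB) extinction/likelihood ODE system is integrated
per branch with an adaptive Cash–Karp Runge–Kutta 4(5) scheme (relative
tolerance 1e-8, absolute 1e-12); the D components are renormalized per
branch with an accumulated log-scaler to prevent underflow on deep trees.

Parameter vector layout: p = [sA, sB, sAB, xA, xB, dA, dB].
State vector layout:     y = [EA, EB, EAB, DA, DB, DAB].
"""

from __future__ import annotations

import numpy as np
from numba import njit

RTOL = 1e-8
ATOL = 1e-12


@njit(cache=True)
def _deriv(y, p, dy):
    sA, sB, sAB, xA, xB, dA, dB = p[0], p[1], p[2], p[3], p[4], p[5], p[6]
    EA, EB, EAB = y[0], y[1], y[2]
    DA, DB, DAB = y[3], y[4], y[5]
    lamAB = sA + sB + sAB + xA + xB
    dy[0] = xA - (sA + dA + xA) * EA + dA * EAB + sA * EA * EA
    dy[1] = xB - (sB + dB + xB) * EB + dB * EAB + sB * EB * EB
    dy[2] = (-lamAB * EAB + xA * EB + xB * EA
             + sA * EA * EAB + sB * EB * EAB + sAB * EA * EB)
    dy[3] = -(sA + dA + xA) * DA + dA * DAB + 2.0 * sA * DA * EA
    dy[4] = -(sB + dB + xB) * DB + dB * DAB + 2.0 * sB * DB * EB
    dy[5] = (-lamAB * DAB + xA * DB + xB * DA
             + sA * (DA * EAB + DAB * EA) + sB * (DB * EAB + DAB * EB)
             + sAB * (DA * EB + DB * EA))


@njit(cache=True)
def _integrate(y, p, duration):
    """Advance y over `duration`; returns 0 on success, 1 on failure."""
    if duration <= 0.0:
        return 0
    # Cash-Karp tableau
    n = 6
    k1 = np.empty(n); k2 = np.empty(n); k3 = np.empty(n)
    k4 = np.empty(n); k5 = np.empty(n); k6 = np.empty(n)
    ytmp = np.empty(n)
    t = 0.0
    rate_scale = (p[0] + p[1] + p[2] + p[3] + p[4] + p[5] + p[6]) + 1e-8
    h = min(duration, 0.5 / rate_scale)
    max_steps = 1000000
    steps = 0
    while t < duration:
        if steps >= max_steps:
            return 1
        steps += 1
        if t + h > duration:
            h = duration - t
        _deriv(y, p, k1)
        for i in range(n):
            ytmp[i] = y[i] + h * 0.2 * k1[i]
        _deriv(ytmp, p, k2)
        for i in range(n):
            ytmp[i] = y[i] + h * (0.075 * k1[i] + 0.225 * k2[i])
        _deriv(ytmp, p, k3)
        for i in range(n):
            ytmp[i] = y[i] + h * (0.3 * k1[i] - 0.9 * k2[i] + 1.2 * k3[i])
        _deriv(ytmp, p, k4)
        for i in range(n):
            ytmp[i] = y[i] + h * ((-11.0 / 54.0) * k1[i] + 2.5 * k2[i]
                                  + (-70.0 / 27.0) * k3[i]
                                  + (35.0 / 27.0) * k4[i])
        _deriv(ytmp, p, k5)
        for i in range(n):
            ytmp[i] = y[i] + h * ((1631.0 / 55296.0) * k1[i]
                                  + (175.0 / 512.0) * k2[i]
                                  + (575.0 / 13824.0) * k3[i]
                                  + (44275.0 / 110592.0) * k4[i]
                                  + (253.0 / 4096.0) * k5[i])
        _deriv(ytmp, p, k6)
        errmax = 0.0
        for i in range(n):
            y5 = y[i] + h * ((37.0 / 378.0) * k1[i]
                             + (250.0 / 621.0) * k3[i]
                             + (125.0 / 594.0) * k4[i]
                             + (512.0 / 1771.0) * k6[i])
            y4 = y[i] + h * ((2825.0 / 27648.0) * k1[i]
                             + (18575.0 / 48384.0) * k3[i]
                             + (13525.0 / 55296.0) * k4[i]
                             + (277.0 / 14336.0) * k5[i]
                             + 0.25 * k6[i])
            err = abs(y5 - y4)
            sc = ATOL + RTOL * max(abs(y[i]), abs(y5))
            if err / sc > errmax:
                errmax = err / sc
            ytmp[i] = y5
        if errmax <= 1.0:
            t += h
            for i in range(n):
                y[i] = ytmp[i]
            # keep E in [0,1]; clip tiny negative D
            for i in range(3):
                if y[i] < 0.0:
                    y[i] = 0.0
                elif y[i] > 1.0:
                    y[i] = 1.0
            for i in range(3, 6):
                if y[i] < 0.0:
                    if y[i] < -1e-10:
                        return 1
                    y[i] = 0.0
            if errmax > 1e-30:
                h = min(h * min(5.0, 0.9 * errmax ** -0.2), duration)
            else:
                h = min(h * 5.0, duration)
        else:
            h *= max(0.1, 0.9 * errmax ** -0.25)
            if h < 1e-14:
                return 1
    return 0


@njit(cache=True)
def geosse_prune(child_left, child_right, blen, tip_state, p, f, root_mode):
    """Pruning log-likelihood over a flattened postorder tree.

    Nodes are numbered in postorder; tips carry ``tip_state`` in {0 (A),
    1 (B), 2 (AB)} and internals -1.  ``child_left/right`` are child node
    indices (-1 for tips); ``blen`` is the subtending branch length (0 for
    the root).  ``f`` are the three sampling fractions; ``root_mode`` 0 =
    observed weights (D-proportional), 1 = flat weights.

    Returns (loglik, status); status 0 = ok, 1 = integration failure,
    2 = zero likelihood at a node, 3 = inconsistent E between sisters.
    """
    n_nodes = child_left.shape[0]
    Eup = np.zeros((n_nodes, 3))
    Dup = np.zeros((n_nodes, 3))
    logcomp = 0.0
    y = np.empty(6)
    for i in range(n_nodes):
        if tip_state[i] >= 0:
            for j in range(3):
                y[j] = 1.0 - f[j]
                y[3 + j] = 0.0
            y[3 + tip_state[i]] = f[tip_state[i]]
        else:
            l = child_left[i]
            r = child_right[i]
            for j in range(3):
                de = Eup[l, j] - Eup[r, j]
                if de > 1e-5 or de < -1e-5:
                    return -np.inf, 3
                y[j] = 0.5 * (Eup[l, j] + Eup[r, j])
            DA1, DB1, DAB1 = Dup[l, 0], Dup[l, 1], Dup[l, 2]
            DA2, DB2, DAB2 = Dup[r, 0], Dup[r, 1], Dup[r, 2]
            sA, sB, sAB = p[0], p[1], p[2]
            y[3] = sA * DA1 * DA2
            y[4] = sB * DB1 * DB2
            y[5] = 0.5 * (sA * (DA1 * DAB2 + DAB1 * DA2)
                          + sB * (DB1 * DAB2 + DAB1 * DB2)
                          + sAB * (DA1 * DB2 + DB1 * DA2))
        s = y[3] + y[4] + y[5]
        if s <= 0.0:
            return -np.inf, 2
        for j in range(3):
            y[3 + j] /= s
        logcomp += np.log(s)
        if i < n_nodes - 1:  # root is last in postorder; no branch above
            status = _integrate(y, p, blen[i])
            if status != 0:
                return -np.inf, 1
            s = y[3] + y[4] + y[5]
            if s <= 0.0:
                return -np.inf, 2
            for j in range(3):
                y[3 + j] /= s
            logcomp += np.log(s)
        for j in range(3):
            Eup[i, j] = y[j]
            Dup[i, j] = y[3 + j]
    root = n_nodes - 1
    DA, DB, DAB = Dup[root, 0], Dup[root, 1], Dup[root, 2]
    tot = DA + DB + DAB
    if root_mode == 0:
        L = (DA * DA + DB * DB + DAB * DAB) / tot
    elif root_mode == 1:
        L = tot / 3.0
    else:  # root state given: 2=A, 3=B, 4=AB
        L = Dup[root, root_mode - 2]
    if L <= 0.0:
        return -np.inf, 2
    return np.log(L) + logcomp, 0
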