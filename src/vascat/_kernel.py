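"""Numba-compiled inner loop of the hierarchical log likelihood and gradient.

The kernel computes, in one pass over trials, the Gaussian log likelihood
under the 4PL mean / log-quadratic variance model and its gradient with
respect to the effective per-trial parameters, accumulated per subject and
per item.  A pure-numpy twin lives in :mod:`vascat.model`; the two are
checked against each other in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

LOG2PI = float(np.log(2.0 * np.pi))


@njit(cache=True, error_model="numpy")
def loglik_grad_kernel(
    y, x, d, j_idx, k_idx,
    L0, U0, c0, s0, w0, w1, w2,
    Ls, Us, cs, ss, th,
    Li, Ui, ci, si,
    J, K,
):
    """Returns (ok, loglik, gpop[7], gsubj[J,5], gitem[K,4])."""
    n = y.size
    gpop = np.zeros(7)
    gsubj = np.zeros((J, 5))
    gitem = np.zeros((K, 4))
    ll = 0.0
    for i in range(n):
        j = j_idx[i]
        k = k_idx[i]
        L = L0 + Ls[j] + Li[k]
        U = U0 + Us[j] + Ui[k]
        c = c0 + cs[j] + ci[k]
        s = s0 + ss[j] + si[k]
        r = U - L
        if r <= 1e-6:
            return False, -np.inf, gpop, gsubj, gitem
        a4 = 4.0 * s / r
        xc = x[i] - c
        t = a4 * xc
        if t >= 0.0:
            z = 1.0 / (1.0 + np.exp(-t))
        else:
            e = np.exp(t)
            z = e / (1.0 + e)
        zz = z * (1.0 - z)
        mu = L + r * z

        lv = w0 + th[j] + w1 * d[i] + w2 * d[i] * d[i]
        if lv > 500.0:
            lv = 500.0
        iv = np.exp(-lv)
        res = y[i] - mu
        ll += -0.5 * (LOG2PI + lv + res * res * iv)

        gmu = res * iv
        glv = -0.5 + 0.5 * res * res * iv

        dL = 1.0 - z + zz * xc * a4
        dU = z - zz * xc * a4
        dc = -4.0 * s * zz
        ds = 4.0 * zz * xc

        gL = gmu * dL
        gU = gmu * dU
        gc = gmu * dc
        gs = gmu * ds

        gpop[0] += gL
        gpop[1] += gU
        gpop[2] += gc
        gpop[3] += gs
        gpop[4] += glv
        gpop[5] += glv * d[i]
        gpop[6] += glv * d[i] * d[i]

        gsubj[j, 0] += gL
        gsubj[j, 1] += gU
        gsubj[j, 2] += gc
        gsubj[j, 3] += gs
        gsubj[j, 4] += glv

        gitem[k, 0] += gL
        gitem[k, 1] += gU
        gitem[k, 2] += gc
        gitem[k, 3] += gs
    return True, ll, gpop, gsubj, gitem
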