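"""Compiled numerical kernels (numba) for trajectory-heavy stages.

The packed parameter layout matches :meth:`bgct.params.ModelParameters.pack`:
C[0:7], R[7:14], I[14:21], s=21, n=22, Dinput=23, then the 13 weights in
the order T16, T21, T26, T31, T36, T42, T45, T47, T53, T57, T64, T71, T75
at indices 24..36.

The deterministic integrator is classical RK4 at a fixed step; the system
is smooth with a ~6 ms membrane time constant, so dt = 0.05 ms resolves it
with ample margin (cross-checked against LSODA in the tests).  The
stochastic integrator is Euler-Maruyama with additive noise.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# weight indices in the packed vector
_T16, _T21, _T26, _T31, _T36, _T42, _T45, _T47, _T53, _T57, _T64, _T71, _T75 = \
    range(24, 37)


@njit(cache=True)
def _rhs(x, P, out):
    s = P[21]
    n = int(P[22])
    sn = s ** n
    h0 = x[0] ** n / (sn + x[0] ** n)
    h1 = x[1] ** n / (sn + x[1] ** n)
    h2 = x[2] ** n / (sn + x[2] ** n)
    h3 = x[3] ** n / (sn + x[3] ** n)
    h4 = x[4] ** n / (sn + x[4] ** n)
    h5 = x[5] ** n / (sn + x[5] ** n)
    h6 = x[6] ** n / (sn + x[6] ** n)
    D = P[23]
    out[0] = (P[14] - x[0] / P[7] + P[_T16] * h5) / P[0]
    out[1] = (P[15] - x[1] / P[8] + P[_T21] * h0 + P[_T26] * h5 + D) / P[1]
    out[2] = (P[16] - x[2] / P[9] + P[_T31] * h0 + P[_T36] * h5 - D) / P[2]
    out[3] = (P[17] - x[3] / P[10] + P[_T47] * h6 - P[_T42] * h1 - P[_T45] * h4) / P[3]
    out[4] = (P[18] - x[4] / P[11] + P[_T57] * h6 - P[_T53] * h2) / P[4]
    out[5] = (P[19] - x[5] / P[12] - P[_T64] * h3) / P[5]
    out[6] = (P[20] - x[6] / P[13] + P[_T71] * h0 - P[_T75] * h4) / P[6]


@njit(cache=True)
def rk4_batch(P, X0, dt, n_steps, stride, skip):
    """Integrate a batch of initial states with fixed-step RK4.

    Records every ``stride``-th step after the first ``skip`` steps
    (state at step ``skip`` included).  Returns (m, n_rec, 7).
    """
    m = X0.shape[0]
    n_rec = (n_steps - skip) // stride + 1
    out = np.empty((m, n_rec, 7))
    k1 = np.empty(7)
    k2 = np.empty(7)
    k3 = np.empty(7)
    k4 = np.empty(7)
    xt = np.empty(7)
    for b in range(m):
        x = X0[b].copy()
        rec = 0
        if skip == 0:
            out[b, 0] = x
            rec = 1
        for step in range(1, n_steps + 1):
            _rhs(x, P, k1)
            for i in range(7):
                xt[i] = x[i] + 0.5 * dt * k1[i]
            _rhs(xt, P, k2)
            for i in range(7):
                xt[i] = x[i] + 0.5 * dt * k2[i]
            _rhs(xt, P, k3)
            for i in range(7):
                xt[i] = x[i] + dt * k3[i]
            _rhs(xt, P, k4)
            for i in range(7):
                x[i] += dt / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
            if step >= skip and (step - skip) % stride == 0 and rec < n_rec:
                out[b, rec] = x
                rec += 1
        if not np.all(np.isfinite(x)):
            out[b, :, :] = np.nan
    return out


@njit(cache=True)
def euler_maruyama(P, x0, dt, n_steps, sqrt2Ddt, noise_mask, stride, skip,
                   seed, reflect):
    """Additive-noise Euler-Maruyama path, recording every stride-th step.

    ``sqrt2Ddt`` = sqrt(2 D dt) scales a standard-normal increment on each
    equation selected by ``noise_mask``.  Fully determined by ``seed``.
    With ``reflect`` the activities are reflected at 0 (optional floor,
    off by default in the callers).
    """
    np.random.seed(seed)
    n_rec = (n_steps - skip) // stride + 1
    out = np.empty((n_rec, 7))
    f = np.empty(7)
    x = x0.copy()
    rec = 0
    if skip == 0:
        out[0] = x
        rec = 1
    for step in range(1, n_steps + 1):
        _rhs(x, P, f)
        for i in range(7):
            x[i] += f[i] * dt
            if noise_mask[i]:
                x[i] += sqrt2Ddt * np.random.normal()
            if reflect and x[i] < 0.0:
                x[i] = -x[i]
        if step >= skip and (step - skip) % stride == 0 and rec < n_rec:
            out[rec] = x
            rec += 1
    return out
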