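"""Vector field of the BGCT loop: Hill response, drift and exact Jacobian.

All functions accept either a single state of shape (7,) or a batch of
states of shape (m, 7); outputs broadcast accordingly.  Time is in ms
throughout, so the drift has units of activity per ms.
"""

from __future__ import annotations

import numpy as np

from .params import COUPLINGS, N_POP, ModelParameters

__all__ = ["hill_response", "hill_derivative", "drift", "jacobian"]


def hill_response(x, s: float, n: int):
    """Saturating response ``x^n / (s^n + x^n)``.

    ``s`` is the half-activation point (Hill coefficient) and ``n`` the
    Hill index.  For x >= 0 the value lies in [0, 1); with even n the
    function is defined (and even) on the whole real line.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("hill_response: non-finite input")
    if s <= 0:
        raise ValueError("hill_response: Hill coefficient s must be > 0")
    if int(n) != n or n < 1:
        raise ValueError("hill_response: Hill index n must be a positive integer")
    xn = x ** int(n)
    return xn / (s ** int(n) + xn)


def hill_derivative(x, s: float, n: int):
    """d/dx of :func:`hill_response`: ``n s^n x^(n-1) / (s^n + x^n)^2``."""
    x = np.asarray(x, dtype=float)
    n = int(n)
    sn = s ** n
    den = (sn + x ** n) ** 2
    return n * sn * x ** (n - 1) / den


def _validate_state(state) -> np.ndarray:
    x = np.asarray(state, dtype=float)
    if x.shape[-1] != N_POP:
        raise ValueError(f"state must have {N_POP} components, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("state contains non-finite entries")
    return x


def drift(state, params: ModelParameters) -> np.ndarray:
    """Right-hand side dx/dt of the seven population-rate equations.

    Each population obeys ``C_i dx_i/dt = I_i - x_i/R_i + coupling``,
    where the coupling sums signed weighted Hill responses of the
    presynaptic activities, and the dopamine level enters the two
    striatal equations as +Dinput (D1) and -Dinput (D2).
    """
    x = _validate_state(state)
    h = hill_response(x, params.s, params.n)
    dx = params.I - x / params.R
    dx = dx + 0.0  # ensure a fresh array when I broadcasts
    dx[..., 1] += params.Dinput
    dx[..., 2] -= params.Dinput
    for name, i, j, sign in COUPLINGS:
        dx[..., i - 1] += sign * getattr(params, name) * h[..., j - 1]
    return dx / params.C


def jacobian(state, params: ModelParameters) -> np.ndarray:
    """Exact Jacobian of :func:`drift`, shape (7, 7) or (m, 7, 7)."""
    x = _validate_state(state)
    dh = hill_derivative(x, params.s, params.n)
    shape = x.shape[:-1] + (N_POP, N_POP)
    J = np.zeros(shape)
    idx = np.arange(N_POP)
    J[..., idx, idx] = -1.0 / (params.C * params.R)
    for name, i, j, sign in COUPLINGS:
        J[..., i - 1, j - 1] += (
            sign * getattr(params, name) * dh[..., j - 1] / params.C[i - 1]
        )
    return J
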