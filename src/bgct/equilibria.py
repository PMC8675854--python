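"""Equilibrium enumeration and linear stability for the BGCT field.

Roots of the drift are found by damped Newton iteration from a
deterministic Sobol multistart grid, deduplicated, and classified by the
eigenvalues of the exact Jacobian.  Because every fixed point satisfies
``x_i = R_i (I_i + signed weighted Hill sums)`` with each Hill factor in
[0, 1), all equilibria lie in an a-priori box computed from the
parameters; roots converging outside it are discarded as numerical
strays (there are none for this field).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .model import drift, jacobian
from .params import N_POP, ModelParameters

__all__ = ["Equilibrium", "find_equilibria", "classify_stability",
           "equilibria_to_frame", "save_equilibria_csv"]

#: residual bound for accepting a Newton root
DEFAULT_TOL = 1e-10
#: two roots closer than this (max-abs) are the same equilibrium
DEDUP_TOL = 1e-5
#: eigenvalue real parts must clear this margin for a firm stability call
STABILITY_MARGIN = 1e-8
#: pinned scramble seed of the Sobol start grid (determinism contract)
_SOBOL_SEED = 20210416


@dataclass
class Equilibrium:
    """A root of the drift with its linearization.

    ``stability`` is "stable" iff every eigenvalue real part is below
    ``-STABILITY_MARGIN``, else "unstable".  ``marginal`` flags roots with
    an eigenvalue real part inside the margin (bifurcation-adjacent);
    ``singular`` flags a numerically singular Jacobian at the root.
    """

    state: np.ndarray
    eigenvalues: np.ndarray | None = None
    stability: str = "unclassified"
    residual: float = np.nan
    marginal: bool = False
    singular: bool = False
    eigenvectors: np.ndarray | None = field(default=None, repr=False)

    @property
    def is_stable(self) -> bool:
        return self.stability == "stable"

    @property
    def leading_pair_omega(self) -> float:
        """|Im| of the eigenvalue with the largest real part (0 if real)."""
        lam = self.eigenvalues[np.argmax(self.eigenvalues.real)]
        return float(abs(lam.imag))


def _newton_batch(params: ModelParameters, X0: np.ndarray, tol: float,
                  max_iter: int = 80, step_cap: float = 3.0) -> np.ndarray:
    """Damped (step-capped) Newton on a batch of starts; returns end states."""
    X = np.array(X0, dtype=float)
    for _ in range(max_iter):
        F = drift(X, params)
        res = np.max(np.abs(F), axis=1)
        active = (res > tol) & np.all(np.isfinite(X), axis=1)
        if not np.any(active):
            break
        J = jacobian(X[active], params)
        try:
            step = np.linalg.solve(J, F[active][..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = np.array([np.linalg.lstsq(Ji, Fi, rcond=None)[0]
                             for Ji, Fi in zip(J, F[active])])
        norms = np.linalg.norm(step, axis=1)
        scale = np.minimum(1.0, step_cap / np.maximum(norms, 1e-30))
        X[active] -= step * scale[:, None]
    return X


def find_equilibria(params: ModelParameters,
                    search_box: np.ndarray | None = None,
                    n_starts: int = 2000,
                    tol: float = DEFAULT_TOL,
                    classify: bool = True) -> list[Equilibrium]:
    """Enumerate all equilibria at fixed parameters.

    Parameters
    ----------
    search_box : (2, 7) array, optional
        Lower/upper start box per variable.  Defaults to the a-priori
        equilibrium bounds implied by the parameters.
    n_starts : int
        Number of Sobol multistart points (deterministic, pinned seed).
    tol : float
        Residual bound ``max|drift| < tol`` for accepting a root.

    Returns a list sorted by cortical activity x1.  No convergence from
    any start yields an empty list.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    box = params.equilibrium_box() if search_box is None \
        else np.asarray(search_box, dtype=float)
    accept = params.equilibrium_box(margin=1e-3)
    sob = qmc.Sobol(d=N_POP, scramble=True, seed=_SOBOL_SEED)
    # draw a power-of-2 block (Sobol balance), keep the first n_starts
    m = int(np.ceil(np.log2(max(n_starts, 2))))
    U = sob.random(2 ** m)[:n_starts]
    X0 = box[0] + U * (box[1] - box[0])
    X = _newton_batch(params, X0, tol)

    F = drift(X, params)
    res = np.max(np.abs(F), axis=1)
    ok = (res < tol) & np.all(np.isfinite(X), axis=1)
    ok &= np.all(X >= accept[0], axis=1) & np.all(X <= accept[1], axis=1)
    roots: list[np.ndarray] = []
    residuals: list[float] = []
    for x, r in zip(X[ok], res[ok]):
        for known in roots:
            if np.max(np.abs(x - known)) < DEDUP_TOL:
                break
        else:
            roots.append(x)
            residuals.append(float(r))
    order = np.argsort([x[0] for x in roots])
    eqs = [Equilibrium(state=roots[i], residual=residuals[i]) for i in order]
    if classify:
        eqs = [classify_stability(eq, params) for eq in eqs]
    return eqs


def classify_stability(eq: Equilibrium, params: ModelParameters,
                       margin: float = STABILITY_MARGIN) -> Equilibrium:
    """Fill eigenvalues and the stable/unstable label of an equilibrium.

    Eigenvalues are reported sorted by descending real part.  Real parts
    with magnitude below ``margin`` mark the root as bifurcation-adjacent
    (``marginal=True``) without changing the label rule.
    """
    J = jacobian(eq.state, params)
    try:
        lam, vec = np.linalg.eig(J)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - LAPACK failure
        raise RuntimeError(f"eigen-solver failed at state {eq.state}") from exc
    order = np.argsort(-lam.real)
    eq.eigenvalues = lam[order]
    eq.eigenvectors = vec[:, order]
    eq.stability = "stable" if np.all(lam.real < -margin) else "unstable"
    eq.marginal = bool(np.any(np.abs(lam.real) < margin))
    eq.singular = bool(np.linalg.cond(J) > 1e12)
    return eq


def equilibria_to_frame(eqs: list[Equilibrium]) -> pd.DataFrame:
    """Tabulate equilibria: x1..x7, re/im eigenvalue columns, labels."""
    rows = []
    for eq in eqs:
        row = {f"x{i + 1}": eq.state[i] for i in range(N_POP)}
        lam = eq.eigenvalues if eq.eigenvalues is not None \
            else np.full(N_POP, np.nan + 0j)
        row.update({f"re_lambda{i + 1}": lam[i].real for i in range(N_POP)})
        row.update({f"im_lambda{i + 1}": lam[i].imag for i in range(N_POP)})
        row["stability"] = eq.stability
        row["residual"] = eq.residual
        rows.append(row)
    return pd.DataFrame(rows)


def save_equilibria_csv(eqs: list[Equilibrium], path: str | Path) -> None:
    equilibria_to_frame(eqs).to_csv(path, index=False)
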