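"""Trajectory integration and attractor census for the BGCT loop.

The census discovers every stable attractor (equilibria and limit
cycles) at fixed parameters by integrating from a deterministic spread
of initial conditions — Sobol points across the equilibrium box plus
perturbations of every equilibrium along its leading eigenvector — and
classifying each trajectory tail as a fixed point or a periodic orbit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.integrate import solve_ivp
from scipy.signal import find_peaks
from scipy.stats import qmc

from ._fast import rk4_batch
from .equilibria import (DEDUP_TOL, Equilibrium, _newton_batch,
                         classify_stability, equilibria_to_frame,
                         find_equilibria)
from .model import drift, jacobian
from .params import N_POP, ModelParameters

__all__ = ["LimitCycle", "AttractorSet", "integrate", "detect_attractor",
           "census", "oscillation_frequency", "BETA_BAND"]

#: beta frequency band (Hz) associated with Parkinsonian oscillation
BETA_BAND = (13.0, 30.0)
#: post-transient peak-to-peak below this on every variable => equilibrium
OSC_THRESHOLD = 1e-3
#: fraction of a trajectory discarded as transient before classification
TRANSIENT_FRACTION = 0.5
#: fixed RK4 step (ms) of the compiled integrator
RK4_DT = 0.05
#: reporting step (ms) of dense output used for period detection
REPORT_STEP = 0.1
_IC_SEED = 902116


@dataclass
class LimitCycle:
    """A stable periodic orbit: period (ms), envelope and mean per variable."""

    period: float
    envelope: np.ndarray          # (2, 7): min / max over one period
    mean_state: np.ndarray        # (7,)
    sample_orbit: np.ndarray = field(default=None, repr=False)  # (k, 7)

    @property
    def frequency(self) -> float:
        """Oscillation frequency in Hz (period is in ms)."""
        return 1000.0 / self.period

    @property
    def beta_band(self) -> bool:
        return BETA_BAND[0] <= self.frequency <= BETA_BAND[1]

    @property
    def amplitude(self) -> float:
        """Peak-to-peak excursion of cortical activity x1."""
        return float(self.envelope[1, 0] - self.envelope[0, 0])

    def same_as(self, other: "LimitCycle",
                period_rtol: float = 0.02, mean_tol: float = 0.05) -> bool:
        """Two cycles are the same attractor if both the relative period
        difference and the mean-state distance are small; coexisting
        cycles (distinct mean or period) must never be merged."""
        dp = abs(self.period - other.period) / max(self.period, other.period)
        dm = float(np.linalg.norm(self.mean_state - other.mean_state))
        return dp <= period_rtol and dm <= mean_tol


@dataclass
class AttractorSet:
    """Census result: stable equilibria, stable cycles, and a regime tag."""

    equilibria: list[Equilibrium]
    cycles: list[LimitCycle]
    all_equilibria: list[Equilibrium] = field(default_factory=list)
    exhaustive: bool = True

    @property
    def regime_tag(self) -> str:
        return f"{len(self.equilibria)}SS+{len(self.cycles)}LC"

    @property
    def n_unstable(self) -> int:
        return sum(not e.is_stable for e in self.all_equilibria)

    def to_json(self, path: str | Path | None = None) -> dict:
        out = {
            "regime_tag": self.regime_tag,
            "exhaustive": self.exhaustive,
            "equilibria": equilibria_to_frame(self.equilibria).to_dict("records"),
            "cycles": [{
                "period_ms": c.period,
                "frequency_hz": c.frequency,
                "beta_band": c.beta_band,
                "mean_state": c.mean_state.tolist(),
                "envelope_min": c.envelope[0].tolist(),
                "envelope_max": c.envelope[1].tolist(),
            } for c in self.cycles],
        }
        if path is not None:
            Path(path).write_text(json.dumps(out, indent=2))
        return out


def integrate(params: ModelParameters, x0, t_end: float,
              rtol: float = 1e-8, atol: float = 1e-10,
              step: float = REPORT_STEP,
              method: str = "lsoda") -> tuple[np.ndarray, np.ndarray]:
    """Integrate the deterministic field from ``x0`` for ``t_end`` ms.

    ``method="lsoda"`` uses stiff-capable adaptive integration with the
    exact Jacobian; ``method="rk4"`` uses the compiled fixed-step kernel
    (dt = 0.05 ms).  Both report states on a uniform grid of spacing
    ``step`` ms.  Returns (times, states) with states of shape (k, 7).
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    x0 = np.asarray(x0, dtype=float)
    t = np.arange(0.0, t_end + 0.5 * step, step)
    if method == "rk4":
        stride = max(1, round(step / RK4_DT))
        n_steps = (len(t) - 1) * stride
        out = rk4_batch(params.pack(), x0[None, :], RK4_DT, n_steps, stride, 0)
        X = out[0]
        if not np.all(np.isfinite(X)):
            raise RuntimeError(f"integration blew up from x0={x0} with {params}")
        return t, X
    sol = solve_ivp(lambda _t, x: drift(x, params), (0.0, t_end), x0,
                    method="LSODA", t_eval=t, rtol=rtol, atol=atol,
                    jac=lambda _t, x: jacobian(x, params))
    if not sol.success:
        raise RuntimeError(
            f"integration failed from x0={x0} with {params}: {sol.message}")
    return sol.t, sol.y.T


def _refine_peak(t: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """Quadratic interpolation of a discrete maximum at index i."""
    if i == 0 or i == len(y) - 1:
        return t[i], y[i]
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0.0:
        return t[i], y[i]
    delta = 0.5 * (y0 - y2) / denom
    dt = t[1] - t[0]
    return t[i] + delta * dt, y1 - 0.25 * (y0 - y2) * delta


def detect_attractor(t: np.ndarray, X: np.ndarray, params: ModelParameters,
                     transient_fraction: float = TRANSIENT_FRACTION,
                     osc_threshold: float = OSC_THRESHOLD,
                     min_peaks: int = 5):
    """Classify a trajectory tail as Equilibrium, LimitCycle or "undecided".

    The leading ``transient_fraction`` of the trajectory is discarded.
    If the remaining peak-to-peak excursion of every variable is below
    ``osc_threshold`` the endpoint is polished by Newton into an
    Equilibrium.  Otherwise the period is estimated from successive
    quadratic-interpolated maxima of x1 (mean of the last >= ``min_peaks``
    inter-peak intervals, coefficient of variation < 2% required).
    """
    k0 = int(len(t) * transient_fraction)
    ts, Xs = t[k0:], X[k0:]
    ptp = Xs.max(axis=0) - Xs.min(axis=0)
    if np.all(ptp < osc_threshold):
        x = _newton_batch(params, Xs[-1][None, :], tol=1e-12)[0]
        res = float(np.max(np.abs(drift(x, params))))
        if res > 1e-9 or np.max(np.abs(x - Xs[-1])) > 0.01:
            return "undecided"
        return classify_stability(Equilibrium(state=x, residual=res), params)

    y = Xs[:, 0]
    prominence = 0.25 * float(ptp[0])
    idx, _ = find_peaks(y, prominence=prominence)
    if len(idx) < min_peaks + 1:
        return "undecided"
    peak_t = np.array([_refine_peak(ts, y, i)[0] for i in idx])
    intervals = np.diff(peak_t)[-max(min_peaks, len(idx) - 1):]
    period = float(np.mean(intervals))
    if period <= 0 or np.std(intervals) / period > 0.02:
        return "undecided"
    # amplitude stationarity: a slowly decaying (or growing) spiral near a
    # Hopf point keeps a near-constant period, so compare the excursion of
    # the two halves of the tail before accepting a cycle
    half = len(Xs) // 2
    a1 = float(np.ptp(Xs[:half, 0]))
    a2 = float(np.ptp(Xs[half:, 0]))
    if a1 <= 0 or not (0.98 <= a2 / a1 <= 1.02):
        if a2 < a1:  # decaying: polish the endpoint toward the focus
            x = _newton_batch(params, Xs[-1][None, :], tol=1e-12)[0]
            res = float(np.max(np.abs(drift(x, params))))
            if res < 1e-9 and np.max(np.abs(x - Xs[-1])) < 2.0 * a2:
                eq = classify_stability(Equilibrium(state=x, residual=res),
                                        params)
                if eq.is_stable:
                    return eq
        return "undecided"
    # envelope / mean over an integer number of trailing periods
    n_span = int(min(len(ts) - 1, max(2, np.floor((ts[-1] - ts[0]) / period) - 1)
                     * period / (ts[1] - ts[0])))
    tail = Xs[-n_span:]
    envelope = np.vstack([tail.min(axis=0), tail.max(axis=0)])
    orbit_len = int(round(period / (ts[1] - ts[0])))
    return LimitCycle(period=period, envelope=envelope,
                      mean_state=tail.mean(axis=0),
                      sample_orbit=Xs[-orbit_len - 1:])


def default_ic_grid(params: ModelParameters, n_box: int = 64,
                    equilibria: list[Equilibrium] | None = None,
                    perturbation: float = 0.05) -> np.ndarray:
    """Deterministic census initial conditions: Sobol points spanning the
    equilibrium box plus leading-eigenvector perturbations of every
    equilibrium (unstable foci seed their surrounding cycles)."""
    box = params.equilibrium_box()
    sob = qmc.Sobol(d=N_POP, scramble=True, seed=_IC_SEED)
    ics = [box[0] + sob.random(n_box) * (box[1] - box[0])]
    for eq in equilibria or []:
        v = eq.eigenvectors[:, 0].real if eq.eigenvectors is not None \
            else np.ones(N_POP)
        nv = np.linalg.norm(v)
        v = v / nv if nv > 0 else np.ones(N_POP) / np.sqrt(N_POP)
        ics.append(eq.state[None, :] + perturbation * v[None, :])
        ics.append(eq.state[None, :] - perturbation * v[None, :])
    return np.vstack(ics)


def census(params: ModelParameters,
           ic_grid: np.ndarray | None = None,
           t_end: float = 3000.0,
           osc_threshold: float = OSC_THRESHOLD,
           transient_fraction: float = TRANSIENT_FRACTION,
           n_starts: int = 2000,
           n_box_ic: int = 64,
           fast: bool = False) -> AttractorSet:
    """Discover all stable attractors at fixed parameters.

    Runs :func:`find_equilibria`, integrates the initial-condition grid
    with the compiled RK4 kernel, classifies each tail, deduplicates, and
    merges with the Newton equilibria.  Trajectories that remain
    "undecided" are re-run once at double ``t_end``; if any persist the
    result is flagged ``exhaustive=False``.

    ``fast=True`` integrates only perturbations of unstable equilibria
    (cycles in this loop are born from Hopf points around unstable foci,
    so this finds every cycle at a fraction of the cost) and skips the
    box-spanning starts when every equilibrium is stable.
    """
    eqs = find_equilibria(params, n_starts=n_starts)
    stable = [e for e in eqs if e.is_stable]
    unstable = [e for e in eqs if not e.is_stable]
    if ic_grid is None:
        if fast:
            if not unstable:
                return AttractorSet(equilibria=stable, cycles=[],
                                    all_equilibria=eqs)
            ic_grid = default_ic_grid(params, n_box=8, equilibria=unstable)
        else:
            ic_grid = default_ic_grid(params, n_box=n_box_ic, equilibria=eqs)
    ic_grid = np.atleast_2d(np.asarray(ic_grid, dtype=float))

    cycles: list[LimitCycle] = []
    found_eq: list[Equilibrium] = []
    P = params.pack()

    def run(ics: np.ndarray, horizon: float) -> list[np.ndarray]:
        stride = max(1, round(REPORT_STEP / RK4_DT))
        n_steps = int(round(horizon / RK4_DT))
        skip = int(n_steps * 0.0)
        return rk4_batch(P, ics, RK4_DT, n_steps, stride, skip)

    def classify(trajs: np.ndarray, horizon: float) -> list[int]:
        undecided = []
        t = np.arange(trajs.shape[1]) * REPORT_STEP
        for b in range(trajs.shape[0]):
            X = trajs[b]
            if not np.all(np.isfinite(X)):
                raise RuntimeError(
                    f"integration blew up from x0={ic_grid[b]} with {params}")
            res = detect_attractor(t, X, params, transient_fraction,
                                   osc_threshold)
            if isinstance(res, LimitCycle):
                if not any(res.same_as(c) for c in cycles):
                    cycles.append(res)
            elif isinstance(res, Equilibrium):
                found_eq.append(res)
            else:
                undecided.append(b)
        return undecided

    trajs = run(ic_grid, t_end)
    undecided = classify(trajs, t_end)
    exhaustive = True
    if undecided:
        trajs2 = run(ic_grid[undecided], 2.0 * t_end)
        still = classify(trajs2, 2.0 * t_end)
        exhaustive = not still

    # merge simulation-found stable equilibria with the Newton census
    for eq in found_eq:
        if eq.is_stable and not any(
                np.max(np.abs(eq.state - e.state)) < 10 * DEDUP_TOL
                for e in stable):
            stable.append(eq)
            eqs.append(eq)
    stable.sort(key=lambda e: e.state[0])
    # degenerate 'cycles' collapsing onto a point would have been caught by
    # the amplitude threshold; assert the envelope is non-degenerate
    cycles[:] = [c for c in cycles if c.amplitude >= osc_threshold]
    return AttractorSet(equilibria=stable, cycles=cycles,
                        all_equilibria=sorted(eqs, key=lambda e: e.state[0]),
                        exhaustive=exhaustive)


def oscillation_frequency(cycle: LimitCycle) -> tuple[float, bool]:
    """Frequency (Hz) of a cycle and whether it falls in the beta band."""
    return cycle.frequency, cycle.beta_band
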