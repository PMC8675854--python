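"""Bifurcation mapping: codim-1 branch diagrams, codim-2 curves, regime maps.

Codim-1: equilibrium branches are traced by pseudo-arclength continuation
in (state, parameter) space, with fold points located where the branch
tangent reverses in the parameter and Hopf points where the leading
complex eigenvalue pair crosses the imaginary axis.  Both are polished by
Newton on their defining extended systems (fold: drift = 0, J v = 0,
|v| = 1; Hopf: drift = 0, J q = i omega q with a normalized complex
eigenvector).

Codim-2: the same extended systems gain a second free parameter and are
continued by pseudo-arclength, yielding fold/Hopf curves in a parameter
plane; cusp points are emitted where the fold curve's projection onto the
plane reverses direction.  The regime map labels a lattice of parameter
points with the attractor configuration ("kSS+mLC") found by the census
and counts connected same-label components.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .dynamics import AttractorSet, census
from .equilibria import Equilibrium, find_equilibria
from .model import drift, hill_response, jacobian
from .params import COUPLINGS, N_POP, ModelParameters

__all__ = ["BranchDiagram", "RegimeMap", "trace_branch_codim1",
           "trace_curve_codim2", "region_map"]

#: Newton corrector tolerance for continuation
CORRECTOR_TOL = 1e-10
#: |Im lambda| below this at a real-part zero => fold-adjacent, not Hopf
OMEGA_MIN = 1e-4
#: state box used to truncate escaping branches
_STATE_BOX = (-20.0, 25.0)


# --------------------------------------------------------------------------
# parameter derivatives and extended-system residuals
# --------------------------------------------------------------------------

_COUPLING_BY_NAME = {name: (i, j, sign) for name, i, j, sign in COUPLINGS}


def _dfdp(x: np.ndarray, params: ModelParameters, pname: str) -> np.ndarray:
    """d(drift)/d(weight): a single signed Hill term in one equation."""
    i, j, sign = _COUPLING_BY_NAME[pname]
    out = np.zeros(N_POP)
    out[i - 1] = sign * hill_response(x[j - 1], params.s, params.n) \
        / params.C[i - 1]
    return out


def _fold_residual(z: np.ndarray, params: ModelParameters,
                   pnames: tuple[str, ...]) -> np.ndarray:
    """Fold system: drift(x)=0, J(x) v=0, |v|^2=1; z = (x, v, p...)."""
    p = params.replace(**dict(zip(pnames, z[14:])))
    x, v = z[:7], z[7:14]
    J = jacobian(x, p)
    return np.concatenate([drift(x, p), J @ v, [v @ v - 1.0]])


def _hopf_residual(z: np.ndarray, params: ModelParameters,
                   pnames: tuple[str, ...]) -> np.ndarray:
    """Hopf system: drift=0, J qr = -w qi, J qi = w qr, |q|=1, qr.qi=0;
    z = (x, qr, qi, w, p...)."""
    p = params.replace(**dict(zip(pnames, z[22:])))
    x, qr, qi, w = z[:7], z[7:14], z[14:21], z[21]
    J = jacobian(x, p)
    return np.concatenate([
        drift(x, p),
        J @ qr + w * qi,
        J @ qi - w * qr,
        [qr @ qr + qi @ qi - 1.0, qr @ qi],
    ])


def _fix_phase(q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotate a complex eigenvector so Re(q).Im(q) = 0 and |q| = 1."""
    qr, qi = np.real(q), np.imag(q)
    num = 2.0 * (qr @ qi)
    den = qr @ qr - qi @ qi
    phi = 0.5 * np.arctan2(num, den)
    qrot = q * np.exp(-1j * phi)
    qr, qi = np.real(qrot), np.imag(qrot)
    nrm = np.sqrt(qr @ qr + qi @ qi)
    return qr / nrm, qi / nrm


def _fd_jacobian(func, z: np.ndarray, h: float = 1e-7) -> np.ndarray:
    f0 = func(z)
    J = np.empty((len(f0), len(z)))
    for k in range(len(z)):
        dz = h * max(1.0, abs(z[k]))
        zp = z.copy(); zp[k] += dz
        zm = z.copy(); zm[k] -= dz
        J[:, k] = (func(zp) - func(zm)) / (2.0 * dz)
    return J


def _newton_square(func, z0: np.ndarray, tol: float = CORRECTOR_TOL,
                   max_iter: int = 25) -> np.ndarray | None:
    z = np.array(z0, dtype=float)
    for _ in range(max_iter):
        F = func(z)
        if np.max(np.abs(F)) < tol:
            return z
        J = _fd_jacobian(func, z)
        try:
            step = np.linalg.solve(J, F)
        except np.linalg.LinAlgError:
            return None
        if not np.all(np.isfinite(step)):
            return None
        z = z - step
    return z if np.max(np.abs(func(z))) < 1e-8 else None


# --------------------------------------------------------------------------
# codim-1 continuation
# --------------------------------------------------------------------------

@dataclass
class Branch:
    """One continued equilibrium branch: states, parameter values, labels."""

    pvals: np.ndarray            # (k,)
    states: np.ndarray           # (k, 7)
    stable: np.ndarray           # (k,) bool
    lead_re: np.ndarray          # (k,) leading eigenvalue real part
    truncated: bool = False      # left the state box before the range edge


@dataclass
class BranchDiagram:
    """Codim-1 continuation output for one scanned connection weight."""

    scan_param: str
    prange: tuple[float, float]
    params: ModelParameters
    branches: list[Branch]
    folds: list[dict]            # {param, state}
    hopfs: list[dict]            # {param, state, omega}
    cycle_envelope: pd.DataFrame = field(default=None, repr=False)

    @property
    def n_folds(self) -> int:
        return len(self.folds)

    @property
    def n_hopfs(self) -> int:
        return len(self.hopfs)

    def equilibria_at(self, pvalue: float) -> list[Equilibrium]:
        p = self.params.replace(**{self.scan_param: pvalue})
        return find_equilibria(p, n_starts=512)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for bid, br in enumerate(self.branches):
            for k in range(len(br.pvals)):
                rows.append({"scan_value": br.pvals[k],
                             "x1": br.states[k, 0],
                             "stability": "stable" if br.stable[k] else "unstable",
                             "branch": bid})
        return pd.DataFrame(rows)

    def save(self, stem: str | Path) -> None:
        """CSV of branch points + JSON sidecar with folds/hopfs/envelope."""
        stem = Path(stem)
        self.to_frame().to_csv(stem.with_suffix(".csv"), index=False)
        side = {
            "scan_param": self.scan_param,
            "range": list(self.prange),
            "folds": [{"param": f["param"], "state": f["state"].tolist()}
                      for f in self.folds],
            "hopfs": [{"param": h["param"], "state": h["state"].tolist(),
                       "omega": h["omega"]} for h in self.hopfs],
        }
        if self.cycle_envelope is not None:
            side["cycle_envelope"] = self.cycle_envelope.to_dict("records")
        stem.with_suffix(".json").write_text(json.dumps(side, indent=2))


def _lead_complex_re(lam: np.ndarray) -> float:
    """Real part of the rightmost genuinely complex eigenvalue pair."""
    cplx = lam[np.abs(lam.imag) > OMEGA_MIN]
    return float(np.max(cplx.real)) if len(cplx) else -np.inf


def _continue_branch(params: ModelParameters, pname: str, x0: np.ndarray,
                     p0: float, prange: tuple[float, float], direction: float,
                     ds0: float = 0.01, ds_min: float = 1e-5, ds_max: float = 0.1,
                     max_steps: int = 4000):
    """Pseudo-arclength continuation of one equilibrium branch, one way."""
    y = np.concatenate([x0, [p0]])
    pts = [y.copy()]
    tangent = None
    truncated = False

    def sys_jac(yv):
        p = params.replace(**{pname: yv[7]})
        J = np.empty((7, 8))
        J[:, :7] = jacobian(yv[:7], p)
        J[:, 7] = _dfdp(yv[:7], p, pname)
        return J

    def tangent_at(yv, t_prev):
        A = sys_jac(yv)
        _u, _s, vt = np.linalg.svd(A)
        t = vt[-1]
        if t_prev is not None and np.dot(t, t_prev) < 0:
            t = -t
        return t / np.linalg.norm(t)

    tangent = tangent_at(y, None)
    if tangent[7] * direction < 0:
        tangent = -tangent
    ds = ds0
    for _ in range(max_steps):
        pred = y + ds * tangent
        z = pred.copy()
        ok = False
        for _it in range(8):
            p = params.replace(**{pname: z[7]})
            F = np.concatenate([drift(z[:7], p), [np.dot(tangent, z - pred)]])
            if np.max(np.abs(F)) < CORRECTOR_TOL:
                ok = True
                break
            A = np.vstack([sys_jac(z), tangent])
            try:
                z = z - np.linalg.solve(A, F)
            except np.linalg.LinAlgError:
                break
            if not np.all(np.isfinite(z)):
                break
        if not ok:
            ds *= 0.5
            if ds < ds_min:
                break
            continue
        y = z
        tangent = tangent_at(y, tangent)
        pts.append(y.copy())
        if _it <= 3:
            ds = min(ds * 1.3, ds_max)
        # stop conditions
        margin = 0.02
        if y[7] < prange[0] - margin or y[7] > prange[1] + margin:
            break
        if np.any(y[:7] < _STATE_BOX[0]) or np.any(y[:7] > _STATE_BOX[1]):
            truncated = True
            break
    return np.array(pts), truncated


def trace_branch_codim1(params: ModelParameters, scan_param: str,
                        prange: tuple[float, float] = (0.0, 7.0),
                        n_seed_slices: int = 9,
                        ds0: float = 0.01,
                        envelope_points: int = 41,
                        with_envelope: bool = True) -> BranchDiagram:
    """Trace all equilibrium branches of one connection weight.

    Branches are seeded from :func:`find_equilibria` at ``n_seed_slices``
    uniformly spaced parameter values (endpoints included) so that
    disconnected branches inside the window are caught, then continued in
    both directions.  Stable-cycle envelopes come from a fast census on a
    uniform sub-grid.
    """
    if scan_param not in _COUPLING_BY_NAME:
        raise ValueError(f"{scan_param!r} is not a declared connection weight")
    pmin, pmax = prange
    branch_pts: list[np.ndarray] = []
    branches: list[Branch] = []

    def on_existing(x, p) -> bool:
        for pts in branch_pts:
            d = np.max(np.abs(pts[:, :7] - x), axis=1) + np.abs(pts[:, 7] - p)
            if np.min(d) < 5e-3:
                return True
        return False

    for pval in np.linspace(pmin, pmax, n_seed_slices):
        base = params.replace(**{scan_param: float(pval)})
        for eq in find_equilibria(base, n_starts=512, classify=False):
            if on_existing(eq.state, pval):
                continue
            fwd, tr_f = _continue_branch(params, scan_param, eq.state,
                                         float(pval), prange, +1.0, ds0=ds0)
            bwd, tr_b = _continue_branch(params, scan_param, eq.state,
                                         float(pval), prange, -1.0, ds0=ds0)
            pts = np.vstack([bwd[::-1], fwd[1:]])
            if len(pts) < 3:
                continue
            branch_pts.append(pts)
            # classify stability along the branch
            lam_all = np.linalg.eigvals(
                np.array([jacobian(pt[:7],
                                   params.replace(**{scan_param: pt[7]}))
                          for pt in pts]))
            stable = np.all(lam_all.real < 0, axis=1)
            lead = np.max(lam_all.real, axis=1)
            branches.append(Branch(pvals=pts[:, 7], states=pts[:, :7],
                                   stable=stable, lead_re=lead,
                                   truncated=tr_f or tr_b))

    folds, hopfs = [], []
    for br, pts in zip(branches, branch_pts):
        dp = np.diff(br.pvals)
        for k in np.where(dp[:-1] * dp[1:] < 0)[0]:
            folds.append((br.states[k + 1], br.pvals[k + 1]))
        # Hopf: sign change of the leading complex pair's real part
        lam_all = np.linalg.eigvals(
            np.array([jacobian(pt[:7], params.replace(**{scan_param: pt[7]}))
                      for pt in pts]))
        re_c = np.array([_lead_complex_re(l) for l in lam_all])
        finite = np.isfinite(re_c)
        for k in range(len(re_c) - 1):
            if finite[k] and finite[k + 1] and re_c[k] * re_c[k + 1] < 0:
                hopfs.append((br.states[k], br.pvals[k], lam_all[k]))

    diagram = BranchDiagram(scan_param=scan_param, prange=prange,
                            params=params, branches=branches,
                            folds=[], hopfs=[])
    # polish candidates on their defining systems, then deduplicate
    for x, p in folds:
        J = jacobian(x, params.replace(**{scan_param: p}))
        _w, V = np.linalg.eig(J)
        v = np.real(V[:, np.argmin(np.abs(_w.real))])
        v /= np.linalg.norm(v)
        z = _newton_square(
            lambda zz: _fold_residual(zz, params, (scan_param,)),
            np.concatenate([x, v, [p]]))
        if z is None or not (pmin - 1e-6 <= z[14] <= pmax + 1e-6):
            continue
        if all(abs(z[14] - f["param"]) > 1e-6
               or np.max(np.abs(z[:7] - f["state"])) > 1e-4
               for f in diagram.folds):
            diagram.folds.append({"param": float(z[14]), "state": z[:7]})
    for x, p, lam in hopfs:
        cplx = lam[np.abs(lam.imag) > OMEGA_MIN]
        if not len(cplx):
            continue
        lam0 = cplx[np.argmax(cplx.real)]
        w0 = abs(lam0.imag)
        J = jacobian(x, params.replace(**{scan_param: p}))
        _w, V = np.linalg.eig(J)
        q = V[:, np.argmin(np.abs(_w - lam0))]
        qr, qi = _fix_phase(q)
        z = _newton_square(
            lambda zz: _hopf_residual(zz, params, (scan_param,)),
            np.concatenate([x, qr, qi, [w0, p]]))
        if z is None or abs(z[21]) < OMEGA_MIN:
            continue
        if not (pmin - 1e-6 <= z[22] <= pmax + 1e-6):
            continue
        if all(abs(z[22] - h["param"]) > 1e-6
               or np.max(np.abs(z[:7] - h["state"])) > 1e-4
               for h in diagram.hopfs):
            diagram.hopfs.append({"param": float(z[22]), "state": z[:7],
                                  "omega": float(abs(z[21]))})
    diagram.folds.sort(key=lambda f: f["param"])
    diagram.hopfs.sort(key=lambda h: h["param"])

    if with_envelope:
        rows = []
        for pval in np.linspace(pmin, pmax, envelope_points):
            aset = census(params.replace(**{scan_param: float(pval)}),
                          fast=True, n_starts=256, t_end=2500.0)
            for c in aset.cycles:
                rows.append({"scan_value": float(pval),
                             "x1_min": float(c.envelope[0, 0]),
                             "x1_max": float(c.envelope[1, 0]),
                             "period_ms": c.period})
        diagram.cycle_envelope = pd.DataFrame(
            rows, columns=["scan_value", "x1_min", "x1_max", "period_ms"])
    return diagram


# --------------------------------------------------------------------------
# codim-2 curves and regime map
# --------------------------------------------------------------------------

@dataclass
class Curve:
    """A continued codim-1 bifurcation curve in a parameter plane."""

    kind: str                    # "fold" | "hopf"
    points: np.ndarray           # (k, 2) parameter-plane polyline
    states: np.ndarray           # (k, 7) equilibrium states along the curve
    partial: bool = False        # continuation stalled inside the window


@dataclass
class RegimeMap:
    """Codim-2 output: bifurcation curves, cusps and labeled regions."""

    p1: str
    p2: str
    window: tuple[tuple[float, float], tuple[float, float]]
    fold_curves: list[Curve] = field(default_factory=list)
    hopf_curves: list[Curve] = field(default_factory=list)
    cusps: list[tuple[float, float]] = field(default_factory=list)
    grid_p1: np.ndarray | None = None
    grid_p2: np.ndarray | None = None
    grid_labels: np.ndarray | None = None   # (len(p2), len(p1)) of tags
    regions: list[dict] = field(default_factory=list)

    @property
    def region_count(self) -> int:
        return len(self.regions)

    @property
    def distinct_tags(self) -> set[str]:
        return {r["tag"] for r in self.regions}

    def save(self, stem: str | Path) -> None:
        """JSON (curves, cusps, regions) + CSV label lattice."""
        stem = Path(stem)
        out = {
            "axes": [self.p1, self.p2],
            "window": [list(self.window[0]), list(self.window[1])],
            "fold_curves": [c.points.tolist() for c in self.fold_curves],
            "hopf_curves": [c.points.tolist() for c in self.hopf_curves],
            "cusps": [list(c) for c in self.cusps],
            "regions": [
                {"tag": r["tag"], "representative": list(r["representative"]),
                 "cells": int(r["cells"])} for r in self.regions],
        }
        stem.with_suffix(".json").write_text(json.dumps(out, indent=2))
        if self.grid_labels is not None:
            rows = []
            for jj, pv2 in enumerate(self.grid_p2):
                for ii, pv1 in enumerate(self.grid_p1):
                    rows.append({self.p1: pv1, self.p2: pv2,
                                 "regime_tag": self.grid_labels[jj, ii]})
            pd.DataFrame(rows).to_csv(stem.with_suffix(".csv"), index=False)


def _continue_codim2(residual, z0: np.ndarray, idx_p: tuple[int, int],
                     window, ds0: float = 0.02, ds_min: float = 1e-5,
                     ds_max: float = 0.08, max_steps: int = 3000):
    """Pseudo-arclength continuation of an extended system with two free
    parameters (at positions ``idx_p`` in z); returns points and stall flag."""
    (a1, b1), (a2, b2) = window
    i1, i2 = idx_p

    def tangent_at(z, t_prev):
        A = _fd_jacobian(residual, z)
        _u, _s, vt = np.linalg.svd(A)
        t = vt[-1]
        if t_prev is not None and np.dot(t, t_prev) < 0:
            t = -t
        return t / np.linalg.norm(t)

    out = []
    stalled = False
    for direction in (+1.0, -1.0):
        z = np.array(z0, dtype=float)
        tangent = tangent_at(z, None) * direction
        pts = [z.copy()]
        ds = ds0
        fails = 0
        for _ in range(max_steps):
            pred = z + ds * tangent
            zz = pred.copy()
            ok = False
            for _it in range(8):
                F = np.concatenate([residual(zz),
                                    [np.dot(tangent, zz - pred)]])
                if np.max(np.abs(F)) < CORRECTOR_TOL:
                    ok = True
                    break
                A = np.vstack([_fd_jacobian(residual, zz), tangent])
                try:
                    zz = zz - np.linalg.solve(A, F)
                except np.linalg.LinAlgError:
                    break
                if not np.all(np.isfinite(zz)):
                    break
            if not ok:
                ds *= 0.5
                fails += 1
                if ds < ds_min:
                    stalled = True
                    break
                continue
            z = zz
            tangent = tangent_at(z, tangent)
            pts.append(z.copy())
            if _it <= 3:
                ds = min(ds * 1.4, ds_max)
            m = 0.05
            if not (a1 - m <= z[i1] <= b1 + m and a2 - m <= z[i2] <= b2 + m):
                break
        out.append(np.array(pts))
    full = np.vstack([out[1][::-1], out[0][1:]]) if len(out[1]) > 1 \
        else out[0]
    return full, stalled


def trace_curve_codim2(params: ModelParameters, p1: str, p2: str,
                       window=((0.0, 7.0), (0.0, 7.0)),
                       curve_type: str = "both",
                       seed_slices: tuple[float, ...] | None = None,
                       ) -> tuple[list[Curve], list[tuple[float, float]]]:
    """Trace fold and/or Hopf curves in the (p1, p2) plane.

    Seeds come from codim-1 scans of ``p1`` at several fixed ``p2``
    values (and one transverse scan of ``p2``); each codim-1 bifurcation
    point is continued in both parameters.  Returns (curves, cusps).
    """
    (a1, b1), (a2, b2) = window
    if seed_slices is None:
        seed_slices = tuple(np.linspace(a2, b2, 8))
    seeds_fold, seeds_hopf = [], []
    for pv2 in seed_slices:
        base = params.replace(**{p2: float(pv2)})
        diag = trace_branch_codim1(base, p1, (a1, b1), with_envelope=False)
        for f in diag.folds:
            seeds_fold.append((f["state"], f["param"], float(pv2)))
        for h in diag.hopfs:
            seeds_hopf.append((h["state"], h["param"], float(pv2), h["omega"]))
    # one transverse sweep to catch curves nearly parallel to the p1 axis
    for pv1 in np.linspace(a1, b1, 4)[1:-1]:
        base = params.replace(**{p1: float(pv1)})
        diag = trace_branch_codim1(base, p2, (a2, b2), with_envelope=False)
        for f in diag.folds:
            seeds_fold.append((f["state"], float(pv1), f["param"]))
        for h in diag.hopfs:
            seeds_hopf.append((h["state"], float(pv1), h["param"], h["omega"]))

    curves: list[Curve] = []
    cusps: list[tuple[float, float]] = []

    def on_existing(kind, q1, q2) -> bool:
        for c in curves:
            if c.kind != kind:
                continue
            d = np.hypot(c.points[:, 0] - q1, c.points[:, 1] - q2)
            if np.min(d) < 0.05:
                return True
        return False

    if curve_type in ("fold", "both"):
        for x, q1, q2 in seeds_fold:
            if on_existing("fold", q1, q2):
                continue
            pset = params.replace(**{p1: q1, p2: q2})
            J = jacobian(x, pset)
            w, V = np.linalg.eig(J)
            v = np.real(V[:, np.argmin(np.abs(w.real))])
            v /= np.linalg.norm(v)
            res = lambda zz: _fold_residual(zz, params, (p1, p2))
            z0 = _newton_square(res, np.concatenate([x, v, [q1, q2]]))
            if z0 is None:
                continue
            pts, stalled = _continue_codim2(res, z0, (14, 15), window)
            if len(pts) < 5:
                continue
            plane = pts[:, [14, 15]]
            curves.append(Curve(kind="fold", points=plane,
                                states=pts[:, :7], partial=stalled))
            # cusp: the parameter-plane tangent reverses direction
            d = np.diff(plane, axis=0)
            keep = np.linalg.norm(d, axis=1) > 1e-12
            d = d[keep]
            dots = np.sum(d[:-1] * d[1:], axis=1)
            kidx = np.where(keep)[0]
            for k in np.where(dots < 0)[0]:
                q = plane[kidx[k] + 1]
                if a1 <= q[0] <= b1 and a2 <= q[1] <= b2:
                    if all(np.hypot(q[0] - c0, q[1] - c1) > 0.05
                           for c0, c1 in cusps):
                        cusps.append((float(q[0]), float(q[1])))

    if curve_type in ("hopf", "both"):
        for x, q1, q2, w0 in seeds_hopf:
            if on_existing("hopf", q1, q2):
                continue
            pset = params.replace(**{p1: q1, p2: q2})
            J = jacobian(x, pset)
            w, V = np.linalg.eig(J)
            lam0 = w[np.argmin(np.abs(w - 1j * w0))]
            q = V[:, np.argmin(np.abs(w - lam0))]
            qr, qi = _fix_phase(q)
            res = lambda zz: _hopf_residual(zz, params, (p1, p2))
            z0 = _newton_square(
                res, np.concatenate([x, qr, qi, [w0, q1, q2]]))
            if z0 is None or abs(z0[21]) < OMEGA_MIN:
                continue
            pts, stalled = _continue_codim2(res, z0, (22, 23), window)
            if len(pts) < 5:
                continue
            curves.append(Curve(kind="hopf", points=pts[:, [22, 23]],
                                states=pts[:, :7], partial=stalled))
    return curves, cusps


def count_curve_branches(curves: list[Curve],
                         window=((0.0, 7.0), (0.0, 7.0)),
                         min_arc: float = 0.3,
                         prominence: float = 0.05) -> dict[str, int]:
    """Count codim-1 bifurcation curve branches the way diagrams label them.

    A continued curve passes smoothly through a cusp (fold) or a turning
    point (Hopf) of its parameter-plane projection, but such a curve is
    conventionally labeled as two branches.  Each traced curve is split at
    interior extrema of its second-parameter coordinate (with the given
    prominence); segments whose in-window arclength is below ``min_arc``
    are discarded as stubs below the drawing resolution.
    """
    (a1, b1), (a2, b2) = window
    counts = {"fold": 0, "hopf": 0}
    for c in curves:
        pts = c.points
        y = pts[:, 1]
        splits = [0]
        for k in range(1, len(y) - 1):
            lo = max(0, k - 1)
            if (y[k] - y[k - 1]) * (y[k + 1] - y[k]) < 0:
                # candidate turning point; require prominence on both sides
                left = y[:k + 1]
                right = y[k:]
                if (abs(y[k] - left.min()) > prominence or
                        abs(y[k] - left.max()) > prominence) and \
                   (abs(y[k] - right.min()) > prominence or
                        abs(y[k] - right.max()) > prominence):
                    if k - splits[-1] > 2:
                        splits.append(k)
        splits.append(len(pts) - 1)
        for s0, s1 in zip(splits[:-1], splits[1:]):
            seg = pts[s0:s1 + 1]
            inside = ((seg[:, 0] >= a1) & (seg[:, 0] <= b1) &
                      (seg[:, 1] >= a2) & (seg[:, 1] <= b2))
            if inside.sum() < 2:
                continue
            segin = seg[inside]
            arc = float(np.sum(np.linalg.norm(np.diff(segin, axis=0), axis=1)))
            if arc >= min_arc:
                counts[c.kind] += 1
    return counts


def _blocked_edges(curves: list[Curve], g1: np.ndarray, g2: np.ndarray):
    """Which cell-to-cell adjacencies are crossed by a bifurcation curve.

    Cells are the rectangles of the (g1, g2) lattice.  Returns boolean
    arrays ``block_h[j, i]`` (edge between cells (i, j) and (i+1, j)) and
    ``block_v[j, i]`` (between (i, j) and (i, j+1)), plus a mask of cells
    the curves pass through.
    """
    n1, n2 = len(g1) - 1, len(g2) - 1
    block_h = np.zeros((n2, n1 - 1), dtype=bool)
    block_v = np.zeros((n2 - 1, n1), dtype=bool)
    crossed = np.zeros((n2, n1), dtype=bool)
    d1, d2 = g1[1] - g1[0], g2[1] - g2[0]

    def cell_of(x, y):
        i = int(np.clip((x - g1[0]) // d1, 0, n1 - 1))
        j = int(np.clip((y - g2[0]) // d2, 0, n2 - 1))
        return i, j

    step = 0.4 * min(d1, d2)
    for c in curves:
        pts = c.points
        seglen = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        dense = [pts[0]]
        for k in range(len(pts) - 1):
            nsub = max(1, int(np.ceil(seglen[k] / step)))
            for t in np.linspace(0, 1, nsub + 1)[1:]:
                dense.append(pts[k] * (1 - t) + pts[k + 1] * t)
        dense = np.array(dense)
        inside = ((dense[:, 0] > g1[0]) & (dense[:, 0] < g1[-1]) &
                  (dense[:, 1] > g2[0]) & (dense[:, 1] < g2[-1]))
        prev = None
        for pt, ok in zip(dense, inside):
            if not ok:
                prev = None
                continue
            i, j = cell_of(pt[0], pt[1])
            crossed[j, i] = True
            if prev is not None:
                i0, j0 = prev
                if (i0, j0) != (i, j):
                    # walk cell-by-cell (samples are < half a cell apart,
                    # so at most one step in each direction)
                    if i != i0 and 0 <= min(i0, i) < n1 - 1:
                        block_h[j0, min(i0, i)] = True
                    if j != j0 and 0 <= min(j0, j) < n2 - 1:
                        block_v[min(j0, j), i if i != i0 else i0] = True
                    if i != i0 and j != j0:  # diagonal hop: block both ways
                        block_v[min(j0, j), i0] = True
                        crossed[j, i0] = True
            prev = (i, j)
    return block_h, block_v, crossed


def _arrangement_components(block_h, block_v, crossed):
    """Connected components of clean cells under unblocked 4-adjacency."""
    n2, n1 = crossed.shape
    comp = -np.ones((n2, n1), dtype=int)
    cid = 0
    from collections import deque
    for j0 in range(n2):
        for i0 in range(n1):
            if crossed[j0, i0] or comp[j0, i0] >= 0:
                continue
            queue = deque([(i0, j0)])
            comp[j0, i0] = cid
            while queue:
                i, j = queue.popleft()
                if i + 1 < n1 and not block_h[j, i] and not crossed[j, i + 1] \
                        and comp[j, i + 1] < 0:
                    comp[j, i + 1] = cid
                    queue.append((i + 1, j))
                if i > 0 and not block_h[j, i - 1] and not crossed[j, i - 1] \
                        and comp[j, i - 1] < 0:
                    comp[j, i - 1] = cid
                    queue.append((i - 1, j))
                if j + 1 < n2 and not block_v[j, i] and not crossed[j + 1, i] \
                        and comp[j + 1, i] < 0:
                    comp[j + 1, i] = cid
                    queue.append((i, j + 1))
                if j > 0 and not block_v[j - 1, i] and not crossed[j - 1, i] \
                        and comp[j - 1, i] < 0:
                    comp[j - 1, i] = cid
                    queue.append((i, j - 1))
            cid += 1
    return comp, cid


def region_map(params: ModelParameters, p1: str, p2: str,
               window=((0.0, 7.0), (0.0, 7.0)),
               resolution: int = 71,
               geometry_resolution: int = 241,
               n_starts: int = 192,
               t_end: float = 2500.0,
               label_lattice: bool = True,
               min_region_cells: int = 4) -> RegimeMap:
    """Divide the (p1, p2) plane into regions and label their dynamics.

    The traced fold/Hopf curves cut the window into connected components
    (computed on a fine geometric lattice of ``geometry_resolution``^2
    cells, so thin wedge regions near cusps survive); each component is a
    region, labeled by a census at its deepest interior cell.  Components
    with fewer than ``min_region_cells`` clean cells are below the
    drawing resolution and are dropped.  ``label_lattice`` additionally
    runs a census on a ``resolution``^2 diagnostic lattice.
    """
    if resolution < 21:
        raise ValueError("resolution must be >= 21 per axis")
    (a1, b1), (a2, b2) = window
    curves, cusps = trace_curve_codim2(params, p1, p2, window)
    rmap = RegimeMap(p1=p1, p2=p2, window=window,
                     fold_curves=[c for c in curves if c.kind == "fold"],
                     hopf_curves=[c for c in curves if c.kind == "hopf"],
                     cusps=cusps)

    g1 = np.linspace(a1, b1, geometry_resolution)
    g2 = np.linspace(a2, b2, geometry_resolution)
    block_h, block_v, crossed = _blocked_edges(curves, g1, g2)
    comp, n_comp = _arrangement_components(block_h, block_v, crossed)
    c1 = 0.5 * (g1[:-1] + g1[1:])
    c2 = 0.5 * (g2[:-1] + g2[1:])
    for cid in range(n_comp):
        mask = comp == cid
        cells = int(mask.sum())
        if cells < min_region_cells:
            continue
        dist = ndimage.distance_transform_cdt(mask, metric="taxicab")
        jj, ii = np.unravel_index(np.argmax(dist), dist.shape)
        rep = (float(c1[ii]), float(c2[jj]))
        aset = census(params.replace(**{p1: rep[0], p2: rep[1]}),
                      fast=True, n_starts=max(n_starts, 512), t_end=t_end)
        rmap.regions.append({
            "tag": aset.regime_tag, "cells": cells,
            "representative": rep,
            "n_unstable": aset.n_unstable,
            "exhaustive": aset.exhaustive,
        })
    rmap.regions.sort(key=lambda r: -r["cells"])

    if label_lattice:
        l1 = np.linspace(a1, b1, resolution)
        l2 = np.linspace(a2, b2, resolution)
        labels = np.empty((resolution, resolution), dtype=object)
        for jj, v2 in enumerate(l2):
            for ii, v1 in enumerate(l1):
                aset = census(params.replace(**{p1: float(v1),
                                                p2: float(v2)}),
                              fast=True, n_starts=n_starts, t_end=t_end)
                labels[jj, ii] = aset.regime_tag if aset.exhaustive else "?"
        rmap.grid_p1, rmap.grid_p2, rmap.grid_labels = l1, l2, labels
    return rmap
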