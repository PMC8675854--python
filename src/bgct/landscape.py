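"""Potential landscapes U = -ln(Pss) from noise-driven ensembles.

Additive Gaussian white noise of strength D (covariance 2 D dt per step,
independently on each selected equation) turns the deterministic loop
into Langevin dynamics integrated by Euler-Maruyama.  An ensemble of
seeded runs started from a deterministic spread of initial conditions
samples the stable attractors; the empirical distribution Pss of the
post-burn-in samples, projected onto the cortical/striatal plane
(x1, x2), defines the quasi-potential U = -ln(Pss).  Minima of U mark
stable steady states; a closed low-U ring marks a stable limit cycle.

At D = 1e-6 the noise cannot hop between basins on any feasible horizon,
so relative depths reflect how the initial-condition grid distributes
mass among basins, not Kramers rates; the grid is deterministic and
documented, which is what makes depth comparisons meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from ._fast import euler_maruyama
from .dynamics import default_ic_grid
from .equilibria import find_equilibria
from .params import N_POP, ModelParameters

__all__ = ["NoiseSpec", "Landscape", "langevin_simulate", "estimate_pss",
           "potential"]

#: depth cut (natural-log units above the global minimum) for the low-U
#: set used in ring detection; infinite by default because occupancy along
#: a cycle ring is strongly inhomogeneous (several nats), so the whole
#: occupied support carries the topology
RING_DEPTH = np.inf


@dataclass(frozen=True)
class NoiseSpec:
    """Additive-noise configuration of the Langevin integrator."""

    D: float = 1e-6              # noise strength
    dt: float = 0.01             # Euler-Maruyama step, ms
    seed: int = 0
    applied_to: tuple[int, ...] = tuple(range(1, N_POP + 1))  # equations 1..7
    reflect: bool = False        # optional reflecting floor at x = 0

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValueError("noise strength D must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if not set(self.applied_to) <= set(range(1, N_POP + 1)):
            raise ValueError("applied_to must name equations 1..7")

    @property
    def mask(self) -> np.ndarray:
        m = np.zeros(N_POP, dtype=np.bool_)
        m[[i - 1 for i in self.applied_to]] = True
        return m


@dataclass
class Landscape:
    """2-D occupancy histogram on (x1, x2) and its quasi-potential."""

    bin_edges: tuple[np.ndarray, np.ndarray]
    pss: np.ndarray                          # normalized, sums to 1
    U: np.ndarray | None = None              # -ln(pss), NaN on empty bins
    minima: list[tuple[float, float]] = field(default_factory=list)
    minima_depths: list[float] = field(default_factory=list)
    ring_detected: bool = False
    n_samples: int = 0

    @property
    def bin_centers(self) -> tuple[np.ndarray, np.ndarray]:
        e1, e2 = self.bin_edges
        return 0.5 * (e1[:-1] + e1[1:]), 0.5 * (e2[:-1] + e2[1:])

    @property
    def bin_diagonal(self) -> float:
        e1, e2 = self.bin_edges
        return float(np.hypot(e1[1] - e1[0], e2[1] - e2[0]))

    def save(self, stem: str | Path) -> None:
        """Text grid container (npz-free): edges + pss + U, and minima CSV."""
        stem = Path(stem)
        e1, e2 = self.bin_edges
        with open(stem.with_suffix(".txt"), "w") as fh:
            fh.write("# potential landscape grid: x1/x2 bin edges, Pss, U\n")
            fh.write("x1_edges " + " ".join(f"{v:.8g}" for v in e1) + "\n")
            fh.write("x2_edges " + " ".join(f"{v:.8g}" for v in e2) + "\n")
            fh.write(f"ring_detected {int(self.ring_detected)}\n")
            np.savetxt(fh, self.pss, header="Pss rows=x1 cols=x2")
            if self.U is not None:
                np.savetxt(fh, self.U, header="U=-ln(Pss)")
        pd.DataFrame({
            "x1": [m[0] for m in self.minima],
            "x2": [m[1] for m in self.minima],
            "U": self.minima_depths,
        }).to_csv(stem.with_suffix(".csv"), index=False)


def langevin_simulate(params: ModelParameters, noise: NoiseSpec,
                      x0, t_end: float,
                      record_step: float = 1.0,
                      burn_in: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """One seeded Euler-Maruyama path; returns (times, states).

    With D = 0 this is deterministic Euler at step ``dt``.  States are
    recorded every ``record_step`` ms after ``burn_in`` ms.
    """
    x0 = np.asarray(x0, dtype=float)
    n_steps = int(round(t_end / noise.dt))
    stride = max(1, int(round(record_step / noise.dt)))
    skip = int(round(burn_in / noise.dt))
    amp = float(np.sqrt(2.0 * noise.D * noise.dt))
    X = euler_maruyama(params.pack(), x0, noise.dt, n_steps, amp,
                       noise.mask, stride, skip, int(noise.seed),
                       noise.reflect)
    if not np.all(np.isfinite(X)):
        raise RuntimeError(
            f"Langevin path blew up (seed={noise.seed}, x0={x0})")
    t = (np.arange(X.shape[0]) * stride + skip) * noise.dt
    return t, X


def estimate_pss(params: ModelParameters, noise: NoiseSpec,
                 ensemble: int = 200,
                 t_end: float = 3000.0,
                 burn_in: float = 1500.0,
                 grid: int = 100,
                 record_step: float = 1.0,
                 sampling: str = "occupancy",
                 ic_grid: np.ndarray | None = None,
                 pad: float = 0.10) -> Landscape:
    """Estimate the stationary occupancy Pss on the (x1, x2) plane.

    ``ensemble`` seeded replicates start from the deterministic census
    initial-condition grid (cycled as needed); per-run seeds fan out as
    ``noise.seed + k``.  ``sampling="occupancy"`` histograms every
    post-burn-in sample (the default: it traces cycle rings);
    ``"endpoint"`` histograms final states only.  The histogram covers
    the occupied bounding box padded by ``pad`` on each side.
    """
    if ensemble < 1:
        raise ValueError("ensemble must be >= 1")
    if sampling not in ("occupancy", "endpoint"):
        raise ValueError("sampling must be 'occupancy' or 'endpoint'")
    if ic_grid is None:
        eqs = find_equilibria(params, n_starts=512)
        ic_grid = default_ic_grid(params, n_box=64, equilibria=eqs)
    ic_grid = np.atleast_2d(ic_grid)
    samples = []
    for k in range(ensemble):
        spec = NoiseSpec(D=noise.D, dt=noise.dt,
                         seed=int(noise.seed) + k,
                         applied_to=noise.applied_to, reflect=noise.reflect)
        _t, X = langevin_simulate(params, spec,
                                  ic_grid[k % len(ic_grid)], t_end,
                                  record_step=record_step, burn_in=burn_in)
        samples.append(X[-1:, :2] if sampling == "endpoint" else X[:, :2])
    pts = np.vstack(samples)
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    span = np.maximum(hi - lo, 1e-6)
    lo -= pad * span
    hi += pad * span
    H, e1, e2 = np.histogram2d(pts[:, 0], pts[:, 1], bins=grid,
                               range=[[lo[0], hi[0]], [lo[1], hi[1]]])
    if H.sum() == 0:
        raise RuntimeError("empty occupancy histogram")
    return Landscape(bin_edges=(e1, e2), pss=H / H.sum(),
                     n_samples=int(H.sum()))


def potential(land: Landscape, ring_depth: float = RING_DEPTH,
              smooth_bins: float = 1.0,
              min_prominence: float = 0.5) -> Landscape:
    """Fill U = -ln(Pss), its strict local minima and the ring flag.

    Empty bins are masked (NaN) and excluded from the minima search: a
    minimum must be strictly below all of its 8 occupied neighbors.  The
    search runs on a lightly smoothed histogram (Gaussian, sigma =
    ``smooth_bins`` bins) and keeps one minimum per basin of prominence
    at least ``min_prominence`` nats, so per-bin sampling jitter does not
    fragment a basin into spurious minima; the stored U is raw.  The
    ring test thresholds U at (global min + ``ring_depth``) and asks
    whether the resulting low-U set encloses a hole (flood fill), the
    occupancy signature of a stable limit cycle.
    """
    pss = land.pss
    occupied = pss > 0
    U = np.full_like(pss, np.nan)
    U[occupied] = -np.log(pss[occupied])
    land.U = U

    psm = ndimage.gaussian_filter(pss, smooth_bins) if smooth_bins > 0 \
        else pss
    Usm = np.where(psm > 0, -np.log(np.maximum(psm, 1e-300)), np.inf)

    # Basins rather than bins: a reported minimum must be at least
    # ``min_prominence`` nats below the ridge connecting it to any deeper
    # basin (h-minima transform), so per-bin sampling jitter inside one
    # basin yields a single minimum.  Within each basin the deepest
    # occupied bin is reported; it is strictly below its 8 neighbors of
    # the smoothed potential by construction of the transform.
    # bins with fewer than 3 samples are not statistically occupied: a
    # stray single-sample bin would otherwise pose as an isolated minimum
    solid = pss * max(land.n_samples, 1) >= 3.0 if land.n_samples else occupied
    ceiling = np.nanmax(Usm[np.isfinite(Usm)]) + 1.0
    Ufill = np.where(np.isfinite(Usm), Usm, ceiling)
    from skimage.morphology import h_minima
    basins, n_basins = ndimage.label(
        h_minima(Ufill, min_prominence) & solid,
        structure=np.ones((3, 3)))
    minima: list[tuple[float, float]] = []
    depths: list[float] = []
    c1, c2 = land.bin_centers
    for bid in range(1, n_basins + 1):
        mask = basins == bid
        Ub = np.where(mask, Usm, np.inf)
        i, j = np.unravel_index(np.argmin(Ub), Ub.shape)
        minima.append((float(c1[i]), float(c2[j])))
        depths.append(float(U[i, j]))
    order = np.argsort(depths)
    land.minima = [minima[k] for k in order]
    land.minima_depths = [depths[k] for k in order]

    low = occupied & (U <= np.nanmin(U) + ring_depth)
    # bridge single-bin sampling gaps before the flood-fill hole test
    low = ndimage.binary_closing(low, structure=np.ones((3, 3)))
    filled = ndimage.binary_fill_holes(low)
    hole = filled & ~low
    land.ring_detected = bool(hole.sum() >= 4)
    return land
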