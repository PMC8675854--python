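"""Reproducible synthetic fixtures: time series and noisy trajectories.

The fixture bundle emulates the raw material of the analysis — panels of
deterministic time series from varied initial conditions, one per
dynamical regime of the (T42, T53) plane, plus seeded stochastic
trajectories for the landscape stage, plus a pinned-state drift
regression table.  Everything is derived from one seed and is
byte-identical across runs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import stage_seed
from .dynamics import census, default_ic_grid, integrate
from .equilibria import find_equilibria
from .landscape import NoiseSpec, langevin_simulate
from .model import drift
from .params import ModelParameters

__all__ = ["REGIME_POINTS", "generate_fixtures", "pinned_drift_table"]

#: One representative (T42, T53) interior point per region of the
#: direct/indirect-pathway plane, as located by region_map (deepest
#: interior cell of each curve-bounded component); tags from the census.
REGIME_POINTS: tuple[tuple[float, float, str], ...] = (
    (0.01, 6.11, "1SS+0LC"),
    (5.24, 4.56, "0SS+1LC"),
    (3.57, 5.59, "2SS+0LC"),
    (5.96, 5.76, "1SS+1LC"),
    (4.77, 6.49, "3SS+0LC"),
    (1.97, 0.01, "2SS+0LC"),
    (6.96, 6.66, "0SS+2LC"),
    (3.66, 6.99, "2SS+0LC"),
    (5.03, 5.76, "2SS+0LC"),
    (6.99, 0.01, "0SS+1LC"),
    (5.76, 6.99, "2SS+1LC"),
    (5.85, 6.55, "1SS+1LC"),
)

#: pinned states for the drift regression fixture
PINNED_STATES = np.array([
    [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
    [1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0],
    [0.5, 1.5, 2.5, 3.5, 4.5, 5.5, 6.5],
    [2.0, 0.1, 4.0, 0.3, 1.2, 0.7, 3.3],
    [-0.5, 2.0, -1.0, 6.0, 0.0, 1.5, 2.2],
])


def pinned_drift_table(params: ModelParameters | None = None) -> pd.DataFrame:
    """Drift components at the pinned states (regression fixture)."""
    params = params or ModelParameters().replace(T42=1.0, T53=1.0)
    rows = []
    for x in PINNED_STATES:
        dx = drift(x, params)
        row = {f"x{i+1}": x[i] for i in range(7)}
        row.update({f"dx{i+1}": dx[i] for i in range(7)})
        rows.append(row)
    return pd.DataFrame(rows)


def generate_fixtures(seed: int, outdir: str | Path,
                      t_end: float = 2000.0,
                      n_ic: int = 4) -> dict:
    """Write the fixture bundle; returns an index of what was written.

    (a) per-regime deterministic time series (``n_ic`` initial
    conditions each, sampled at 1 ms), (b) seeded Langevin paths at a
    bistable and an oscillatory point, (c) the pinned-state drift table.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    base = ModelParameters()
    index: dict = {"seed": int(seed), "time_series": [], "stochastic": []}

    for k, (t42, t53, tag) in enumerate(REGIME_POINTS):
        p = base.replace(T42=t42, T53=t53)
        ics = default_ic_grid(p, n_box=n_ic,
                              equilibria=find_equilibria(p, n_starts=256))
        frames = {}
        for j, x0 in enumerate(ics[:n_ic + 4]):
            t, X = integrate(p, x0, t_end, method="rk4", step=1.0)
            frames[f"ic{j}"] = X[:, 0]
        df = pd.DataFrame({"t_ms": t, **frames})
        name = f"timeseries_region{k + 1:02d}_{tag}.csv"
        with open(outdir / name, "w") as fh:
            fh.write(f"# deterministic cortical activity x1, T42={t42} "
                     f"T53={t53}, regime {tag}; units: t in ms\n")
            df.to_csv(fh, index=False, float_format="%.10g")
        index["time_series"].append({"file": name, "T42": t42, "T53": t53,
                                     "tag": tag})

    sseed = stage_seed(seed, "fixtures")
    for k, (t42, t53, label) in enumerate(
            [(1.97, 0.01, "bistable"), (5.24, 4.56, "oscillatory")]):
        p = base.replace(T42=t42, T53=t53)
        eqs = find_equilibria(p, n_starts=256)
        x0 = default_ic_grid(p, n_box=2, equilibria=eqs)[0]
        noise = NoiseSpec(D=1e-6, seed=sseed + k)
        t, X = langevin_simulate(p, noise, x0, t_end, record_step=1.0)
        df = pd.DataFrame(np.column_stack([t, X]),
                          columns=["t_ms"] + [f"x{i+1}" for i in range(7)])
        name = f"langevin_{label}_seed{noise.seed}.csv"
        with open(outdir / name, "w") as fh:
            fh.write(f"# Langevin path, D=1e-6, T42={t42} T53={t53}, "
                     f"seed={noise.seed}; units: t in ms\n")
            df.to_csv(fh, index=False, float_format="%.10g")
        index["stochastic"].append({"file": name, "label": label,
                                    "seed": noise.seed})

    pinned_drift_table().to_csv(outdir / "drift_regression.csv", index=False,
                                float_format="%.17g")
    index["drift_regression"] = "drift_regression.csv"
    (outdir / "index.json").write_text(json.dumps(index, indent=2))
    return index
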