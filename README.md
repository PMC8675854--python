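# bgct

Bifurcation structure, attractor census and potential landscapes of a
cortex–basal ganglia–thalamus (BGCT) firing-rate loop.

Cortical beta-band oscillation (13–30 Hz) is the electrophysiological
hallmark of Parkinsonian motor dysfunction and is driven by an imbalance
between the striatal **direct pathway** (D1 neurons → GPi, weight `T42`)
and **indirect pathway** (D2 neurons → GPe, weight `T53`) under low
dopamine.  This package implements the standard seven-population
firing-rate model of that loop — cortex, striatum-D1, striatum-D2, GPi,
GPe, thalamus, STN, each obeying

```
C_i dx_i/dt = I_i − x_i/R_i + Σ_j ±T_ij · x_j^n/(s^n + x_j^n)
```

(with ±D_input on the two striatal equations) — and the complete
analysis chain a dynamicist would apply to it:

- **Equilibria** (`find_equilibria`): deterministic multistart Newton
  inside an a-priori root box, with eigenvalue stability labels.
- **Attractor census** (`census`): compiled integration from a
  deterministic spread of initial conditions, classifying fixed points
  vs limit cycles (period, envelope, Hz, beta-band flag) into regime
  tags like `2SS+1LC`.
- **Codim-1 continuation** (`trace_branch_codim1`): pseudo-arclength
  equilibrium branches with fold and Hopf points polished on their
  extended defining systems.
- **Codim-2 mapping** (`region_map`, `trace_curve_codim2`): fold/Hopf
  curves continued through a parameter plane, cusp points, and the
  region decomposition the curves induce, each region labeled by its
  attractor configuration.
- **Potential landscapes** (`estimate_pss`, `potential`): seeded
  Euler–Maruyama ensembles under weak additive noise; the quasi-
  potential `U = −ln(P_ss)` on the cortical/striatal `(x1, x2)` plane,
  whose minima mark stable states and whose closed low-U rings mark
  limit cycles.

It is a library first (see `examples/`), with a thin `bgct` CLI
(`census`, `scan1d`, `scan2d`, `landscape`, `fixtures`) for shell use.

## Worked example

Scan the direct-pathway weight at indirect pathway `T53 = 4`
(`examples/02_branch_diagram.py`):

```
8 equilibrium branches traced
fold  at T42 = 1.4508  (x1 = 0.4983)
fold  at T42 = 1.7761  (x1 = 0.9998)
Hopf  at T42 = 4.0553  (omega = 0.0834/ms -> 13.3 Hz at onset)
Hopf  at T42 = 5.7625  (omega = 0.1014/ms -> 16.1 Hz at onset)
stable cycle present for T42 in [4.20, 5.60], periods 63.1-74.5 ms
```

The equilibrium curve is Z-shaped (two folds bounding a bistable
window); between the two supercritical Hopf points the only attractor is
a limit cycle whose frequency (`1000/period ≈ 13–16 Hz`) sits in the
beta band — the model's expression of the Parkinsonian rhythm.  The full
two-parameter map (`examples/04_region_map.py`) cuts `(T42, T53) ∈
[0,7]²` by 5 fold and 4 Hopf curve branches (3 cusps) into **12
regions**:

```
12 regions, cut by 5 fold and 4 Hopf curve branches; 3 cusp points
  1SS+0LC   at (T42=0.01, T53=6.11)  area ~73.8% of the window
  0SS+1LC   at (T42=5.24, T53=4.56)  area ~6.6% of the window
  ...
  0SS+2LC   at (T42=6.96, T53=6.66)  area ~1.8% of the window
```

`kSS+mLC` counts coexisting stable steady states and stable limit
cycles; oscillatory regions concentrate where both weights are large,
especially where the indirect pathway outweighs the direct one.  At a
bistable point, the noise-driven landscape
(`examples/05_potential_landscape.py`) recovers the deterministic
attractors:

```
2 landscape minima, ring: False
  minimum at (x1=0.163, x2=1.098)  U = 0.991
  minimum at (x1=1.938, x2=3.453)  U = 1.244
deterministic stable states (x1, x2): [(0.17, 1.104), (1.946, 3.468)]
```

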