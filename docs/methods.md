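# Methods

## Model

The package implements a firing-rate model of the cortex–basal
ganglia–thalamus (BGCT) loop with seven populations, indexed 1–7:
cortex, striatal D1 and D2 neurons, GPi, GPe, thalamus, STN.  Each
activity `x_i` obeys

    C_i dx_i/dt = I_i − x_i/R_i + Σ_j ±T_ij · H(x_j)   (+D_input in eq. 2,
                                                        −D_input in eq. 3)

with the Hill response `H(x) = x^n/(s^n + x^n)` (`s = 2`, `n = 2`).
Excitatory couplings (cortex→striatum/STN, thalamus→cortex/striatum,
STN→GPi/GPe) enter with `+`, inhibitory ones (striatum→GPi/GPe,
GPe→GPi/STN — via T45 and T75 —, GPi→thalamus) with `−`.  Time is in
ms; with `C = 3.60` and `R = 1.67` the membrane time constant is
`RC ≈ 6 ms` (the table values are used verbatim; the nominal τ = 6 ms is
documentation only).  Reported frequencies are `1000/period(ms)` Hz.

The central control parameters are the direct-pathway weight `T42`
(striatum-D1→GPi) and indirect-pathway weight `T53` (striatum-D2→GPe),
explored on `[0, 7]`.  The typical table omits values for them because
they are the scanned quantities; `ModelParameters` defaults both to 1.0
(deep inside the monostable regime) and every analysis sets them
explicitly.  The dopamine level `D_input = 0.6` models the low-dopamine
condition throughout.

The equations do not clamp negative activity and, with even `n`, the
Hill term is defined on all of ℝ; the deterministic field is therefore
evaluated exactly as written.  Equilibria genuinely reach `x4 ≈ −9` at
large `T42`.  The stochastic integrator offers an optional reflecting
floor at 0, off by default.

## Equilibria

All fixed points satisfy `x_i = R_i (I_i + signed weight sums)` with
each Hill factor in `[0, 1)`, which yields a rigorous a-priori box
containing every root.  `find_equilibria` runs step-capped Newton from a
scrambled Sobol grid inside that box (pinned scramble seed; fully
deterministic), deduplicates roots at 1e−5 max-abs distance, discards
non-roots, and classifies stability by the eigenvalues of the analytic
Jacobian (stable iff every real part < −1e−8; real parts inside the
margin flag a bifurcation-adjacent root).  Saturation of the root list
under doubling of the multistart count is a tested property.

## Attractor census

`census` integrates a deterministic spread of initial conditions —
Sobol points across the equilibrium box plus perturbations of every
equilibrium along its leading eigenvector — with a compiled fixed-step
RK4 kernel (dt = 0.05 ms, ~120 steps per membrane time constant;
cross-checked against adaptive LSODA, which also backs the public
`integrate`).  Each trajectory tail (after discarding the leading 50%)
is classified:

- peak-to-peak below 1e−3 on every variable → equilibrium, polished by
  Newton;
- otherwise the period is the mean of the trailing inter-peak intervals
  of x1 (quadratic peak interpolation, ≥ 5 intervals, CV < 2%), subject
  to an amplitude-stationarity check: the excursions of the two halves
  of the tail must agree within 2%.  Without that check, spirals
  decaying slowly near a Hopf point keep a near-constant period and
  masquerade as cycles; decaying cases are polished back to the stable
  focus instead.
- anything else is "undecided" and re-run once at double horizon; if it
  persists the census is flagged non-exhaustive.

Cycles are distinct attractors when the relative period difference
exceeds 2% **or** the mean-state distance exceeds 0.05 — both small for
the same orbit — so the two coexisting cycles at strong weights are
never merged.  A `fast` mode integrates only perturbations of unstable
equilibria (every cycle here is born by a supercritical Hopf around an
unstable focus); agreement between fast and exhaustive censuses at
random parameter points is a tested property.

## Bifurcation continuation

Codim-1 diagrams use pseudo-arclength continuation in `(x, p)`:
SVD-nullspace tangents, Newton corrector to 1e−10, adaptive arclength
step in `[1e−5, 0.1]`, branches seeded from equilibria at nine uniform
slices so disconnected branches are caught.  Folds are flagged by
reversal of the parameter component of the tangent and polished on the
extended system `{f = 0, J v = 0, |v| = 1}`; Hopf points by sign change
of the leading complex pair's real part (direct pair tracking; pairs
with `|Im λ| < 1e−4` count as fold-adjacent, not Hopf) and polished on
`{f = 0, J q = iωq, |q| = 1, Re q·Im q = 0}` with an explicitly
phase-rotated eigenvector seed.

Codim-2 curves continue the same extended systems with a second free
parameter, seeded from codim-1 scans along eight horizontal and two
transverse slices.  Jacobians of the extended systems are central finite
differences (the residuals themselves are analytic).  Cusps are emitted
where the curve's parameter-plane projection reverses direction; the
continued curve passes smoothly through a cusp in the full space, so
the conventional curve *labels* of two-parameter diagrams correspond to
segments split at such turning points.  `count_curve_branches` performs
that split and drops stubs shorter than 0.3 in-window arclength
(drawing resolution), giving the 5 fold + 4 Hopf branches of the
(T42, T53) plane from 3 + 3 continued curves.

### Regions

Connected components of *identical census tags* are not the right
notion of "region": a stable cycle can die on a saddle (homoclinically)
in the interior of a fold/Hopf-bounded cell — the period blow-up at
T53 = 5 is the tested signature — so tag components over-count.
`region_map` instead cuts the window by the traced fold/Hopf curves on
a fine geometric lattice (default 241² cells; cells crossed by a curve
are excluded, adjacencies crossing a curve are blocked), takes connected
components, drops components below 4 cells (sub-resolution slivers),
and labels each region by a census at its deepest interior cell.  For
(T42, T53) in `[0, 7]²` this yields 12 regions whose configuration
multiset is {1×1SS, 4×2SS, 2×1LC, 1×3SS, 2×(1SS+1LC), 1×(2SS+1LC),
1×2LC}.  An optional diagnostic lattice (default 71²) stores a census
tag per grid point.

The GPi-input map over `(T45, T47)` is computed at `T42 = T53 = 2.0`
(a value chosen once for this package): it exhibits six regions showing
four distinct stable dynamics (1SS, 2SS, 1LC, 1SS+1LC), with fold
cusps and two Hopf branches.  The CLI requires the two pathway weights
explicitly for this map.

## Potential landscapes

Additive Gaussian white noise with `⟨ζ(t)ζ(t′)⟩ = 2Dδ(t−t′)` acts
isotropically on all seven equations (strength `D = 1e−6` by default;
the noise "tensor" is read as the simplest isotropic diagonal consistent
with a scalar D).  Euler–Maruyama at dt = 0.01 ms integrates 200 seeded
replicates (seeds fan out as `seed + k`) from the census
initial-condition grid for 3000 ms; samples after a 1500 ms burn-in are
histogrammed on a 100×100 grid over the padded occupied bounding box of
`(x1, x2)`, normalized into `Pss`, and `U = −ln(Pss)` on occupied bins.

At `D = 1e−6` basin hopping is astronomically slow, so `Pss` is a
multi-start ensemble average, not an ergodic average: relative depths of
minima reflect how the deterministic IC grid distributes mass among
basins and are comparable *within* one grid, which is deterministic and
recorded.  Both occupancy sampling (default; it traces cycle rings) and
endpoint-only sampling are implemented.

Minima: the raw histogram carries Poisson jitter, so strict
8-neighbor minima fragment a single basin into dozens.  Reported minima
are one per basin of topographic prominence ≥ 0.5 nat (h-minima of the
σ = 1 bin Gaussian-smoothed histogram), restricted to bins holding ≥ 3
samples (a stray single-sample bin would otherwise pose as an isolated
minimum); the stored `U` remains raw.  Ring detection flood-fills the
occupied support (after one binary closing to bridge single-bin gaps)
and reports a ring when a hole of ≥ 4 bins is enclosed; a fixed
depth-threshold variant is available but off by default because
occupancy along a ring varies by several nats.

## Reproducibility and problem sizes

Everything deterministic (equilibria, continuation, census, regions) is
seed-free and exactly repeatable; stochastic stages derive per-stage
seeds from one global seed via `stage_seed` (stage index appended, kept
below 2³¹).  Default problem sizes — 2000 multistarts, 241² geometric
lattice, 200-run ensembles, 3000 ms horizons — are the package's
operating choices and complete on a single CPU in a few minutes
altogether.

## Known limitations

- Unstable limit cycles and homoclinic/period-doubling/torus
  continuation are out of scope; the cycle–saddle collision is detected
  only as period blow-up, and first Lyapunov coefficients are not
  computed ("supercritical" is established empirically by the stable
  cycle on one side).
- Census completeness is empirical (multi-start saturation), not
  certified; attractors with basins thinner than the start grids would
  be missed.
- Landscape depth comparisons across different IC grids or noise
  strengths are not meaningful (see above).
- The synthetic fixtures emulate model-generated time series only; no
  feature of experimental recordings (measurement noise, nonstationary
  drifts, finite sampling) is modeled, so passing tests validate the
  analysis chain, not its behavior on real recordings.
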