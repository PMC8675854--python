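"""Codim-1 bifurcation diagram of cortical activity vs the direct pathway.

Scanning the striatum-D1 -> GPi weight T42 at fixed indirect pathway
T53 = 4 produces a Z-shaped equilibrium curve with a fold pair and two
supercritical Hopf points on the lower branch; between the Hopf points
the cortex oscillates on a stable limit cycle.
"""

from bgct import ModelParameters, trace_branch_codim1

diagram = trace_branch_codim1(ModelParameters().replace(T53=4.0),
                              "T42", (0.0, 7.0))

print(f"{len(diagram.branches)} equilibrium branches traced")
for f in diagram.folds:
    print(f"fold  at T42 = {f['param']:.4f}  (x1 = {f['state'][0]:.4f})")
for h in diagram.hopfs:
    freq = 1000.0 * h["omega"] / (2.0 * 3.141592653589793)
    print(f"Hopf  at T42 = {h['param']:.4f}  (omega = {h['omega']:.4f}/ms "
          f"-> {freq:.1f} Hz at onset)")

env = diagram.cycle_envelope
osc = env[env.x1_max - env.x1_min > 1e-3]
if len(osc):
    print(f"stable cycle present for T42 in "
          f"[{osc.scan_value.min():.2f}, {osc.scan_value.max():.2f}], "
          f"periods {osc.period_ms.min():.1f}-{osc.period_ms.max():.1f} ms")
# The Hopf angular frequency omega fixes the oscillation frequency at
# onset; 2*pi/omega in ms converts to Hz via 1000/period.
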