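"""Census of coexisting attractors, including two rival limit cycles.

Right of the upper-branch Hopf point at T53 = 6 the loop supports two
distinct stable oscillations at once — a slow large-amplitude cycle and
a faster one around a different mean activity.  The census integrates a
deterministic spread of initial conditions and classifies every tail.
"""

from bgct import ModelParameters, census

aset = census(ModelParameters().replace(T42=6.7, T53=6.0), n_starts=512)

print(f"regime: {aset.regime_tag} "
      f"(+{aset.n_unstable} unstable steady states)")
for c in aset.cycles:
    print(f"cycle: period {c.period:6.2f} ms  ({c.frequency:5.2f} Hz, "
          f"beta band: {c.beta_band})  "
          f"x1 range [{c.envelope[0, 0]:.3f}, {c.envelope[1, 0]:.3f}]")
# The regime tag counts stable attractors: kSS+mLC = k stable steady
# states and m stable limit cycles.  Which cycle the cortex follows is
# set by the initial condition - multistability of rhythms.
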