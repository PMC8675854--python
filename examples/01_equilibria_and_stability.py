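"""Enumerate the coexisting steady states in the tristable window.

At a strong indirect pathway (T53 = 6) and intermediate direct pathway
(T42 = 4.5) the loop holds three stable cortical activity levels at
once, separated by two saddles; which one the cortex settles into
depends purely on initial conditions.
"""

from bgct import ModelParameters, find_equilibria

params = ModelParameters().replace(T42=4.5, T53=6.0)
equilibria = find_equilibria(params, n_starts=2000)

print(f"{len(equilibria)} equilibria at T42=4.5, T53=6.0")
print(f"{'x1 (cortex)':>12} {'x4 (GPi)':>10} {'x6 (thal.)':>10} "
      f"{'lead Re(lambda)':>16} stability")
for eq in equilibria:
    lead = eq.eigenvalues[0].real
    print(f"{eq.state[0]:12.4f} {eq.state[3]:10.4f} {eq.state[5]:10.4f} "
          f"{lead:16.6f} {eq.stability}")
# x1 is the cortical activity the analysis tracks; negative leading
# eigenvalue real parts mean perturbations decay back to that state.
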