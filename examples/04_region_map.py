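"""Two-parameter regime map of the direct/indirect pathway plane.

Fold and Hopf curves are continued through (T42, T53) in [0,7]^2 and cut
the plane into regions; a census labels each region's attractor
configuration.  The full map takes about half a minute.
"""

from bgct import ModelParameters, count_curve_branches, region_map

rmap = region_map(ModelParameters(), "T42", "T53", label_lattice=False)

branches = count_curve_branches(rmap.fold_curves + rmap.hopf_curves)
print(f"{rmap.region_count} regions, cut by {branches['fold']} fold and "
      f"{branches['hopf']} Hopf curve branches; "
      f"{len(rmap.cusps)} cusp points")
for r in rmap.regions:
    x, y = r["representative"]
    print(f"  {r['tag']:9s} at (T42={x:.2f}, T53={y:.2f})  "
          f"area ~{100 * r['cells'] / 240 ** 2:.1f}% of the window")
# Oscillatory tags (..+1LC/&2LC) appear only at larger weights, mostly
# where the indirect pathway T53 exceeds the direct pathway T42 - the
# imbalance associated with Parkinsonian beta oscillation.
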