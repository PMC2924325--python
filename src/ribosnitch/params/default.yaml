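# Default nearest-neighbor energy parameter set (version 1).
#
# A deliberately compact, fully specified thermodynamic model for nested RNA
# secondary structure:
#   * stacking free energies for each step of adjacent base pairs,
#   * length-dependent penalties for hairpin, bulge and internal loops
#     (tabulated, with logarithmic Jacobson-Stockmayer extrapolation beyond
#     the table),
#   * an affine multiloop penalty (closing + per-branch + per-unpaired-base).
# Stacking magnitudes follow the familiar nearest-neighbor ordering
# (GC-rich steps strongest, GU weakest); loop tables are coarse.  All values
# in kcal/mol at the default temperature.
version: 1
temperature_kelvin: 310.15
gas_constant_kcal: 0.0019872
min_hairpin_loop: 3
max_interior_loop: 30          # bulge/internal loops above this size are disallowed
loop_extrapolation_factor: 1.75  # E(s) = E(s_max) + f * R*T * ln(s / s_max)

allowed_pairs: [AU, UA, GC, CG, GU, UG]

# stack[XY][WZ]: free energy of the step where pair X.Y (outer, 5'X...Y3')
# is stacked on pair W.Z (inner, at positions i+1, j-1).
stack:
  AU: {AU: -0.9, UA: -1.1, GC: -2.2, CG: -2.1, GU: -0.6, UG: -1.4}
  UA: {AU: -1.3, UA: -0.9, GC: -2.4, CG: -2.1, GU: -1.0, UG: -1.3}
  GC: {AU: -2.1, UA: -2.2, GC: -3.3, CG: -3.4, GU: -1.5, UG: -2.5}
  CG: {AU: -2.1, UA: -2.4, GC: -3.3, CG: -2.4, GU: -1.4, UG: -2.1}
  GU: {AU: -1.3, UA: -1.4, GC: -2.5, CG: -2.1, GU: -0.5, UG: -0.4}
  UG: {AU: -0.6, UA: -1.0, GC: -1.5, CG: -1.4, GU: -0.2, UG: -0.5}

# hairpin[size]: penalty for a hairpin loop of `size` unpaired residues.
hairpin:
  3: 5.4
  4: 5.6
  5: 5.7
  6: 5.4
  7: 6.0
  8: 5.5
  9: 6.4

# bulge[size]: penalty for a bulge loop (unpaired residues on one side only).
bulge:
  1: 3.8
  2: 2.8
  3: 3.2
  4: 3.6
  5: 4.0
  6: 4.4

# internal[size]: penalty for an internal loop of total size l1 + l2 (both >= 1).
internal:
  2: 1.5
  3: 1.6
  4: 1.7
  5: 2.0
  6: 2.0
  7: 2.2
  8: 2.3
  9: 2.4
  10: 2.5

multiloop:
  closing: 3.4      # once per multiloop
  branch: 0.4       # per interior helix
  unpaired: 0.0     # per unpaired residue inside the loop
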