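# Built-in simplified nearest-neighbour parameter set, version 1 (frozen).
# Units: kcal/mol.  Stack energies are keyed by outer pair then inner pair,
# where a pair is named by its 5' and 3' base, e.g. "GC" is G paired with C.
# Strong (GC-type) on strong stacks -3.0, weak (AU/GU-type) on weak -1.0,
# mixed -2.0.  Loop penalties follow a + b*ln(size); the multiloop penalty is
# linear in branch and unpaired counts.  Do not edit in place: bump the
# version and ship a new file, since trained models fingerprint this table.
version: builtin-v1
temperature_kelvin: 310.15
gas_constant_kcal: 0.0019872
hairpin: {a: 4.5, b: 1.0, min_unpaired: 3}
internal: {a: 1.5, b: 1.0}
multiloop: {a: 3.0, b_branch: 0.3, c_unpaired: 0.1}
max_interior_loop: 30
stacks:
  GC: {GC: -3.0, CG: -3.0, AU: -2.0, UA: -2.0, GU: -2.0, UG: -2.0}
  CG: {GC: -3.0, CG: -3.0, AU: -2.0, UA: -2.0, GU: -2.0, UG: -2.0}
  AU: {GC: -2.0, CG: -2.0, AU: -1.0, UA: -1.0, GU: -1.0, UG: -1.0}
  UA: {GC: -2.0, CG: -2.0, AU: -1.0, UA: -1.0, GU: -1.0, UG: -1.0}
  GU: {GC: -2.0, CG: -2.0, AU: -1.0, UA: -1.0, GU: -1.0, UG: -1.0}
  UG: {GC: -2.0, CG: -2.0, AU: -1.0, UA: -1.0, GU: -1.0, UG: -1.0}
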