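# 16x16 two-type cell-sorting demonstration (simulation only; the state space
# is far above the enumeration cap).  Illustrative parameter values.
lattice:
  dimensions: [16, 16]
  boundary: periodic
  copy_neighborhood: {kind: von_neumann, order: 1}
cells:
  K: 16
  types:
    1: A
    2: A
    3: A
    4: A
    5: A
    6: A
    7: A
    8: A
    9: B
    10: B
    11: B
    12: B
    13: B
    14: B
    15: B
    16: B
hamiltonian:
  surface:
    A: {A: 2.0, B: 11.0, medium: 16.0}
    B: {B: 2.0, medium: 16.0}
    medium: {medium: 0.0}
  volume:
    include_medium: false
    per_type:
      A: {target: 16.0, strength: 1.0}
      B: {target: 16.0, strength: 1.0}
dynamics:
  kernel: modified
  temperature: 4.0
  threshold: 0.0
  convention: shifted
  seed: 1
experiment:
  name: sorting-16x16
  steps: 256000   # 1000 MCS
  record_every: 2560
  exact: false
  initial: {kind: equal_blocks}
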