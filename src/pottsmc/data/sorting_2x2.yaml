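# 2x2 lattice, medium + two cells (types A, B), differential-adhesion surface
# term plus a weak volume constraint.  81 states: fully enumerable.
lattice:
  dimensions: [2, 2]
  boundary: periodic
  copy_neighborhood: {kind: moore, order: 1}
cells:
  K: 2
  types: {1: A, 2: B}
hamiltonian:
  surface:
    A: {A: 1.0, B: 2.0, medium: 1.0}
    B: {B: 1.0, medium: 1.0}
    medium: {medium: 0.0}
  volume:
    include_medium: false
    per_type:
      A: {target: 1.0, strength: 0.5}
      B: {target: 1.0, strength: 0.5}
dynamics:
  kernel: modified
  temperature: 1.0
  threshold: 0.0
  convention: shifted
  seed: 1
experiment:
  name: sorting-2x2
  steps: 2000
  replicates: 10000
  max_steps: 100000
  record_every: 10
  initial: {kind: single_site_cells}
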