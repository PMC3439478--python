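# Voter limit: H == 0 on a 4-site ring with two cells plus medium.
lattice:
  dimensions: [4]
  boundary: periodic
  copy_neighborhood: {kind: von_neumann, order: 2}
cells:
  K: 2
hamiltonian: {}
dynamics:
  kernel: modified
  temperature: 1.0
  threshold: 0.0
  convention: shifted
  seed: 1
experiment:
  name: voter-ring
  steps: 2000
  replicates: 10000
  max_steps: 100000
  record_every: 10
  initial: {kind: single_site_cells}
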