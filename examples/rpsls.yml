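# Five-species cyclic lattice game (each species poisons the next two),
# reference parameter set, low toxin diffusivity, patched start.
model: ca
network:
  cycle: {n: 5, out_degree: 2}
params:
  L: 60
  p0: 0.5
  q0: 0.5
  A: 0.5
  C: 0.5
  beta: 0.7
  gamma_deg: 0.2
  D: 0.001
  relax_iters: 400
init:
  mode: patched
run:
  n_mcs: 500
  record_every: 10
output: runs/rpsls
seed: 1
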