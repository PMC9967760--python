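# Three-species cyclic (rock-paper-scissors) game, continuous model,
# reference parameter set, patched initial condition.
model: pde
network:
  cycle: {n: 3, out_degree: 1}
params:
  r: 0.3
  nu: 0.5
  mu: 0.4
  gamma: 0.1
  beta: 0.5
  delta: 0.1
  d: 0.005
  D: 0.005
  response_kind: 2
grid:
  nx: 96
  ny: 96
  dx: 1.0
  boundary: dirichlet_zero
init:
  mode: patches
  density0: 0.25
run:
  t_end: 600.0
  dt: 0.05
  record_dt: 10.0
output: runs/rps
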