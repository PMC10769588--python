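# Low-dimensional generator task with a quadrature-tractable oracle.
task:
  kind: blob
  generator: {k: 2, fov: 16}
  signal: {amplitude: 0.5, width: 2.0, center: [7.5, 7.5]}
  noise: {kind: real, sigma: 1.5}
observer:
  engine: mcmc
  chain: {n_iterations: 30000, burn_in: 3000, thin: 1000}
study:
  n_per_class: 20
  master_seed: 3
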