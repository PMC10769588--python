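# Lumpy-background SKE/BKS task, conventional MCMC ideal observer.
task:
  kind: lumpy
  lumpy: {mean_lumps: 6.0, lump_amplitude: 1.0, lump_width: 8.0, fov_size: 64}
  prf: {height: 35.0, width: 2.0, fov_size: 64}
  signal: {amplitude: 0.3, width: 2.5, center: [32, 32]}
  noise: {kind: real, sigma: 20.0}
observer:
  engine: mcmc
  chain: {n_iterations: 20000, burn_in: 2000, thin: 2000}
study:
  n_per_class: 200
  master_seed: 7
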