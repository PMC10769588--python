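# iomcmc

Markov-chain Monte Carlo approximation of the **Bayesian ideal observer
(IO)** for signal-known-exactly / background-known-statistically (SKE/BKS)
detection tasks in virtual imaging studies.

## The problem

Task-based assessment of imaging systems scores an observer on a
clinically motivated task — here, detecting a known signal in a random
background.  The IO, which decides with the full likelihood ratio

```
Λ(g) = p(g | H1) / p(g | H0),
```

sets the upper performance bound among all observers and is the preferred
figure of merit for system optimization.  For BKS tasks Λ(g) is an
intractable marginal over background variability, but it can be rewritten
as a posterior expectation of the *background-known-exactly* (BKE)
likelihood ratio,

```
Λ(g) = E[ Λ_BKE(g | b) | g, H0 ],      log Λ_BKE(g | b) = (g − b − s/2)ᵀ s / σ²
```

(the closed form holds for i.i.d. Gaussian noise), and estimated by
averaging Λ_BKE along a Markov chain that samples the background
posterior under the signal-absent hypothesis.

`iomcmc` provides two chain engines:

* **Latent-space chains** (`run_latent_chain`) for *any* generative
  stochastic object model obeying a simple contract: a deterministic map
  from a standard-normal latent vector `z` to a background image
  (`LatentGenerator`; a trained GAN generator fits this contract).
  Proposals follow the preconditioned Crank–Nicolson (pCN) rule
  `z̃ = √(1−β²) z + β ξ`, which preserves the Gaussian latent prior so the
  acceptance probability is a pure likelihood ratio.
* **Lumpy-parameter chains** (`run_lumpy_chain`): the conventional
  reversible-jump sampler specialized to the lumpy background model
  (Poisson-distributed Gaussian lumps at uniform positions), with
  center-perturbation and birth/death moves.

Around the engines: analytic Gaussian-PRF collimator imaging, an
undersampled-k-space MRI operator with a variable-density Poisson-disc
mask, the Hotelling observer via covariance decomposition, closed-form and
brute-force IO oracles for validation, Gelman–Rubin-style PSRF convergence
diagnostics, and ROC/AUC study drivers.

## Worked example

Validate the latent-space engine against an exhaustive quadrature oracle
on a two-dimensional generator (a Gaussian blob whose center is a smooth
bounded function of `z`):

```python
import numpy as np
import iomcmc as m
from iomcmc.evaluation import simulate_measurement

task = m.GeneratorDetectionTask(
    generator=m.make_blob_generator(k=2, fov=16),
    signal=m.evaluate_gaussian_signal(
        m.GaussianSignalSpec(amplitude=0.5, width=2.0, center=(7.5, 7.5)),
        m.pixel_grid(16),
    ),
    noise=m.NoiseModel("real", 1.5),
)
rng = np.random.default_rng(0)
g, z_true = simulate_measurement(task, signal_present=True, rng=rng)

chain = m.run_latent_chain(
    g, task.generator, task.signal_image(), task.noise,
    m.ChainConfig(n_iterations=30_000, burn_in=3_000, seed=1), z0=z_true,
)
log_lr, se = m.estimate_log_lr(chain, return_se=True)
ref, ref_err = m.oracle_quadrature_log_lr(
    g, task.generator, task.signal_image(), task.noise
)
print(f"pCN chain  : log LR = {log_lr:.3f} +/- {se:.3f} "
      f"(acceptance {chain.acceptance_rate:.2f}, beta {chain.beta_final:.3f})")
print(f"quadrature : log LR = {ref:.3f} (refinement error {ref_err:.1e})")
```

prints

```
pCN chain  : log LR = 1.691 +/- 0.007 (acceptance 0.33, beta 0.164)
quadrature : log LR = 1.678 (refinement error 1.5e-05)
```

The chain's Monte-Carlo estimate of the IO test statistic for this
signal-present measurement agrees with the brute-force posterior integral
within its standard error; the pCN step size β was adapted during burn-in
to land in the 20–40% acceptance band.  Running both observers over a
paired study (`run_detection_study`) turns per-image log likelihood
ratios into an ROC curve and a Mann–Whitney AUC.

## Command line

Experiments are driven by YAML configs (task, observer, study blocks; see
`examples/lumpy.yaml` and `examples/blob.yaml`):

```sh
iomcmc simulate --config examples/lumpy.yaml --out data.h5
iomcmc run-mcmc --config examples/lumpy.yaml --dataset data.h5 --out-dir chains/
iomcmc evaluate --config examples/lumpy.yaml --dataset data.h5 --chains-dir chains/ --out-dir results/
iomcmc diagnose --config examples/lumpy.yaml --dataset data.h5 --index 0 --out psrf.json
iomcmc oracle   --config examples/blob.yaml  --dataset data.h5 --out oracle.json
```

Chains are persisted to HDF5 with their full log-Λ_BKE series, acceptance
flags, thinned states, configuration and seed; studies emit per-image
score CSVs and JSON summaries.  All randomness derives from one master
seed, so identical configs reproduce identical files.

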