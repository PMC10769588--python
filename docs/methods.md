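# Methods

## Detection model

A binary SKE/BKS task compares signal-absent and signal-present
measurements

```
H0:  g = b + n,        H1:  g = b + s + n,
```

where `b` is the imaged random background, `s` the imaged deterministic
signal, and `n` i.i.d. Gaussian noise — real with variance σ² per
element, or complex with independent N(0, σ²) real and imaginary
components on sampled k-space locations.  Complex data are handled
everywhere as stacked real/imaginary real vectors, which keeps every
likelihood a standard isotropic Gaussian.

The ideal observer's statistic is the likelihood ratio marginalized over
background variability.  Writing it as the posterior expectation of the
BKE ratio under H0 gives the Monte-Carlo estimator

```
log Λ_BKE(g | b) = (g − b − s/2)ᵀ s / σ²,
Λ(g) ≈ (1/J) Σ_j Λ_BKE(g | b_j),     b_j ~ p(b | g, H0),
```

computed here as a log-mean-exp over all post-burn-in iterations;
rejected proposals repeat the held state's value, as the
Metropolis–Hastings estimator requires.  A batch-means standard error of
the log estimate (50 batches, delta method on the mean of shifted
exponentials) is available; it mildly understates the error when the
chain is strongly autocorrelated, which the validation tests account for.

## Samplers

**Latent-space (pCN) chains.** A generative background model is any
deterministic continuous map `b(z)` with `z ~ N(0, I_k)` — the
`LatentGenerator` contract.  Proposals `z̃ = √(1−β²) z + β ξ` leave the
prior invariant, so the acceptance probability reduces to the ratio of
signal-absent likelihoods, evaluated entirely in the log domain (the
exponents reach ~10³ for σ of order 1 on 64×64 images; nothing in the
chain ever exponentiates an unshifted value).  The step size β is adapted
during burn-in — multiplied by 0.8 (or divided, capped at 1) whenever the
acceptance rate over a 100-iteration window leaves the 20–40% band — and
frozen afterwards; the frozen value is recorded in the chain result.
Fixed-β operation is available by disabling adaptation.

**Lumpy-parameter chains.** The lumpy background is a Poisson(N̄) number
of Gaussian lumps with i.i.d. uniform centers.  The reversible-jump chain
mixes three moves: a symmetric Gaussian perturbation of one uniformly
chosen center (probability 0.8, step w_b/4), a birth at a uniform
position, and a death of a uniformly chosen lump (0.1 each).  With the
exchangeable ordered representation (births insert at a uniform index),
the Hastings factor for a birth from n lumps is N̄/(n+1) — the Poisson
pmf ratio times the uniform position density, cancelled against the
proposal ratio p_death·L²/p_birth — and its reciprocal for a death.  A
death (or center move) drawn with zero lumps auto-rejects, preserving
detailed balance; a center proposed outside the field of view has zero
prior density and is rejected.  With a flat data term the chain
reproduces the Poisson count prior (chi-square-tested).  The background
image is updated incrementally: only the moved/born/dead lump's
analytically imaged field is recomputed per iteration, and the final
maintained background is stored so the incremental path can be audited
against a full recomputation.

**Initialization.** Chains on simulated measurements start from the true
latent vector or true lump configuration.  For measurements without
known truth, a bounded least-squares latent fit under H0 is used, falling
back to a prior draw.

**Defaults.** 200,000 iterations with a 10,000-iteration burn-in — the
long-chain regime; the validation studies in the test suite use 20,000 to
30,000 iterations with proportional burn-in, which the oracle-agreement
checks show is ample for the tasks they run (latent dimensions ≤ 6, the
lumpy task's ~6 lumps).

## Imaging operators

The collimator system is a Gaussian point response function (PRF) of
height h and width w_h on the pixel grid.  Both object models are sums of
Gaussians, so imaging is exact: a lump of amplitude a and width w_b maps
to a Gaussian image of peak `a·h·w_b²/(w_h²+w_b²)` and width
`√(w_h²+w_b²)`; the signal analogously with w_s.  The implementation is
validated against brute-force quadrature convolution to relative L² error
below 10⁻³.  Pixel centers sit at integer coordinates 0..L−1; lump
centers are continuous and never snapped.

The MRI operator is an orthonormal 2D DFT (DC shifted to the array
center) restricted to a k-space mask.  The unitary convention makes noise
statistics unit-unambiguous across domains.  Masks come from a
variable-density Poisson-disc sampler: dart throwing with a local
exclusion radius growing linearly with k-space radius (slope 3), a fully
sampled central calibration disc (default radius 4), and a bisection on
the global radius scale until the sampled fraction is within 2% of the
target 1/acceleration.  Two accepted points outside the calibration disc
are never closer than the smaller of their two radii.  The sampler is the
package's own design; the literature names the pattern but not an
algorithm.

## Reference observers

The Hotelling (optimal linear) observer solves `(K_b + σ²I) w = s` by
Cholesky factorization, with K_b the unbiased sample covariance of
noiseless background images (default 50,000 samples for 64×64 images;
the benchmark uses 20,000).  An upper bound on the condition number
(power-iteration largest eigenvalue over the σ² noise floor) is reported;
a ridge of 10⁻⁶·trace(K_g)/M is added only if it exceeds 10¹⁰.

For the linear-Gaussian fixture generator `b(z) = b0 + A z`, the IO is
available in closed form, `log Λ = (g − b0 − s/2)ᵀ K_g⁻¹ s` with
`K_g = A Aᵀ + σ²I`; its decision variable is affine in `g`, hence
equivalent to the Hotelling observer for this model — the basis of the
closed-form equivalence test.

Two brute-force oracles evaluate the latent posterior integral
independently of any chain: a prior-expectation Monte-Carlo estimator
with shared draws and a jackknife standard error (any k), and a tensor
trapezoid quadrature over [−6, 6]^k with the normal weight, in the log
domain (k ≤ 3; 201 points per axis; the coarse/fine refinement
difference is reported as its error).

## Convergence diagnostics

The potential scale reduction factor is computed across parallel chains
on the scalar the estimator actually averages — the log BKE likelihood
ratio.  The default statistic is the ratio form

```
PSRF = (Nc−1)/Nc + B/(Nc·W),
```

with W the mean per-chain unbiased variance and B the scaled
between-chain variance.  This form is the *square* of the conventional
Gelman–Rubin statistic and, when B ≈ 0 (e.g. identical chains), falls
slightly below one at (Nc−1)/Nc; the square-root and split-chain variants
are available behind flags.  Convergence is flagged below 1.01.  A
normalized autocorrelation utility complements it.

## Study driver and figures of merit

`run_detection_study` simulates paired H0/H1 measurement sets (defaults:
200 per class) with per-image seeds derived from one master seed via seed
sequences, scores each with the configured observer, and reports the
empirical ROC (all thresholds, ties grouped), the Mann–Whitney AUC (ties
half-credit) and the Hanley–McNeil standard error.  An observer failure
on an image is recorded and the study continues.  No parametric ROC
model is fitted; the empirical AUC is the figure of merit throughout.
A radially averaged power spectrum utility supports second-order
comparison of image ensembles (e.g. real versus generated backgrounds).

## Synthetic fixtures and what the tests show

No external data are used; all inputs are simulated.  The lumpy task uses
the full study conditions (Poisson mean 6, a=1, w_b=8, 64×64; PRF h=35,
w_h=2; signal a_s=0.3, w_s=2.5 centered; σ=20).  Trained generative
models are *not* built here; the latent-generator contract is exercised
by two analytic stand-ins:

* a linear-Gaussian generator (smooth random mixing columns on a 16×16
  grid), for which the exact IO is known; and
* a k≤3 "blob" generator — a Gaussian blob whose center (and optionally
  log-width) are bounded smooth functions of the latent vector
  (amplitude 3, width 3 px, center range ±4 px via tanh, σ=1.5 in the
  study conditions) — chosen once so the latent posterior is broad enough
  for the quadrature oracle to converge while the task remains
  non-trivial.

Passing oracle- and closed-form-equivalence tests therefore demonstrates
that the pCN machinery targets the right posterior and estimator for any
contract-conforming generator; they do not certify that a particular
trained generator matches a real object distribution, which is a
property of the generator, not of this sampler.

On the lumpy benchmark, a well-converged Hotelling observer (20,000+
covariance samples, large test sets) attains AUC ≈ 0.785–0.79, matching
a circulant-approximation closed-form calculation; single 200+200
studies scatter around this with SE ≈ 0.023, which is why the benchmark
script averages five independent replications of the 200+200 protocol.
The MCMC ideal observer on the same task reaches AUC ≈ 0.84, the
expected ordering (the IO bounds the linear observer from above).

## Numerical choices and limitations

* All acceptance computations and likelihood-ratio averages are in the
  log domain; `-inf` log-ratios are tolerated anywhere except an entire
  chain of them.
* Degenerate inputs fail loudly: empty measurement sets, singleton
  covariance ensembles, all-constant chain ensembles (W = 0), latent
  dimension > 3 for quadrature, infeasible mask targets.
* HDF5 outputs disable timestamp tracking so identical seeds yield
  byte-identical files.
* Out of scope: training generative models; channelized or CNN
  observers; multi-coil/non-Cartesian MRI and reconstruction; 3D
  objects; gradient-based samplers (MALA/HMC) — the engine records what
  a gradient-aware proposal would need, but only pCN is implemented.
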