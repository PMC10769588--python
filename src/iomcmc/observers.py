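"""Reference observers and likelihood-ratio oracles.

These comparators bracket the MCMC ideal-observer estimates:

* the **Hotelling observer** (HO), the optimal linear observer, built by
  covariance decomposition ``Kg = Kb + sigma^2 I`` with the background
  covariance ``Kb`` estimated from an ensemble of noiseless background
  images;
* the **closed-form ideal observer** for the linear-Gaussian fixture
  generator, where the background distribution is exactly Gaussian;
* **brute-force oracles** for the latent posterior integral: a
  prior-expectation Monte-Carlo estimator (any latent dimension, with a
  jackknife standard error) and a tensor-grid quadrature (latent
  dimension at most three, with a refinement error estimate).

Complex (k-space) data are handled throughout as stacked real/imaginary
real vectors, consistent with the i.i.d. Gaussian noise model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import logsumexp
from scipy.stats import norm

from .imaging import NoiseModel
from .mcmc import _as_real
from .som_models import LatentGenerator

__all__ = [
    "HotellingTemplate",
    "estimate_background_covariance",
    "hotelling_template",
    "hotelling_score",
    "analytic_gaussian_io_log_lr",
    "oracle_prior_mc_log_lr",
    "oracle_quadrature_log_lr",
]


@dataclass
class HotellingTemplate:
    """Hotelling template ``w`` with a conditioning report.

    ``cond_estimate`` is an upper bound on the condition number of
    ``Kb + sigma^2 I`` (largest eigenvalue by power iteration; the noise
    floor bounds the smallest); ``ridge`` records any diagonal loading
    that was applied, and ``residual`` the relative solve residual.
    """

    w: np.ndarray
    cond_estimate: float
    ridge: float
    residual: float

    def score(self, g: np.ndarray) -> float:
        return hotelling_score(self.w, g)


def estimate_background_covariance(samples: np.ndarray) -> np.ndarray:
    """Unbiased sample covariance of a noiseless background-image ensemble.

    ``samples`` is ``(n, M)`` with ``n >= 2``.  Accumulated in chunks so
    the centered design matrix never has to be materialized in one piece.
    """
    samples = np.asarray(samples)
    if samples.ndim != 2 or samples.shape[0] < 2:
        raise ValueError("need a 2D array of at least two samples")
    n, m = samples.shape
    mean = samples.mean(axis=0)
    cov = np.zeros((m, m))
    chunk = max(1, int(2e8 // (8 * m)))
    for start in range(0, n, chunk):
        x = samples[start : start + chunk] - mean
        cov += x.T @ x
    cov /= n - 1
    return cov


def _power_iteration_lmax(mat: np.ndarray, iters: int = 30, seed: int = 0) -> float:
    rng = np.random.default_rng(seed)
    v = rng.standard_normal(mat.shape[0])
    v /= np.linalg.norm(v)
    lam = 0.0
    for _ in range(iters):
        w = mat @ v
        lam = float(np.linalg.norm(w))
        if lam == 0.0:
            return 0.0
        v = w / lam
    return lam


def hotelling_template(
    Kb: np.ndarray,
    noise: NoiseModel,
    s: np.ndarray,
    cond_threshold: float = 1e10,
) -> HotellingTemplate:
    """Solve ``(Kb + sigma^2 I) w = s`` for the Hotelling template.

    Solved by Cholesky factorization (no explicit inverse).  If the
    estimated condition number exceeds ``cond_threshold`` a ridge of
    ``1e-6 * trace(Kg) / M`` is added and reported.
    """
    Kb = np.asarray(Kb)
    s_r = _as_real(s)
    m = s_r.size
    if Kb.shape != (m, m):
        raise ValueError(f"Kb shape {Kb.shape} does not match signal length {m}")
    sigma2 = noise.sigma**2
    lmax = _power_iteration_lmax(Kb)
    cond = (lmax + sigma2) / sigma2  # Kb is PSD, so the noise floor bounds below
    ridge = 0.0
    if cond > cond_threshold:
        ridge = 1e-6 * (np.trace(Kb) + m * sigma2) / m
    Kg = Kb + (sigma2 + ridge) * np.eye(m)
    w = cho_solve(cho_factor(Kg, lower=True), s_r)
    residual = float(np.linalg.norm(Kg @ w - s_r) / np.linalg.norm(s_r))
    return HotellingTemplate(w=w, cond_estimate=cond, ridge=ridge, residual=residual)


def hotelling_score(w: np.ndarray, g: np.ndarray) -> float:
    """Linear test statistic ``t = w^T g`` (stacked real components)."""
    w_r = _as_real(w)
    g_r = _as_real(g)
    if w_r.shape != g_r.shape:
        raise ValueError("template and measurement shapes differ")
    return float(w_r @ g_r)


def analytic_gaussian_io_log_lr(
    g: np.ndarray,
    mean_image: np.ndarray,
    mixing: np.ndarray,
    s: np.ndarray,
    noise: NoiseModel,
) -> float:
    """Closed-form IO log likelihood ratio for a Gaussian background.

    With background ``b ~ N(b0, A A^T)`` and i.i.d. Gaussian noise the
    marginal data distribution under each hypothesis is Gaussian with
    covariance ``Kg = A A^T + sigma^2 I``, and

        log Lambda = (g - b0 - s/2)^T Kg^{-1} s .

    The decision variable is affine in ``g``, so the IO and the Hotelling
    observer are equivalent for this generator.  ``mixing = 0`` recovers
    the BKE log likelihood ratio with ``b = b0``.
    """
    g_r = _as_real(g)
    b0 = _as_real(mean_image)
    s_r = _as_real(s)
    A = np.asarray(mixing, dtype=float)
    m = g_r.size
    Kg = A @ A.T + noise.sigma**2 * np.eye(m)
    x = cho_solve(cho_factor(Kg, lower=True), s_r)
    return float((g_r - b0 - 0.5 * s_r) @ x)


def _batch_log_likelihoods(
    g: np.ndarray,
    generator: LatentGenerator,
    s: np.ndarray,
    noise: NoiseModel,
    Z: np.ndarray,
    imaging_op: Optional[Callable[[np.ndarray], np.ndarray]],
) -> tuple[np.ndarray, np.ndarray]:
    """H0 and H1 log likelihoods of ``g`` for a batch of latent vectors.

    Evaluated in chunks so arbitrarily large batches never materialize
    the full ``(n, N)`` background array.
    """
    g_r = _as_real(g)
    s_r = _as_real(s)
    sigma2 = noise.sigma**2
    n = Z.shape[0]
    ll0 = np.empty(n)
    ll1 = np.empty(n)
    chunk = max(1, int(2e8 // (8 * max(g_r.size, 1))))
    for start in range(0, n, chunk):
        B = generator.batch(Z[start : start + chunk])
        if imaging_op is not None:
            B = np.stack([_as_real(imaging_op(b)) for b in B])
        elif np.iscomplexobj(np.asarray(g)):
            B = np.stack([_as_real(b) for b in B])
        d0 = g_r[None, :] - B
        ll0[start : start + chunk] = -np.einsum("ij,ij->i", d0, d0) / (2.0 * sigma2)
        d1 = d0 - s_r[None, :]
        ll1[start : start + chunk] = -np.einsum("ij,ij->i", d1, d1) / (2.0 * sigma2)
    return ll0, ll1


def oracle_prior_mc_log_lr(
    g: np.ndarray,
    generator: LatentGenerator,
    s: np.ndarray,
    noise: NoiseModel,
    n_samples: int = 100_000,
    rng: Optional[np.random.Generator] = None,
    imaging_op: Optional[Callable[[np.ndarray], np.ndarray]] = None,
) -> tuple[float, float]:
    """Prior-expectation Monte-Carlo oracle for the IO log likelihood ratio.

    Writes the posterior-expectation form of the likelihood ratio as a
    ratio of prior expectations,

        Lambda(g) = E_z[p(g | b(z), H1)] / E_z[p(g | b(z), H0)] ,

    and estimates both expectations with *shared* standard-normal draws
    (log-mean-exp).  Returns ``(log Lambda, jackknife SE)``; the
    leave-one-out estimates reuse the two log-sum-exp totals.
    """
    rng = np.random.default_rng() if rng is None else rng
    Z = rng.standard_normal((n_samples, generator.latent_dim))
    ll0, ll1 = _batch_log_likelihoods(g, generator, s, noise, Z, imaging_op)

    def _lse_loo(ll: np.ndarray) -> tuple[float, np.ndarray]:
        m = ll.max()
        e = np.exp(ll - m)
        total = e.sum()
        with np.errstate(divide="ignore"):
            loo = m + np.log(np.maximum(total - e, 0.0))
        return m + np.log(total), loo

    lse1, loo1 = _lse_loo(ll1)
    lse0, loo0 = _lse_loo(ll0)
    val = float(lse1 - lse0)
    loo_vals = loo1 - loo0  # the log(n-1) terms cancel in the difference
    mean_loo = loo_vals.mean()
    se = float(
        np.sqrt((n_samples - 1) / n_samples * ((loo_vals - mean_loo) ** 2).sum())
    )
    return val, se


def _quadrature_value(
    g: np.ndarray,
    generator: LatentGenerator,
    s: np.ndarray,
    noise: NoiseModel,
    grid_range: float,
    grid_points: int,
    imaging_op: Optional[Callable[[np.ndarray], np.ndarray]],
) -> float:
    x = np.linspace(-grid_range, grid_range, grid_points)
    logw1 = norm.logpdf(x) + np.log(x[1] - x[0])
    axes = [x] * generator.latent_dim
    Z = np.stack(
        [a.ravel() for a in np.meshgrid(*axes, indexing="ij")], axis=-1
    )
    logw = np.add.reduce(
        np.meshgrid(*([logw1] * generator.latent_dim), indexing="ij")
    ).ravel()
    ll0, ll1 = _batch_log_likelihoods(g, generator, s, noise, Z, imaging_op)
    return float(logsumexp(logw + ll1) - logsumexp(logw + ll0))


def oracle_quadrature_log_lr(
    g: np.ndarray,
    generator: LatentGenerator,
    s: np.ndarray,
    noise: NoiseModel,
    grid_range: float = 6.0,
    grid_points: int = 201,
    imaging_op: Optional[Callable[[np.ndarray], np.ndarray]] = None,
) -> tuple[float, float]:
    """Tensor-grid quadrature oracle for latent dimension at most three.

    Evaluates both prior expectations on a uniform tensor grid over
    ``[-grid_range, grid_range]^k`` weighted by the standard-normal
    density, entirely in the log domain.  Returns the value at the finer
    of two nested grids together with the refinement difference as an
    error estimate.
    """
    if generator.latent_dim > 3:
        raise ValueError("quadrature oracle requires latent_dim <= 3")
    coarse = _quadrature_value(
        g, generator, s, noise, grid_range, max(grid_points // 2, 11), imaging_op
    )
    fine = _quadrature_value(
        g, generator, s, noise, grid_range, grid_points, imaging_op
    )
    return fine, abs(fine - coarse)
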