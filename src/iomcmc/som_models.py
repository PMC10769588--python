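"""Stochastic object models for SKE/BKS detection tasks.

This module provides the two object-model ingredients of a
signal-known-exactly / background-known-statistically (SKE/BKS) detection
task:

* a **lumpy background** model -- a Poisson-distributed number of Gaussian
  "lumps" at positions uniform over the field of view, the canonical
  stochastic background of task-based image-quality studies; and
* a deterministic **Gaussian signal**.

It also defines the :class:`LatentGenerator` contract through which any
generative stochastic object model (for example a trained GAN generator)
can be plugged into the latent-space MCMC engine: a deterministic,
continuous map from a ``k``-dimensional standard-normal latent vector to an
``N``-dimensional object or image vector.  Two analytic fixture generators
are included -- a linear-Gaussian generator (for which the ideal observer
has a closed form) and a low-dimensional nonlinear "blob" generator (for
which the latent posterior integral can be evaluated by quadrature).

Coordinate convention: pixel centers sit at integer coordinates
``0 .. L-1`` on each axis, so a 64x64 field of view spans ``[0, 64)^2``
and the grid center is at ``(32, 32)``.  Lump centers are continuous and
are never snapped to the grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal, Optional

import numpy as np

__all__ = [
    "LumpyModelSpec",
    "LumpyParams",
    "GaussianSignalSpec",
    "LatentGenerator",
    "pixel_grid",
    "sample_lumpy_params",
    "evaluate_lumpy_object",
    "evaluate_gaussian_signal",
    "make_linear_gaussian_generator",
    "make_blob_generator",
    "make_constant_generator",
]


def pixel_grid(fov_size: int) -> np.ndarray:
    """Return the ``(L*L, 2)`` array of pixel-center coordinates.

    Row-major ordering: the pixel at grid indices ``(i, j)`` maps to flat
    index ``i * L + j`` and has coordinates ``(i, j)``.
    """
    x = np.arange(fov_size, dtype=float)
    xx, yy = np.meshgrid(x, x, indexing="ij")
    return np.stack([xx.ravel(), yy.ravel()], axis=-1)


@dataclass(frozen=True)
class LumpyModelSpec:
    """Parameters of the lumpy background object model.

    Attributes
    ----------
    mean_lumps:
        Expected number of lumps (Poisson mean), dimensionless.
    lump_amplitude:
        Peak value of a single lump, object units.
    lump_width:
        Gaussian width of a lump, pixels.
    fov_size:
        Pixels per side of the square field of view.
    """

    mean_lumps: float = 6.0
    lump_amplitude: float = 1.0
    lump_width: float = 8.0
    fov_size: int = 64

    def __post_init__(self) -> None:
        if self.mean_lumps <= 0:
            raise ValueError("mean_lumps must be positive")
        if self.lump_width <= 0:
            raise ValueError("lump_width must be positive")
        if self.fov_size <= 0:
            raise ValueError("fov_size must be positive")


@dataclass
class LumpyParams:
    """One realization of the lumpy model: the lump centers.

    ``centers`` has shape ``(n_lumps, 2)``; a zero-lump realization is a
    valid draw and is represented by an empty ``(0, 2)`` array.
    """

    centers: np.ndarray

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        if self.centers.size == 0:
            self.centers = np.empty((0, 2))
        if self.centers.ndim != 2 or self.centers.shape[1] != 2:
            raise ValueError("centers must have shape (n_lumps, 2)")

    @property
    def n_lumps(self) -> int:
        return self.centers.shape[0]

    def copy(self) -> "LumpyParams":
        return LumpyParams(self.centers.copy())


@dataclass(frozen=True)
class GaussianSignalSpec:
    """Deterministic 2D Gaussian signal: amplitude, width and center."""

    amplitude: float = 0.3
    width: float = 2.5
    center: tuple[float, float] = (32.0, 32.0)

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be positive")


def sample_lumpy_params(spec: LumpyModelSpec, rng: np.random.Generator) -> LumpyParams:
    """Draw one lumpy realization from the prior.

    The lump count is Poisson(``mean_lumps``) and each center is i.i.d.
    uniform over ``[0, L)^2``.
    """
    n = int(rng.poisson(spec.mean_lumps))
    centers = rng.uniform(0.0, spec.fov_size, size=(n, 2))
    return LumpyParams(centers)


def evaluate_lumpy_object(
    params: LumpyParams, spec: LumpyModelSpec, grid: np.ndarray
) -> np.ndarray:
    """Evaluate the lumpy object on a set of 2D points.

    The object is a sum of isotropic Gaussians,
    ``f(r) = sum_n a * exp(-|r - r_n|^2 / (2 w_b^2))``.

    Parameters
    ----------
    grid:
        ``(P, 2)`` array of evaluation points.

    Returns
    -------
    ``(P,)`` array of object values.
    """
    grid = np.atleast_2d(np.asarray(grid, dtype=float))
    out = np.zeros(grid.shape[0])
    if params.n_lumps == 0:
        return out
    d2 = ((grid[:, None, :] - params.centers[None, :, :]) ** 2).sum(axis=-1)
    out = spec.lump_amplitude * np.exp(-d2 / (2.0 * spec.lump_width**2)).sum(axis=1)
    return out


def evaluate_gaussian_signal(spec: GaussianSignalSpec, grid: np.ndarray) -> np.ndarray:
    """Evaluate the Gaussian signal object on a set of 2D points."""
    grid = np.atleast_2d(np.asarray(grid, dtype=float))
    d2 = ((grid - np.asarray(spec.center)) ** 2).sum(axis=-1)
    return spec.amplitude * np.exp(-d2 / (2.0 * spec.width**2))


@dataclass
class LatentGenerator:
    """Contract for a generative stochastic object model.

    A deterministic, continuous map from a ``latent_dim``-vector ``z``
    (drawn, under the prior, from a standard normal) to a flat image or
    object vector of fixed length.  ``output_domain`` records whether the
    map produces noiseless *image data* (the measurement-domain path, no
    further imaging operator needed) or an *object* (to be pushed through
    an imaging operator before comparison with measurements).

    Calling the generator with a ``(k,)`` vector returns an ``(N,)``
    vector; calling it with a ``(n, k)`` batch returns ``(n, N)``.
    """

    latent_dim: int
    output_size: int
    fn: Callable[[np.ndarray], np.ndarray]
    output_domain: Literal["image", "object"] = "image"
    output_shape: Optional[tuple[int, int]] = None
    batch_fn: Optional[Callable[[np.ndarray], np.ndarray]] = field(
        default=None, repr=False
    )

    def __call__(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        if z.ndim == 1:
            if z.shape[0] != self.latent_dim:
                raise ValueError(
                    f"latent vector has length {z.shape[0]}, expected {self.latent_dim}"
                )
            return self.fn(z)
        return self.batch(z)

    def batch(self, Z: np.ndarray) -> np.ndarray:
        """Evaluate on a ``(n, k)`` batch of latent vectors."""
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        if Z.shape[1] != self.latent_dim:
            raise ValueError(
                f"latent batch has width {Z.shape[1]}, expected {self.latent_dim}"
            )
        if self.batch_fn is not None:
            return self.batch_fn(Z)
        return np.stack([self.fn(z) for z in Z])

    def sample_prior(
        self, rng: np.random.Generator
    ) -> tuple[np.ndarray, np.ndarray]:
        """Draw ``z ~ N(0, I)`` and return ``(z, output)``.

        The returned latent is the *true latent* of the sample; chains run
        on measurements simulated from this sample can be initialized at
        it.
        """
        z = rng.standard_normal(self.latent_dim)
        return z, self.fn(z)


def make_linear_gaussian_generator(
    mean_image: np.ndarray,
    mixing: np.ndarray,
    output_domain: Literal["image", "object"] = "image",
) -> LatentGenerator:
    """Linear-Gaussian fixture generator: ``b(z) = mean_image + mixing @ z``.

    The induced background distribution is Gaussian with mean
    ``mean_image`` and covariance ``mixing @ mixing.T``, for which the
    ideal observer is available in closed form
    (:func:`iomcmc.observers.analytic_gaussian_io_log_lr`).  A warning is
    emitted if ``mixing`` is rank deficient; the closed-form observer
    remains valid in that case.
    """
    mean_image = np.asarray(mean_image, dtype=float).ravel()
    mixing = np.asarray(mixing, dtype=float)
    if mixing.ndim != 2 or mixing.shape[0] != mean_image.size:
        raise ValueError("mixing must be (N, k) with N matching mean_image")
    if np.linalg.matrix_rank(mixing) < mixing.shape[1]:
        warnings.warn("mixing matrix is rank deficient", stacklevel=2)

    def fn(z: np.ndarray) -> np.ndarray:
        return mean_image + mixing @ z

    def batch_fn(Z: np.ndarray) -> np.ndarray:
        return mean_image[None, :] + Z @ mixing.T

    return LatentGenerator(
        latent_dim=mixing.shape[1],
        output_size=mean_image.size,
        fn=fn,
        batch_fn=batch_fn,
        output_domain=output_domain,
    )


def make_blob_generator(
    k: int = 2,
    fov: int = 16,
    amplitude: float = 3.0,
    width: float = 3.0,
    center_range: float = 4.0,
    log_width_range: float = 0.4,
) -> LatentGenerator:
    """Low-dimensional nonlinear fixture generator.

    Produces a single Gaussian blob on an ``fov x fov`` grid whose center
    (and, for ``k = 3``, log-width) are bounded smooth functions of the
    latent vector:

    * center = grid center + ``center_range * tanh(z[0:2])``,
    * log-width offset = ``log_width_range * tanh(z[2])`` (k = 3 only).

    The map is continuous and bounded, and the output is strictly
    positive, so with ``k <= 3`` the latent posterior integral can be
    evaluated to high accuracy on a tensor quadrature grid -- this is the
    oracle fixture for validating the latent-space MCMC engine.
    """
    if k not in (2, 3):
        raise ValueError("blob generator supports k = 2 or 3")
    x = np.arange(fov, dtype=float)
    c0 = (fov - 1) / 2.0

    def fn(z: np.ndarray) -> np.ndarray:
        cx = c0 + center_range * np.tanh(z[0])
        cy = c0 + center_range * np.tanh(z[1])
        w = width * (np.exp(log_width_range * np.tanh(z[2])) if k == 3 else 1.0)
        ex = np.exp(-((x - cx) ** 2) / (2.0 * w**2))
        ey = np.exp(-((x - cy) ** 2) / (2.0 * w**2))
        return amplitude * np.outer(ex, ey).ravel()

    def batch_fn(Z: np.ndarray) -> np.ndarray:
        cx = c0 + center_range * np.tanh(Z[:, 0])
        cy = c0 + center_range * np.tanh(Z[:, 1])
        if k == 3:
            w = width * np.exp(log_width_range * np.tanh(Z[:, 2]))
        else:
            w = np.full(Z.shape[0], width)
        ex = np.exp(-((x[None, :] - cx[:, None]) ** 2) / (2.0 * w[:, None] ** 2))
        ey = np.exp(-((x[None, :] - cy[:, None]) ** 2) / (2.0 * w[:, None] ** 2))
        return amplitude * (ex[:, :, None] * ey[:, None, :]).reshape(Z.shape[0], -1)

    return LatentGenerator(
        latent_dim=k,
        output_size=fov * fov,
        fn=fn,
        batch_fn=batch_fn,
        output_domain="image",
        output_shape=(fov, fov),
    )


def make_constant_generator(image: np.ndarray, latent_dim: int = 2) -> LatentGenerator:
    """Generator that ignores its latent input (constant likelihood).

    With a constant output the MCMC acceptance ratio is identically one,
    so the pCN chain must sample the standard-normal latent prior -- a
    sharp sanity check of the proposal mechanics.
    """
    image = np.asarray(image, dtype=float).ravel().copy()

    def fn(z: np.ndarray) -> np.ndarray:
        return image

    def batch_fn(Z: np.ndarray) -> np.ndarray:
        return np.broadcast_to(image, (Z.shape[0], image.size)).copy()

    return LatentGenerator(
        latent_dim=latent_dim,
        output_size=image.size,
        fn=fn,
        batch_fn=batch_fn,
        output_domain="image",
    )
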