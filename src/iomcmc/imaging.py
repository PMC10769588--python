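"""Virtual imaging operators and noise models.

Two stylized imaging systems are provided:

* an idealized parallel-hole collimator described by a Gaussian point
  response function (PRF).  Because both the lumpy objects and the signal
  are sums of Gaussians, the continuous-to-discrete imaging integral has
  an exact closed form: the convolution of a Gaussian of width ``w`` with
  the PRF of height ``h`` and width ``w_h`` is a Gaussian of width
  ``sqrt(w^2 + w_h^2)`` and peak ``a * h * w^2 / (w^2 + w_h^2)``;
* a stylized undersampled-MRI system: unitary 2D DFT followed by
  restriction to a variable-density Poisson-disc k-space sampling mask,
  with i.i.d. complex Gaussian noise.

Measurement noise is i.i.d. Gaussian in both cases -- real for the
collimator system, independent real/imaginary components for k-space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np

from .som_models import (
    GaussianSignalSpec,
    LumpyModelSpec,
    LumpyParams,
    sample_lumpy_params,
)

__all__ = [
    "GaussianPRFSpec",
    "NoiseModel",
    "KSpaceMask",
    "image_lumpy_background",
    "image_single_lump",
    "image_gaussian_signal",
    "sample_lumpy_background_images",
    "generate_poisson_disc_mask",
    "mri_forward",
    "add_noise",
    "psnr",
]


@dataclass(frozen=True)
class GaussianPRFSpec:
    """Gaussian point response function of the collimator system.

    ``height`` is the PRF sensitivity ``h`` and ``width`` its Gaussian
    width ``w_h`` in pixels.  The detector grid coincides with the pixel
    grid of the object field of view (``fov_size`` per side).
    """

    height: float = 35.0
    width: float = 2.0
    fov_size: int = 64

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise ValueError("height must be positive")
        if self.width <= 0:
            raise ValueError("width must be positive")


@dataclass(frozen=True)
class NoiseModel:
    """I.i.d. Gaussian measurement noise.

    ``kind="real"`` adds ``N(0, sigma^2)`` to every element; with
    ``kind="complex"`` independent ``N(0, sigma^2)`` noise is added to the
    real and imaginary part of every sampled k-space location.  ``sigma``
    is the standard deviation per (real) component in measurement units.
    """

    kind: Literal["real", "complex"] = "real"
    sigma: float = 20.0

    def __post_init__(self) -> None:
        if self.kind not in ("real", "complex"):
            raise ValueError("kind must be 'real' or 'complex'")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


def _separable_gaussian_image(
    center: np.ndarray, peak: float, width: float, fov_size: int
) -> np.ndarray:
    # Isotropic Gaussian factorizes over axes; two length-L exponentials
    # and one outer product instead of an L^2 exponential evaluation.
    x = np.arange(fov_size, dtype=float)
    ex = np.exp(-((x - center[0]) ** 2) / (2.0 * width**2))
    ey = np.exp(-((x - center[1]) ** 2) / (2.0 * width**2))
    return peak * np.outer(ex, ey)


def image_single_lump(
    center: np.ndarray, lumpy: LumpyModelSpec, prf: GaussianPRFSpec
) -> np.ndarray:
    """Noiseless image of one lump at ``center``: ``(L, L)`` array.

    Exact Gaussian-Gaussian convolution: peak
    ``a h w_b^2 / (w_h^2 + w_b^2)`` and width ``sqrt(w_h^2 + w_b^2)``.
    """
    w2 = prf.width**2 + lumpy.lump_width**2
    peak = lumpy.lump_amplitude * prf.height * lumpy.lump_width**2 / w2
    return _separable_gaussian_image(np.asarray(center, float), peak, np.sqrt(w2), prf.fov_size)


def image_lumpy_background(
    params: LumpyParams, lumpy: LumpyModelSpec, prf: GaussianPRFSpec
) -> np.ndarray:
    """Noiseless background image ``b`` of a lumpy realization, flat ``(M,)``."""
    out = np.zeros((prf.fov_size, prf.fov_size))
    for center in params.centers:
        out += image_single_lump(center, lumpy, prf)
    return out.ravel()


def image_gaussian_signal(
    signal: GaussianSignalSpec, prf: GaussianPRFSpec
) -> np.ndarray:
    """Noiseless signal image ``s``, flat ``(M,)``.

    Exact convolution of the Gaussian signal with the Gaussian PRF: peak
    ``a_s h w_s^2 / (w_h^2 + w_s^2)`` and width ``sqrt(w_h^2 + w_s^2)``.
    """
    w2 = prf.width**2 + signal.width**2
    peak = signal.amplitude * prf.height * signal.width**2 / w2
    return _separable_gaussian_image(
        np.asarray(signal.center, float), peak, np.sqrt(w2), prf.fov_size
    ).ravel()


def sample_lumpy_background_images(
    lumpy: LumpyModelSpec,
    prf: GaussianPRFSpec,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample ``n`` noiseless background images; returns ``(n, M)``.

    Used to build covariance estimates for the Hotelling observer and as
    the "real" ensemble in power-spectrum comparisons.
    """
    out = np.empty((n, prf.fov_size * prf.fov_size))
    for i in range(n):
        out[i] = image_lumpy_background(sample_lumpy_params(lumpy, rng), lumpy, prf)
    return out


@dataclass
class KSpaceMask:
    """Boolean k-space sampling pattern with DC at the array center.

    ``mask[i, j]`` is True where k-space is sampled.  ``acceleration`` is
    the target inverse sampling fraction; ``calibration_radius`` is the
    radius (k-space pixels) of the fully sampled central disc.
    """

    mask: np.ndarray
    acceleration: float
    calibration_radius: float
    seed: int | None = None
    radius_scale: float | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def n_sampled(self) -> int:
        return int(self.mask.sum())

    @property
    def sampled_fraction(self) -> float:
        return self.n_sampled / self.mask.size


def _poisson_disc_throw(
    shape: tuple[int, int],
    calibration_radius: float,
    scale: float,
    radius_slope: float,
    order: np.ndarray,
) -> np.ndarray:
    """Dart throwing at a fixed radius scale; returns the boolean mask.

    The local exclusion radius grows linearly with normalized k-space
    radius ``rho``: ``r(rho) = scale * (1 + radius_slope * rho)``.  A pair
    of accepted points (both outside the calibration disc) is admissible
    when their distance is at least the smaller of their two radii.
    """
    ny, nx = shape
    cy, cx = ny // 2, nx // 2
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    rho = np.hypot(yy - cy, xx - cx)
    rho_max = rho.max()

    mask = rho <= calibration_radius
    radii = scale * (1.0 + radius_slope * rho / rho_max)

    acc_pts: list[np.ndarray] = []
    acc_r: list[float] = []
    pts = np.stack([yy.ravel(), xx.ravel()], axis=1)[order]
    for p in pts:
        r_local = radii[p[0], p[1]]
        if rho[p[0], p[1]] <= calibration_radius:
            continue
        if acc_pts:
            d = np.hypot(*(np.array(acc_pts) - p).T)
            if np.any(d < np.minimum(acc_r, r_local)):
                continue
        acc_pts.append(p)
        acc_r.append(r_local)
        mask[p[0], p[1]] = True
    return mask


def generate_poisson_disc_mask(
    shape: tuple[int, int] | int,
    acceleration: float,
    calibration_radius: float = 4.0,
    rng: np.random.Generator | None = None,
    radius_slope: float = 3.0,
    tol: float = 0.02,
    max_bisect: int = 40,
) -> KSpaceMask:
    """Variable-density Poisson-disc k-space sampling mask.

    Dart throwing with a local exclusion radius that grows linearly with
    k-space radius (denser sampling near DC), a fully sampled calibration
    disc at the center, and a bisection on the global radius scale so the
    sampled fraction lands within ``tol`` (relative) of
    ``1 / acceleration``.

    Raises
    ------
    ValueError
        If ``acceleration <= 1`` or no radius scale in the search bracket
        achieves the target fraction.
    """
    if acceleration <= 1:
        if acceleration == 1:
            shape = (shape, shape) if np.isscalar(shape) else tuple(shape)
            return KSpaceMask(np.ones(shape, bool), 1.0, calibration_radius)
        raise ValueError("acceleration must be >= 1")
    if np.isscalar(shape):
        shape = (int(shape), int(shape))
    rng = np.random.default_rng() if rng is None else rng
    seed = int(rng.integers(0, 2**31 - 1))
    order = np.random.default_rng(seed).permutation(shape[0] * shape[1])
    target = 1.0 / acceleration

    def frac(scale: float) -> tuple[float, np.ndarray]:
        m = _poisson_disc_throw(shape, calibration_radius, scale, radius_slope, order)
        return m.mean(), m

    lo, hi = 0.25, 32.0
    f_lo, m_lo = frac(lo)
    f_hi, m_hi = frac(hi)
    if not (f_hi <= target <= f_lo):
        raise ValueError(
            f"cannot reach sampling fraction {target:.4f} with radius scales in "
            f"[{lo}, {hi}] (achievable range [{f_hi:.4f}, {f_lo:.4f}])"
        )
    best_scale, best_m, best_f = lo, m_lo, f_lo
    for _ in range(max_bisect):
        mid = 0.5 * (lo + hi)
        f_mid, m_mid = frac(mid)
        if abs(f_mid - target) < abs(best_f - target):
            best_scale, best_m, best_f = mid, m_mid, f_mid
        if abs(f_mid / target - 1.0) <= tol:
            break
        if f_mid > target:
            lo = mid
        else:
            hi = mid
    return KSpaceMask(
        best_m, acceleration, calibration_radius, seed=seed, radius_scale=best_scale
    )


def mri_forward(obj: np.ndarray, mask: KSpaceMask) -> np.ndarray:
    """Noiseless k-space measurement: unitary 2D DFT then mask restriction.

    The DFT uses orthonormal scaling (``norm="ortho"``) and is shifted so
    DC sits at the array center, matching the mask convention.  Returns
    the complex vector of sampled k-space values, in row-major mask order.
    """
    obj = np.asarray(obj)
    if obj.ndim == 1:
        side = int(round(np.sqrt(obj.size)))
        if side * side != obj.size:
            raise ValueError("flat object length is not a perfect square")
        obj = obj.reshape(side, side)
    if obj.shape != mask.shape:
        raise ValueError(f"object shape {obj.shape} does not match mask {mask.shape}")
    F = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(obj), norm="ortho"))
    return F[mask.mask]


def add_noise(
    noiseless: np.ndarray, noise: NoiseModel, rng: np.random.Generator
) -> np.ndarray:
    """Add i.i.d. Gaussian noise to a noiseless measurement."""
    noiseless = np.asarray(noiseless)
    if noise.kind == "real":
        if np.iscomplexobj(noiseless):
            raise ValueError("real noise model applied to complex data")
        return noiseless + rng.normal(0.0, noise.sigma, noiseless.shape)
    if not np.iscomplexobj(noiseless):
        raise ValueError("complex noise model applied to real data")
    n = rng.normal(0.0, noise.sigma, noiseless.shape + (2,))
    return noiseless + n[..., 0] + 1j * n[..., 1]


def psnr(measurements: Iterable[np.ndarray] | np.ndarray, sigma: float) -> float:
    """Peak signal-to-noise ratio over a measurement set, in dB.

    ``PSNR = 20 log10(MAX / sigma)`` where ``MAX`` is the largest modulus
    over the whole evaluation set.
    """
    arrs = [np.asarray(m) for m in measurements] if not isinstance(
        measurements, np.ndarray
    ) else [measurements]
    if not arrs or all(a.size == 0 for a in arrs):
        raise ValueError("empty measurement set")
    peak = max(np.abs(a).max() for a in arrs if a.size)
    return 20.0 * np.log10(peak / sigma)
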