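"""Shared fixtures: study conditions for the detection tasks under test."""

import numpy as np
import pytest

from iomcmc import (
    GaussianPRFSpec,
    GaussianSignalSpec,
    LumpyModelSpec,
    NoiseModel,
    evaluate_gaussian_signal,
    make_blob_generator,
    make_linear_gaussian_generator,
    pixel_grid,
)
from iomcmc.evaluation import GeneratorDetectionTask, LumpyDetectionTask


@pytest.fixture(scope="session")
def lumpy_task() -> LumpyDetectionTask:
    """The full-scale lumpy-background task: Poisson-mean-6 lumps (a=1,
    w_b=8) on a 64x64 field, Gaussian PRF (h=35, w_h=2), centered Gaussian
    signal (a_s=0.3, w_s=2.5), i.i.d. Gaussian noise sigma=20."""
    return LumpyDetectionTask(
        lumpy=LumpyModelSpec(mean_lumps=6.0, lump_amplitude=1.0, lump_width=8.0, fov_size=64),
        prf=GaussianPRFSpec(height=35.0, width=2.0, fov_size=64),
        signal=GaussianSignalSpec(amplitude=0.3, width=2.5, center=(32.0, 32.0)),
        noise=NoiseModel(kind="real", sigma=20.0),
    )


@pytest.fixture(scope="session")
def blob_task() -> GeneratorDetectionTask:
    """Low-dimensional nonlinear task: k=2 blob generator on 16x16 images,
    centered Gaussian signal, sigma=1.5 noise.  Small enough that the
    latent posterior integral is quadrature-tractable."""
    gen = make_blob_generator(k=2, fov=16)
    s = evaluate_gaussian_signal(
        GaussianSignalSpec(amplitude=0.5, width=2.0, center=(7.5, 7.5)), pixel_grid(16)
    )
    return GeneratorDetectionTask(generator=gen, signal=s, noise=NoiseModel("real", 1.5))


def _smooth_mixing(fov: int, k: int, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    grid = pixel_grid(fov)
    cols = []
    for _ in range(k):
        c = rng.uniform(0, fov, 2)
        w = rng.uniform(fov / 8, fov / 3)
        d2 = ((grid - c) ** 2).sum(axis=1)
        cols.append(amplitude * np.exp(-d2 / (2 * w**2)))
    return np.stack(cols, axis=1)


@pytest.fixture(scope="session")
def linear_gaussian_pieces():
    """Linear-Gaussian fixture: mean image, smooth mixing map, signal, noise.

    Background b = b0 + A z with z ~ N(0, I_6) on a 16x16 grid; the ideal
    observer is available in closed form for this model.
    """
    fov, k = 16, 6
    rng = np.random.default_rng(20240817)
    mixing = _smooth_mixing(fov, k, amplitude=2.0, rng=rng)
    mean_image = np.ones(fov * fov)
    gen = make_linear_gaussian_generator(mean_image, mixing)
    s = evaluate_gaussian_signal(
        GaussianSignalSpec(amplitude=0.35, width=2.0, center=(7.5, 7.5)), pixel_grid(fov)
    )
    noise = NoiseModel("real", 1.0)
    return {
        "generator": gen,
        "mean_image": mean_image,
        "mixing": mixing,
        "signal": s,
        "noise": noise,
        "task": GeneratorDetectionTask(generator=gen, signal=s, noise=noise),
    }
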