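"""Detection-study orchestration and ROC/AUC figures of merit.

A *detection study* simulates paired signal-absent (H0) and
signal-present (H1) measurement sets from a task description, applies an
observer (a scoring rule) to every measurement, and summarizes the two
score sets with an empirical ROC curve and the Mann-Whitney AUC with a
Hanley-McNeil standard error.  Observers can be any callable; builders
are provided for the Hotelling observer and the MCMC and oracle ideal
observers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Union

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from .config import derive_seed
from .imaging import (
    GaussianPRFSpec,
    NoiseModel,
    add_noise,
    image_gaussian_signal,
    image_lumpy_background,
    sample_lumpy_background_images,
)
from .mcmc import (
    ChainConfig,
    estimate_log_lr,
    run_latent_chain,
    run_lumpy_chain,
)
from .observers import (
    analytic_gaussian_io_log_lr,
    estimate_background_covariance,
    hotelling_template,
    oracle_prior_mc_log_lr,
    oracle_quadrature_log_lr,
)
from .som_models import (
    GaussianSignalSpec,
    LatentGenerator,
    LumpyModelSpec,
    LumpyParams,
    sample_lumpy_params,
)

__all__ = [
    "LumpyDetectionTask",
    "GeneratorDetectionTask",
    "DetectionStudyResult",
    "simulate_measurement",
    "empirical_roc",
    "auc",
    "run_detection_study",
    "radial_power_spectrum",
    "make_hotelling_scorer",
    "make_mcmc_scorer",
    "make_analytic_io_scorer",
    "make_oracle_scorer",
]


@dataclass(frozen=True)
class LumpyDetectionTask:
    """SKE/BKS task: lumpy background, Gaussian signal, Gaussian-PRF imaging."""

    lumpy: LumpyModelSpec = LumpyModelSpec()
    prf: GaussianPRFSpec = GaussianPRFSpec()
    signal: GaussianSignalSpec = GaussianSignalSpec()
    noise: NoiseModel = NoiseModel(kind="real", sigma=20.0)

    def signal_image(self) -> np.ndarray:
        return image_gaussian_signal(self.signal, self.prf)


@dataclass(frozen=True)
class GeneratorDetectionTask:
    """SKE/BKS task whose background comes from a latent generator.

    ``signal_image`` lives in the generator's output domain when no
    imaging operator is given, otherwise in the measurement domain of
    ``imaging_op``.
    """

    generator: LatentGenerator
    signal: np.ndarray
    noise: NoiseModel
    imaging_op: Optional[Callable[[np.ndarray], np.ndarray]] = None

    def signal_image(self) -> np.ndarray:
        return np.asarray(self.signal)


Task = Union[LumpyDetectionTask, GeneratorDetectionTask]


def simulate_measurement(
    task: Task, signal_present: bool, rng: np.random.Generator
) -> tuple[np.ndarray, object]:
    """Simulate one measurement; returns ``(g, truth)``.

    ``truth`` is the ground-truth background parameterization (a
    :class:`LumpyParams` or a latent vector), available for true-state
    chain initialization.
    """
    s = task.signal_image()
    if isinstance(task, LumpyDetectionTask):
        theta = sample_lumpy_params(task.lumpy, rng)
        mean = image_lumpy_background(theta, task.lumpy, task.prf)
        if signal_present:
            mean = mean + s
        return add_noise(mean, task.noise, rng), theta
    z, b = task.generator.sample_prior(rng)
    mean = task.imaging_op(b) if task.imaging_op is not None else b
    if signal_present:
        mean = mean + s
    return add_noise(mean, task.noise, rng), z


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


def empirical_roc(
    h0_scores: np.ndarray, h1_scores: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical ROC: (FPF, TPF) over all score thresholds, ties grouped."""
    h0 = np.asarray(h0_scores, dtype=float)
    h1 = np.asarray(h1_scores, dtype=float)
    if h0.size == 0 or h1.size == 0:
        raise ValueError("both score sets must be non-empty")
    labels = np.concatenate([np.zeros(h0.size), np.ones(h1.size)])
    fpf, tpf, _ = roc_curve(labels, np.concatenate([h0, h1]), drop_intermediate=False)
    return fpf, tpf


def auc(h0_scores: np.ndarray, h1_scores: np.ndarray) -> tuple[float, float]:
    """Mann-Whitney AUC (ties one-half) with the Hanley-McNeil SE."""
    h0 = np.asarray(h0_scores, dtype=float)
    h1 = np.asarray(h1_scores, dtype=float)
    n0, n1 = h0.size, h1.size
    if n0 == 0 or n1 == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = rankdata(np.concatenate([h0, h1]))
    a = (ranks[n0:].sum() - n1 * (n1 + 1) / 2.0) / (n0 * n1)
    q1 = a / (2.0 - a)
    q2 = 2.0 * a**2 / (1.0 + a)
    var = (a * (1 - a) + (n1 - 1) * (q1 - a**2) + (n0 - 1) * (q2 - a**2)) / (n0 * n1)
    return float(a), float(np.sqrt(max(var, 0.0)))


@dataclass
class DetectionStudyResult:
    """Paired H0/H1 scores with ROC, AUC and bookkeeping."""

    h0_scores: np.ndarray
    h1_scores: np.ndarray
    fpf: np.ndarray
    tpf: np.ndarray
    auc: float
    auc_se: float
    config: dict = field(default_factory=dict)
    failures: list = field(default_factory=list)

    @property
    def n_failures(self) -> int:
        return len(self.failures)


# ---------------------------------------------------------------------------
# observer builders
# ---------------------------------------------------------------------------

Scorer = Callable[[np.ndarray, object, int], float]


def make_hotelling_scorer(
    task: Task,
    n_cov_samples: int = 50_000,
    seed: int = 0,
) -> Scorer:
    """Build a Hotelling scorer for a task.

    The background covariance is estimated from ``n_cov_samples``
    noiseless background images (the covariance-decomposition route); for
    a lumpy task these are analytic Gaussian-PRF images, for a generator
    task they are prior draws pushed through the imaging operator if one
    is present.
    """
    rng = np.random.default_rng(seed)
    s = task.signal_image()
    if isinstance(task, LumpyDetectionTask):
        samples = sample_lumpy_background_images(
            task.lumpy, task.prf, n_cov_samples, rng
        )
    else:
        Z = rng.standard_normal((n_cov_samples, task.generator.latent_dim))
        samples = task.generator.batch(Z)
        if task.imaging_op is not None:
            from .mcmc import _as_real

            samples = np.stack([_as_real(task.imaging_op(b)) for b in samples])
    Kb = estimate_background_covariance(samples)
    template = hotelling_template(Kb, task.noise, s)

    def scorer(g: np.ndarray, truth: object, seed_: int) -> float:
        return template.score(g)

    return scorer


def make_mcmc_scorer(task: Task, chain_config: ChainConfig) -> Scorer:
    """Build the MCMC ideal-observer scorer for a task.

    Lumpy tasks run the conventional reversible-jump chain over lump
    configurations; generator tasks run the pCN latent chain.  The
    per-image seed passed by :func:`run_detection_study` overrides the
    seed in ``chain_config``.
    """
    s = task.signal_image()

    if isinstance(task, LumpyDetectionTask):

        def scorer(g: np.ndarray, truth: object, seed_: int) -> float:
            cfg = replace(chain_config, seed=seed_)
            chain = run_lumpy_chain(
                g, task.lumpy, task.prf, s, task.noise, cfg, theta0=truth
            )
            return estimate_log_lr(chain)

        return scorer

    def scorer(g: np.ndarray, truth: object, seed_: int) -> float:
        cfg = replace(chain_config, seed=seed_)
        chain = run_latent_chain(
            g,
            task.generator,
            s,
            task.noise,
            cfg,
            imaging_op=task.imaging_op,
            z0=truth if cfg.init == "true-latent" else None,
        )
        return estimate_log_lr(chain)

    return scorer


def make_analytic_io_scorer(
    task: GeneratorDetectionTask, mean_image: np.ndarray, mixing: np.ndarray
) -> Scorer:
    """Closed-form IO scorer for a linear-Gaussian generator task."""
    s = task.signal_image()

    def scorer(g: np.ndarray, truth: object, seed_: int) -> float:
        return analytic_gaussian_io_log_lr(g, mean_image, mixing, s, task.noise)

    return scorer


def make_oracle_scorer(
    task: GeneratorDetectionTask,
    method: str = "quadrature",
    **kwargs,
) -> Scorer:
    """Oracle IO scorer: ``method`` is ``"quadrature"`` or ``"prior-mc"``."""
    s = task.signal_image()

    def scorer(g: np.ndarray, truth: object, seed_: int) -> float:
        if method == "quadrature":
            val, _ = oracle_quadrature_log_lr(
                g, task.generator, s, task.noise, imaging_op=task.imaging_op, **kwargs
            )
        elif method == "prior-mc":
            val, _ = oracle_prior_mc_log_lr(
                g,
                task.generator,
                s,
                task.noise,
                rng=np.random.default_rng(seed_),
                imaging_op=task.imaging_op,
                **kwargs,
            )
        else:
            raise ValueError(f"unknown oracle method {method!r}")
        return val

    return scorer


# ---------------------------------------------------------------------------
# study driver
# ---------------------------------------------------------------------------


def run_detection_study(
    task: Task,
    scorer: Scorer,
    n_per_class: int = 200,
    seed: int = 0,
    config_echo: Optional[dict] = None,
) -> DetectionStudyResult:
    """Simulate a paired H0/H1 study and score every measurement.

    Measurements are simulated with seeds derived deterministically from
    ``seed``; the scorer receives a distinct derived seed per image.  A
    scorer failure on an image is recorded (hypothesis, index, message)
    and the study continues without that image.
    """
    scores: dict[int, list[float]] = {0: [], 1: []}
    failures: list[tuple[int, int, str]] = []
    for hyp in (0, 1):
        for i in range(n_per_class):
            rng = np.random.default_rng(derive_seed(seed, hyp, i))
            g, truth = simulate_measurement(task, bool(hyp), rng)
            try:
                scores[hyp].append(scorer(g, truth, derive_seed(seed, hyp, i, 1)))
            except Exception as exc:  # noqa: BLE001 - study must continue
                failures.append((hyp, i, str(exc)))
    h0 = np.asarray(scores[0])
    h1 = np.asarray(scores[1])
    fpf, tpf = empirical_roc(h0, h1)
    a, se = auc(h0, h1)
    return DetectionStudyResult(
        h0_scores=h0,
        h1_scores=h1,
        fpf=fpf,
        tpf=tpf,
        auc=a,
        auc_se=se,
        config=dict(config_echo or {}, n_per_class=n_per_class, seed=seed),
        failures=failures,
    )


def radial_power_spectrum(
    images: np.ndarray, n_bins: Optional[int] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Ensemble-averaged, radially-binned power spectrum of square images.

    Returns ``(radius, power)`` where ``power[r]`` is the mean squared
    modulus of the orthonormal 2D DFT over all frequencies whose radius
    (DC at the center) rounds to ``r``.  Useful for comparing the
    second-order statistics of two image ensembles, e.g. real versus
    generated backgrounds.
    """
    images = np.asarray(images, dtype=float)
    if images.ndim == 2 and images.shape[0] == images.shape[1]:
        images = images[None]  # a single square image
    elif images.ndim == 2:
        side = int(round(np.sqrt(images.shape[1])))
        if side * side != images.shape[1]:
            raise ValueError("flat image length is not a perfect square")
        images = images.reshape(images.shape[0], side, side)
    if images.ndim != 3 or images.shape[1] != images.shape[2]:
        raise ValueError("expected (n, L, L) images or (n, L*L) flat rows")
    n, ny, nx = images.shape
    F = np.fft.fftshift(np.fft.fft2(images, norm="ortho"), axes=(-2, -1))
    P = (np.abs(F) ** 2).mean(axis=0)
    cy, cx = ny // 2, nx // 2
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    r = np.round(np.hypot(yy - cy, xx - cx)).astype(int)
    n_bins = n_bins or r.max() + 1
    power = np.bincount(r.ravel(), weights=P.ravel(), minlength=n_bins)[:n_bins]
    counts = np.bincount(r.ravel(), minlength=n_bins)[:n_bins]
    valid = counts > 0
    return np.arange(n_bins)[valid], power[valid] / counts[valid]
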