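"""Convergence diagnostics for scalar chain summaries.

The potential scale reduction factor (PSRF) compares between-chain and
within-chain variance of a scalar quantity across parallel chains run
from different seeds; values near one indicate convergence, with 1.01 a
commonly advocated threshold.  Here the monitored scalar is the log BKE
likelihood ratio -- the quantity the Monte-Carlo likelihood-ratio
estimator averages.

The default PSRF is the ratio form

    PSRF = (Nc - 1)/Nc + B / (Nc W) ,

with ``W`` the mean of the per-chain unbiased variances and ``B`` the
between-chain variance (scaled by chain length).  Note this form equals
the squared Gelman-Rubin statistic; ``sqrt_variant=True`` returns the
conventional square-rooted version, and ``split=True`` halves each chain
first (the split-chain variant).  With identical non-constant chains
``B = 0`` and the statistic equals ``(Nc - 1)/Nc``, slightly below one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .mcmc import ChainResult

__all__ = ["PsrfReport", "psrf", "autocorrelation", "run_parallel_chains"]


@dataclass
class PsrfReport:
    """PSRF value with its ingredients and a convergence flag."""

    psrf: float
    W: float
    B: float
    n_chains: int
    chain_length: int
    threshold: float = 1.01

    @property
    def converged(self) -> bool:
        return self.psrf < self.threshold


def psrf(
    chains: Sequence[np.ndarray] | np.ndarray,
    threshold: float = 1.01,
    sqrt_variant: bool = False,
    split: bool = False,
) -> PsrfReport:
    """Potential scale reduction factor across parallel scalar chains.

    Parameters
    ----------
    chains:
        ``M`` equal-length scalar series, ``M > 1``.
    sqrt_variant:
        Return the square root of the ratio form (the conventional
        Gelman-Rubin R-hat) instead of the ratio itself.
    split:
        Split every chain into halves before computing the statistic.

    Raises
    ------
    ValueError
        On fewer than two chains, unequal or too-short lengths, or a
        degenerate ensemble in which every chain is internally constant
        (``W = 0``).
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need at least two equal-length chains")
    if split:
        half = arr.shape[1] // 2
        arr = np.vstack([arr[:, :half], arr[:, half : 2 * half]])
    M, Nc = arr.shape
    if Nc < 2:
        raise ValueError("chains must have length > 1")
    chain_means = arr.mean(axis=1)
    W = float(arr.var(axis=1, ddof=1).mean())
    B = float(Nc * chain_means.var(ddof=1))
    if W == 0.0:
        raise ValueError("degenerate ensemble: all chains internally constant (W = 0)")
    value = (Nc - 1) / Nc + B / (Nc * W)
    if sqrt_variant:
        value = float(np.sqrt(value))
    return PsrfReport(
        psrf=float(value), W=W, B=B, n_chains=M, chain_length=Nc, threshold=threshold
    )


def autocorrelation(series: np.ndarray, max_lag: int) -> np.ndarray:
    """Normalized autocorrelation of a scalar series up to ``max_lag``.

    Returns ``max_lag + 1`` values; lag zero is one by construction.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1D series of length > 1")
    if max_lag >= x.size:
        raise ValueError("max_lag must be smaller than the series length")
    x = x - x.mean()
    acov = np.correlate(x, x, mode="full")[x.size - 1 : x.size + max_lag]
    if acov[0] == 0.0:
        raise ValueError("constant series has undefined autocorrelation")
    return acov / acov[0]


def run_parallel_chains(
    chain_factory: Callable[[int], ChainResult],
    n_chains: int = 5,
    seeds: Optional[Sequence[int]] = None,
    master_seed: int = 0,
    threshold: float = 1.01,
) -> tuple[PsrfReport, list[ChainResult]]:
    """Run parallel chains from distinct seeds and report their PSRF.

    ``chain_factory(seed)`` must return a :class:`ChainResult`; the PSRF
    is computed on the post-burn-in log BKE likelihood-ratio series of
    the chains.  Seeds default to a deterministic spawn of
    ``master_seed``.
    """
    if seeds is None:
        from .config import derive_seed

        seeds = [derive_seed(master_seed, c) for c in range(n_chains)]
    if len(set(seeds)) != len(seeds):
        raise ValueError("chain seeds must be distinct")
    chains = [chain_factory(int(s)) for s in seeds]
    report = psrf([c.post_burn_in for c in chains], threshold=threshold)
    return report, chains


def plot_diagnostics(
    chains: Sequence[ChainResult],
    path: str,
    max_lag: int = 200,
) -> None:
    """Write a trace + autocorrelation figure for a set of chains."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax0, ax1) = plt.subplots(1, 2, figsize=(10, 3.5))
    for c in chains:
        ax0.plot(c.log_lr_bke, lw=0.5)
    ax0.set_xlabel("iteration")
    ax0.set_ylabel(r"$\log \Lambda_{\rm BKE}$")
    ax0.set_title("trace")
    for c in chains:
        ax1.plot(autocorrelation(c.post_burn_in, max_lag), lw=0.8)
    ax1.set_xlabel("lag")
    ax1.set_ylabel("autocorrelation")
    ax1.set_title("post-burn-in autocorrelation")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
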