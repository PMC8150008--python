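"""Sampler configuration and convergence diagnostics shared by all models."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

with warnings.catch_warnings():
    warnings.simplefilter("ignore", FutureWarning)
    import arviz as az

__all__ = ["McmcConfig", "rhat", "ess", "chunk_chains"]


@dataclass(frozen=True)
class McmcConfig:
    """Chain layout and convergence contract for every fitted model.

    ``iterations`` is the per-chain total including ``warmup`` burn-in
    draws, mirroring the study's sampler settings (4 chains of 2,000
    with 1,000 burn-in; convergence declared at R-hat < 1.02).
    """

    chains: int = 4
    iterations: int = 2000
    warmup: int = 1000
    rhat_threshold: float = 1.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("need at least 2 chains for R-hat")
        if not 0 <= self.warmup < self.iterations:
            raise ValueError("warmup must satisfy 0 <= warmup < iterations")

    @property
    def kept(self) -> int:
        return self.iterations - self.warmup

    def doubled(self) -> "McmcConfig":
        return McmcConfig(
            chains=self.chains,
            iterations=2 * self.iterations,
            warmup=2 * self.warmup,
            rhat_threshold=self.rhat_threshold,
            seed=self.seed,
        )


def rhat(draws: np.ndarray) -> float:
    """Rank-normalized split Gelman–Rubin statistic for (chain, draw) draws."""
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2:
        raise ValueError("expected a (chains, draws) array")
    if np.allclose(draws, draws.flat[0]):
        return 1.0
    return float(az.rhat(draws))


def ess(draws: np.ndarray) -> float:
    """Bulk effective sample size for (chain, draw) draws."""
    draws = np.asarray(draws, dtype=float)
    if np.allclose(draws, draws.flat[0]):
        return float(draws.size)
    return float(az.ess(draws))


def chunk_chains(flat: np.ndarray, chains: int) -> np.ndarray:
    """Reshape a flat vector of draws into (chains, draws) pseudo-chains.

    Used for samplers that produce independent draws (grid samplers,
    closed-form mixtures) so they report the same diagnostics as MCMC.
    """
    flat = np.asarray(flat, dtype=float).ravel()
    keep = (flat.size // chains) * chains
    return flat[:keep].reshape(chains, -1)
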