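"""Synthetic conditioning-style data with known effect size and correlation.

Each participant contributes a correlated (cs1, cs2) pair drawn from a
bivariate normal with common within-condition sd ``sigma`` and correlation
``rho``; the implied standardised paired effect size is

    delta = (mu1 - mu2) / (sigma * sqrt(2 * (1 - rho)))

because the difference score cs1 - cs2 has sd sigma*sqrt(2(1-rho)).  The
generator matches the normal-theory assumptions of the t-tests it feeds;
real startle EMG is often skewed and zero-inflated, which this model does
not emulate.

Randomness uses numpy's PCG64 via ``default_rng`` so identical
(config, seed) pairs give identical tables on every platform.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from condlab.data import ConditioningTable

__all__ = ["SimConfig", "simulate_conditioning", "null_batch"]


@dataclass(frozen=True)
class SimConfig:
    """Generator settings.

    ``n`` participants per group; ``mu1``/``mu2`` condition means (CR
    units); ``sigma`` within-condition sd; ``rho`` within-subject
    correlation; ``groups`` 1 or 2 (the second group uses ``mu1_g2``/
    ``mu2_g2``, defaulting to the first group's means); ``seed`` for full
    reproducibility.
    """

    n: int = 40
    mu1: float = 1.0
    mu2: float = 0.0
    sigma: float = 1.0
    rho: float = 0.5
    groups: int = 1
    mu1_g2: Optional[float] = None
    mu2_g2: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be at least 2")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must lie strictly inside (-1, 1)")
        if self.groups not in (1, 2):
            raise ValueError("groups must be 1 or 2")

    @property
    def delta(self) -> float:
        """Implied standardised paired effect size of group 1."""
        return (self.mu1 - self.mu2) / (self.sigma * np.sqrt(2.0 * (1.0 - self.rho)))


def _draw_pairs(rng: np.random.Generator, n: int, mu1: float, mu2: float, sigma: float, rho: float) -> np.ndarray:
    cov = sigma**2 * np.array([[1.0, rho], [rho, 1.0]])
    return rng.multivariate_normal([mu1, mu2], cov, size=n, method="cholesky")


def simulate_conditioning(config: SimConfig) -> ConditioningTable:
    """Draw one conditioning table from the configured bivariate normal."""
    rng = np.random.default_rng(config.seed)
    pairs = _draw_pairs(rng, config.n, config.mu1, config.mu2, config.sigma, config.rho)
    group = None
    if config.groups == 2:
        mu1b = config.mu1 if config.mu1_g2 is None else config.mu1_g2
        mu2b = config.mu2 if config.mu2_g2 is None else config.mu2_g2
        pairs2 = _draw_pairs(rng, config.n, mu1b, mu2b, config.sigma, config.rho)
        pairs = np.vstack([pairs, pairs2])
        group = np.array(["g1"] * config.n + ["g2"] * config.n)
    return ConditioningTable(cs1=pairs[:, 0], cs2=pairs[:, 1], group=group)


def null_batch(config: SimConfig, reps: int) -> list[ConditioningTable]:
    """``reps`` independent tables from the null configuration (mu1 == mu2).

    Replicate i uses the seed derived from ``SeedSequence(config.seed)``
    spawn key ``(i,)``, a counter-based scheme, so any single replicate can
    be regenerated in isolation.
    """
    if reps < 1:
        raise ValueError("reps must be at least 1")
    if config.mu1 != config.mu2:
        raise ValueError("null_batch requires mu1 == mu2")
    tables = []
    for i in range(reps):
        seed_i = np.random.SeedSequence(config.seed, spawn_key=(i,)).generate_state(1)[0]
        tables.append(simulate_conditioning(replace(config, seed=int(seed_i))))
    return tables
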