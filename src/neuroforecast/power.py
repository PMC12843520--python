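"""Monte Carlo power analysis for video-level correlation tests.

The study design correlates a neural statistic with an outcome across a
small number of stimuli (14 videos), so its power to detect video-level
effects is limited regardless of how many subjects contribute to the group
statistic. Each Monte Carlo iteration draws ``n_videos`` bivariate-normal
pairs with true correlation ``rho`` and applies the exact two-sided t-test
of zero Pearson correlation; power is the rejection fraction over
iterations, with a Wilson binomial confidence interval.

A closed-form Fisher-z approximation is included for cross-checking the
simulation.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint


@dataclass(frozen=True)
class PowerSimResult:
    """Monte Carlo power estimate for one effect size."""

    rho: float
    n_videos: int
    iterations: int
    alpha: float
    power: float
    ci: tuple[float, float]   # Wilson 95% interval
    seed: int | None

    def __post_init__(self) -> None:
        if self.iterations < 1000:
            raise ValueError("power estimates require at least 1000 iterations")
        if not 0.0 <= self.power <= 1.0:
            raise ValueError("power must lie in [0, 1]")
        if not self.ci[0] <= self.power <= self.ci[1]:
            raise ValueError("confidence interval must contain the estimate")


def simulate_power(rho: float, n_videos: int = 14, iters: int = 5000,
                   alpha: float = 0.05,
                   seed: int | np.random.Generator | None = None) -> PowerSimResult:
    """Estimate power to detect a video-level correlation of ``rho``.

    Vectorized over iterations; deterministic given the seed.
    """
    if not abs(rho) < 1:
        raise ValueError(f"rho must satisfy |rho| < 1, got {rho}")
    if n_videos < 4:
        raise ValueError(f"n_videos must be at least 4, got {n_videos}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = rng.standard_normal((iters, n_videos))
    y = rho * x + np.sqrt(1.0 - rho ** 2) * rng.standard_normal((iters, n_videos))
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    r = (xc * yc).sum(axis=1) / np.sqrt((xc ** 2).sum(axis=1) * (yc ** 2).sum(axis=1))
    r = np.clip(r, -0.9999999, 0.9999999)
    t = r * np.sqrt((n_videos - 2) / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n_videos - 2)
    rejected = int((p < alpha).sum())
    power = rejected / iters
    lo, hi = proportion_confint(rejected, iters, alpha=0.05, method="wilson")
    return PowerSimResult(rho=rho, n_videos=n_videos, iterations=iters,
                          alpha=alpha, power=power, ci=(float(lo), float(hi)),
                          seed=seed if isinstance(seed, int) else None)


def power_table(rhos: list[float] = (0.10, 0.30, 0.50), n_videos: int = 14,
                iters: int = 5000, alpha: float = 0.05,
                seed: int | None = None) -> list[PowerSimResult]:
    """Map :func:`simulate_power` over effect sizes with independent streams."""
    if len(rhos) == 0:
        raise ValueError("rho list must not be empty")
    streams = np.random.SeedSequence(seed).spawn(len(rhos))
    return [
        simulate_power(rho, n_videos=n_videos, iters=iters, alpha=alpha,
                       seed=np.random.default_rng(s))
        for rho, s in zip(rhos, streams)
    ]


def analytic_power_fisher(rho: float, n: int, alpha: float = 0.05) -> float:
    """Fisher-z normal approximation to the power of the correlation t-test."""
    if n <= 3:
        raise ValueError("Fisher approximation needs n > 3")
    se = 1.0 / np.sqrt(n - 3)
    lam = np.arctanh(rho) / se
    z = stats.norm.isf(alpha / 2.0)
    return float(stats.norm.cdf(-z + lam) + stats.norm.cdf(-z - lam))
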