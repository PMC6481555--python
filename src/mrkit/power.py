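"""Analytic power for two-sample MR with a binary (case-control) outcome.

The normal-approximation method: the IVW estimate of the log odds ratio per
SD of exposure has approximate standard error ``1 / sqrt(N * R^2 * k * (1-k))``
where N is the total outcome sample size, k the case fraction and R^2 the
proportion of exposure variance explained by the instrument. Two-sided
power at level alpha to detect a true OR per SD of ``exp(b)`` is then

    power = Phi( |b| * sqrt(N * R^2 * k * (1-k)) - z_{1-alpha/2} ).

At OR = 1 the formula returns alpha/2 (the one-tail residual), a known
property of this approximation, documented rather than patched.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, stats


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of the binary-outcome MR power calculation.

    n_cases / n_controls: outcome GWAS sample sizes.
    r_squared: proportion of exposure variance explained by the instrument,
        in (0, 1) — an input taken from the exposure GWAS, never computed here.
    odds_ratio_per_sd: true OR for the outcome per 1-SD increase in exposure.
    alpha: two-sided significance level.
    """

    n_cases: int
    n_controls: int
    r_squared: float
    odds_ratio_per_sd: float = 1.0
    alpha: float = 0.05

    def __post_init__(self):
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("n_cases and n_controls must be positive")
        if not 0 < self.r_squared < 1:
            raise ValueError(f"r_squared must be in (0,1), got {self.r_squared}")
        if self.odds_ratio_per_sd <= 0:
            raise ValueError("odds_ratio_per_sd must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")


def mr_power(spec: PowerSpec) -> float:
    """Two-sided power of the IVW test for the given design. In [0, 1]."""
    n = spec.n_cases + spec.n_controls
    k = spec.n_cases / n
    b = np.log(spec.odds_ratio_per_sd)
    z = stats.norm.ppf(1 - spec.alpha / 2)
    ncp = abs(b) * np.sqrt(n * spec.r_squared * k * (1 - k))
    return float(stats.norm.cdf(ncp - z))


def minimum_detectable_or(spec: PowerSpec, target_power: float = 0.8,
                          or_bound: float = 10.0) -> tuple[float, float]:
    """The protective and harmful ORs detectable at ``target_power``.

    Power is symmetric on the log-OR scale, so the pair is ``(1/OR*, OR*)``
    with OR* > 1 found by monotone root-finding on ``mr_power`` between 1
    and ``or_bound``. ``target_power`` must exceed ``alpha/2`` (the power at
    OR = 1) and be attainable below ``or_bound``.
    """
    if not spec.alpha / 2 < target_power < 1:
        raise ValueError(
            f"target_power must be in (alpha/2, 1) = ({spec.alpha / 2}, 1); "
            f"got {target_power}")

    def gap(log_or: float) -> float:
        return mr_power(replace(spec, odds_ratio_per_sd=float(np.exp(log_or)))) \
            - target_power

    hi = np.log(or_bound)
    if gap(hi) < 0:
        raise ValueError(f"target power {target_power} not attainable below "
                         f"OR {or_bound}; raise or_bound")
    log_or = optimize.brentq(gap, 0.0, hi, xtol=1e-12)
    return float(np.exp(-log_or)), float(np.exp(log_or))
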