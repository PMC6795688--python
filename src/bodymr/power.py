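"""Statistical power for MR with a binary (case-control) outcome.

Uses the standard asymptotic approximation: the two-stage causal log-OR
estimate has standard error approximately 1 / sqrt(N * R^2 * K * (1-K)),
where N is the outcome sample size, K the case fraction and R^2 the
exposure variance explained by the instruments.  Power against a true OR
per 1-SD of exposure follows from the normal test of that estimate; the
calculation inverts cleanly into the minimal (>1) and maximal (<1) OR
detectable at a target power.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import InputError

__all__ = ["PowerInputs", "mr_power_binary", "detectable_or"]


@dataclass
class PowerInputs:
    """Inputs for binary-outcome MR power.

    ``r2`` is the instrument variance explained in the exposure (0-1
    scale); ``or_alt`` the alternative OR per 1-SD of exposure; ``alpha``
    the two-sided test level; ``target_power`` is used only by
    :func:`detectable_or`.
    """

    n_cases: int
    n_controls: int
    r2: float
    or_alt: float = 1.0
    alpha: float = 0.05
    target_power: float = 0.80

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise InputError("case and control counts must be positive")
        if not (0.0 < self.r2 < 1.0):
            raise InputError(f"r2 must lie in (0, 1), got {self.r2}")
        if self.or_alt <= 0:
            raise InputError("or_alt must be positive")
        if not (0.0 < self.alpha < 1.0):
            raise InputError("alpha must lie in (0, 1)")

    @property
    def n_total(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def case_fraction(self) -> float:
        return self.n_cases / self.n_total


def _ncp(inputs: PowerInputs, log_or: float) -> float:
    K = inputs.case_fraction
    return abs(log_or) * np.sqrt(inputs.n_total * inputs.r2 * K * (1.0 - K))


def mr_power_binary(inputs: PowerInputs) -> float:
    """Power of the two-sided level-``alpha`` test against ``or_alt``.

    power = Phi(x - z_{1-a/2}) + Phi(-x - z_{1-a/2}) with
    x = |ln OR| * sqrt(N R^2 K (1-K)).  At OR = 1 this equals alpha
    (the size of the test); it increases strictly in N, R^2 and |ln OR|.
    """
    z = stats.norm.ppf(1.0 - inputs.alpha / 2.0)
    x = _ncp(inputs, np.log(inputs.or_alt))
    return float(stats.norm.cdf(x - z) + stats.norm.cdf(-x - z))


def detectable_or(inputs: PowerInputs) -> tuple[float, float]:
    """(minimal OR > 1, maximal OR < 1) detectable at ``target_power``.

    Inverts the dominant tail of the power formula:
    ln(or_min) = (z_{1-a/2} + z_{power}) / sqrt(N R^2 K (1-K)) and
    or_max = 1/or_min.  The neglected opposite-tail term is positive, so
    realized power at or_min slightly exceeds the target (by < 0.005 at
    80% power).
    """
    if not (inputs.alpha < inputs.target_power < 1.0):
        raise InputError("target_power must lie in (alpha, 1)")
    K = inputs.case_fraction
    denom = np.sqrt(inputs.n_total * inputs.r2 * K * (1.0 - K))
    z_a = stats.norm.ppf(1.0 - inputs.alpha / 2.0)
    z_p = stats.norm.ppf(inputs.target_power)
    log_or = (z_a + z_p) / denom
    or_min = float(np.exp(log_or))
    return or_min, 1.0 / or_min
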