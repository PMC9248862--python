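"""Statistical power for Mendelian randomization with a binary outcome.

Under the standard normal approximation, the test statistic for the causal
log odds ratio b = ln(OR) per unit exposure has non-centrality

    ncp = |b| * sqrt(N * R2 * K * (1 - K))

where N is the outcome-study sample size, K the case fraction and R2 the
proportion of exposure variance explained by the instruments.  Two-sided
power at level alpha is then Phi(ncp - z_{1-alpha/2}), and the minimal
detectable OR at a target power inverts this in closed form.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from scipy import stats


@dataclass(frozen=True)
class PowerSpec:
    """Inputs for a binary-outcome MR power calculation.

    Exactly one of ``target_or`` (forward problem: compute power) or
    ``target_power`` (inverse problem: compute the detectable OR) must be
    set.
    """

    n: int
    case_fraction: float
    r2: float
    alpha: float = 0.05
    target_or: float | None = None
    target_power: float | None = None

    def __post_init__(self):
        if not (0.0 < self.case_fraction < 1.0):
            raise ValueError(f"case fraction must be in (0, 1), got {self.case_fraction}")
        if not (0.0 <= self.r2 < 1.0):
            raise ValueError(f"r2 must be in [0, 1), got {self.r2}")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.n <= 2:
            raise ValueError(f"sample size must exceed 2, got {self.n}")
        if (self.target_or is None) == (self.target_power is None):
            raise ValueError("set exactly one of target_or / target_power")
        if self.target_or is not None and self.target_or <= 0:
            raise ValueError("target_or must be positive")

    @property
    def ncp_unit(self) -> float:
        """Non-centrality per unit |ln OR|: sqrt(N * R2 * K * (1-K))."""
        k = self.case_fraction
        return math.sqrt(self.n * self.r2 * k * (1.0 - k))


@dataclass(frozen=True)
class PowerResult:
    power: float
    detectable_or: float | None
    ncp: float


def mr_power(spec: PowerSpec) -> PowerResult:
    """Power to detect ``spec.target_or`` at two-sided level alpha."""
    if spec.target_or is None:
        raise ValueError("mr_power needs target_or; use detectable_or for the inverse problem")
    if spec.r2 == 0:
        warnings.warn("r2 = 0: power reduces to the alpha/2 tail", stacklevel=2)
    z_alpha = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    ncp = abs(math.log(spec.target_or)) * spec.ncp_unit
    power = float(stats.norm.cdf(ncp - z_alpha))
    return PowerResult(power=power, detectable_or=None, ncp=ncp)


def detectable_or(spec: PowerSpec, protective: bool = True) -> PowerResult:
    """Minimal detectable OR at ``spec.target_power``.

    Closed-form inverse of :func:`mr_power`:
    |ln OR| = (z_{1-alpha/2} + z_power) / sqrt(N * R2 * K * (1-K)).
    By default the protective-side OR (< 1) is returned; set
    ``protective=False`` for the risk-side reciprocal.
    """
    if spec.target_power is None:
        raise ValueError("detectable_or needs target_power")
    if spec.target_power <= spec.alpha:
        raise ValueError(
            f"target power {spec.target_power} must exceed alpha {spec.alpha}; "
            "the test rejects that often under the null already"
        )
    if spec.r2 == 0:
        raise ValueError("r2 = 0: no effect is detectable")
    z_alpha = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    z_power = stats.norm.ppf(spec.target_power)
    abs_log_or = (z_alpha + z_power) / spec.ncp_unit
    or_value = math.exp(-abs_log_or) if protective else math.exp(abs_log_or)
    return PowerResult(power=spec.target_power, detectable_or=or_value, ncp=z_alpha + z_power)
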