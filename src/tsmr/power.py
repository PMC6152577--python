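"""Analytic power for two-sample Mendelian randomization.

Normal-approximation (non-centrality) scheme of the Burgess-style online MR
power calculators.  The IVW estimator's standard error is approximately
1/√(n·R²) for a continuous outcome and 1/√(n·R²·K(1−K)) for a binary
outcome analyzed on the log-odds scale (K the case fraction), so the power
of a two-sided level-α Wald test against a true effect b is

    power = Φ( √(n·R²·[K(1−K)]) · |b| − z_{1−α/2} )

counting only the tail on the side of the true effect (one-sided accounting
of a two-sided test, standard for this calculator family).  At b = 0 the
formula returns exactly α/2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .errors import ValidationError


@dataclass(frozen=True)
class PowerParams:
    """Inputs of the analytic power formula.

    ``effect`` is the hypothesized causal effect: a raw beta for
    continuous-outcome calls, an odds ratio for binary-outcome calls.
    ``r2`` is the fraction of exposure variance the instrument explains;
    ``case_fraction`` (K) is required only for binary outcomes.
    """

    n: int
    r2: float
    effect: float
    case_fraction: float | None = None
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValidationError("outcome sample size must be positive")
        if not (0 < self.r2 < 1):
            raise ValidationError(f"instrument R² {self.r2} outside (0, 1)")
        if self.case_fraction is not None and not (0 < self.case_fraction < 1):
            raise ValidationError(f"case fraction {self.case_fraction} outside (0, 1)")
        if not (0 < self.alpha < 1):
            raise ValidationError(f"alpha {self.alpha} outside (0, 1)")


def power_continuous(params: PowerParams) -> float:
    """Power to detect a causal effect beta on a continuous outcome."""
    z = stats.norm.ppf(1 - params.alpha / 2)
    ncp = math.sqrt(params.n * params.r2) * abs(params.effect)
    return float(stats.norm.cdf(ncp - z))


def power_binary(params: PowerParams) -> float:
    """Power to detect a causal odds ratio on a binary outcome.

    The non-centrality is scaled by √(K(1−K)), the standard deviation factor
    of the binary case indicator, and the effect enters as |log(OR)|.
    """
    if params.case_fraction is None:
        raise ValidationError("binary-outcome power requires a case fraction")
    if params.effect <= 0:
        raise ValidationError("odds ratio must be positive")
    z = stats.norm.ppf(1 - params.alpha / 2)
    k = params.case_fraction
    ncp = math.sqrt(params.n * params.r2 * k * (1 - k)) * abs(math.log(params.effect))
    return float(stats.norm.cdf(ncp - z))


def power_percent(power: float) -> int:
    """Power rendered as a whole percentage, the convention of the online calculators."""
    return round(power * 100)
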