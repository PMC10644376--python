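"""Statistical power for an IVW Mendelian randomization estimate, binary outcome.

The non-centrality approximation: with causal log-odds ratio b = ln(OR),
outcome sample size n, case fraction K, and instrument variance explained
r²_xz, the IVW z statistic is approximately normal with mean

    z = b · sqrt(n · r²_xz · K · (1 − K)),

so two-sided power at level alpha is

    1 − Φ(z_{1−α/2} − z) + Φ(−z_{1−α/2} − z).

Deterministic; symmetric under OR ↔ 1/OR; equal to alpha exactly at OR = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .errors import ValidationError


@dataclass(frozen=True)
class PowerInput:
    """Inputs to the binary-outcome power computation.

    n: outcome-study sample size; case_fraction: proportion of cases in
    (0,1); r2_xz: instrument variance explained in (0,1); odds_ratio:
    hypothesized OR per unit exposure; alpha: two-sided level.
    """

    n: float
    case_fraction: float
    r2_xz: float
    odds_ratio: float
    alpha: float = 0.05

    def __post_init__(self):
        if self.n <= 0:
            raise ValidationError("n must be positive")
        if not (0 < self.case_fraction < 1):
            raise ValidationError("case_fraction must lie in (0, 1)")
        if not (0 < self.r2_xz < 1):
            raise ValidationError("r2_xz must lie in (0, 1)")
        if self.odds_ratio <= 0:
            raise ValidationError("odds_ratio must be positive")
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must lie in (0, 1)")


def mr_power_binary(inp: PowerInput) -> float:
    """Two-sided power of the IVW test under the non-centrality approximation."""
    b = math.log(inp.odds_ratio)
    z = b * math.sqrt(inp.n * inp.r2_xz
                      * inp.case_fraction * (1.0 - inp.case_fraction))
    za = stats.norm.ppf(1.0 - inp.alpha / 2.0)
    return float(stats.norm.sf(za - z) + stats.norm.cdf(-za - z))


def solve_n_for_power(target_power: float, case_fraction: float, r2_xz: float,
                      odds_ratio: float, alpha: float = 0.05,
                      n_max: float = 1e10) -> float:
    """Smallest outcome sample size reaching ``target_power``, by bisection."""
    if not (alpha < target_power < 1):
        raise ValidationError("target_power must lie in (alpha, 1)")
    if odds_ratio == 1.0:
        raise ValidationError("power never exceeds alpha at OR = 1")
    lo, hi = 1.0, n_max
    if mr_power_binary(PowerInput(hi, case_fraction, r2_xz, odds_ratio, alpha)) \
            < target_power:
        raise ValidationError("target power unreachable below n_max")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        p = mr_power_binary(PowerInput(mid, case_fraction, r2_xz, odds_ratio, alpha))
        if p < target_power:
            lo = mid
        else:
            hi = mid
        if hi - lo < 0.5:
            break
    return math.ceil(hi)
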