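"""Causal-effect estimators for two-sample Mendelian randomization.

Three estimators over a set of harmonized instruments:

* **IVW** — inverse-variance-weighted meta-analysis of per-SNP Wald ratios
  r_j = beta_y_j / beta_x_j with first-order weights w_j = beta_x_j²/se_y_j²,
  equivalent to a zero-intercept weighted regression of outcome on exposure
  effects.  The multiplicative random-effects flavour inflates the
  fixed-effects SE by sqrt(Q/(J−1)), floored at 1.
* **Weighted median** — the ratio at cumulative normalized weight 0.5;
  consistent when at least half of the instrument weight is valid.  SE from a
  parametric bootstrap with a mandatory seed.
* **MR-Egger** — weighted regression of beta_y on beta_x with a free
  intercept after orienting all instruments to beta_x ≥ 0; the intercept
  estimates average directional pleiotropy, the slope a pleiotropy-adjusted
  causal effect under the InSIDE assumption.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .errors import (ConfigurationError, DegenerateInstrumentError,
                     InsufficientInstrumentsError)
from .summary_io import HarmonizedPair

logger = logging.getLogger(__name__)

Z_95 = 1.96  # CI multiplier, fixed


@dataclass(frozen=True)
class MREstimate:
    """One estimator's result: the row type of the results table."""

    method: str
    beta: float
    se: float
    pval: float
    n_snps: int

    @property
    def or_(self) -> float:
        return math.exp(self.beta)

    @property
    def ci_low(self) -> float:
        return math.exp(self.beta - Z_95 * self.se)

    @property
    def ci_high(self) -> float:
        return math.exp(self.beta + Z_95 * self.se)

    def to_dict(self) -> dict:
        return {
            "method": self.method, "nsnp": self.n_snps, "beta": self.beta,
            "se": self.se, "or": self.or_, "ci_low": self.ci_low,
            "ci_high": self.ci_high, "pval": self.pval,
        }


@dataclass(frozen=True)
class EggerIntercept:
    """Average directional pleiotropy per SNP, with its test."""

    intercept: float
    se: float
    pval: float


def _arrays(instruments):
    """Accept an InstrumentSet or a sequence of HarmonizedPair."""
    if hasattr(instruments, "arrays"):
        return instruments.arrays()
    pairs = list(instruments)
    return (np.array([p.beta_x for p in pairs]),
            np.array([p.se_x for p in pairs]),
            np.array([p.beta_y for p in pairs]),
            np.array([p.se_y for p in pairs]))


def wald_ratio(pair: HarmonizedPair) -> tuple[float, float]:
    """Per-SNP causal estimate beta_y/beta_x and its first-order SE se_y/|beta_x|.

    Exposure-side uncertainty is ignored (first-order approximation), the
    convention under which the downstream IVW weights are derived.
    """
    if pair.beta_x == 0:
        raise DegenerateInstrumentError(
            f"{pair.snp_id}: zero exposure effect, Wald ratio undefined")
    return pair.beta_y / pair.beta_x, pair.se_y / abs(pair.beta_x)


def _ivw_core(bx, by, sy):
    """Fixed-effects IVW point estimate, SE, and Cochran's Q."""
    w = bx**2 / sy**2
    r = by / bx
    beta = float(np.sum(w * r) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    q = float(np.sum(w * (r - beta) ** 2))
    return beta, se_fixed, q


def ivw(instruments, model: str = "multiplicative_random") -> MREstimate:
    """Inverse-variance-weighted estimate over the instruments.

    ``model`` is ``"fixed"`` or ``"multiplicative_random"`` (default); the
    latter scales the fixed-effects SE by max(1, sqrt(Q/(J−1))).  A single
    instrument degenerates to its Wald ratio (allowed with a warning).
    """
    if model not in ("fixed", "multiplicative_random"):
        raise ConfigurationError(f"unknown IVW model {model!r}")
    bx, sx, by, sy = _arrays(instruments)
    j = len(bx)
    if j == 0:
        raise InsufficientInstrumentsError("IVW requires at least one instrument")
    if np.any(bx == 0):
        raise DegenerateInstrumentError("zero exposure effect among instruments")
    if j == 1:
        warnings.warn("single instrument: IVW degenerates to the Wald ratio")
        beta, se = by[0] / bx[0], sy[0] / abs(bx[0])
        pval = 2 * stats.norm.sf(abs(beta) / se)
        return MREstimate("IVW", float(beta), float(se), float(pval), 1)
    beta, se_fixed, q = _ivw_core(bx, by, sy)
    se = se_fixed
    if model == "multiplicative_random":
        se = se_fixed * max(1.0, math.sqrt(q / (j - 1)))
    pval = 2 * stats.norm.sf(abs(beta) / se)
    return MREstimate("IVW", beta, float(se), float(pval), j)


def mr_egger(instruments) -> tuple[MREstimate, EggerIntercept]:
    """MR-Egger regression: pleiotropy-adjusted slope and intercept test.

    Instruments are oriented so beta_x ≥ 0 (both effects negated otherwise);
    the weighted fit (weights 1/se_y²) uses a multiplicative overdispersion
    scale floored at 1, and p-values from the t distribution on J−2 degrees
    of freedom.
    """
    bx, sx, by, sy = _arrays(instruments)
    j = len(bx)
    if j < 3:
        raise InsufficientInstrumentsError("MR-Egger requires at least 3 instruments")
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    x = sm.add_constant(bx)
    fit = sm.WLS(by, x, weights=1.0 / sy**2).fit()
    sigma2 = float(fit.mse_resid)  # RSS_w / (J-2)
    scale = max(1.0, math.sqrt(sigma2))
    se_unit = fit.bse / math.sqrt(sigma2)  # SEs at unit dispersion
    se = se_unit * scale
    tvals = np.abs(fit.params) / se
    pvals = 2 * stats.t.sf(tvals, df=j - 2)
    slope = MREstimate("MR_Egger", float(fit.params[1]), float(se[1]),
                       float(pvals[1]), j)
    intercept = EggerIntercept(float(fit.params[0]), float(se[0]), float(pvals[0]))
    return slope, intercept


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median: the ratio at cumulative weight 0.5.

    With sorted ratios and normalized weights w_j, the cumulative grid is
    s_j = sum_{k<=j} w_k − w_j/2; the estimate linearly interpolates between
    the two ratios bracketing s = 0.5.
    """
    order = np.argsort(ratios)
    r, w = ratios[order], weights[order]
    w = w / w.sum()
    s = np.cumsum(w) - w / 2
    if 0.5 <= s[0]:
        return float(r[0])
    if 0.5 >= s[-1]:
        return float(r[-1])
    return float(np.interp(0.5, s, r))


def weighted_median(instruments, n_boot: int = 1000,
                    seed: int | None = None) -> MREstimate:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    The point estimate is deterministic; only the SE is stochastic, hence
    ``seed`` is mandatory (reproducibility contract).  Each bootstrap
    replicate redraws every beta_x_j and beta_y_j from normal distributions
    with their reported SEs and recomputes the weighted median.
    """
    if seed is None:
        raise ConfigurationError("weighted_median requires an explicit seed")
    bx, sx, by, sy = _arrays(instruments)
    j = len(bx)
    if j < 3:
        raise InsufficientInstrumentsError(
            "weighted median requires at least 3 instruments")
    if np.any(bx == 0):
        raise DegenerateInstrumentError("zero exposure effect among instruments")
    ratios = by / bx
    weights = bx**2 / sy**2
    beta = _weighted_median(ratios, weights)

    rng = np.random.default_rng(seed)
    bx_b = rng.normal(bx, sx, size=(n_boot, j))
    by_b = rng.normal(by, sy, size=(n_boot, j))
    est = np.empty(n_boot)
    for b in range(n_boot):
        bxb = bx_b[b]
        bxb = np.where(bxb == 0, np.finfo(float).tiny, bxb)  # guard degenerate draw
        est[b] = _weighted_median(by_b[b] / bxb, bxb**2 / sy**2)
    se = float(np.std(est, ddof=1))
    pval = float(2 * stats.norm.sf(abs(beta) / se))
    return MREstimate("weighted_median", beta, se, pval, j)


def estimates_table(estimates) -> "pd.DataFrame":
    """Results table with a fixed column order (method, nsnp, beta, se, or, CI, p)."""
    import pandas as pd
    return pd.DataFrame([e.to_dict() for e in estimates],
                        columns=["method", "nsnp", "beta", "se", "or",
                                 "ci_low", "ci_high", "pval"])
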