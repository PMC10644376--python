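"""Sensitivity diagnostics: heterogeneity, outliers, and influence.

* Cochran's Q over Wald ratios, with I² = max(0, (Q−df)/Q)·100 and the
  conventional 25/75 low/moderate/high bands.
* A simulation-based residual-sum-of-squares outlier test in the style of
  MR-PRESSO: the observed RSS (each SNP's weighted squared residual from the
  IVW slope fitted *without* it) is compared with its parametric null
  distribution; per-SNP outlier calls are Bonferroni-corrected, and a
  distortion test measures how much flagged outliers move the estimate.
* Leave-one-out re-estimation of the IVW effect.
* Funnel-plot data (Wald ratio vs. precision) for visual symmetry checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InsufficientInstrumentsError
from .estimators import MREstimate, _arrays, _ivw_core, ivw

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HeterogeneityResult:
    q: float
    df: int
    pval: float
    i2: float  # percentage in [0, 100]
    band: str  # low | moderate | high

    def to_dict(self) -> dict:
        return {"q": self.q, "df": self.df, "pval": self.pval,
                "i2": self.i2, "band": self.band}


@dataclass
class PressoResult:
    global_rss: float
    global_pval: float
    outlier_snps: list[tuple[str, float]]  # (snp_id, empirical p)
    distortion_pval: float | None = None
    corrected_estimate: MREstimate | None = None

    def to_dict(self) -> dict:
        return {
            "global_rss": self.global_rss,
            "global_pval": self.global_pval,
            "outlier_snps": [{"snp_id": s, "pval": p} for s, p in self.outlier_snps],
            "distortion_pval": self.distortion_pval,
            "corrected_estimate": (None if self.corrected_estimate is None
                                   else self.corrected_estimate.to_dict()),
        }


@dataclass
class LeaveOneOutTable:
    """J rows of (excluded snp_id, IVW beta, se, pval) plus the all-SNP row."""

    table: pd.DataFrame
    flagged: list[str] = field(default_factory=list)


def _i2_band(i2: float) -> str:
    # boundary values 25 and 75 fall in the moderate band (closed interval)
    if i2 < 25:
        return "low"
    if i2 <= 75:
        return "moderate"
    return "high"


def cochran_q(instruments) -> HeterogeneityResult:
    """Cochran's Q over the per-SNP Wald ratios, with I² and its band."""
    bx, sx, by, sy = _arrays(instruments)
    j = len(bx)
    if j < 2:
        raise InsufficientInstrumentsError("Cochran's Q requires >= 2 instruments")
    _, _, q = _ivw_core(bx, by, sy)
    df = j - 1
    pval = float(stats.chi2.sf(q, df))
    i2 = 0.0 if q <= 0 else max(0.0, (q - df) / q) * 100.0
    return HeterogeneityResult(q=q, df=df, pval=pval, i2=i2, band=_i2_band(i2))


def _loo_slopes(bx, by, sy):
    """Leave-one-out zero-intercept WLS slopes, vectorized over the left-out SNP."""
    wxy = bx * by / sy**2
    wxx = bx**2 / sy**2
    return (wxy.sum() - wxy) / (wxx.sum() - wxx)


def mr_presso(instruments, n_sim: int = 1000, seed: int | None = None,
              outlier_alpha: float = 0.05) -> PressoResult:
    """Simulation-based pleiotropy-residual global and per-SNP outlier test.

    Observed RSS uses leave-one-out predicted residuals: SNP j's residual is
    measured against the IVW slope fitted without j, weighted by 1/se_y_j².
    The null distribution redraws each beta_y_j from
    N(slope_{−j}·beta_x_j, se_y_j) ``n_sim`` times and recomputes the same
    statistic.  Empirical p-values are floored at 1/(n_sim+1); per-SNP calls
    are Bonferroni-corrected at ``outlier_alpha``.  When outliers are found,
    the distortion test compares the outlier-free IVW estimate with the full
    one against a null of randomly removed inlier subsets.
    """
    if seed is None:
        raise ConfigurationError("mr_presso requires an explicit seed")
    bx, sx, by, sy = _arrays(instruments)
    j = len(bx)
    if j < 4:
        raise InsufficientInstrumentsError("mr_presso requires >= 4 instruments")
    snp_ids = (instruments.snp_ids if hasattr(instruments, "snp_ids")
               else [p.snp_id for p in instruments])

    slopes = _loo_slopes(bx, by, sy)
    obs_resid = (by - slopes * bx) ** 2 / sy**2
    obs_rss = float(obs_resid.sum())

    rng = np.random.default_rng(seed)
    by_sim = slopes * bx + sy * rng.standard_normal((n_sim, j))
    wxy_sim = bx * by_sim / sy**2
    wxx = bx**2 / sy**2
    slopes_sim = (wxy_sim.sum(axis=1, keepdims=True) - wxy_sim) / (wxx.sum() - wxx)
    resid_sim = (by_sim - slopes_sim * bx) ** 2 / sy**2
    rss_sim = resid_sim.sum(axis=1)

    global_pval = float((1 + np.sum(rss_sim >= obs_rss)) / (n_sim + 1))
    per_snp_p = (1 + np.sum(resid_sim >= obs_resid, axis=0)) / (n_sim + 1)
    bonf = outlier_alpha / j
    outliers = [(snp_ids[k], float(per_snp_p[k]))
                for k in np.flatnonzero(per_snp_p < bonf)]

    result = PressoResult(global_rss=obs_rss, global_pval=global_pval,
                          outlier_snps=outliers)
    if outliers:
        out_ids = {s for s, _ in outliers}
        in_idx = [k for k, s in enumerate(snp_ids) if s not in out_ids]
        if len(in_idx) >= 2:
            pairs = (instruments.pairs if hasattr(instruments, "pairs")
                     else list(instruments))
            inliers = [pairs[k] for k in in_idx]
            corrected = ivw(inliers)
            full = ivw(pairs)
            obs_shift = abs(corrected.beta - full.beta)
            # null: removing an equally sized random subset of inliers
            n_rm = len(outliers)
            shifts = np.empty(n_sim)
            bx_in, by_in, sy_in = bx[in_idx], by[in_idx], sy[in_idx]
            beta_full, _, _ = _ivw_core(bx, by, sy)
            for b in range(n_sim):
                keep = rng.permutation(len(in_idx))[: len(in_idx) - n_rm]
                if len(keep) < 2:
                    shifts[b] = 0.0
                    continue
                bsub, _, _ = _ivw_core(bx_in[keep], by_in[keep], sy_in[keep])
                shifts[b] = abs(bsub - beta_full)
            result.distortion_pval = float(
                (1 + np.sum(shifts >= obs_shift)) / (n_sim + 1))
            result.corrected_estimate = corrected
    return result


def leave_one_out(instruments) -> LeaveOneOutTable:
    """Re-estimate the random-effects IVW effect excluding each SNP in turn.

    The final row (snp_id ``"ALL"``) is the full-set estimate.  Exclusions
    that change the sign of beta or move p across 0.05 relative to the full
    set are flagged.
    """
    pairs = (instruments.pairs if hasattr(instruments, "pairs")
             else list(instruments))
    j = len(pairs)
    if j < 3:
        raise InsufficientInstrumentsError("leave-one-out requires >= 3 instruments")
    full = ivw(pairs)
    rows, flagged = [], []
    for k in range(j):
        sub = pairs[:k] + pairs[k + 1:]
        est = ivw(sub)
        rows.append({"snp_id": pairs[k].snp_id, "beta": est.beta,
                     "se": est.se, "pval": est.pval})
        if np.sign(est.beta) != np.sign(full.beta) \
                or (est.pval < 0.05) != (full.pval < 0.05):
            flagged.append(pairs[k].snp_id)
    rows.append({"snp_id": "ALL", "beta": full.beta, "se": full.se,
                 "pval": full.pval})
    return LeaveOneOutTable(table=pd.DataFrame(rows), flagged=flagged)


def funnel_data(instruments) -> pd.DataFrame:
    """Per-SNP (wald_ratio, precision = 1/wald_se) table behind the funnel plot."""
    bx, sx, by, sy = _arrays(instruments)
    if len(bx) < 1:
        raise InsufficientInstrumentsError("funnel data requires >= 1 instrument")
    snp_ids = (instruments.snp_ids if hasattr(instruments, "snp_ids")
               else [p.snp_id for p in instruments])
    ratio = by / bx
    precision = np.abs(bx) / sy
    return pd.DataFrame({"snp_id": snp_ids, "wald_ratio": ratio,
                         "precision": precision})


def diagnostics_report(instruments, egger_intercept=None, seed: int | None = None,
                       n_sim: int = 1000) -> dict:
    """Combined diagnostics document: Q/I², Egger intercept, PRESSO, LOO flags."""
    het = cochran_q(instruments)
    report = {"heterogeneity": het.to_dict()}
    if egger_intercept is not None:
        report["egger_intercept"] = {
            "intercept": egger_intercept.intercept,
            "se": egger_intercept.se,
            "pval": egger_intercept.pval,
        }
    if seed is not None and len(instruments) >= 4:
        report["mr_presso"] = mr_presso(instruments, n_sim=n_sim, seed=seed).to_dict()
    loo = leave_one_out(instruments)
    report["leave_one_out_flags"] = loo.flagged
    return report
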