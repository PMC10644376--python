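"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator works directly at the summary level: for each instrument it
draws an effect-allele frequency and a true per-allele exposure effect,
attaches case-control log-odds standard errors

    se = 1 / sqrt(2·p(1−p) · n · K(1−K)),

and samples observed effects from normal distributions around the truth.
Outcome effects are ``true_beta · b_j + α_j`` where α_j is a per-SNP
horizontal-pleiotropy effect controlled by ``pleiotropy_mode``:

* ``none`` — α_j = 0: all three instrumental-variable assumptions hold;
* ``balanced`` — α_j ~ N(0, sd): exclusion restriction violated but with
  zero mean, so IVW remains consistent;
* ``directional`` — α_j ~ N(mean, sd): IVW is biased; the Egger intercept
  targets ``mean``.  Setting ``inside_violation`` correlates α_j with
  instrument strength, breaking the InSIDE assumption Egger relies on.

Exposure and outcome draws are independent (non-overlapping samples).  The
true per-SNP strength spectrum is drawn from a truncated Pareto distribution
whose scale sits at the genome-wide-significance boundary (F ≈ 29.7) and
whose upper end is ≈1488, with shape solved so the mean strength is ≈116 —
the spectrum a genome-wide-significant instrument panel for a well-powered
autoimmune-disease GWAS exhibits.  For 77 such instruments in an exposure
study of n ≈ 58,000 this puts the total variance explained near 15%.

A configurable fraction of SNPs is given palindromic (A/T or C/G) alleles,
and the emitted outcome table randomly swaps allele order and strand, so the
harmonization code path is genuinely exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .errors import ConfigurationError, ValidationError
from .instruments import LDMatrix
from .summary_io import COMPLEMENT, HarmonizedPair, SummaryRecord

_NONPALINDROMIC = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]
_PALINDROMIC = [("A", "T"), ("C", "G")]
_PVAL_FLOOR = 1e-300


@dataclass(frozen=True)
class SimConfig:
    """Generating parameters for a two-sample summary-statistics study.

    Defaults describe the study conditions of a 77-instrument analysis of a
    case-control exposure GWAS (n=58,284 with 14,361 cases) against a large
    biobank outcome GWAS (n=361,822 with 682 cases), true causal log-odds
    ratio 0.19 per unit exposure.
    """

    n_snps: int = 77
    true_beta: float = 0.19
    n_exposure: int = 58_284
    n_outcome: int = 361_822
    case_fraction_exposure: float = 14_361 / 58_284
    case_fraction_outcome: float = 682 / 361_822
    eaf_range: tuple[float, float] = (0.05, 0.95)
    # true per-SNP noncentrality F ~ truncated Pareto on [f_scale, f_max]:
    # scale at the genome-wide-significance boundary (z² at p=5e-8), upper
    # truncation at the strongest instrument of the emulated panel, shape
    # solved so the mean strength is ~116
    f_scale: float = 29.7
    f_max: float = 1487.9
    f_shape: float = 1.0183
    pleiotropy_mode: str = "none"  # none | balanced | directional
    pleiotropy_sd: float = 0.0
    pleiotropy_mean: float = 0.0
    inside_violation: bool = False
    palindromic_fraction: float = 0.05
    seed: int | None = None

    def __post_init__(self):
        if self.seed is None:
            raise ConfigurationError("SimConfig requires an explicit seed")
        if self.n_snps < 1:
            raise ValidationError("n_snps must be >= 1")
        for name in ("n_exposure", "n_outcome"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("case_fraction_exposure", "case_fraction_outcome"):
            if not (0 < getattr(self, name) < 1):
                raise ValidationError(f"{name} must lie in (0, 1)")
        if not (0 < self.f_scale < self.f_max):
            raise ValidationError("requires 0 < f_scale < f_max")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ValidationError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if self.pleiotropy_mode == "none" and (
                self.pleiotropy_sd != 0 or self.pleiotropy_mean != 0):
            raise ValidationError("pleiotropy_mode='none' forces both "
                                  "pleiotropy parameters to 0")
        if self.pleiotropy_mode == "balanced" and self.pleiotropy_mean != 0:
            raise ValidationError("balanced pleiotropy requires pleiotropy_mean = 0")
        if not (0 <= self.palindromic_fraction <= 1):
            raise ValidationError("palindromic_fraction must lie in [0, 1]")


@dataclass
class SimulationTruth:
    """Generated tables paired with the parameters that produced them."""

    config: SimConfig
    true_per_snp_exposure_effects: np.ndarray
    true_pleiotropy_effects: np.ndarray
    exposure_table: list[SummaryRecord]
    outcome_table: list[SummaryRecord]
    aligned: dict = field(default_factory=dict)  # ground-truth-aligned arrays

    def to_pairs(self) -> list[HarmonizedPair]:
        """Ground-truth harmonized pairs (bypasses the allele scrambling)."""
        a = self.aligned
        out = []
        for k, ex in enumerate(self.exposure_table):
            out.append(HarmonizedPair(
                snp_id=ex.snp_id, effect_allele=ex.effect_allele,
                other_allele=ex.other_allele,
                beta_x=float(a["beta_x"][k]), se_x=float(a["se_x"][k]),
                pval_x=float(a["pval_x"][k]),
                beta_y=float(a["beta_y"][k]), se_y=float(a["se_y"][k]),
                pval_y=float(a["pval_y"][k]),
                eaf_x=float(a["eaf"][k]), eaf_y=float(a["eaf"][k]),
            ))
        return out


def _case_control_se(eaf, n, case_fraction):
    return 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * n
                         * case_fraction * (1.0 - case_fraction))


def _two_sided_p(beta, se):
    return np.maximum(2.0 * stats.norm.sf(np.abs(beta) / se), _PVAL_FLOOR)


def simulate_arrays(config: SimConfig, rng: np.random.Generator | None = None) -> dict:
    """Fast path: the generated summary arrays without record objects.

    Returns a dict with keys eaf, true_b, alpha, beta_x, se_x, pval_x,
    beta_y, se_y, pval_y — all aligned on the exposure's effect allele.
    Used by replicate studies where building thousands of record objects
    would dominate the runtime; `simulate_two_sample` builds its tables on
    top of exactly this function.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    j = config.n_snps
    eaf = rng.uniform(*config.eaf_range, size=j)
    se_x = _case_control_se(eaf, config.n_exposure, config.case_fraction_exposure)
    # inverse-CDF draw from the truncated Pareto strength spectrum
    u = rng.uniform(size=j)
    ratio_term = 1.0 - (config.f_scale / config.f_max) ** config.f_shape
    f_true = config.f_scale * (1.0 - u * ratio_term) ** (-1.0 / config.f_shape)
    sign = rng.choice([-1.0, 1.0], size=j)
    true_b = sign * np.sqrt(f_true) * se_x

    if config.pleiotropy_mode == "none":
        alpha = np.zeros(j)
    else:
        alpha = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, size=j)
        if config.inside_violation:
            # tie the pleiotropic effect to instrument strength (breaks InSIDE)
            strength = np.abs(true_b) / np.mean(np.abs(true_b))
            alpha = config.pleiotropy_mean * strength + rng.normal(
                0.0, config.pleiotropy_sd, size=j)

    beta_x = rng.normal(true_b, se_x)
    se_y = _case_control_se(eaf, config.n_outcome, config.case_fraction_outcome)
    # alpha is defined on the exposure-increasing allele ("directional" means
    # directional with respect to the exposure); on the reported allele its
    # contribution carries the allele sign
    beta_y = rng.normal(config.true_beta * true_b + sign * alpha, se_y)
    return {
        "eaf": eaf, "true_b": true_b, "alpha": alpha,
        "beta_x": beta_x, "se_x": se_x, "pval_x": _two_sided_p(beta_x, se_x),
        "beta_y": beta_y, "se_y": se_y, "pval_y": _two_sided_p(beta_y, se_y),
    }


def simulate_two_sample(config: SimConfig) -> SimulationTruth:
    """Generate a full two-sample study: exposure and outcome record tables.

    Tables regenerate bit-identically from the same config (the seed is part
    of the config).  The outcome table's allele orientation and strand are
    randomly scrambled per SNP so that downstream harmonization is exercised;
    the ``aligned`` arrays in the returned truth are the unscrambled values.
    """
    rng = np.random.default_rng(config.seed)
    arrays = simulate_arrays(config, rng)
    j = config.n_snps

    n_pal = int(round(config.palindromic_fraction * j))
    pal_mask = np.zeros(j, dtype=bool)
    if n_pal:
        pal_mask[rng.choice(j, size=n_pal, replace=False)] = True
    chroms = [str(1 + k % 22) for k in range(j)]
    positions = [1_000_000 + 2_000_000 * (k // 22) for k in range(j)]

    exposure, outcome = [], []
    for k in range(j):
        if pal_mask[k]:
            ea, oa = _PALINDROMIC[rng.integers(len(_PALINDROMIC))]
        else:
            ea, oa = _NONPALINDROMIC[rng.integers(len(_NONPALINDROMIC))]
        snp = f"rs{100000 + k}"
        eaf = float(arrays["eaf"][k])
        exposure.append(SummaryRecord(
            snp_id=snp, effect_allele=ea, other_allele=oa,
            beta=float(arrays["beta_x"][k]), se=float(arrays["se_x"][k]),
            pval=float(arrays["pval_x"][k]), eaf=eaf,
            n=config.n_exposure, chrom=chroms[k], pos=positions[k]))

        # scramble the outcome row: maybe swap allele order, maybe flip strand
        o_ea, o_oa = ea, oa
        beta_y, eaf_y = float(arrays["beta_y"][k]), eaf
        if rng.uniform() < 0.5:  # report the other allele as effect allele
            o_ea, o_oa = o_oa, o_ea
            beta_y, eaf_y = -beta_y, 1.0 - eaf_y
        if rng.uniform() < 0.3:  # report on the opposite strand
            o_ea, o_oa = COMPLEMENT[o_ea], COMPLEMENT[o_oa]
        outcome.append(SummaryRecord(
            snp_id=snp, effect_allele=o_ea, other_allele=o_oa,
            beta=beta_y, se=float(arrays["se_y"][k]),
            pval=float(arrays["pval_y"][k]), eaf=eaf_y,
            n=config.n_outcome, chrom=chroms[k], pos=positions[k]))

    return SimulationTruth(
        config=config,
        true_per_snp_exposure_effects=arrays["true_b"],
        true_pleiotropy_effects=arrays["alpha"],
        exposure_table=exposure,
        outcome_table=outcome,
        aligned=arrays,
    )


def make_block_ld_fixture(
    n_blocks: int,
    block_size: int,
    within_r2: float,
    seed: int,
    within_block_spacing_kb: float = 100.0,
    block_gap_kb: float = 50_000.0,
) -> tuple[LDMatrix, dict[str, tuple[str, int]]]:
    """Block-diagonal LD matrix with a known independent-set answer.

    All SNPs sit on one chromosome; within-block spacing keeps correlated
    SNPs inside the clumping window while the gap between blocks exceeds it,
    so both halves of the window rule are exercised.  Returns the LDMatrix
    (positions attached) and the position map.
    """
    if not (0 <= within_r2 < 1):
        raise ValidationError("within_r2 must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    n = n_blocks * block_size
    snp_ids = [f"blk{b}_snp{i}" for b in range(n_blocks) for i in range(block_size)]
    r2 = np.eye(n)
    for b in range(n_blocks):
        lo, hi = b * block_size, (b + 1) * block_size
        r2[lo:hi, lo:hi] = within_r2
    np.fill_diagonal(r2, 1.0)
    positions: dict[str, tuple[str, int]] = {}
    pos = 1_000_000
    k = 0
    for b in range(n_blocks):
        for i in range(block_size):
            jitter = int(rng.integers(0, 1000))
            positions[snp_ids[k]] = ("1", pos + jitter)
            pos += int(within_block_spacing_kb * 1000)
            k += 1
        pos += int(block_gap_kb * 1000)
    ld = LDMatrix(snp_ids=snp_ids, r2=r2, positions=positions)
    return ld, positions
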