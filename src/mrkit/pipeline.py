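"""End-to-end orchestration of the two-sample MR analysis.

Stage order: read → harmonize → select (exposure significance, LD clump,
outcome exclusion, F gate) → estimate (IVW, weighted median, MR-Egger) →
sensitivity (Q/I², Egger intercept, PRESSO, leave-one-out, funnel) → power.
A ``skip_selection`` entry point accepts a pre-harmonized instrument table
directly, for re-analysis of a published instrument list without the source
GWAS downloads.

All stochastic steps (weighted-median bootstrap, PRESSO simulations) derive
their streams from the single configured seed, so re-running with the same
config reproduces all output files byte-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigurationError, EmptyInstrumentSetError
from .estimators import estimates_table, ivw, mr_egger, weighted_median
from .instruments import (LDMatrix, build_instrument_set,
                          exclude_outcome_significant,
                          filter_exposure_significant, ld_clump,
                          variance_explained)
from .power import PowerInput, mr_power_binary
from .sensitivity import diagnostics_report, funnel_data, leave_one_out
from .summary_io import (harmonize, read_harmonized_table, read_summary_table,
                         write_harmonized_table)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one analysis run needs; YAML-loadable.

    Every printed threshold of the analysis has a config home with the
    conventional value as default.
    """

    exposure_path: str | None = None
    outcome_path: str | None = None
    exposure_column_map: dict | None = None
    outcome_column_map: dict | None = None
    delimiter: str = "\t"
    harmonized_path: str | None = None  # used when skip_selection
    skip_selection: bool = False
    ld_path: str | None = None
    ld_format: str = "wide"  # wide | long
    p_exposure: float = 5e-8
    p_outcome: float = 5e-8
    clump_r2: float = 0.001
    clump_window_kb: float = 10_000
    f_min: float = 10.0
    palindrome_eaf_window: float = 0.08
    ivw_model: str = "multiplicative_random"
    n_boot: int = 1000
    presso_n_sim: int = 1000
    seed: int | None = None
    n_exposure: int | None = None
    n_outcome: int | None = None
    case_fraction_outcome: float | None = None
    output_dir: str = "mr_output"

    def __post_init__(self):
        if self.seed is None:
            raise ConfigurationError("RunConfig requires a seed (stochastic "
                                     "steps: weighted-median bootstrap, PRESSO)")
        for name, lo, hi in (("p_exposure", 0, 1), ("p_outcome", 0, 1),
                             ("clump_r2", 0, 1), ("palindrome_eaf_window", 0, 0.5)):
            v = getattr(self, name)
            if not (lo < v <= hi):
                raise ConfigurationError(f"{name}={v} outside ({lo}, {hi}]")
        if self.skip_selection and self.harmonized_path is None:
            raise ConfigurationError("skip_selection requires harmonized_path")
        if not self.skip_selection and (self.exposure_path is None
                                        or self.outcome_path is None):
            raise ConfigurationError("exposure_path and outcome_path required")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _sub_seeds(seed: int, k: int) -> list[int]:
    """Derive k independent 31-bit seeds from the run seed."""
    return [int(s % 2**31) for s in np.random.SeedSequence(seed).generate_state(k)]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write all artifacts to ``output_dir``.

    Returns the run report (estimates, diagnostics, selection log, power) as
    a plain dict; raises :class:`EmptyInstrumentSetError` naming the stage
    that emptied the instrument set.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed_wm, seed_presso = _sub_seeds(config.seed, 2)
    selection_log: list[dict] = []

    if config.skip_selection:
        logger.info("skip_selection: reading pre-harmonized table %s",
                    config.harmonized_path)
        pairs = read_harmonized_table(config.harmonized_path,
                                      delimiter=config.delimiter)
        selection_log.append({"stage": "pre_harmonized_input",
                              "n_in": len(pairs), "n_out": len(pairs)})
    else:
        exposure = read_summary_table(config.exposure_path,
                                      config.exposure_column_map,
                                      config.delimiter)
        outcome = read_summary_table(config.outcome_path,
                                     config.outcome_column_map,
                                     config.delimiter)
        exposure = filter_exposure_significant(
            exposure, config.p_exposure, selection_log)
        if not exposure:
            raise EmptyInstrumentSetError("exposure_significance")
        if config.ld_path is not None:
            reader = (LDMatrix.from_wide if config.ld_format == "wide"
                      else LDMatrix.from_long)
            ld = reader(config.ld_path)
            exposure = ld_clump(exposure, ld, config.clump_r2,
                                config.clump_window_kb, selection_log)
            if not exposure:
                raise EmptyInstrumentSetError("ld_clump")
        else:
            logger.info("no LD matrix supplied; clumping skipped "
                        "(instruments assumed independent)")
        pairs = harmonize(exposure, outcome, config.palindrome_eaf_window)
        if not any(p.retained for p in pairs):
            raise EmptyInstrumentSetError("harmonization")
        retained = [p for p in pairs if p.retained]
        selection_log.append({"stage": "harmonization", "n_in": len(pairs),
                              "n_out": len(retained)})
        retained = exclude_outcome_significant(
            retained, config.p_outcome, selection_log)
        if not retained:
            raise EmptyInstrumentSetError("outcome_exclusion")
        pairs = retained

    instruments = build_instrument_set(
        pairs, n_exposure=config.n_exposure, f_min=config.f_min,
        selection_log=selection_log)

    est_ivw = ivw(instruments, model=config.ivw_model)
    est_wm = weighted_median(instruments, n_boot=config.n_boot, seed=seed_wm)
    est_egger, intercept = mr_egger(instruments)
    table = estimates_table([est_ivw, est_wm, est_egger])

    diagnostics = diagnostics_report(instruments, egger_intercept=intercept,
                                     seed=seed_presso,
                                     n_sim=config.presso_n_sim)
    loo = leave_one_out(instruments)
    funnel = funnel_data(instruments)

    report: dict = {
        "n_instruments": len(instruments),
        "mean_f": float(np.mean(instruments.f_stats)),
        "min_f": float(np.min(instruments.f_stats)),
        "max_f": float(np.max(instruments.f_stats)),
        "estimates": [e.to_dict() for e in (est_ivw, est_wm, est_egger)],
        "diagnostics": diagnostics,
        "selection_log": selection_log,
        "seed": config.seed,
    }
    if config.n_exposure is not None:
        report["variance_explained"] = variance_explained(
            instruments.f_stats, config.n_exposure)
    if (config.n_outcome is not None and config.case_fraction_outcome is not None
            and "variance_explained" in report
            and 0 < report["variance_explained"] < 1):
        report["power_ivw"] = mr_power_binary(PowerInput(
            n=config.n_outcome, case_fraction=config.case_fraction_outcome,
            r2_xz=report["variance_explained"], odds_ratio=est_ivw.or_))

    write_harmonized_table(instruments.pairs, outdir / "instruments.tsv")
    table.to_csv(outdir / "estimates.tsv", sep="\t", index=False)
    loo.table.to_csv(outdir / "leave_one_out.tsv", sep="\t", index=False)
    funnel.to_csv(outdir / "funnel.tsv", sep="\t", index=False)
    with open(outdir / "diagnostics.json", "w") as fh:
        json.dump(diagnostics, fh, indent=2)
    with open(outdir / "selection_log.json", "w") as fh:
        json.dump(selection_log, fh, indent=2)
    _write_summary(outdir / "summary.txt", report, table)
    logger.info("pipeline complete: %d instruments, outputs in %s",
                len(instruments), outdir)
    return report


def _write_summary(path, report, table) -> None:
    lines = [
        "Two-sample MR run summary",
        "p-values are unadjusted across estimators (no multiple-testing "
        "correction is applied).",
        "",
        f"instruments: {report['n_instruments']}",
        f"mean F: {report['mean_f']:.1f} "
        f"(range {report['min_f']:.1f}-{report['max_f']:.1f})",
    ]
    if "variance_explained" in report:
        lines.append(f"variance explained: {100 * report['variance_explained']:.1f}%")
    if "power_ivw" in report:
        lines.append(f"IVW power (binary outcome): {100 * report['power_ivw']:.0f}%")
    lines += ["", table.to_string(index=False,
                                  float_format=lambda v: f"{v:.4g}")]
    het = report["diagnostics"]["heterogeneity"]
    lines += ["", f"Cochran's Q = {het['q']:.2f} (df {het['df']}, "
                  f"p = {het['pval']:.3f}), I² = {het['i2']:.2f}% ({het['band']})"]
    if "egger_intercept" in report["diagnostics"]:
        eg = report["diagnostics"]["egger_intercept"]
        lines.append(f"Egger intercept = {eg['intercept']:.4f} "
                     f"(p = {eg['pval']:.2f})")
    if "mr_presso" in report["diagnostics"]:
        pr = report["diagnostics"]["mr_presso"]
        lines.append(f"PRESSO global p = {pr['global_pval']:.3f}, "
                     f"outliers: {len(pr['outlier_snps'])}")
    Path(path).write_text("\n".join(lines) + "\n")
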