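"""Instrument selection and quality control.

Candidate instruments are SNPs genome-wide significantly associated with the
exposure (p < 5e-8), thinned to approximate linkage-equilibrium by greedy LD
clumping (r² < 0.001 within a 10,000 kb window by default), stripped of SNPs
that are themselves genome-wide significant for the outcome, and gated on
per-SNP instrument strength F = (beta/se)² > 10.  The per-SNP variance
explained follows r² = F / (F + n − 2).

The LD panel is supplied as a precomputed matrix of pairwise r² values; this
module never computes LD from genotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EmptyInstrumentSetError, ValidationError
from .summary_io import HarmonizedPair, SummaryRecord

logger = logging.getLogger(__name__)


@dataclass
class LDMatrix:
    """Pairwise squared-correlation matrix over an ordered set of SNPs.

    ``positions`` optionally maps snp_id -> (chrom, pos) so the clumping
    window can be applied; without positions every pair is compared.
    """

    snp_ids: list[str]
    r2: np.ndarray
    positions: dict[str, tuple[str, int]] | None = None

    def __post_init__(self):
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.snp_ids)
        if self.r2.shape != (k, k):
            raise ValidationError("LD matrix shape does not match snp_ids")
        if not np.allclose(self.r2, self.r2.T):
            raise ValidationError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0):
            raise ValidationError("LD matrix diagonal must be 1")
        if self.r2.min() < 0 or self.r2.max() > 1 + 1e-12:
            raise ValidationError("LD r² values must lie in [0, 1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def lookup(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])

    @classmethod
    def from_wide(cls, path, delimiter: str = "\t") -> "LDMatrix":
        """Square matrix with SNP IDs as header row and index column."""
        df = pd.read_csv(path, sep=delimiter, index_col=0)
        return cls(snp_ids=[str(c) for c in df.columns], r2=df.to_numpy(float))

    @classmethod
    def from_long(cls, path, delimiter: str = "\t") -> "LDMatrix":
        """Long format: columns snp_a, snp_b, r2; absent pairs default to 0."""
        df = pd.read_csv(path, sep=delimiter)
        ids = sorted(set(df["snp_a"].astype(str)) | set(df["snp_b"].astype(str)))
        idx = {s: i for i, s in enumerate(ids)}
        m = np.eye(len(ids))
        for a, b, r in zip(df["snp_a"].astype(str), df["snp_b"].astype(str), df["r2"]):
            m[idx[a], idx[b]] = m[idx[b], idx[a]] = float(r)
        return cls(snp_ids=ids, r2=m)


@dataclass
class InstrumentSet:
    """The post-QC instruments all estimators consume.

    ``pairs`` holds only retained harmonized pairs; ``f_stats`` the per-SNP
    strength statistics; ``r2_exposure`` per-SNP variance explained (None when
    the exposure sample size is unknown); ``selection_log`` the ordered
    input/output counts of every filter applied upstream.
    """

    pairs: list[HarmonizedPair]
    f_stats: np.ndarray
    r2_exposure: np.ndarray | None = None
    selection_log: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def snp_ids(self) -> list[str]:
        return [p.snp_id for p in self.pairs]

    def arrays(self):
        """(beta_x, se_x, beta_y, se_y) as float arrays."""
        return (
            np.array([p.beta_x for p in self.pairs]),
            np.array([p.se_x for p in self.pairs]),
            np.array([p.beta_y for p in self.pairs]),
            np.array([p.se_y for p in self.pairs]),
        )

    def to_frame(self) -> pd.DataFrame:
        from .summary_io import HARMONIZED_COLUMNS
        df = pd.DataFrame([{c: getattr(p, c) for c in HARMONIZED_COLUMNS}
                           for p in self.pairs])
        df["f_stat"] = self.f_stats
        if self.r2_exposure is not None:
            df["r2_exposure"] = self.r2_exposure
        return df


def _log_stage(log: list[dict] | None, stage: str, n_in: int, n_out: int,
               dropped: list[str] | None = None) -> None:
    entry = {"stage": stage, "n_in": n_in, "n_out": n_out}
    if dropped:
        entry["dropped"] = dropped
    logger.info("%s: %d -> %d", stage, n_in, n_out)
    if log is not None:
        log.append(entry)


def filter_exposure_significant(
    records: list[SummaryRecord],
    p_threshold: float = 5e-8,
    selection_log: list[dict] | None = None,
) -> list[SummaryRecord]:
    """Retain records with exposure p-value strictly below the threshold."""
    kept = [r for r in records if r.pval < p_threshold]
    _log_stage(selection_log, "exposure_significance", len(records), len(kept))
    return kept


def exclude_outcome_significant(
    pairs: list[HarmonizedPair],
    p_threshold: float = 5e-8,
    selection_log: list[dict] | None = None,
) -> list[HarmonizedPair]:
    """Drop pairs genome-wide significant for the outcome (reverse-signal guard)."""
    kept = [p for p in pairs if p.pval_y >= p_threshold]
    dropped = [p.snp_id for p in pairs if p.pval_y < p_threshold]
    _log_stage(selection_log, "outcome_exclusion", len(pairs), len(kept), dropped)
    return kept


def f_statistic(beta, se):
    """Per-SNP instrument strength F = (beta / se)².

    Accepts scalars or arrays; the squared Wald z, which is what the
    conventional F > 10 weak-instrument gate uses for a single-SNP
    instrument.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValidationError("se must be > 0 for the F statistic")
    out = (beta / se) ** 2
    return float(out) if out.ndim == 0 else out


def variance_explained(f_stats, n: int) -> float:
    """Total exposure variance explained by independent instruments.

    Per SNP r²_j = F_j / (F_j + n − 2); the total is the sum over
    instruments, valid when they are mutually independent (post-clumping).
    """
    if n <= 2:
        raise ValidationError("exposure sample size must exceed 2")
    f = np.asarray(f_stats, dtype=float)
    if np.any(f < 0):
        raise ValidationError("F statistics must be non-negative")
    return float(np.sum(f / (f + n - 2)))


def ld_clump(
    records: list[SummaryRecord],
    ld: LDMatrix,
    r2_threshold: float = 0.001,
    window_kb: float = 10_000,
    selection_log: list[dict] | None = None,
) -> list[SummaryRecord]:
    """Greedy index-SNP clumping.

    Records are visited in ascending p-value order (ties: genomic coordinate,
    then snp_id); a record is kept iff its r² with every already-kept record
    on the same chromosome within ``window_kb`` is below ``r2_threshold``.
    Records absent from the LD matrix are dropped with a warning.  Records
    without chrom/pos are compared against all kept records (no window).
    """
    if not (0 < r2_threshold <= 1):
        raise ConfigurationError("r2_threshold must lie in (0, 1]")
    window_bp = window_kb * 1000.0

    def sort_key(r: SummaryRecord):
        return (r.pval, r.chrom or "", r.pos if r.pos is not None else 0, r.snp_id)

    kept: list[SummaryRecord] = []
    missing: list[str] = []
    for rec in sorted(records, key=sort_key):
        if rec.snp_id not in ld:
            missing.append(rec.snp_id)
            continue
        independent = True
        for k in kept:
            if rec.chrom is not None and k.chrom is not None:
                if rec.chrom != k.chrom:
                    continue
                if rec.pos is not None and k.pos is not None \
                        and abs(rec.pos - k.pos) > window_bp:
                    continue
            if ld.lookup(rec.snp_id, k.snp_id) >= r2_threshold:
                independent = False
                break
        if independent:
            kept.append(rec)
    if missing:
        logger.warning("ld_clump: %d SNP(s) absent from LD matrix dropped: %s",
                       len(missing), missing[:10])
    # restore a deterministic output order (by p, the index-SNP convention)
    _log_stage(selection_log, "ld_clump", len(records), len(kept))
    return kept


def apply_f_gate(
    pairs: list[HarmonizedPair],
    f_min: float = 10.0,
    selection_log: list[dict] | None = None,
) -> list[HarmonizedPair]:
    """Drop weak instruments with exposure F = (beta_x/se_x)² ≤ f_min."""
    f = np.array([f_statistic(p.beta_x, p.se_x) for p in pairs])
    kept = [p for p, fj in zip(pairs, f) if fj > f_min]
    dropped = [p.snp_id for p, fj in zip(pairs, f) if fj <= f_min]
    _log_stage(selection_log, "f_gate", len(pairs), len(kept), dropped)
    return kept


def build_instrument_set(
    pairs: list[HarmonizedPair],
    n_exposure: int | None = None,
    f_min: float = 10.0,
    selection_log: list[dict] | None = None,
) -> InstrumentSet:
    """Assemble the final InstrumentSet: retained pairs, F gate, r² per SNP."""
    log = selection_log if selection_log is not None else []
    retained = [p for p in pairs if p.retained]
    _log_stage(log, "harmonization_retained", len(pairs), len(retained))
    gated = apply_f_gate(retained, f_min=f_min, selection_log=log)
    if not gated:
        raise EmptyInstrumentSetError("f_gate")
    f = np.array([f_statistic(p.beta_x, p.se_x) for p in gated])
    r2 = None
    if n_exposure is not None:
        r2 = f / (f + n_exposure - 2)
    return InstrumentSet(pairs=gated, f_stats=f, r2_exposure=r2, selection_log=log)
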