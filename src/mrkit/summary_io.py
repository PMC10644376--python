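"""Reading, validation, and allele harmonization of GWAS summary statistics.

A two-sample Mendelian randomization analysis starts from two tables of
per-SNP association statistics: one for the exposure, one for the outcome.
Before any estimation the two tables must be expressed on the same effect
allele for every shared SNP ("harmonization").  Three situations arise:

* the outcome row already reports the exposure's effect allele — nothing to do;
* the outcome row reports the opposite allele (possibly on the opposite
  strand) — the outcome effect changes sign and the effect-allele frequency
  is complemented;
* the alleles are strand-complementary within the SNP itself (A/T or C/G,
  "palindromic") — allele labels cannot resolve strand, and the SNP is either
  aligned by allele frequency or dropped when the frequency is too close to
  0.5 to disambiguate.

This module owns the record types, the delimited-text readers/writers, and
the harmonization algorithm.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: action_flag values for retained pairs
RETAINED_FLAGS = frozenset({"unchanged", "outcome_flipped"})

#: default header names used when no column map is supplied
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "snp_id": "SNP",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pval": "pval",
    "n": "n",
    "chrom": "chrom",
    "pos": "pos",
}

_REQUIRED_FIELDS = ("snp_id", "effect_allele", "other_allele", "beta", "se", "pval")
_OPTIONAL_FIELDS = ("eaf", "n", "chrom", "pos")

HARMONIZED_COLUMNS = [
    "snp_id", "effect_allele", "other_allele",
    "beta_x", "se_x", "pval_x", "beta_y", "se_y", "pval_y",
    "eaf_x", "eaf_y", "action_flag",
]


@dataclass(frozen=True)
class SummaryRecord:
    """One SNP's association statistics in one GWAS.

    ``beta`` is the per-allele effect of ``effect_allele`` (log-odds for a
    binary trait); ``eaf`` is the effect-allele frequency.  ``eaf``, ``n``,
    ``chrom`` and ``pos`` are optional and only required by operations that
    use them (palindrome disambiguation, variance explained, windowed
    clumping).
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: float | None = None
    n: int | None = None
    chrom: str | None = None
    pos: int | None = None

    def __post_init__(self):
        if self.effect_allele not in VALID_ALLELES:
            raise ValidationError(
                f"{self.snp_id}: effect_allele {self.effect_allele!r} not in A/C/G/T")
        if self.other_allele not in VALID_ALLELES:
            raise ValidationError(
                f"{self.snp_id}: other_allele {self.other_allele!r} not in A/C/G/T")
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.snp_id}: effect_allele equals other_allele")
        if not math.isfinite(self.beta):
            raise ValidationError(f"{self.snp_id}: beta is not finite")
        if not (math.isfinite(self.se) and self.se > 0):
            raise ValidationError(f"{self.snp_id}: se must be finite and > 0")
        if not (0 < self.pval <= 1):
            raise ValidationError(f"{self.snp_id}: pval must be in (0, 1]")
        if self.eaf is not None and not (0 < self.eaf < 1):
            raise ValidationError(f"{self.snp_id}: eaf must be in (0, 1)")
        if self.n is not None and self.n <= 0:
            raise ValidationError(f"{self.snp_id}: n must be positive")


@dataclass(frozen=True)
class HarmonizedPair:
    """A SNP with exposure and outcome effects on the same effect allele.

    The allele columns carry the exposure orientation after alignment;
    ``action_flag`` records what harmonization did:

    * ``unchanged`` — outcome orientation already matched;
    * ``outcome_flipped`` — outcome beta negated, frequency complemented;
    * ``dropped_palindromic`` — strand-ambiguous and frequency could not
      disambiguate;
    * ``dropped_incompatible`` — allele sets match under neither identity,
      swap, strand complement, nor complement-swap.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta_x: float
    se_x: float
    pval_x: float
    beta_y: float
    se_y: float
    pval_y: float
    eaf_x: float | None = None
    eaf_y: float | None = None
    action_flag: str = "unchanged"

    @property
    def retained(self) -> bool:
        return self.action_flag in RETAINED_FLAGS


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is strand-complementary ({A,T} or {C,G})."""
    for a in (effect_allele, other_allele):
        if a not in VALID_ALLELES:
            raise ValidationError(f"allele {a!r} not in A/C/G/T")
    return COMPLEMENT[effect_allele] == other_allele


def swap_orientation(record: SummaryRecord) -> SummaryRecord:
    """Re-express a record on the opposite effect allele.

    Swaps the allele labels, negates beta, and complements eaf.  Applying it
    twice is the identity.
    """
    return replace(
        record,
        effect_allele=record.other_allele,
        other_allele=record.effect_allele,
        beta=-record.beta,
        eaf=None if record.eaf is None else 1.0 - record.eaf,
    )


def _coerce(field: str, raw) -> object:
    """Parse one raw cell for a SummaryRecord field; None for missing optionals."""
    if raw is None or (isinstance(raw, float) and math.isnan(raw)) or raw == "":
        if field in _REQUIRED_FIELDS:
            raise ValidationError(f"missing required field {field!r}")
        return None
    if field in ("snp_id", "chrom"):
        return str(raw)
    if field in ("effect_allele", "other_allele"):
        return str(raw).strip().upper()
    if field in ("n", "pos"):
        try:
            return int(float(raw))
        except (TypeError, ValueError):
            raise ValidationError(f"unparseable integer in field {field!r}: {raw!r}")
    try:
        return float(raw)
    except (TypeError, ValueError):
        raise ValidationError(f"unparseable numeric in field {field!r}: {raw!r}")


def read_summary_table(
    path,
    column_map: Mapping[str, str] | None = None,
    delimiter: str = "\t",
) -> list[SummaryRecord]:
    """Read a delimited GWAS summary-statistics table into validated records.

    ``column_map`` maps SummaryRecord field names to header names in the file
    (missing optional fields may simply be absent from the map).  Rows that
    fail validation are rejected with a logged row-number diagnostic naming
    the offending field; a missing mapped column raises
    :class:`ConfigurationError` before any row is read.  gzip-compressed
    input is accepted transparently.
    """
    cmap = dict(DEFAULT_COLUMN_MAP if column_map is None else column_map)
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    if column_map is None:
        # with the default map, tolerate absent optional columns
        cmap = {f: c for f, c in cmap.items()
                if c in df.columns or f in _REQUIRED_FIELDS}
    missing = [col for col in cmap.values() if col not in df.columns]
    if missing:
        raise ConfigurationError(
            f"mapped column(s) {missing} absent from header of {path}")
    for field in _REQUIRED_FIELDS:
        if field not in cmap:
            raise ConfigurationError(f"column_map lacks required field {field!r}")

    records: list[SummaryRecord] = []
    n_rejected = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        rowd = dict(zip(df.columns, row))
        try:
            kwargs = {f: _coerce(f, rowd.get(c)) for f, c in cmap.items()}
            records.append(SummaryRecord(**kwargs))
        except ValidationError as exc:
            n_rejected += 1
            logger.warning("row %d rejected: %s", i, exc)
    logger.info("read %d records, rejected %d rows from %s",
                len(records), n_rejected, path)
    return records


def write_summary_table(
    records: Iterable[SummaryRecord], path, delimiter: str = "\t"
) -> None:
    """Write records back to a delimited table using the default header names."""
    rows = [{
        "SNP": r.snp_id, "effect_allele": r.effect_allele,
        "other_allele": r.other_allele, "eaf": r.eaf, "beta": r.beta,
        "se": r.se, "pval": r.pval, "n": r.n, "chrom": r.chrom, "pos": r.pos,
    } for r in records]
    pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False)


def _orientation(exp_ea, exp_oa, out_ea, out_oa):
    """Classify outcome allele orientation relative to the exposure.

    Returns 'same', 'swap', or None (incompatible).  Strand complements are
    tried before declaring incompatibility.
    """
    if (out_ea, out_oa) == (exp_ea, exp_oa):
        return "same"
    if (out_ea, out_oa) == (exp_oa, exp_ea):
        return "swap"
    c_ea, c_oa = COMPLEMENT[out_ea], COMPLEMENT[out_oa]
    if (c_ea, c_oa) == (exp_ea, exp_oa):
        return "same"
    if (c_ea, c_oa) == (exp_oa, exp_ea):
        return "swap"
    return None


def _index_unique(records: Sequence[SummaryRecord], label: str):
    index: dict[str, SummaryRecord] = {}
    for r in records:
        if r.snp_id in index:
            raise ValidationError(f"duplicate snp_id {r.snp_id!r} in {label} table")
        index[r.snp_id] = r
    return index


def harmonize(
    exposure: Sequence[SummaryRecord],
    outcome: Sequence[SummaryRecord],
    palindrome_eaf_window: float = 0.08,
) -> list[HarmonizedPair]:
    """Align outcome effects onto the exposure's effect alleles.

    Only SNPs present in both tables are considered.  For a swapped
    orientation the outcome beta is negated and its frequency complemented.
    Palindromic SNPs are dropped when either frequency is missing or within
    ``palindrome_eaf_window`` of 0.5 (closed interval), otherwise aligned by
    frequency (same side of 0.5 means same orientation).  Output is sorted by
    snp_id, so it is independent of input row order.  Duplicate IDs within
    one table are a hard error — silent deduplication corrupts instrument
    counts.
    """
    exp_idx = _index_unique(exposure, "exposure")
    out_idx = _index_unique(outcome, "outcome")
    shared = sorted(set(exp_idx) & set(out_idx))
    logger.info("harmonize: %d exposure, %d outcome, %d shared SNPs",
                len(exp_idx), len(out_idx), len(shared))

    pairs: list[HarmonizedPair] = []
    for snp in shared:
        ex, ou = exp_idx[snp], out_idx[snp]
        base = dict(
            snp_id=snp, effect_allele=ex.effect_allele, other_allele=ex.other_allele,
            beta_x=ex.beta, se_x=ex.se, pval_x=ex.pval,
            beta_y=ou.beta, se_y=ou.se, pval_y=ou.pval,
            eaf_x=ex.eaf, eaf_y=ou.eaf,
        )
        orient = _orientation(ex.effect_allele, ex.other_allele,
                              ou.effect_allele, ou.other_allele)
        if orient is None:
            pairs.append(HarmonizedPair(**base, action_flag="dropped_incompatible"))
            continue
        if is_palindromic(ex.effect_allele, ex.other_allele):
            # allele labels cannot resolve strand; frequency must decide
            # closed interval, with an epsilon so printed boundary
            # frequencies (0.42, 0.58 at the default window) are inclusive
            # despite binary rounding
            tol = palindrome_eaf_window + 1e-12
            ambiguous = (
                ex.eaf is None or ou.eaf is None
                or abs(ex.eaf - 0.5) <= tol
                or abs(ou.eaf - 0.5) <= tol
            )
            if ambiguous:
                pairs.append(HarmonizedPair(**base, action_flag="dropped_palindromic"))
                continue
            if (ex.eaf - 0.5) * (ou.eaf - 0.5) > 0:
                pairs.append(HarmonizedPair(**base, action_flag="unchanged"))
            else:
                base.update(beta_y=-ou.beta, eaf_y=1.0 - ou.eaf)
                pairs.append(HarmonizedPair(**base, action_flag="outcome_flipped"))
            continue
        if orient == "same":
            pairs.append(HarmonizedPair(**base, action_flag="unchanged"))
        else:
            base.update(beta_y=-ou.beta,
                        eaf_y=None if ou.eaf is None else 1.0 - ou.eaf)
            pairs.append(HarmonizedPair(**base, action_flag="outcome_flipped"))

    n_kept = sum(p.retained for p in pairs)
    logger.info("harmonize: %d retained, %d dropped", n_kept, len(pairs) - n_kept)
    return pairs


def write_harmonized_table(
    pairs: Iterable[HarmonizedPair], path, delimiter: str = "\t"
) -> None:
    """Write harmonized pairs as a delimited table with a fixed column order."""
    rows = [{c: getattr(p, c) for c in HARMONIZED_COLUMNS} for p in pairs]
    pd.DataFrame(rows, columns=HARMONIZED_COLUMNS).to_csv(
        path, sep=delimiter, index=False)


def read_harmonized_table(path, delimiter: str = "\t") -> list[HarmonizedPair]:
    """Read a pre-harmonized table (the ``--skip-selection`` entry point)."""
    df = pd.read_csv(path, sep=delimiter)
    missing = [c for c in HARMONIZED_COLUMNS if c not in df.columns and c != "action_flag"]
    if missing:
        raise ConfigurationError(f"harmonized table lacks column(s) {missing}")
    pairs = []
    for _, row in df.iterrows():
        pairs.append(HarmonizedPair(
            snp_id=str(row["snp_id"]),
            effect_allele=str(row["effect_allele"]),
            other_allele=str(row["other_allele"]),
            beta_x=float(row["beta_x"]), se_x=float(row["se_x"]),
            pval_x=float(row["pval_x"]),
            beta_y=float(row["beta_y"]), se_y=float(row["se_y"]),
            pval_y=float(row["pval_y"]),
            eaf_x=None if pd.isna(row.get("eaf_x")) else float(row["eaf_x"]),
            eaf_y=None if pd.isna(row.get("eaf_y")) else float(row["eaf_y"]),
            action_flag=str(row.get("action_flag", "unchanged")),
        ))
    return pairs
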