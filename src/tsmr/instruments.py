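"""Instrument selection: p-value filtering, LD clumping, instrument strength.

Instruments for two-sample MR are independent variants robustly associated
with the exposure. Selection follows the usual three ingredients:

* a p-value screen (default ``p < 5e-7``, a suggestive threshold used when
  few variants reach genome-wide significance),
* greedy LD clumping (default 1000 kb window, ``r^2 < 0.01``) — repeatedly
  keep the most significant remaining variant as an index SNP and discard
  its correlated neighbours,
* per-SNP F-statistics, with ``F > 10`` the conventional weak-instrument
  screen.

LD is always caller-supplied as an explicit r-squared matrix; this package
never guesses a reference panel. When no LD is given, clumping falls back to
distance alone, which is conservative (removes too much, never too little).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .summary_io import SummaryStats, VariantAssociation

logger = logging.getLogger(__name__)

WEAK_INSTRUMENT_F = 10.0


class LDMatrixError(ValueError):
    """The LD matrix does not cover or describe the variants it is used on."""


@dataclass(frozen=True)
class ClumpingConfig:
    p_threshold: float = 5e-7
    window_kb: int = 1000
    r2_threshold: float = 0.01

    def __post_init__(self) -> None:
        if not (0.0 < self.p_threshold < 1.0):
            raise ValueError("p_threshold must be in (0,1)")
        if self.window_kb <= 0:
            raise ValueError("window_kb must be positive")
        if not (0.0 <= self.r2_threshold <= 1.0):
            raise ValueError("r2_threshold must be in [0,1]")


class LDMatrix:
    """Symmetric matrix of pairwise squared correlations with unit diagonal."""

    def __init__(self, variant_ids: list[str], r2: np.ndarray):
        r2 = np.asarray(r2, dtype=float)
        k = len(variant_ids)
        if r2.shape != (k, k):
            raise LDMatrixError(f"r2 shape {r2.shape} does not match {k} variant ids")
        if not np.allclose(r2, r2.T):
            raise LDMatrixError("r2 matrix is not symmetric")
        if not np.allclose(np.diag(r2), 1.0):
            raise LDMatrixError("r2 diagonal must be 1")
        if r2.min() < 0 or r2.max() > 1 + 1e-12:
            raise LDMatrixError("r2 entries must lie in [0,1]")
        self.variant_ids = list(variant_ids)
        self.r2 = r2
        self._pos = {v: i for i, v in enumerate(self.variant_ids)}

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._pos

    def r2_between(self, a: str, b: str) -> float:
        try:
            return float(self.r2[self._pos[a], self._pos[b]])
        except KeyError as exc:
            raise LDMatrixError(f"variant {exc.args[0]!r} not in LD matrix") from None

    @classmethod
    def read(cls, path: str | Path, delimiter: str = "\t") -> "LDMatrix":
        df = pd.read_csv(path, sep=delimiter)
        return cls(list(df.columns), df.to_numpy(dtype=float))

    def write(self, path: str | Path, delimiter: str = "\t") -> None:
        pd.DataFrame(self.r2, columns=self.variant_ids).to_csv(
            path, sep=delimiter, index=False, float_format="%.10g"
        )


def filter_by_pvalue(stats: SummaryStats, p_threshold: float = 5e-7) -> SummaryStats:
    """Keep records with ``pvalue`` strictly below ``p_threshold`` (order preserved)."""
    return stats.subset([r for r in stats if r.pvalue < p_threshold])


def _tie_key(rec: VariantAssociation) -> tuple:
    # deterministic across runs and input orderings
    return (rec.pvalue, rec.chrom or "", rec.pos or 0, rec.variant_id)


def clump(
    stats: SummaryStats, config: Optional[ClumpingConfig] = None, ld: Optional[LDMatrix] = None
) -> SummaryStats:
    """Greedy p-value clumping to a set of independent index SNPs.

    Repeatedly promote the remaining record with the smallest p-value (ties
    broken by chrom, pos, variant_id) to index SNP and remove every remaining
    record on the same chromosome within ``window_kb`` of it that, when an LD
    matrix is supplied, also has ``r^2 >= r2_threshold`` with it. Without LD,
    distance alone removes, with a logged warning. Cross-chromosome pairs
    never clump.
    """
    config = config or ClumpingConfig()
    if ld is None:
        logger.warning("clumping without LD matrix: removing by distance alone (conservative)")
        missing_pos = [r.variant_id for r in stats if r.chrom is None or r.pos is None]
        if missing_pos:
            raise ValueError(
                "distance-only clumping needs chrom/pos on all records; missing for "
                + ", ".join(missing_pos[:5])
            )
    else:
        absent = [r.variant_id for r in stats if r.variant_id not in ld]
        if absent:
            raise LDMatrixError("LD matrix missing variants: " + ", ".join(absent))

    window_bp = config.window_kb * 1000
    remaining = sorted(stats.records, key=_tie_key)
    index_snps: list[VariantAssociation] = []
    while remaining:
        idx = remaining.pop(0)
        index_snps.append(idx)
        survivors = []
        for rec in remaining:
            same_chrom = idx.chrom is not None and rec.chrom == idx.chrom
            within = (
                same_chrom
                and idx.pos is not None
                and rec.pos is not None
                and abs(rec.pos - idx.pos) <= window_bp
            )
            if ld is None:
                remove = within
            else:
                # without positions the distance clause cannot veto; LD decides
                if idx.pos is None or rec.pos is None:
                    within = True
                remove = within and ld.r2_between(idx.variant_id, rec.variant_id) >= config.r2_threshold
            if not remove:
                survivors.append(rec)
        remaining = survivors
    return stats.subset(index_snps)


def f_statistic(rec: VariantAssociation, method: str = "wald") -> float:
    """Single-SNP instrument-strength F-statistic.

    ``wald`` uses the (beta/se)^2 approximation, which needs no allele
    frequency or sample size. ``variance_explained`` uses the explained
    variance route ``r2 = 2 maf (1-maf) beta^2`` (standardized trait) with
    ``F = (n-2) r2 / (1-r2)`` and requires ``eaf`` and ``n``.
    """
    if rec.se is None or rec.se <= 0:
        raise ValueError(f"{rec.variant_id}: F-statistic requires se > 0")
    if method == "wald":
        return float((rec.beta / rec.se) ** 2)
    if method == "variance_explained":
        if rec.eaf is None or rec.n is None:
            raise ValueError(f"{rec.variant_id}: variance_explained F needs eaf and n")
        maf = min(rec.eaf, 1.0 - rec.eaf)
        r2 = 2.0 * maf * (1.0 - maf) * rec.beta**2
        if r2 >= 1.0:
            raise ValueError(f"{rec.variant_id}: explained variance >= 1")
        return float((rec.n - 2) * r2 / (1.0 - r2))
    raise ValueError(f"unknown F-statistic method {method!r}")


@dataclass
class InstrumentReport:
    """Per-SNP instrument strength plus summary statistics."""

    table: pd.DataFrame  # columns: variant_id, F
    min_f: float
    mean_f: float

    def all_above(self, threshold: float = WEAK_INSTRUMENT_F) -> bool:
        return bool(self.min_f > threshold)


def instrument_report(stats: SummaryStats, method: str = "wald") -> InstrumentReport:
    """Tabulate per-SNP F-statistics for an instrument set."""
    if not stats.records:
        raise ValueError("instrument_report needs a non-empty instrument set")
    fs = [f_statistic(r, method=method) for r in stats]
    table = pd.DataFrame({"variant_id": [r.variant_id for r in stats], "F": fs})
    return InstrumentReport(table=table, min_f=float(min(fs)), mean_f=float(np.mean(fs)))


__all__ = [
    "ClumpingConfig",
    "InstrumentReport",
    "LDMatrix",
    "LDMatrixError",
    "WEAK_INSTRUMENT_F",
    "clump",
    "f_statistic",
    "filter_by_pvalue",
    "instrument_report",
]
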