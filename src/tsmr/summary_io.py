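"""Reading, validating and writing GWAS summary statistics.

Summary statistics travel as delimited text with a header row. Canonical
column names are ``variant_id, chrom, pos, effect_allele, other_allele, eaf,
beta, se, pvalue, n``; arbitrary source layouts are accommodated through a
:class:`ColumnMap`. Positions are 1-based, the usual GWAS convention. For
binary traits ``beta`` is a log odds ratio per effect allele; for
quantitative traits it is in SD units.

Delimiter auto-detection is deliberately not attempted: the delimiter is an
explicit part of the column map so that a run is reproducible from its
configuration alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Optional, Sequence

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

CANONICAL_FIELDS = (
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
)
#: fields a usable association record cannot do without
REQUIRED_FIELDS = ("variant_id", "effect_allele", "other_allele", "beta", "se", "pvalue")

_VALID_BASES = frozenset("ACGT")


class ConfigurationError(ValueError):
    """A column map does not match the file it is applied to."""


class SummaryStatsError(ValueError):
    """The file content violates a dataset-level invariant (e.g. duplicate IDs)."""


@dataclass(frozen=True)
class VariantAssociation:
    """One SNP's association record in one GWAS.

    Alleles are uppercase strings over {A,C,G,T}; multi-character (indel)
    alleles are tolerated by validation but cannot be strand-resolved
    downstream.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    chrom: Optional[str] = None
    pos: Optional[int] = None
    eaf: Optional[float] = None
    n: Optional[float] = None


def validate_record(rec: VariantAssociation) -> list[str]:
    """Return human-readable invariant violations for ``rec`` (empty = valid).

    Reports rather than raises so ingestion can count and log bad rows.
    """
    violations: list[str] = []
    if not rec.variant_id:
        violations.append("empty variant_id")
    ea, oa = rec.effect_allele, rec.other_allele
    if not ea or not oa:
        violations.append("missing allele")
    else:
        if ea == oa:
            violations.append("effect_allele equals other_allele")
        for label, allele in (("effect_allele", ea), ("other_allele", oa)):
            if not set(allele) <= _VALID_BASES:
                violations.append(f"{label} has non-ACGT characters: {allele!r}")
    if rec.beta is None or not pd.notna(rec.beta):
        violations.append("missing beta")
    if rec.se is None or not pd.notna(rec.se):
        violations.append("missing SE")
    elif rec.se <= 0:
        violations.append("nonpositive SE")
    if rec.pvalue is None or not pd.notna(rec.pvalue):
        violations.append("missing pvalue")
    elif not (0.0 < rec.pvalue <= 1.0):
        violations.append("pvalue out of (0,1]")
    if rec.eaf is not None and not (0.0 <= rec.eaf <= 1.0):
        violations.append("eaf out of [0,1]")
    if rec.pos is not None and rec.pos < 1:
        violations.append("pos not 1-based positive")
    return violations


@dataclass
class SummaryStats:
    """A trait-labelled collection of association records, unique by variant ID."""

    trait_name: str
    records: list[VariantAssociation]
    trait_type: str = "binary"  # "binary" (log-odds betas) or "quantitative"
    ancestry: str = "unspecified"

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "quantitative"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        ids = [r.variant_id for r in self.records]
        dupes = sorted({v for v in ids if ids.count(v) > 1}) if len(set(ids)) != len(ids) else []
        if dupes:
            raise SummaryStatsError(f"duplicate variant_id values: {', '.join(dupes)}")
        self._index = {r.variant_id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[VariantAssociation]:
        return iter(self.records)

    def get(self, variant_id: str) -> Optional[VariantAssociation]:
        return self._index.get(variant_id)

    def subset(self, keep: Sequence[VariantAssociation]) -> "SummaryStats":
        """A new SummaryStats with the same metadata and the given records."""
        return SummaryStats(
            trait_name=self.trait_name,
            records=list(keep),
            trait_type=self.trait_type,
            ancestry=self.ancestry,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [{f: getattr(r, f) for f in CANONICAL_FIELDS} for r in self.records]
        return pd.DataFrame(rows, columns=list(CANONICAL_FIELDS))


@dataclass(frozen=True)
class ColumnMap:
    """Mapping from canonical field names to source column headers.

    ``mapping`` only needs entries for columns whose header differs from the
    canonical name; unmapped optional fields absent from the file are simply
    left unset.
    """

    mapping: dict = field(default_factory=dict)
    delimiter: str = "\t"
    missing_token: str = "NA"

    def source_column(self, canonical: str) -> str:
        return self.mapping.get(canonical, canonical)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ColumnMap":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(
            mapping=doc.get("mapping", {}),
            delimiter=doc.get("delimiter", "\t"),
            missing_token=doc.get("missing_token", "NA"),
        )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "mapping": dict(self.mapping),
                    "delimiter": self.delimiter,
                    "missing_token": self.missing_token,
                },
                fh,
            )


@dataclass
class ReadReport:
    """Per-file ingestion accounting: rows in = records kept + rejected."""

    n_rows: int = 0
    n_kept: int = 0
    rejections: list[tuple[int, str, str]] = field(default_factory=list)  # (row, id, reason)

    @property
    def n_rejected(self) -> int:
        return len(self.rejections)


def _parse_float(token, what: str, row: int, errors: list[str]) -> Optional[float]:
    if token is None or (isinstance(token, float) and pd.isna(token)) or token == "":
        return None
    try:
        return float(token)
    except (TypeError, ValueError):
        errors.append(f"unparseable {what}: {token!r}")
        return None


def read_summary_stats(
    path: str | Path,
    column_map: Optional[ColumnMap] = None,
    *,
    trait_name: str,
    trait_type: str = "binary",
    ancestry: str = "unspecified",
) -> tuple[SummaryStats, ReadReport]:
    """Read one GWAS summary-statistics table.

    Rows failing validation are recorded in the returned :class:`ReadReport`
    with the reason, never silently dropped. Duplicate variant IDs among
    valid rows raise :class:`SummaryStatsError` listing the duplicates, and a
    required column missing from the header raises
    :class:`ConfigurationError` naming it.
    """
    cmap = column_map or ColumnMap()
    df = pd.read_csv(
        path,
        sep=cmap.delimiter,
        dtype=str,
        na_values=[cmap.missing_token],
        keep_default_na=False,
    )
    for canonical in REQUIRED_FIELDS:
        col = cmap.source_column(canonical)
        if col not in df.columns:
            raise ConfigurationError(
                f"required column {col!r} (canonical {canonical!r}) not in header of {path}"
            )
    have = {f: cmap.source_column(f) for f in CANONICAL_FIELDS if cmap.source_column(f) in df.columns}

    report = ReadReport(n_rows=len(df))
    records: list[VariantAssociation] = []
    for row_idx, row in enumerate(df.itertuples(index=False), start=1):
        row_d = dict(zip(df.columns, row))
        errors: list[str] = []
        vid = row_d.get(have["variant_id"])
        vid = "" if vid is None or pd.isna(vid) else str(vid).strip()
        beta = _parse_float(row_d.get(have["beta"]), "beta", row_idx, errors)
        se = _parse_float(row_d.get(have["se"]), "se", row_idx, errors)
        pvalue = _parse_float(row_d.get(have["pvalue"]), "pvalue", row_idx, errors)
        eaf = n = None
        if "eaf" in have:
            eaf = _parse_float(row_d.get(have["eaf"]), "eaf", row_idx, errors)
        if "n" in have:
            n = _parse_float(row_d.get(have["n"]), "n", row_idx, errors)
        chrom = pos = None
        if "chrom" in have:
            raw = row_d.get(have["chrom"])
            chrom = None if raw is None or pd.isna(raw) else str(raw).strip()
        if "pos" in have:
            pos_f = _parse_float(row_d.get(have["pos"]), "pos", row_idx, errors)
            pos = int(pos_f) if pos_f is not None else None
        ea = row_d.get(have["effect_allele"])
        oa = row_d.get(have["other_allele"])
        rec = VariantAssociation(
            variant_id=vid,
            effect_allele="" if ea is None or pd.isna(ea) else str(ea).strip().upper(),
            other_allele="" if oa is None or pd.isna(oa) else str(oa).strip().upper(),
            beta=beta if beta is not None else float("nan"),
            se=se if se is not None else float("nan"),
            pvalue=pvalue if pvalue is not None else float("nan"),
            chrom=chrom,
            pos=pos,
            eaf=eaf,
            n=n,
        )
        errors.extend(validate_record(rec))
        if errors:
            report.rejections.append((row_idx, vid, "; ".join(errors)))
        else:
            records.append(rec)
    report.n_kept = len(records)
    if report.n_rejected:
        logger.warning(
            "%s: rejected %d/%d rows during ingestion", path, report.n_rejected, report.n_rows
        )
    stats = SummaryStats(
        trait_name=trait_name, records=records, trait_type=trait_type, ancestry=ancestry
    )
    return stats, report


def write_summary_stats(
    stats: SummaryStats, path: str | Path, column_map: Optional[ColumnMap] = None
) -> None:
    """Write ``stats`` as delimited text, numeric fields at full precision.

    Refuses to write an empty dataset (an empty file is indistinguishable
    from a failed extraction downstream).
    """
    if not stats.records:
        raise ValueError("refusing to write empty SummaryStats")
    cmap = column_map or ColumnMap()
    df = stats.to_frame()
    df = df.rename(columns={f: cmap.source_column(f) for f in CANONICAL_FIELDS})
    df.to_csv(
        path,
        sep=cmap.delimiter,
        index=False,
        na_rep=cmap.missing_token,
        float_format="%.15g",
    )


__all__ = [
    "CANONICAL_FIELDS",
    "REQUIRED_FIELDS",
    "ColumnMap",
    "ConfigurationError",
    "ReadReport",
    "SummaryStats",
    "SummaryStatsError",
    "VariantAssociation",
    "read_summary_stats",
    "replace",
    "validate_record",
    "write_summary_stats",
]
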