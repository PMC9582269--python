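"""Reading, validating and writing GWAS summary-statistics tables.

A summary-statistics file is a delimited text table with one row per SNP
and a header naming at least the canonical columns::

    rsid  chrom  pos  effect_allele  other_allele  eaf  beta  se  pval  n

Files exported by different consortia use different column names; a
``column_map`` translates them on read.  Rows violating basic sanity
constraints (non-positive SE, frequency outside [0, 1], identical
alleles, ...) are rejected individually and reported rather than
aborting the whole load.
"""

from __future__ import annotations

import math
import sys
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_COLUMNS",
    "SnpRecord",
    "SummaryStats",
    "RejectedRow",
    "read_sumstats",
    "write_sumstats",
    "write_rejection_report",
]

CANONICAL_COLUMNS = (
    "rsid",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
)

_VALID_BASES = frozenset("ACGT")

#: Smallest positive double; substituted for p-values of exactly zero so
#: downstream -log10 transforms stay finite.
TINY_P = sys.float_info.min


class SumstatsError(ValueError):
    """Fatal problem with a summary-statistics table (missing column,
    duplicate rsid, unparsable file)."""


@dataclass(frozen=True, slots=True)
class SnpRecord:
    """One SNP association: alleles, frequency and effect estimate.

    ``beta`` is the per-effect-allele change in the trait; for binary
    traits it is on the log-odds scale.
    """

    rsid: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: int

    def validate(self) -> str | None:
        """Return a reason string if the record is invalid, else None."""
        if not self.rsid:
            return "empty_rsid"
        if self.pos < 1:
            return "pos_below_1"
        if self.effect_allele == self.other_allele:
            return "identical_alleles"
        if not (0.0 <= self.eaf <= 1.0) or not math.isfinite(self.eaf):
            return "eaf_out_of_range"
        if not math.isfinite(self.beta):
            return "beta_not_finite"
        if not (self.se > 0) or not math.isfinite(self.se):
            return "se_not_positive"
        if not (0.0 < self.pval <= 1.0):
            return "pval_out_of_range"
        if self.n <= 0:
            return "n_not_positive"
        return None

    @property
    def is_snv(self) -> bool:
        """True for single-base substitutions; indels are accepted on
        read but cannot be harmonized."""
        return (
            self.effect_allele in _VALID_BASES
            and self.other_allele in _VALID_BASES
        )


@dataclass(frozen=True, slots=True)
class RejectedRow:
    rsid: str
    row_index: int
    reason: str


@dataclass
class SummaryStats:
    """Ordered SNP association table for one trait.

    ``table`` holds the canonical columns (see :data:`CANONICAL_COLUMNS`)
    with unique rsids; ``trait_type`` marks whether beta is a log-odds
    (binary) or a unit-scale (continuous) effect.
    """

    trait_name: str
    trait_type: str  # "binary" | "continuous"
    table: pd.DataFrame
    rejected: list[RejectedRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "continuous"):
            raise SumstatsError(
                f"trait_type must be 'binary' or 'continuous', got "
                f"{self.trait_type!r}"
            )
        missing = [c for c in CANONICAL_COLUMNS if c not in self.table.columns]
        if missing:
            raise SumstatsError(f"missing canonical columns: {missing}")
        dup = self.table["rsid"][self.table["rsid"].duplicated()]
        if len(dup):
            raise SumstatsError(f"duplicate rsid: {dup.iloc[0]!r}")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def records(self) -> list[SnpRecord]:
        return [
            SnpRecord(
                rsid=row.rsid,
                chrom=str(row.chrom),
                pos=int(row.pos),
                effect_allele=row.effect_allele,
                other_allele=row.other_allele,
                eaf=float(row.eaf),
                beta=float(row.beta),
                se=float(row.se),
                pval=float(row.pval),
                n=int(row.n),
            )
            for row in self.table.itertuples(index=False)
        ]

    @classmethod
    def from_records(
        cls,
        trait_name: str,
        trait_type: str,
        records: Iterable[SnpRecord],
    ) -> "SummaryStats":
        rows = list(records)
        table = pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))
        if not rows:
            table = _empty_table()
        return cls(trait_name=trait_name, trait_type=trait_type, table=table)

    def lookup(self, rsid: str) -> SnpRecord | None:
        hit = self.table[self.table["rsid"] == rsid]
        if hit.empty:
            return None
        row = hit.iloc[0]
        return SnpRecord(
            rsid=row["rsid"],
            chrom=str(row["chrom"]),
            pos=int(row["pos"]),
            effect_allele=row["effect_allele"],
            other_allele=row["other_allele"],
            eaf=float(row["eaf"]),
            beta=float(row["beta"]),
            se=float(row["se"]),
            pval=float(row["pval"]),
            n=int(row["n"]),
        )


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "rsid": pd.Series(dtype=str),
            "chrom": pd.Series(dtype=str),
            "pos": pd.Series(dtype=np.int64),
            "effect_allele": pd.Series(dtype=str),
            "other_allele": pd.Series(dtype=str),
            "eaf": pd.Series(dtype=float),
            "beta": pd.Series(dtype=float),
            "se": pd.Series(dtype=float),
            "pval": pd.Series(dtype=float),
            "n": pd.Series(dtype=np.int64),
        }
    )


def _detect_delimiter(header_line: str) -> str:
    # Tab preferred; comma fallback. Both occur in public GWAS exports.
    return "\t" if "\t" in header_line else ","


def read_sumstats(
    path,
    column_map: Mapping[str, str] | None = None,
    trait_type: str = "binary",
    trait_name: str | None = None,
) -> SummaryStats:
    """Load a delimited summary-statistics file.

    Parameters
    ----------
    path
        Tab- or comma-delimited file with a header row.
    column_map
        Mapping from canonical name to the file's column name, for files
        whose headers differ from the canonical ones.  Only the names
        that differ need to be listed.
    trait_type
        "binary" (beta on log-odds scale) or "continuous".
    trait_name
        Label for the trait; defaults to the file stem.

    Rows that fail per-record validation are dropped and recorded on the
    returned object's ``rejected`` list.  A missing mandatory column or
    a duplicated rsid is fatal.
    """
    path = str(path)
    with open(path, "rt") as fh:
        header_line = fh.readline()
    if not header_line.strip():
        raise SumstatsError(f"{path}: empty file")
    sep = _detect_delimiter(header_line)

    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    rename = {}
    if column_map:
        rename = {v: k for k, v in column_map.items()}
        frame = frame.rename(columns=rename)
    missing = [c for c in CANONICAL_COLUMNS if c not in frame.columns]
    if missing:
        raise SumstatsError(
            f"{path}: missing mandatory column(s) {missing}; "
            f"provide a column_map"
        )

    records: list[SnpRecord] = []
    rejected: list[RejectedRow] = []
    for i, row in enumerate(frame.itertuples(index=False)):
        raw = dict(zip(frame.columns, row))
        try:
            pval = float(raw["pval"])
            if pval == 0.0:
                # keep the row usable for log transforms downstream
                pval = TINY_P
            rec = SnpRecord(
                rsid=raw["rsid"].strip(),
                chrom=str(raw["chrom"]).strip(),
                pos=int(float(raw["pos"])),
                effect_allele=raw["effect_allele"].strip().upper(),
                other_allele=raw["other_allele"].strip().upper(),
                eaf=float(raw["eaf"]),
                beta=float(raw["beta"]),
                se=float(raw["se"]),
                pval=pval,
                n=int(float(raw["n"])),
            )
        except (ValueError, KeyError):
            rejected.append(
                RejectedRow(rsid=str(raw.get("rsid", "?")), row_index=i,
                            reason="unparsable_field")
            )
            continue
        reason = rec.validate()
        if reason is not None:
            rejected.append(
                RejectedRow(rsid=rec.rsid, row_index=i, reason=reason)
            )
            continue
        records.append(rec)

    seen: set[str] = set()
    for rec in records:
        if rec.rsid in seen:
            raise SumstatsError(f"{path}: duplicate rsid {rec.rsid!r}")
        seen.add(rec.rsid)

    name = trait_name if trait_name is not None else _stem(path)
    stats = SummaryStats.from_records(name, trait_type, records)
    stats.rejected = rejected
    return stats


def _stem(path: str) -> str:
    base = path.rsplit("/", 1)[-1]
    return base.rsplit(".", 1)[0] if "." in base else base


def write_sumstats(stats: SummaryStats, path) -> None:
    """Write a tab-delimited file with the canonical header.

    Floats are rendered with 17 significant digits so that a
    read-after-write round-trip reproduces every field bit-exactly.
    """
    table = stats.table
    with open(str(path), "wt") as fh:
        fh.write("\t".join(CANONICAL_COLUMNS) + "\n")
        for row in table.itertuples(index=False):
            fh.write(
                "\t".join(
                    [
                        str(row.rsid),
                        str(row.chrom),
                        str(int(row.pos)),
                        str(row.effect_allele),
                        str(row.other_allele),
                        format(float(row.eaf), ".17g"),
                        format(float(row.beta), ".17g"),
                        format(float(row.se), ".17g"),
                        format(float(row.pval), ".17g"),
                        str(int(row.n)),
                    ]
                )
                + "\n"
            )


def write_rejection_report(rejected: list[RejectedRow], path) -> None:
    """Write the per-row rejection report as TSV (rsid, row, reason)."""
    with open(str(path), "wt") as fh:
        fh.write("rsid\trow_index\treason\n")
        for r in rejected:
            fh.write(f"{r.rsid}\t{r.row_index}\t{r.reason}\n")
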