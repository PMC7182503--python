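"""Reading, validating and writing GWAS summary-statistic tables.

The canonical on-disk dialect is a TSV (or CSV) with a header row and one
row per SNP.  Third-party headers are adapted through a ``column_map`` that
maps the canonical field names to the file's column names.  Canonical
fields::

    snp_id          variant identifier (rsID or synthetic id)
    effect_allele   single base A/C/G/T
    other_allele    single base A/C/G/T
    eaf             effect-allele frequency, optional, strictly in (0, 1)
    beta            per-allele effect (SD units, or log-odds for binary traits)
    se              standard error, > 0
    pval            p-value in (0, 1], optional
    n               per-SNP sample size, optional
    chrom, pos      optional coordinates (pos 1-based)

Rows violating the invariants are dropped, counted per reason and reported
in a :class:`LoadReport` attached to the returned table.
"""

from __future__ import annotations

import dataclasses
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigError, InputError

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")

CANONICAL_COLUMNS = (
    "snp_id", "effect_allele", "other_allele", "eaf",
    "beta", "se", "pval", "n", "chrom", "pos",
)
MANDATORY_COLUMNS = ("snp_id", "effect_allele", "other_allele", "beta", "se")
OPTIONAL_COLUMNS = tuple(c for c in CANONICAL_COLUMNS if c not in MANDATORY_COLUMNS)

#: serialization precision: 12 significant digits round-trips float estimates
#: beyond reporting precision
FLOAT_FORMAT = "%.12g"


@dataclass
class LoadReport:
    """Row accounting for one :func:`read_gwas` call."""

    rows_read: int = 0
    rows_kept: int = 0
    dropped: dict[str, int] = field(default_factory=dict)

    def log_lines(self) -> list[str]:
        lines = [f"rows read: {self.rows_read}", f"rows kept: {self.rows_kept}"]
        lines += [f"rows dropped ({reason}): {k}" for reason, k in sorted(self.dropped.items())]
        return lines


@dataclass
class GWASTable:
    """One trait's per-SNP summary statistics plus trait metadata.

    ``data`` holds the canonical columns; ``snp_id`` values are unique.
    """

    trait_name: str
    data: pd.DataFrame
    n_total: int = 0
    is_binary: bool = False
    trait_unit: str = ""
    load_report: LoadReport | None = None

    def __post_init__(self) -> None:
        if self.data["snp_id"].duplicated().any():
            raise InputError(f"duplicate snp_id in table '{self.trait_name}'")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.data["snp_id"])

    def restrict(self, snp_ids) -> "GWASTable":
        """Subset to ``snp_ids``, preserving the given order where present."""
        sub = self.data.set_index("snp_id", drop=False)
        keep = [s for s in snp_ids if s in sub.index]
        return dataclasses.replace(
            self, data=sub.loc[keep].reset_index(drop=True), load_report=None
        )


def _validate_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, Counter]:
    dropped: Counter = Counter()
    keep = pd.Series(True, index=df.index)

    def drop(mask: pd.Series, reason: str) -> None:
        mask = mask & keep
        if mask.any():
            dropped[reason] += int(mask.sum())
            keep[mask] = False

    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.strip().str.upper()
    drop(df["snp_id"].isna() | (df["snp_id"].astype(str).str.len() == 0), "missing_snp_id")
    single_base = df["effect_allele"].isin(VALID_ALLELES) & df["other_allele"].isin(VALID_ALLELES)
    drop(~single_base, "invalid_alleles")  # indels / multi-allelic codes included here
    drop(df["effect_allele"] == df["other_allele"], "identical_alleles")
    drop(df["beta"].isna() | df["se"].isna(), "missing_beta_or_se")
    drop(~(df["se"] > 0), "nonpositive_se")
    if "eaf" in df:
        drop(df["eaf"].notna() & ~((df["eaf"] > 0) & (df["eaf"] < 1)), "eaf_out_of_range")
    if "pval" in df:
        drop(df["pval"].notna() & ~((df["pval"] > 0) & (df["pval"] <= 1)), "pval_out_of_range")
    if "n" in df:
        drop(df["n"].notna() & ~(df["n"] > 0), "nonpositive_n")
    drop(df["snp_id"].duplicated(keep="first"), "duplicate_snp_id")
    return df[keep].reset_index(drop=True), dropped


def read_gwas(
    path,
    column_map: dict[str, str] | None = None,
    *,
    trait_name: str | None = None,
    n_total: int = 0,
    is_binary: bool = False,
    trait_unit: str = "",
    sep: str | None = None,
) -> GWASTable:
    """Read a summary-statistics file into a validated :class:`GWASTable`.

    Parameters
    ----------
    path
        TSV/CSV file with a header row.
    column_map
        Mapping from canonical names (see module docstring) to the file's
        column names.  May be omitted when the file already uses canonical
        names.  Must cover ``snp_id, effect_allele, other_allele, beta, se``.
    sep
        Field separator; inferred from the extension when ``None``
        (``.csv`` -> comma, otherwise tab).

    Raises
    ------
    ConfigError
        A mandatory column is missing (the message names it).
    InputError
        The file has no data rows.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    raw = pd.read_csv(path, sep=sep, dtype={0: str})
    if raw.empty:
        raise InputError(f"empty GWAS file: {path}")

    column_map = dict(column_map or {})
    for canonical in CANONICAL_COLUMNS:
        column_map.setdefault(canonical, canonical)
    for canonical in MANDATORY_COLUMNS:
        if column_map[canonical] not in raw.columns:
            raise ConfigError(
                f"mandatory column '{canonical}' (file column "
                f"'{column_map[canonical]}') missing from {path.name}"
            )

    df = pd.DataFrame({"snp_id": raw[column_map["snp_id"]].astype(str)})
    for canonical in CANONICAL_COLUMNS[1:]:
        src = column_map[canonical]
        if src in raw.columns:
            df[canonical] = raw[src]
        elif canonical not in ("chrom", "pos"):
            df[canonical] = np.nan
    for col in ("eaf", "beta", "se", "pval", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    n_read = len(df)
    df, dropped = _validate_rows(df)
    report = LoadReport(rows_read=n_read, rows_kept=len(df), dropped=dict(dropped))
    for line in report.log_lines():
        logger.info("%s: %s", path.name, line)
    return GWASTable(
        trait_name=trait_name or path.stem,
        data=df,
        n_total=n_total,
        is_binary=is_binary,
        trait_unit=trait_unit,
        load_report=report,
    )


def _as_frame(records) -> pd.DataFrame:
    """Coerce supported result objects to a DataFrame for serialization."""
    if isinstance(records, pd.DataFrame):
        return records
    if isinstance(records, GWASTable):
        return records.data
    if hasattr(records, "pairs") and isinstance(records.pairs, pd.DataFrame):
        return records.pairs  # HarmonizedTable
    if isinstance(records, (list, tuple)):
        rows = []
        for item in records:
            if dataclasses.is_dataclass(item) and not isinstance(item, type):
                rows.append(dataclasses.asdict(item))
            elif isinstance(item, dict):
                rows.append(item)
            else:
                raise InputError(f"cannot serialize record of type {type(item).__name__}")
        return pd.DataFrame(rows)
    if dataclasses.is_dataclass(records) and not isinstance(records, type):
        return pd.DataFrame([dataclasses.asdict(records)])
    raise InputError(f"cannot serialize object of type {type(records).__name__}")


def write_table(records, path) -> None:
    """Write a tabular result as TSV with deterministic column order.

    Floats are serialized with 12 significant digits so that write/read
    round-trips preserve estimates to (beyond) reporting precision.  Empty
    input is an error and creates no file.
    """
    frame = _as_frame(records)
    if len(frame) == 0:
        raise InputError("refusing to write an empty table")
    frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
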