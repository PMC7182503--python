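"""Instrument construction for two-sample MR.

Covers genome-wide-significance filtering, greedy LD clumping against a
supplied r-squared matrix, proxy substitution for SNPs missing from an
outcome dataset, secondary-trait (e.g. household income) filtering at a
Bonferroni-corrected threshold, and the sample-overlap fraction used to
gauge weak-instrument bias from overlapping cohorts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InputError
from .gwas_io import GWASTable

logger = logging.getLogger(__name__)

GENOME_WIDE_P = 5e-8


@dataclass
class LDMatrix:
    """Pairwise LD r-squared between candidate SNPs.

    ``r2`` is square and symmetric with unit diagonal, values in [0, 1];
    ``chrom``/``pos`` optionally carry per-SNP coordinates (pos in bp).
    """

    snp_ids: list[str]
    r2: np.ndarray
    chrom: dict[str, str] | None = None
    pos: dict[str, int] | None = None

    def validate(self) -> "LDMatrix":
        r2 = np.asarray(self.r2, dtype=float)
        n = len(self.snp_ids)
        if r2.shape != (n, n):
            raise InputError(f"LD matrix shape {r2.shape} does not match {n} snp_ids")
        if not np.allclose(r2, r2.T, atol=1e-8):
            raise InputError("LD matrix is not symmetric")
        if not np.allclose(np.diag(r2), 1.0, atol=1e-8):
            raise InputError("LD matrix diagonal must be 1")
        if np.nanmin(r2) < -1e-12 or np.nanmax(r2) > 1 + 1e-12:
            raise InputError("LD r2 values must lie in [0, 1]")
        return self

    @classmethod
    def identity(cls, snp_ids) -> "LDMatrix":
        ids = list(snp_ids)
        return cls(snp_ids=ids, r2=np.eye(len(ids)))

    @classmethod
    def from_tsv(cls, path, pos_path=None) -> "LDMatrix":
        """Load from TSV: first column snp_id, remaining columns the square
        matrix in the same SNP order; optional companion TSV with columns
        snp_id, chrom, pos."""
        df = pd.read_csv(path, sep="\t", dtype={0: str})
        ids = list(df.iloc[:, 0])
        mat = df.iloc[:, 1:].to_numpy(dtype=float)
        chrom = pos = None
        if pos_path is not None:
            pdf = pd.read_csv(pos_path, sep="\t", dtype={"snp_id": str, "chrom": str})
            chrom = dict(zip(pdf["snp_id"], pdf["chrom"]))
            pos = dict(zip(pdf["snp_id"], pdf["pos"].astype(int)))
        return cls(snp_ids=ids, r2=mat, chrom=chrom, pos=pos).validate()

    def to_tsv(self, path) -> None:
        out = pd.DataFrame(self.r2, columns=self.snp_ids)
        out.insert(0, "snp_id", self.snp_ids)
        out.to_csv(path, sep="\t", index=False, float_format="%.12g")


@dataclass
class InstrumentSet:
    """An ordered instrument list with full per-SNP provenance.

    Every SNP ever considered appears exactly once in ``provenance`` with an
    action in {kept, removed_ld, removed_pval, removed_secondary_trait,
    proxied, removed_missing}.
    """

    snp_ids: list[str]
    source_trait: str = ""
    p_threshold: float | None = None
    clump_r2: float | None = None
    clump_kb: float | None = None
    provenance: list[tuple[str, str, str]] = field(default_factory=list)
    pvals: dict[str, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.snp_ids)

    def __post_init__(self) -> None:
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise InputError("instrument snp_ids must be unique")


def select_significant(gwas: GWASTable, p_threshold: float = GENOME_WIDE_P) -> InstrumentSet:
    """Retain SNPs with association p-value strictly below ``p_threshold``.

    All rows must carry p-values.  An empty result is valid (warned, not an
    error).
    """
    df = gwas.data
    if "pval" not in df or df["pval"].isna().any():
        raise InputError(f"p-values missing in '{gwas.trait_name}'; cannot select instruments")
    keep_mask = df["pval"] < p_threshold
    provenance = [
        (row.snp_id, "kept" if ok else "removed_pval", f"p={row.pval:.3g}")
        for row, ok in zip(df.itertuples(), keep_mask)
    ]
    kept = list(df.loc[keep_mask, "snp_id"])
    if not kept:
        warnings.warn(f"no SNP passes p < {p_threshold:g} in '{gwas.trait_name}'", stacklevel=2)
    return InstrumentSet(
        snp_ids=kept,
        source_trait=gwas.trait_name,
        p_threshold=p_threshold,
        provenance=provenance,
        pvals=dict(zip(df.loc[keep_mask, "snp_id"], df.loc[keep_mask, "pval"])),
    )


def clump(
    candidates: InstrumentSet,
    ld: LDMatrix,
    r2_threshold: float = 0.001,
    window_kb: float = 10_000,
) -> InstrumentSet:
    """Greedy LD clumping: repeatedly keep the most significant remaining SNP
    and remove every other remaining SNP correlated with it above
    ``r2_threshold`` and (when positions are known for both) within
    ``window_kb`` kilobases on the same chromosome.

    Ties on p-value break by lexicographic snp_id so reruns are
    deterministic.  SNPs absent from ``ld`` are kept with a warning (they can
    neither remove nor be removed on LD grounds).
    """
    ld.validate()
    missing_p = [s for s in candidates.snp_ids if s not in candidates.pvals]
    if missing_p:
        raise InputError(f"candidates lack p-values for clumping: {missing_p[:5]}")
    not_in_ld = [s for s in candidates.snp_ids if s not in ld.snp_ids]
    if not_in_ld:
        warnings.warn(
            f"{len(not_in_ld)} candidate SNP(s) absent from LD matrix are kept unclumped",
            stacklevel=2,
        )
    idx = {s: i for i, s in enumerate(ld.snp_ids)}

    def within_window(a: str, b: str) -> bool:
        if ld.pos is None or a not in ld.pos or b not in ld.pos:
            return True  # no positions: LD-only clumping
        if ld.chrom is not None and ld.chrom.get(a) != ld.chrom.get(b):
            return False
        return abs(ld.pos[a] - ld.pos[b]) <= window_kb * 1000

    remaining = sorted(candidates.snp_ids, key=lambda s: (candidates.pvals[s], s))
    kept: list[str] = []
    removed: dict[str, str] = {}
    while remaining:
        index_snp = remaining.pop(0)
        kept.append(index_snp)
        if index_snp not in idx:
            continue
        survivors = []
        for s in remaining:
            if s in idx and ld.r2[idx[index_snp], idx[s]] > r2_threshold and within_window(index_snp, s):
                removed[s] = index_snp
            else:
                survivors.append(s)
        remaining = survivors

    order = {s: i for i, s in enumerate(candidates.snp_ids)}
    kept.sort(key=lambda s: order[s])
    provenance = [
        (s, "kept", "index SNP") if s in set(kept) else (s, "removed_ld", f"clumped by {removed[s]}")
        for s in candidates.snp_ids
    ]
    logger.info("clump: %d in, %d kept, %d removed", len(candidates), len(kept), len(removed))
    return replace(
        candidates,
        snp_ids=kept,
        clump_r2=r2_threshold,
        clump_kb=window_kb,
        provenance=provenance,
        pvals={s: candidates.pvals[s] for s in kept},
    )


def substitute_proxies(
    needed: InstrumentSet,
    available: GWASTable,
    proxy_table,
    proxy_r2_min: float = 0.8,
) -> InstrumentSet:
    """Replace instruments missing from ``available`` by their best proxy.

    ``proxy_table`` is an iterable of (index_snp, proxy_snp, r2) or a
    DataFrame with those columns.  For each needed SNP absent from
    ``available`` the highest-r2 proxy with r2 >= ``proxy_r2_min`` that is
    present (and not already an instrument) is substituted in place;
    otherwise the SNP is dropped with a logged reason.
    """
    if isinstance(proxy_table, pd.DataFrame):
        proxy_rows = list(proxy_table[["index_snp", "proxy_snp", "r2"]].itertuples(index=False))
    else:
        proxy_rows = [tuple(row) for row in proxy_table]
    for _, _, r2 in proxy_rows:
        if not 0 <= r2 <= 1:
            raise InputError(f"proxy r2 {r2} outside [0, 1]")

    have = set(available.snp_ids)
    current = set(needed.snp_ids)
    new_ids: list[str] = []
    pvals: dict[str, float] = {}
    provenance: list[tuple[str, str, str]] = []
    for s in needed.snp_ids:
        if s in have:
            new_ids.append(s)
            if s in needed.pvals:
                pvals[s] = needed.pvals[s]
            provenance.append((s, "kept", "present in outcome data"))
            continue
        options = [
            (r2, p)
            for (i, p, r2) in proxy_rows
            if i == s and r2 >= proxy_r2_min and p in have and p not in current and p not in new_ids
        ]
        if options:
            r2, proxy = max(options, key=lambda t: (t[0], t[1]))
            new_ids.append(proxy)
            if s in needed.pvals:  # proxy inherits the index SNP's exposure p-value
                pvals[proxy] = needed.pvals[s]
            provenance.append((s, "proxied", f"{proxy} (r2={r2:g})"))
        else:
            provenance.append((s, "removed_missing", "absent and no eligible proxy"))
            logger.info("substitute_proxies: dropped %s (no proxy)", s)
    return replace(needed, snp_ids=new_ids, provenance=provenance, pvals=pvals)


def filter_secondary_trait(
    instruments: InstrumentSet,
    secondary: GWASTable,
    alpha: float = 0.05,
) -> InstrumentSet:
    """Drop instruments associated with a secondary trait at a Bonferroni
    threshold of ``alpha / len(instruments)``.

    Instruments missing from ``secondary`` are kept with a warning.
    """
    if len(instruments) == 0:
        return instruments
    threshold = alpha / len(instruments)
    sec_p = dict(zip(secondary.data["snp_id"], secondary.data["pval"]))
    missing = [s for s in instruments.snp_ids if s not in sec_p or pd.isna(sec_p.get(s))]
    if missing:
        warnings.warn(
            f"{len(missing)} instrument(s) missing from '{secondary.trait_name}' kept unfiltered",
            stacklevel=2,
        )
    kept, provenance = [], []
    for s in instruments.snp_ids:
        p = sec_p.get(s)
        if p is not None and not pd.isna(p) and p < threshold:
            provenance.append((s, "removed_secondary_trait", f"p={p:.3g} < {threshold:.3g}"))
        else:
            kept.append(s)
            provenance.append((s, "kept", ""))
    logger.info(
        "filter_secondary_trait: threshold %.3g, removed %d of %d",
        threshold, len(instruments) - len(kept), len(instruments),
    )
    return replace(
        instruments,
        snp_ids=kept,
        provenance=provenance,
        pvals={s: p for s, p in instruments.pvals.items() if s in kept},
    )


def overlap_fraction(n_shared: int, n_larger_study: int) -> float:
    """Fraction of the larger study's participants shared with the other
    study; the quantity relevant to weak-instrument bias from overlap."""
    if n_larger_study <= 0:
        raise InputError("n_larger_study must be positive")
    if not 0 <= n_shared <= n_larger_study:
        raise InputError("need 0 <= n_shared <= n_larger_study")
    return n_shared / n_larger_study
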