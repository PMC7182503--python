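"""Allele harmonization of paired exposure/outcome summary statistics.

Two-sample MR needs the per-SNP exposure effect (gamma-hat) and outcome
effect (Gamma-hat) expressed relative to the *same* effect allele.  Source
GWASs may report the opposite allele (swap), the opposite strand (flip), or
both; palindromic SNPs (A/T, G/C) cannot be resolved from allele labels and
are resolved from effect-allele frequencies — or removed when either
frequency is missing or intermediate (close to 0.5).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gwas_io import GWASTable

logger = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

STATUS_OK = "ok"
STATUS_PALINDROMIC = "removed_palindromic_intermediate"
STATUS_INCOMPATIBLE = "removed_incompatible_alleles"
STATUS_MISSING = "removed_missing"
ALL_STATUSES = (STATUS_OK, STATUS_PALINDROMIC, STATUS_INCOMPATIBLE, STATUS_MISSING)

PAIR_COLUMNS = (
    "snp_id", "effect_allele", "other_allele",
    "beta_exp", "se_exp", "beta_out", "se_out",
    "eaf_exp", "eaf_out", "n_exp", "n_out", "status",
)


def is_palindromic(a1: str, a2: str) -> bool:
    return COMPLEMENT.get(a1) == a2


@dataclass
class HarmonizedTable:
    """Per-SNP paired effects on a common (exposure) effect-allele
    orientation, with a removal-reason status per SNP.

    Analysis code consumes only the ``status == "ok"`` rows via :meth:`ok`.
    """

    pairs: pd.DataFrame
    exposure_name: str = ""
    outcome_name: str = ""
    outcome_binary: bool = False

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def counts(self) -> dict[str, int]:
        c = self.pairs["status"].value_counts().to_dict()
        return {s: int(c.get(s, 0)) for s in ALL_STATUSES}

    def ok(self) -> pd.DataFrame:
        return self.pairs[self.pairs["status"] == STATUS_OK].reset_index(drop=True)

    @property
    def n_ok(self) -> int:
        return int((self.pairs["status"] == STATUS_OK).sum())

    def drop_snps(self, snp_ids) -> "HarmonizedTable":
        """Remove SNPs (e.g. pleiotropy outliers) entirely."""
        drop = set(snp_ids)
        return dataclasses.replace(
            self, pairs=self.pairs[~self.pairs["snp_id"].isin(drop)].reset_index(drop=True)
        )


def _harmonize_one(exp_row, out_row, low: float, high: float) -> dict:
    """Resolve one SNP; returns beta_out/eaf_out on the exposure orientation
    plus a status."""
    ea, oa = exp_row.effect_allele, exp_row.other_allele
    ea_o, oa_o = out_row.effect_allele, out_row.other_allele
    beta_out, eaf_out = out_row.beta, out_row.eaf

    if is_palindromic(ea, oa):
        if {ea_o, oa_o} != {ea, oa}:
            return {"status": STATUS_INCOMPATIBLE}
        eaf_exp = exp_row.eaf
        if pd.isna(eaf_exp) or pd.isna(eaf_out):
            return {"status": STATUS_PALINDROMIC}
        if low <= eaf_exp <= high or low <= eaf_out <= high:
            return {"status": STATUS_PALINDROMIC}
        # align labels assuming same strand, then use frequency side to
        # detect a strand flip (which, for a palindrome, acts as a swap)
        if ea_o != ea:
            beta_out, eaf_out = -beta_out, 1.0 - eaf_out
        if (eaf_exp < 0.5) != (eaf_out < 0.5):
            beta_out, eaf_out = -beta_out, 1.0 - eaf_out
        return {"status": STATUS_OK, "beta_out": beta_out, "eaf_out": eaf_out}

    for flip in (False, True):
        a1, a2 = (COMPLEMENT[ea_o], COMPLEMENT[oa_o]) if flip else (ea_o, oa_o)
        if (a1, a2) == (ea, oa):
            return {"status": STATUS_OK, "beta_out": beta_out, "eaf_out": eaf_out}
        if (a1, a2) == (oa, ea):
            eaf = 1.0 - eaf_out if not pd.isna(eaf_out) else eaf_out
            return {"status": STATUS_OK, "beta_out": -beta_out, "eaf_out": eaf}
    return {"status": STATUS_INCOMPATIBLE}


def harmonize(
    exposure: GWASTable,
    outcome: GWASTable,
    instruments=None,
    intermediate_eaf_low: float = 0.42,
    intermediate_eaf_high: float = 0.58,
) -> HarmonizedTable:
    """Pair exposure rows (optionally restricted to an instrument set) with
    outcome rows by snp_id and align them to the exposure effect allele.

    Every exposure SNP yields exactly one row whose ``status`` records the
    outcome: ``ok``, ``removed_palindromic_intermediate``,
    ``removed_incompatible_alleles``, or ``removed_missing``.
    """
    if instruments is not None:
        ids = instruments if isinstance(instruments, (list, tuple)) else instruments.snp_ids
        exposure = exposure.restrict(ids)
    out_by_id = {row.snp_id: row for row in outcome.data.itertuples()}

    rows = []
    for exp_row in exposure.data.itertuples():
        rec = {
            "snp_id": exp_row.snp_id,
            "effect_allele": exp_row.effect_allele,
            "other_allele": exp_row.other_allele,
            "beta_exp": exp_row.beta,
            "se_exp": exp_row.se,
            "beta_out": np.nan,
            "se_out": np.nan,
            "eaf_exp": exp_row.eaf,
            "eaf_out": np.nan,
            "n_exp": getattr(exp_row, "n", np.nan),
            "n_out": np.nan,
        }
        out_row = out_by_id.get(exp_row.snp_id)
        if out_row is None:
            rec["status"] = STATUS_MISSING
        else:
            res = _harmonize_one(exp_row, out_row, intermediate_eaf_low, intermediate_eaf_high)
            rec["status"] = res["status"]
            if res["status"] == STATUS_OK:
                rec["beta_out"] = res["beta_out"]
                rec["eaf_out"] = res["eaf_out"]
                rec["se_out"] = out_row.se
                rec["n_out"] = getattr(out_row, "n", np.nan)
        rows.append(rec)

    pairs = pd.DataFrame(rows, columns=list(PAIR_COLUMNS))
    table = HarmonizedTable(
        pairs=pairs,
        exposure_name=exposure.trait_name,
        outcome_name=outcome.trait_name,
        outcome_binary=outcome.is_binary,
    )
    logger.info(
        "harmonize %s -> %s: %s", exposure.trait_name, outcome.trait_name, table.counts
    )
    return table


def orient_positive_exposure(table: HarmonizedTable) -> HarmonizedTable:
    """Re-orient every usable pair so the exposure effect is non-negative
    (the exposure-increasing allele becomes the effect allele).

    Both effects flip sign together and frequencies mirror, so Wald ratios
    and the IVW/median/mode estimates are unchanged; MR-Egger's intercept
    sign convention requires this orientation.
    """
    pairs = table.pairs.copy()
    flip = (pairs["status"] == STATUS_OK) & (pairs["beta_exp"] < 0)
    for col in ("beta_exp", "beta_out"):
        pairs.loc[flip, col] = -pairs.loc[flip, col]
    for col in ("eaf_exp", "eaf_out"):
        pairs.loc[flip, col] = 1.0 - pairs.loc[flip, col]
    ea = pairs.loc[flip, "effect_allele"].copy()
    pairs.loc[flip, "effect_allele"] = pairs.loc[flip, "other_allele"]
    pairs.loc[flip, "other_allele"] = ea
    return dataclasses.replace(table, pairs=pairs)
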