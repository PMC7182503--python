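"""End-to-end orchestration for one exposure->outcome analysis and its
reverse.

The full analysis: harmonize the instrument effects, orient the exposure
effects positive, estimate with IVW / MR-Egger / weighted median / weighted
mode, run the diagnostics (Cochran's Q, Egger intercept, PRESSO, Steiger),
remove any PRESSO outliers and re-estimate once, then apply the reporting
rules as boolean flags:

* ``ivw_significant``       — IVW p < ``ivw_report_alpha`` (default 0.01)
* ``methods_direction_concordant`` — IVW, median and mode agree in sign
  (Egger's sign is recorded but non-blocking)
* ``methods_magnitude_concordant`` — IVW's 95% CI overlaps both the
  median's and the mode's (non-blocking sub-flag)
* ``no_horizontal_pleiotropy``   — PRESSO global p > ``pleiotropy_alpha``
* ``no_directional_pleiotropy``  — Egger intercept p > ``pleiotropy_alpha``
* ``direction_supported``   — Steiger p < ``steiger_alpha`` with the
  hypothesized direction
* ``bonferroni_significant`` — IVW p < alpha_nominal / n_comparisons
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import diagnostics, estimators
from .diagnostics import HeterogeneityResult, PressoResult, SteigerResult
from .estimators import EggerResult, MREstimate
from .exceptions import InputError, InsufficientInstrumentsError
from .gwas_io import GWASTable
from .harmonize import HarmonizedTable, harmonize, orient_positive_exposure
from .instruments import InstrumentSet, LDMatrix, clump, select_significant

logger = logging.getLogger(__name__)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold alpha/m for m comparisons."""
    if m < 1:
        raise InputError("number of comparisons must be >= 1")
    return alpha / m


@dataclass
class AnalysisConfig:
    """Tunable settings of the full analysis (all alphas in (0, 1))."""

    p_instrument: float = 5e-8
    clump_r2: float = 0.001
    clump_kb: float = 10_000
    outlier_alpha: float = 0.10
    n_sim: int = 1000
    n_boot: int = 1000
    seed: int = 0
    alpha_nominal: float = 0.05
    n_comparisons: int = 1
    ivw_report_alpha: float = 0.01
    pleiotropy_alpha: float = 0.01
    steiger_alpha: float = 0.01
    intermediate_eaf_low: float = 0.42
    intermediate_eaf_high: float = 0.58

    def validate(self) -> "AnalysisConfig":
        for name in ("alpha_nominal", "ivw_report_alpha", "pleiotropy_alpha",
                     "steiger_alpha", "outlier_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise InputError(f"{name} must lie in (0, 1), got {v}")
        if self.n_comparisons < 1:
            raise InputError("n_comparisons must be >= 1")
        return self

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {})).validate()


@dataclass
class EstimateSet:
    """All four method estimates from one fit of a harmonized table."""

    ivw: MREstimate
    egger: EggerResult | None
    weighted_median: MREstimate
    weighted_mode: MREstimate

    def as_dict(self) -> dict[str, MREstimate]:
        d = {
            "ivw": self.ivw,
            "weighted_median": self.weighted_median,
            "weighted_mode": self.weighted_mode,
        }
        if self.egger is not None:
            d["egger_slope"] = self.egger.slope
        return d


@dataclass
class AnalysisReport:
    """Everything one exposure->outcome run produced."""

    exposure_name: str
    outcome_name: str
    harmonized: HarmonizedTable
    estimates_raw: EstimateSet
    estimates_outlier_corrected: EstimateSet | None
    heterogeneity_raw: HeterogeneityResult
    heterogeneity_corrected: HeterogeneityResult | None
    presso: PressoResult | None
    steiger: SteigerResult | None
    single_snp: list[tuple[str, MREstimate]]
    leave_one_out: list[tuple[str, MREstimate]]
    flags: dict[str, bool | None]
    provenance: dict = field(default_factory=dict)
    estimable: bool = True
    reason: str = ""

    @property
    def estimates_reported(self) -> EstimateSet:
        """Outlier-corrected estimates when outliers were removed, raw
        otherwise (the two coincide when no outliers exist)."""
        return self.estimates_outlier_corrected or self.estimates_raw

    @property
    def egger_intercept(self) -> tuple[float, float]:
        res = self.estimates_reported.egger
        return diagnostics.egger_intercept_test(res)


def not_estimable(exposure_name: str, outcome_name: str, reason: str) -> AnalysisReport:
    """Placeholder report for a direction that cannot be estimated."""
    return AnalysisReport(
        exposure_name=exposure_name, outcome_name=outcome_name,
        harmonized=None, estimates_raw=None, estimates_outlier_corrected=None,
        heterogeneity_raw=None, heterogeneity_corrected=None, presso=None,
        steiger=None, single_snp=[], leave_one_out=[],
        flags={}, estimable=False, reason=reason,
    )


def _digest(gwas: GWASTable) -> str:
    payload = gwas.data.to_csv(index=False).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _estimate_all(table: HarmonizedTable, config: AnalysisConfig, seed_offset: int) -> EstimateSet:
    egger_res = estimators.egger(table) if table.n_ok >= 3 else None
    return EstimateSet(
        ivw=estimators.ivw(table, random_effects=True),
        egger=egger_res,
        weighted_median=estimators.weighted_median(
            table, n_boot=config.n_boot, seed=config.seed + seed_offset
        ),
        weighted_mode=estimators.weighted_mode(
            table, n_boot=config.n_boot, seed=config.seed + seed_offset + 1
        ),
    )


def compute_flags(
    estimates: EstimateSet,
    presso: PressoResult | None,
    steiger_res: SteigerResult | None,
    config: AnalysisConfig,
) -> dict[str, bool | None]:
    """Reporting flags as a pure function of the stored components."""
    ivw_e = estimates.ivw
    signs = {np.sign(e.theta) for e in
             (ivw_e, estimates.weighted_median, estimates.weighted_mode)}

    def overlaps(a: MREstimate, b: MREstimate) -> bool:
        return a.ci_low <= b.ci_high and b.ci_low <= a.ci_high

    egger_res = estimates.egger
    intercept_p = egger_res.intercept_pval if egger_res is not None else None
    return {
        "ivw_significant": bool(ivw_e.pval < config.ivw_report_alpha),
        "methods_direction_concordant": len(signs) == 1,
        "methods_magnitude_concordant": bool(
            overlaps(ivw_e, estimates.weighted_median)
            and overlaps(ivw_e, estimates.weighted_mode)
        ),
        "no_horizontal_pleiotropy": (
            None if presso is None else bool(presso.global_pval > config.pleiotropy_alpha)
        ),
        "no_directional_pleiotropy": (
            None if intercept_p is None else bool(intercept_p > config.pleiotropy_alpha)
        ),
        "direction_supported": (
            None if steiger_res is None
            else bool(steiger_res.direction_ok and steiger_res.pval < config.steiger_alpha)
        ),
        "bonferroni_significant": bool(
            ivw_e.pval < bonferroni_threshold(config.alpha_nominal, config.n_comparisons)
        ),
    }


def run_analysis(
    exposure: GWASTable,
    outcome: GWASTable,
    instruments: InstrumentSet,
    config: AnalysisConfig | None = None,
) -> AnalysisReport:
    """Run the full analysis for one exposure->outcome pair.

    Raises :class:`InsufficientInstrumentsError` when fewer than 3 usable
    pairs survive harmonization (the message lists the status tallies).
    """
    config = (config or AnalysisConfig()).validate()
    table = harmonize(
        exposure, outcome, instruments,
        intermediate_eaf_low=config.intermediate_eaf_low,
        intermediate_eaf_high=config.intermediate_eaf_high,
    )
    table = orient_positive_exposure(table)
    if table.n_ok < 3:
        raise InsufficientInstrumentsError(
            f"only {table.n_ok} usable pairs after harmonization; statuses: {table.counts}"
        )
    logger.info("run_analysis %s -> %s: %d usable instruments",
                exposure.trait_name, outcome.trait_name, table.n_ok)

    estimates_raw = _estimate_all(table, config, seed_offset=1)
    het_raw = diagnostics.cochran_q(table)
    presso_res = (
        diagnostics.presso(
            table, n_sim=config.n_sim, outlier_alpha=config.outlier_alpha,
            seed=config.seed + 7,
        )
        if table.n_ok >= 4 else None
    )
    steiger_res = None
    ok = table.ok()
    if not (ok["n_exp"].isna().any() or ok["n_out"].isna().any()):
        steiger_res = diagnostics.steiger(table)

    estimates_corr = None
    het_corr = None
    if presso_res is not None and presso_res.outlier_ids:
        corrected = table.drop_snps(presso_res.outlier_ids)
        if corrected.n_ok >= 3:
            logger.info("outlier correction: removed %s", presso_res.outlier_ids)
            estimates_corr = _estimate_all(corrected, config, seed_offset=3)
            het_corr = diagnostics.cochran_q(corrected)

    reported = estimates_corr or estimates_raw
    flags = compute_flags(reported, presso_res, steiger_res, config)

    if outcome.is_binary:
        for est_set in filter(None, (estimates_raw, estimates_corr)):
            est_set.ivw = estimators.to_odds_ratio(est_set.ivw)
            est_set.weighted_median = estimators.to_odds_ratio(est_set.weighted_median)
            est_set.weighted_mode = estimators.to_odds_ratio(est_set.weighted_mode)
            if est_set.egger is not None:
                est_set.egger = dataclasses.replace(
                    est_set.egger, slope=estimators.to_odds_ratio(est_set.egger.slope)
                )

    return AnalysisReport(
        exposure_name=exposure.trait_name,
        outcome_name=outcome.trait_name,
        harmonized=table,
        estimates_raw=estimates_raw,
        estimates_outlier_corrected=estimates_corr,
        heterogeneity_raw=het_raw,
        heterogeneity_corrected=het_corr,
        presso=presso_res,
        steiger=steiger_res,
        single_snp=estimators.wald_ratios(table),
        leave_one_out=estimators.leave_one_out(table),
        flags=flags,
        provenance={
            "config": dataclasses.asdict(config),
            "exposure_digest": _digest(exposure),
            "outcome_digest": _digest(outcome),
            "instruments": list(instruments.snp_ids)
            if isinstance(instruments, InstrumentSet) else list(instruments),
            "harmonization_counts": table.counts,
        },
    )


def _one_direction(
    src: GWASTable, dst: GWASTable, ld: LDMatrix | None, config: AnalysisConfig
) -> AnalysisReport:
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sig = select_significant(src, config.p_instrument)
    if len(sig) == 0:
        return not_estimable(src.trait_name, dst.trait_name, "no genome-wide significant SNPs")
    if ld is not None:
        sig = clump(sig, ld, r2_threshold=config.clump_r2, window_kb=config.clump_kb)
    try:
        return run_analysis(src, dst, sig, config)
    except InsufficientInstrumentsError as exc:
        return not_estimable(src.trait_name, dst.trait_name, str(exc))


def run_bidirectional(
    gwas_a: GWASTable,
    gwas_b: GWASTable,
    ld_a: LDMatrix | None = None,
    ld_b: LDMatrix | None = None,
    config: AnalysisConfig | None = None,
) -> tuple[AnalysisReport, AnalysisReport]:
    """Run A->B (instruments selected and clumped from A) and B->A
    (likewise from B).  A direction with no usable instruments yields a
    ``not_estimable`` report; the other direction is still returned."""
    config = (config or AnalysisConfig()).validate()
    report_ab = _one_direction(gwas_a, gwas_b, ld_a, config)
    report_ba = _one_direction(gwas_b, gwas_a, ld_b, config)
    return report_ab, report_ba


def estimates_frame(report: AnalysisReport, corrected: bool = True):
    """Flatten a report's (reported) estimates into rows suitable for
    :func:`summr.gwas_io.write_table`."""
    import pandas as pd

    est = report.estimates_reported if corrected else report.estimates_raw
    rows = []
    for name, e in est.as_dict().items():
        rows.append({
            "method": name, "beta": e.theta, "se": e.se, "ci_low": e.ci_low,
            "ci_high": e.ci_high, "pval": e.pval, "n_snp": e.n_snp,
            "odds_ratio": e.odds_ratio, "or_ci_low": e.or_ci_low,
            "or_ci_high": e.or_ci_high,
        })
    return pd.DataFrame(rows)
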