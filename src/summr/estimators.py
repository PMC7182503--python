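"""Causal-effect estimators from harmonized summary statistics.

Notation: for instrument j, gamma-hat_j (``beta_exp``) and its SE sigma_xj
are the SNP-exposure association, Gamma-hat_j (``beta_out``) and sigma_yj
the SNP-outcome association.  The per-SNP Wald ratio is
theta_j = Gamma_j / gamma_j with first-order SE sigma_yj / |gamma_j|.

Implemented estimators:

* **IVW** — inverse-variance-weighted combination of Wald ratios,
  equivalently weighted least squares of Gamma on gamma through the origin
  with weights 1/sigma_y^2.  By default a multiplicative random-effects
  scale max(1, sqrt(Q/(J-1))) inflates (never deflates) the fixed-effect SE.
* **MR-Egger** — the same regression with a free intercept; the slope is a
  pleiotropy-adjusted estimate (consistent under InSIDE), the intercept
  estimates the average directional pleiotropy.  Requires the exposure
  effects to be oriented non-negative first.
* **Weighted median** — the weighted median of the Wald ratios, consistent
  when at least half the weight comes from valid instruments; SE by
  parametric bootstrap.
* **Weighted mode** — the mode of a weighted normal-kernel density of the
  ratios, consistent when the largest homogeneous cluster is valid; SE by
  parametric bootstrap.

Binary outcomes are handled on the log-odds scale; :func:`to_odds_ratio`
exponentiates an estimate and its CI.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import InsufficientInstrumentsError
from .harmonize import HarmonizedTable

logger = logging.getLogger(__name__)

Z95 = float(stats.norm.ppf(0.975))

METHOD_WALD = "wald_ratio"
METHOD_IVW = "ivw"
METHOD_EGGER = "egger_slope"
METHOD_MEDIAN = "weighted_median"
METHOD_MODE = "weighted_mode"


@dataclass
class MREstimate:
    """One method's causal-effect estimate.

    ``theta`` is the effect per SD of exposure (log-OR scale when the
    outcome is binary); the OR fields are populated by
    :func:`to_odds_ratio`.
    """

    method: str
    theta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int
    odds_ratio: float | None = None
    or_ci_low: float | None = None
    or_ci_high: float | None = None


@dataclass
class EggerResult:
    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_pval: float


def _ok_arrays(table: HarmonizedTable, *, drop_zero_exposure: bool = True):
    ok = table.ok()
    bx = ok["beta_exp"].to_numpy(float)
    if drop_zero_exposure and (bx == 0).any():
        warnings.warn(
            f"excluding {(bx == 0).sum()} SNP(s) with zero exposure effect from "
            "ratio-based estimation",
            stacklevel=3,
        )
        ok = ok[bx != 0].reset_index(drop=True)
        bx = ok["beta_exp"].to_numpy(float)
    return (
        ok["snp_id"].to_list(),
        bx,
        ok["se_exp"].to_numpy(float),
        ok["beta_out"].to_numpy(float),
        ok["se_out"].to_numpy(float),
    )


def _require(n: int, minimum: int, what: str) -> None:
    if n < minimum:
        raise InsufficientInstrumentsError(
            f"{what} needs at least {minimum} instruments, got {n}"
        )


def _normal_estimate(method: str, theta: float, se: float, n_snp: int) -> MREstimate:
    z = theta / se if se > 0 else np.inf * np.sign(theta)
    pval = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else 0.0
    return MREstimate(
        method=method,
        theta=float(theta),
        se=float(se),
        ci_low=float(theta - Z95 * se),
        ci_high=float(theta + Z95 * se),
        pval=float(pval),
        n_snp=n_snp,
    )


def wald_ratios(table: HarmonizedTable) -> list[tuple[str, MREstimate]]:
    """Per-SNP Wald ratio estimates (single-SNP analysis)."""
    ids, bx, _sx, by, sy = _ok_arrays(table)
    _require(len(ids), 1, "wald_ratios")
    out = []
    for snp, g, G, s in zip(ids, bx, by, sy):
        out.append((snp, _normal_estimate(METHOD_WALD, G / g, s / abs(g), 1)))
    return out


def _ivw_point(bx, by, sy):
    """Closed-form IVW slope and fixed-effect SE (weights 1/sigma_y^2)."""
    w = 1.0 / sy**2
    denom = np.sum(w * bx**2)
    theta = np.sum(w * bx * by) / denom
    se_fixed = denom**-0.5
    return theta, se_fixed


def _cochran_q_value(bx, by, sy) -> float:
    theta_fixed, _ = _ivw_point(bx, by, sy)
    ratios = by / bx
    w = bx**2 / sy**2
    return float(np.sum(w * (ratios - theta_fixed) ** 2))


def ivw(
    table: HarmonizedTable,
    random_effects: bool = True,
    min_instruments: int = 2,
) -> MREstimate:
    """Inverse-variance-weighted estimate.

    ``random_effects`` multiplies the fixed-effect SE by
    max(1, sqrt(Q/(J-1))) where Q is Cochran's statistic, so the SE never
    falls below the fixed-effect one; the point estimate is unaffected.
    """
    ids, bx, _sx, by, sy = _ok_arrays(table)
    J = len(ids)
    _require(J, max(min_instruments, 1), "ivw")
    theta, se = _ivw_point(bx, by, sy)
    if random_effects and J >= 2:
        scale = max(1.0, np.sqrt(_cochran_q_value(bx, by, sy) / (J - 1)))
        se = se * scale
    return _normal_estimate(METHOD_IVW, theta, se, J)


def egger(table: HarmonizedTable) -> EggerResult:
    """MR-Egger regression (weighted, with intercept).

    The table should first pass through
    :func:`summr.harmonize.orient_positive_exposure`; the intercept's sign
    is only meaningful with exposure effects oriented non-negative.
    SEs use a multiplicative residual scale floored at 1 with J-2 degrees
    of freedom; p-values are two-sided t(J-2).
    """
    ids, bx, _sx, by, sy = _ok_arrays(table)
    J = len(ids)
    _require(J, 3, "egger")
    w = 1.0 / sy**2
    X = np.column_stack([np.ones(J), bx])
    XtW = X.T * w
    xtwx = XtW @ X
    coef = np.linalg.solve(xtwx, XtW @ by)
    resid = by - X @ coef
    df = J - 2
    sigma2 = float(np.sum(w * resid**2) / df)
    scale2 = max(1.0, sigma2)
    cov = scale2 * np.linalg.inv(xtwx)
    intercept, slope = coef
    se_int, se_slope = np.sqrt(np.diag(cov))
    tq = float(stats.t.ppf(0.975, df))
    slope_p = float(2 * stats.t.sf(abs(slope / se_slope), df))
    int_p = float(2 * stats.t.sf(abs(intercept / se_int), df))
    slope_est = MREstimate(
        method=METHOD_EGGER,
        theta=float(slope),
        se=float(se_slope),
        ci_low=float(slope - tq * se_slope),
        ci_high=float(slope + tq * se_slope),
        pval=slope_p,
        n_snp=J,
    )
    return EggerResult(
        slope=slope_est,
        intercept=float(intercept),
        intercept_se=float(se_int),
        intercept_pval=int_p,
    )


def _weighted_median_point(ratios, weights) -> float:
    order = np.argsort(ratios)
    r = np.asarray(ratios, float)[order]
    w = np.asarray(weights, float)[order]
    w = w / w.sum()
    s = np.cumsum(w) - w / 2
    return float(np.interp(0.5, s, r))


def _mode_bandwidth(ratios, phi: float) -> float:
    r = np.asarray(ratios, float)
    J = len(r)
    sd = float(np.std(r, ddof=1)) if J > 1 else 0.0
    mad = float(np.median(np.abs(r - np.median(r)))) / 0.6745
    spread = min(sd, mad)
    return phi * 0.9 * spread * J ** (-1 / 5)


def _weighted_mode_point(ratios, weights, phi: float, grid_points: int = 512) -> float:
    r = np.asarray(ratios, float)
    w = np.asarray(weights, float)
    w = w / w.sum()
    h = _mode_bandwidth(r, phi)
    if h <= 0:  # all ratios (essentially) identical
        return float(r[0])
    grid = np.linspace(r.min() - 3 * h, r.max() + 3 * h, grid_points)
    dens = (w[None, :] * stats.norm.pdf((grid[:, None] - r[None, :]) / h)).sum(axis=1) / h
    return float(grid[np.argmax(dens)])  # argmax takes the first (smallest) tie


def _bootstrap_se(bx, sx, by, sy, point_fn, n_boot: int, seed) -> float:
    """Parametric bootstrap: resample both effect vectors from their
    sampling distributions and recompute the point estimate."""
    if n_boot <= 0:
        return float("nan")
    rng = np.random.default_rng(seed)
    J = len(bx)
    bx_star = rng.normal(bx, sx, size=(n_boot, J))
    by_star = rng.normal(by, sy, size=(n_boot, J))
    ests = np.empty(n_boot)
    for b in range(n_boot):
        gx = bx_star[b]
        nz = gx != 0
        ests[b] = point_fn(by_star[b][nz] / gx[nz], gx[nz] ** 2 / sy[nz] ** 2)
    return float(np.std(ests, ddof=1))


def weighted_median(
    table: HarmonizedTable,
    n_boot: int = 1000,
    seed: int | None = 0,
) -> MREstimate:
    """Weighted median of the Wald ratios (weights gamma^2/sigma_y^2).

    With ``n_boot == 0`` only the point estimate is computed (SE/CI/p NaN).
    """
    ids, bx, sx, by, sy = _ok_arrays(table)
    J = len(ids)
    _require(J, 3, "weighted_median")
    ratios = by / bx
    weights = bx**2 / sy**2
    theta = _weighted_median_point(ratios, weights)
    se = _bootstrap_se(bx, sx, by, sy, _weighted_median_point, n_boot, seed)
    if np.isnan(se):
        return MREstimate(METHOD_MEDIAN, theta, np.nan, np.nan, np.nan, np.nan, J)
    return _normal_estimate(METHOD_MEDIAN, theta, se, J)


def weighted_mode(
    table: HarmonizedTable,
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int | None = 0,
) -> MREstimate:
    """Weighted-mode estimate: argmax of a normal-kernel weighted density of
    the Wald ratios on a 512-point grid.

    ``phi`` scales the modified-Silverman bandwidth
    0.9 * min(sd, MAD/0.6745) * J^(-1/5).
    """
    ids, bx, sx, by, sy = _ok_arrays(table)
    J = len(ids)
    _require(J, 3, "weighted_mode")
    ratios = by / bx
    weights = bx**2 / sy**2
    theta = _weighted_mode_point(ratios, weights, phi)
    se = _bootstrap_se(
        bx, sx, by, sy, lambda r, w: _weighted_mode_point(r, w, phi), n_boot, seed
    )
    if np.isnan(se):
        return MREstimate(METHOD_MODE, theta, np.nan, np.nan, np.nan, np.nan, J)
    return _normal_estimate(METHOD_MODE, theta, se, J)


def leave_one_out(table: HarmonizedTable, random_effects: bool = True) -> list[tuple[str, MREstimate]]:
    """IVW re-estimated J times, each time excluding one SNP."""
    ids, *_ = _ok_arrays(table)
    _require(len(ids), 3, "leave_one_out")
    out = []
    for snp in ids:
        out.append((snp, ivw(table.drop_snps([snp]), random_effects=random_effects)))
    return out


def to_odds_ratio(estimate: MREstimate, outcome_binary: bool = True) -> MREstimate:
    """Exponentiate a log-OR estimate (binary outcomes) into OR with CI."""
    if not outcome_binary:
        warnings.warn("to_odds_ratio called on a continuous outcome; no-op", stacklevel=2)
        return estimate
    return dataclasses.replace(
        estimate,
        odds_ratio=float(np.exp(estimate.theta)),
        or_ci_low=float(np.exp(estimate.ci_low)),
        or_ci_high=float(np.exp(estimate.ci_high)),
    )
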