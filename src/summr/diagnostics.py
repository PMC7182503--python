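"""Heterogeneity, pleiotropy, outlier and directionality diagnostics.

* :func:`cochran_q` — Cochran's Q over the per-SNP Wald ratios; excess
  heterogeneity signals instrumental-variable violations.
* :func:`egger_intercept_test` — the MR-Egger intercept and its t-test;
  a nonzero intercept indicates directional horizontal pleiotropy.
* :func:`presso` — residual-sum-and-outlier test: a parametric simulation
  under the no-pleiotropy model yields a global p-value for the observed
  residual sum of squares, per-SNP outlier p-values (Bonferroni-scaled),
  and an optional distortion test comparing the outlier-corrected estimate
  with random same-size subsets.
* :func:`steiger` — directionality test comparing instrument variance
  explained in exposure vs outcome via Fisher's z.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .estimators import EggerResult, _ivw_point, _ok_arrays, _require
from .exceptions import InputError
from .harmonize import HarmonizedTable


@dataclass
class HeterogeneityResult:
    Q: float
    df: int
    pval: float


@dataclass
class PressoResult:
    rss_obs: float
    global_pval: float
    per_snp_pvals: dict[str, float]
    outlier_ids: list[str]
    distortion_pval: float | None
    n_sim: int
    seed: int | None


@dataclass
class SteigerResult:
    r2_exposure: float
    r2_outcome: float
    direction_ok: bool
    z: float
    pval: float
    log_odds_scale: bool = False  # binary outcome: r2 on observed log-odds scale


def cochran_q(table: HarmonizedTable) -> HeterogeneityResult:
    """Cochran's Q = sum_j w_j (theta_j - theta_IVW,fixed)^2 with
    w_j = gamma_j^2 / sigma_yj^2, df = J-1, upper-tail chi-square p."""
    ids, bx, _sx, by, sy = _ok_arrays(table)
    J = len(ids)
    _require(J, 2, "cochran_q")
    theta_fixed, _ = _ivw_point(bx, by, sy)
    w = bx**2 / sy**2
    Q = float(np.sum(w * (by / bx - theta_fixed) ** 2))
    df = J - 1
    return HeterogeneityResult(Q=Q, df=df, pval=float(stats.chi2.sf(Q, df)))


def egger_intercept_test(egger_result: EggerResult) -> tuple[float, float]:
    """The MR-Egger intercept and its two-sided t-test p-value."""
    return egger_result.intercept, egger_result.intercept_pval


def _loo_slopes(bx, by, w):
    """Leave-one-out IVW slopes via sum updates (vectorized over SNPs and,
    when the inputs are 2-D, over simulation replicates)."""
    num = w * bx * by
    den = w * bx**2
    s_num = num.sum(axis=-1, keepdims=True)
    s_den = den.sum(axis=-1, keepdims=True)
    return (s_num - num) / (s_den - den)


def presso(
    table: HarmonizedTable,
    n_sim: int = 1000,
    outlier_alpha: float = 0.10,
    seed: int | None = 0,
    compute_distortion: bool = True,
) -> PressoResult:
    """Pleiotropy residual-sum-and-outlier test.

    Observed statistic: RSS = sum_j (Gamma_j - theta_{-j} gamma_j)^2 /
    sigma_yj^2, with theta_{-j} the leave-one-out IVW slope.  The null
    distribution is simulated by redrawing gamma*_j ~ N(gamma_j, sigma_xj^2)
    and Gamma*_j ~ N(theta_{-j} gamma_j, sigma_yj^2) and recomputing RSS
    (with leave-one-out slopes re-estimated on the simulated data).
    Empirical p-values carry the +1 correction and are never exactly 0;
    per-SNP p-values are Bonferroni-scaled by J and SNPs below
    ``outlier_alpha`` are flagged as outliers.
    """
    ids, bx, sx, by, sy = _ok_arrays(table)
    J = len(ids)
    _require(J, 4, "presso")
    w = 1.0 / sy**2

    theta_loo = np.asarray(_loo_slopes(bx, by, w)).reshape(-1)
    resid_obs = w * (by - theta_loo * bx) ** 2
    rss_obs = float(resid_obs.sum())

    rng = np.random.default_rng(seed)
    bx_star = rng.normal(bx, sx, size=(n_sim, J))
    by_star = rng.normal(theta_loo * bx, sy, size=(n_sim, J))
    theta_loo_star = _loo_slopes(bx_star, by_star, w)
    resid_star = w * (by_star - theta_loo_star * bx_star) ** 2
    rss_star = resid_star.sum(axis=1)

    global_pval = (np.sum(rss_star >= rss_obs) + 1) / (n_sim + 1)
    p_raw = (np.sum(resid_star >= resid_obs, axis=0) + 1) / (n_sim + 1)
    per_snp = np.minimum(1.0, p_raw * J)
    outliers = [s for s, p in zip(ids, per_snp) if p < outlier_alpha]

    distortion_pval = None
    if compute_distortion and 0 < len(outliers) < J - 1:
        keep = [s for s in ids if s not in set(outliers)]
        keep_idx = [ids.index(s) for s in keep]
        theta_no_out, _ = _ivw_point(bx[keep_idx], by[keep_idx], sy[keep_idx])
        k = len(keep_idx)
        subs = np.empty(n_sim)
        for i in range(n_sim):
            pick = rng.choice(J, size=k, replace=False)
            subs[i], _ = _ivw_point(bx[pick], by[pick], sy[pick])
        lo = (np.sum(subs <= theta_no_out) + 1) / (n_sim + 1)
        hi = (np.sum(subs >= theta_no_out) + 1) / (n_sim + 1)
        distortion_pval = float(min(1.0, 2 * min(lo, hi)))

    return PressoResult(
        rss_obs=rss_obs,
        global_pval=float(global_pval),
        per_snp_pvals=dict(zip(ids, per_snp.astype(float))),
        outlier_ids=outliers,
        distortion_pval=distortion_pval,
        n_sim=n_sim,
        seed=seed,
    )


def presso_rss(table: HarmonizedTable) -> float:
    """The observed PRESSO residual sum of squares alone (no simulation)."""
    ids, bx, _sx, by, sy = _ok_arrays(table)
    _require(len(ids), 2, "presso_rss")
    w = 1.0 / sy**2
    theta_loo = np.asarray(_loo_slopes(bx, by, w)).reshape(-1)
    return float(np.sum(w * (by - theta_loo * bx) ** 2))


def steiger(table: HarmonizedTable) -> SteigerResult:
    """Directionality test: compares total instrument variance explained in
    the exposure (R2_x) and in the outcome (R2_y).

    Per SNP, r2 = t^2 / (t^2 + n - 2) from the association t-statistic;
    these are summed over instruments per side.  The two R2 values are
    compared through Fisher's z-transform of the correlation sqrt(R2),
    using the median per-SNP sample size on each side.  The hypothesized
    direction is supported when R2_x > R2_y.  For binary outcomes the
    outcome r2 is on the observed log-odds scale (no liability correction),
    flagged in the result.
    """
    ok = table.ok()
    _require(len(ok), 1, "steiger")
    for side, col in (("exposure", "n_exp"), ("outcome", "n_out")):
        if col not in ok or ok[col].isna().any() or (ok[col] <= 3).any():
            raise InputError(f"steiger requires per-SNP sample sizes on the {side} side")
    bx, sx = ok["beta_exp"].to_numpy(float), ok["se_exp"].to_numpy(float)
    by, sy = ok["beta_out"].to_numpy(float), ok["se_out"].to_numpy(float)
    n_x = ok["n_exp"].to_numpy(float)
    n_y = ok["n_out"].to_numpy(float)

    t_x = bx / sx
    t_y = by / sy
    r2x = float(np.sum(t_x**2 / (t_x**2 + n_x - 2)))
    r2y = float(np.sum(t_y**2 / (t_y**2 + n_y - 2)))
    eps = 1e-15
    r2x_c = min(max(r2x, 0.0), 1 - eps)
    r2y_c = min(max(r2y, 0.0), 1 - eps)
    nx = float(np.median(n_x))
    ny = float(np.median(n_y))
    z = (np.arctanh(np.sqrt(r2x_c)) - np.arctanh(np.sqrt(r2y_c))) / np.sqrt(
        1 / (nx - 3) + 1 / (ny - 3)
    )
    pval = float(2 * stats.norm.sf(abs(z)))
    return SteigerResult(
        r2_exposure=r2x_c,
        r2_outcome=r2y_c,
        direction_ok=bool(r2x_c > r2y_c),
        z=float(z),
        pval=pval,
        log_odds_scale=table.outcome_binary,
    )
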