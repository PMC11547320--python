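"""Two-sample MR estimator suite on harmonized summary data.

Every estimator consumes :class:`~mrpipe.summary_stats.HarmonizedData` and
returns an :class:`MrEstimate`. The per-SNP building block is the Wald ratio
beta_out/beta_exp with first-order standard error se_out/|beta_exp|.

Methods
-------
ivw
    Inverse-variance-weighted mean of the Wald ratios with a multiplicative
    random-effects scale: the standard error is inflated by
    sqrt(max(1, Q/(k-1))) when the instruments are over-dispersed.
egger
    Weighted regression of outcome on exposure effects with an intercept;
    the intercept (with its own test) measures directional pleiotropy, the
    slope is a pleiotropy-consistent causal estimate under the InSIDE
    assumption.
weighted_median
    Weighted median of the ratios; consistent when instruments carrying at
    least half the weight are valid. Parametric-bootstrap standard error.
weighted_mode
    Mode of a weighted kernel density of the ratios; consistent when the
    largest group of instruments is valid (zero modal pleiotropy assumption).
pivw
    Penalized debiased IVW: removes weak-instrument bias by subtracting the
    exposure sampling variance from the IVW denominator and penalizing the
    debiased denominator away from zero; variance accounts for balanced
    horizontal pleiotropy.
mr_presso
    Residual-sum-of-squares global pleiotropy test with parametric
    simulations, per-SNP outlier detection, and an outlier-corrected IVW
    estimate.

All p-values are two-sided normal. For binary outcomes, estimates are
additionally reported as odds ratios per SD of exposure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .summary_stats import HarmonizedData

Z95 = stats.norm.ppf(0.975)


class InsufficientInstrumentsError(ValueError):
    """An estimator received fewer SNPs than its minimum."""


@dataclass
class HeterogeneityStat:
    """Cochran's Q with its degrees of freedom and chi-square tail p."""

    q: float
    df: int
    pval: float


@dataclass
class MrEstimate:
    """One method's causal estimate on the exposure-SD scale."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int
    or_scale: Optional[tuple[float, float, float]] = None  # (OR, lo, hi)
    extras: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        row = {
            "method": self.method, "n_snp": self.n_snp, "beta": self.beta,
            "se": self.se, "ci_low": self.ci_low, "ci_high": self.ci_high,
            "pval": self.pval,
        }
        if self.or_scale is not None:
            row["or"], row["or_ci_low"], row["or_ci_high"] = self.or_scale
        else:
            row["or"] = row["or_ci_low"] = row["or_ci_high"] = np.nan
        return row


def _require(data: HarmonizedData, k_min: int, method: str) -> None:
    if data.n_snp < k_min:
        raise InsufficientInstrumentsError(
            f"{method} needs >= {k_min} instruments, got {data.n_snp}"
        )


def _finish(method: str, beta: float, se: float, n_snp: int,
            binary: bool, extras: Optional[dict] = None) -> MrEstimate:
    se = float(se)
    beta = float(beta)
    z = beta / se if se > 0 else np.inf * np.sign(beta)
    pval = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    pval = max(pval, np.finfo(float).tiny)
    lo, hi = beta - Z95 * se, beta + Z95 * se
    or_scale = (math.exp(beta), math.exp(lo), math.exp(hi)) if binary else None
    return MrEstimate(method=method, beta=beta, se=se, ci_low=lo, ci_high=hi,
                      pval=pval, n_snp=n_snp, or_scale=or_scale,
                      extras=extras or {})


def wald_ratio(beta_exp: float, se_exp: float, beta_out: float, se_out: float
               ) -> tuple[float, float]:
    """Per-SNP causal estimate beta_out/beta_exp with first-order SE se_out/|beta_exp|.

    The exposure sampling error is ignored (first-order delta method), the
    standard default for summary-data MR when instruments are strong.
    """
    if beta_exp == 0:
        raise ValueError("wald_ratio: beta_exp must be nonzero")
    return beta_out / beta_exp, se_out / abs(beta_exp)


def _ratios(data: HarmonizedData) -> tuple[np.ndarray, np.ndarray]:
    bx = data.snps["beta_exp"].to_numpy(dtype=float)
    by = data.snps["beta_out"].to_numpy(dtype=float)
    sy = data.snps["se_out"].to_numpy(dtype=float)
    if np.any(bx == 0):
        raise ValueError("wald ratios undefined: some beta_exp are zero")
    return by / bx, sy / np.abs(bx)


def _ivw_core(ratio: np.ndarray, ratio_se: np.ndarray) -> tuple[float, float, float, float]:
    """Returns (beta, se, Q, phi) for the multiplicative random-effects IVW."""
    w = 1.0 / ratio_se ** 2
    beta = float(np.sum(w * ratio) / np.sum(w))
    q = float(np.sum(w * (ratio - beta) ** 2))
    k = ratio.size
    phi = max(1.0, q / (k - 1)) if k > 1 else 1.0
    se = math.sqrt(phi / np.sum(w))
    return beta, se, q, phi


def ivw(data: HarmonizedData) -> tuple[MrEstimate, HeterogeneityStat]:
    """Inverse-variance-weighted estimate with multiplicative random effects."""
    _require(data, 2, "ivw")
    ratio, ratio_se = _ratios(data)
    beta, se, q, phi = _ivw_core(ratio, ratio_se)
    k = data.n_snp
    het = HeterogeneityStat(q=q, df=k - 1, pval=float(stats.chi2.sf(q, k - 1)))
    est = _finish("ivw", beta, se, k, data.outcome_binary,
                  extras={"overdispersion_scale": phi, "q": q, "q_pval": het.pval})
    return est, het


def egger(data: HarmonizedData) -> tuple[MrEstimate, HeterogeneityStat]:
    """MR-Egger regression: weighted fit of beta_out on beta_exp with intercept.

    SNPs are oriented so beta_exp > 0; weights are 1/se_out^2; coefficient
    standard errors are inflated by the residual scale when it exceeds 1.
    The intercept estimates average directional pleiotropy.
    """
    _require(data, 3, "egger")
    bx = data.snps["beta_exp"].to_numpy(dtype=float).copy()
    by = data.snps["beta_out"].to_numpy(dtype=float).copy()
    sy = data.snps["se_out"].to_numpy(dtype=float)
    flip = bx < 0
    bx[flip] *= -1
    by[flip] *= -1

    w = 1.0 / sy ** 2
    X = np.column_stack([np.ones_like(bx), bx])
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * by)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = by - X @ coef
    k = bx.size
    rss_w = float(np.sum(w * resid ** 2))
    sigma2 = rss_w / (k - 2)
    cov_unscaled = np.linalg.inv(xtwx)
    scale = max(1.0, math.sqrt(sigma2))
    se_int, se_slope = scale * np.sqrt(np.diag(cov_unscaled))

    intercept, slope = coef
    z_int = intercept / se_int
    p_int = float(min(1.0, 2.0 * stats.norm.sf(abs(z_int))))
    het = HeterogeneityStat(q=rss_w, df=k - 2, pval=float(stats.chi2.sf(rss_w, k - 2)))
    est = _finish("egger", slope, se_slope, k, data.outcome_binary, extras={
        "intercept": float(intercept), "intercept_se": float(se_int),
        "intercept_pval": p_int, "residual_scale": math.sqrt(sigma2),
        "q": rss_w, "q_pval": het.pval,
    })
    return est, het


def _weighted_median_point(ratio: np.ndarray, weight: np.ndarray) -> float:
    order = np.argsort(ratio, kind="stable")
    r = ratio[order]
    w = weight[order] / np.sum(weight)
    cum = np.cumsum(w) - w / 2.0
    if 0.5 <= cum[0]:
        return float(r[0])
    if 0.5 >= cum[-1]:
        return float(r[-1])
    return float(np.interp(0.5, cum, r))


def _parametric_boot_se(data: HarmonizedData, point_fn, boot_reps: int, seed: int) -> float:
    rng = np.random.default_rng(seed)
    bx = data.snps["beta_exp"].to_numpy(dtype=float)
    sx = data.snps["se_exp"].to_numpy(dtype=float)
    by = data.snps["beta_out"].to_numpy(dtype=float)
    sy = data.snps["se_out"].to_numpy(dtype=float)
    ests = np.empty(boot_reps)
    for b in range(boot_reps):
        bx_b = rng.normal(bx, sx)
        by_b = rng.normal(by, sy)
        bad = bx_b == 0
        if np.any(bad):  # vanishing denominator: resample those entries
            bx_b[bad] = rng.normal(bx[bad], sx[bad])
            bx_b[bx_b == 0] = np.finfo(float).tiny
        ratio = by_b / bx_b
        ratio_se = sy / np.abs(bx_b)
        ests[b] = point_fn(ratio, 1.0 / ratio_se ** 2)
    return float(np.std(ests, ddof=1))


def weighted_median(data: HarmonizedData, boot_reps: int = 1000, seed: int = 0
                    ) -> MrEstimate:
    """Weighted median of the Wald ratios with parametric-bootstrap SE."""
    _require(data, 3, "weighted_median")
    ratio, ratio_se = _ratios(data)
    w = 1.0 / ratio_se ** 2
    beta = _weighted_median_point(ratio, w)
    se = _parametric_boot_se(data, _weighted_median_point, boot_reps, seed)
    if se <= 0:
        se = np.finfo(float).tiny
    return _finish("weighted_median", beta, se, data.n_snp, data.outcome_binary,
                   extras={"boot_reps": boot_reps, "seed": seed})


def _weighted_mode_point(ratio: np.ndarray, weight: np.ndarray,
                         bandwidth_factor: float = 1.0, grid_size: int = 512) -> float:
    w = weight / np.sum(weight)
    mad = np.median(np.abs(ratio - np.median(ratio)))
    spread = min(np.std(ratio, ddof=1) if ratio.size > 1 else 0.0, 1.4826 * mad)
    h = bandwidth_factor * 0.9 * spread * ratio.size ** (-0.2)
    if h <= 0:  # degenerate: (near-)point mass
        return float(ratio[np.argmax(w)])
    grid = np.linspace(ratio.min() - 2 * h, ratio.max() + 2 * h, grid_size)
    dens = np.sum(w[None, :] * np.exp(-0.5 * ((grid[:, None] - ratio[None, :]) / h) ** 2),
                  axis=1)
    return float(grid[np.argmax(dens)])


def weighted_mode(data: HarmonizedData, bandwidth_factor: float = 1.0,
                  boot_reps: int = 1000, seed: int = 0) -> MrEstimate:
    """Mode of the weighted normal-kernel density of the Wald ratios."""
    _require(data, 3, "weighted_mode")
    ratio, ratio_se = _ratios(data)
    w = 1.0 / ratio_se ** 2
    beta = _weighted_mode_point(ratio, w, bandwidth_factor)
    se = _parametric_boot_se(
        data, lambda r, wt: _weighted_mode_point(r, wt, bandwidth_factor),
        boot_reps, seed)
    if se <= 0:
        se = np.finfo(float).tiny
    return _finish("weighted_mode", beta, se, data.n_snp, data.outcome_binary,
                   extras={"boot_reps": boot_reps, "seed": seed,
                           "bandwidth_factor": bandwidth_factor})


def pivw(data: HarmonizedData, penalty: float = 1.0) -> MrEstimate:
    """Penalized debiased IVW estimator for weak-instrument-robust MR.

    The IVW denominator Sum(beta_exp^2/se_out^2) is biased upward by the
    exposure sampling variance; the debiased denominator subtracts it:
    mu_hat = Sum((beta_exp^2 - se_exp^2)/se_out^2). With many weak
    instruments mu_hat can approach (or cross) zero, so it is penalized away
    from zero: the estimate uses the positive root

        mu~ = (mu_hat + sqrt(mu_hat^2 + 4*lambda*V_hat)) / 2,

    where V_hat estimates Var(mu_hat) and lambda (default 1) controls the
    penalty; lambda -> 0 recovers the plain debiased IVW. The variance
    estimator includes a method-of-moments balanced-pleiotropy component
    tau^2.
    """
    _require(data, 2, "pivw")
    bx = data.snps["beta_exp"].to_numpy(dtype=float)
    sx = data.snps["se_exp"].to_numpy(dtype=float)
    by = data.snps["beta_out"].to_numpy(dtype=float)
    sy = data.snps["se_out"].to_numpy(dtype=float)
    if np.any(~np.isfinite(sx)) or np.any(sx < 0):
        raise ValueError("pivw requires finite se_exp for every SNP")

    w = 1.0 / sy ** 2
    num = float(np.sum(w * bx * by))
    mu_hat = float(np.sum(w * (bx ** 2 - sx ** 2)))
    # Var(mu_hat): each term has variance (4*gamma^2*sx^2 + 2*sx^4)/sy^4;
    # plug in gamma^2 ~ max(bx^2 - sx^2, 0)
    gamma2 = np.maximum(bx ** 2 - sx ** 2, 0.0)
    v_hat = float(np.sum(w ** 2 * (4.0 * gamma2 * sx ** 2 + 2.0 * sx ** 4)))
    if penalty > 0 and v_hat > 0:
        mu_pen = 0.5 * (mu_hat + math.sqrt(mu_hat ** 2 + 4.0 * penalty * v_hat))
    else:
        mu_pen = mu_hat
    if mu_pen == 0:
        raise ValueError("pivw: penalized denominator is zero; instruments carry no signal")
    beta = num / mu_pen

    # balanced-pleiotropy over-dispersion (method of moments, floored at 0)
    resid2 = (by - beta * bx) ** 2
    tau2 = float(np.sum(w * (resid2 - sy ** 2 - beta ** 2 * sx ** 2)) / np.sum(w))
    tau2 = max(0.0, tau2)

    var_terms = w ** 2 * (
        gamma2 * (sy ** 2 + tau2 + beta ** 2 * sx ** 2)
        + sx ** 2 * (sy ** 2 + tau2)
        + 2.0 * beta ** 2 * sx ** 4
    )
    se = math.sqrt(float(np.sum(var_terms))) / abs(mu_pen)
    # effective instrument-strength statistic (condition-number analogue)
    kappa = mu_hat / math.sqrt(v_hat) if v_hat > 0 else float("inf")
    return _finish("pivw", beta, se, data.n_snp, data.outcome_binary, extras={
        "penalty": penalty, "instrument_strength": kappa, "tau2": tau2,
    })


def _loo_ivw_beta(ratio: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW point estimates, one per omitted SNP (vectorized)."""
    sw, swr = np.sum(w), np.sum(w * ratio)
    return (swr - w * ratio) / (sw - w)


def mr_presso(data: HarmonizedData, n_sim: int = 1000, outlier_p: float = 0.05,
              seed: int = 0) -> tuple[MrEstimate, MrEstimate, list[str]]:
    """MR-PRESSO global pleiotropy test, outlier detection and correction.

    The observed statistic is the weighted residual sum of squares where each
    SNP's residual uses the IVW fit excluding that SNP. Its null distribution
    comes from ``n_sim`` parametric simulations under the fitted model; the
    same simulations give per-SNP residual distributions, whose tail
    probabilities (Bonferroni-adjusted across SNPs) flag outliers below
    ``outlier_p``. The corrected estimate is the IVW fit on the non-outlier
    SNPs; a distortion test compares the raw-vs-corrected change against
    changes from removing random same-size SNP subsets.

    Returns (raw estimate, corrected estimate, outlier rsids).
    """
    _require(data, 4, "mr_presso")
    rng = np.random.default_rng(seed)
    bx = data.snps["beta_exp"].to_numpy(dtype=float)
    sx = data.snps["se_exp"].to_numpy(dtype=float)
    by = data.snps["beta_out"].to_numpy(dtype=float)
    sy = data.snps["se_out"].to_numpy(dtype=float)
    rsids = data.snps["rsid"].tolist()
    k = bx.size

    ratio = by / bx
    w = (bx / sy) ** 2  # 1/ratio_se^2
    loo_beta = _loo_ivw_beta(ratio, w)
    obs_resid2 = w * (ratio - loo_beta) ** 2
    rss_obs = float(np.sum(obs_resid2))

    # parametric simulations under the leave-one-out fitted model, vectorized
    bx_sim = rng.normal(bx, sx, size=(n_sim, k))
    by_sim = rng.normal(loo_beta * bx, sy, size=(n_sim, k))
    ratio_sim = by_sim / np.where(bx_sim == 0, np.finfo(float).tiny, bx_sim)
    w_sim = (bx_sim / sy) ** 2
    sw = np.sum(w_sim, axis=1, keepdims=True)
    swr = np.sum(w_sim * ratio_sim, axis=1, keepdims=True)
    loo_sim = (swr - w_sim * ratio_sim) / (sw - w_sim)
    resid2_sim = w_sim * (ratio_sim - loo_sim) ** 2
    rss_sim = np.sum(resid2_sim, axis=1)

    global_p = float((np.sum(rss_sim >= rss_obs) + 1) / (n_sim + 1))
    # per-SNP outlier p: simulated residual exceeding the observed one
    p_snp = (np.sum(resid2_sim >= obs_resid2[None, :], axis=0) + 1) / (n_sim + 1)
    p_adj = np.minimum(1.0, p_snp * k)
    outlier_mask = p_adj < outlier_p
    outliers = [r for r, m in zip(rsids, outlier_mask) if m]

    binary = data.outcome_binary
    raw, _ = ivw(data)
    raw.method = "presso_raw"
    raw.extras.update({"global_pval": global_p, "n_sim": n_sim, "seed": seed,
                       "outliers": outliers,
                       "outlier_pvals": dict(zip(rsids, p_adj.round(6).tolist()))})

    no_outliers_flag = len(outliers) == 0 or (k - len(outliers)) < 2
    if no_outliers_flag:
        corrected = _finish("presso_corrected", raw.beta, raw.se, k, binary,
                            extras=dict(raw.extras, corrected=False))
        return raw, corrected, outliers

    keep = ~outlier_mask
    corrected_ivw, _ = ivw(data.subset([r for r, m in zip(rsids, keep) if m]))
    beta_c, se_c = corrected_ivw.beta, corrected_ivw.se

    # distortion test: observed shift vs shifts from random same-size removals
    n_out = len(outliers)
    obs_dist = (raw.beta - beta_c) / abs(beta_c) if beta_c != 0 else np.inf
    n_dist = min(n_sim, 500)
    dists = np.empty(n_dist)
    for i in range(n_dist):
        drop = rng.choice(k, size=n_out, replace=False)
        m = np.ones(k, dtype=bool)
        m[drop] = False
        b_i = float(np.sum(w[m] * ratio[m]) / np.sum(w[m]))
        dists[i] = (raw.beta - b_i) / abs(b_i) if b_i != 0 else np.inf
    distortion_p = float((np.sum(np.abs(dists) >= abs(obs_dist)) + 1) / (n_dist + 1))

    corrected = _finish("presso_corrected", beta_c, se_c, int(np.sum(keep)), binary,
                        extras=dict(raw.extras, corrected=True,
                                    distortion_pval=distortion_p))
    return raw, corrected, outliers


def leave_one_out(data: HarmonizedData) -> pd.DataFrame:
    """IVW estimates omitting each SNP in turn; one row per omitted rsid."""
    _require(data, 3, "leave_one_out")
    rows = []
    for rsid in data.snps["rsid"]:
        sub = data.subset([r for r in data.snps["rsid"] if r != rsid])
        est, _ = ivw(sub)
        rows.append({"omitted_rsid": rsid, "beta": est.beta, "se": est.se,
                     "ci_low": est.ci_low, "ci_high": est.ci_high, "pval": est.pval})
    return pd.DataFrame(rows)


def estimates_table(estimates: list[MrEstimate]) -> pd.DataFrame:
    """Flat table of estimates with method extras JSON-encoded."""
    import json

    rows = []
    for e in estimates:
        row = e.as_row()
        row["extras"] = json.dumps(e.extras, default=str, sort_keys=True)
        rows.append(row)
    return pd.DataFrame(rows)
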