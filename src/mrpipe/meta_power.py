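"""Cross-GWAS meta-analysis, sex-difference testing, multiple-testing
classification and MR power calculation.

Pooling across outcome datasets uses a fixed-effect inverse-variance model on
the beta (log-odds) scale, with Cochran's Q and I^2 reporting between-dataset
heterogeneity. The sex-difference test is the two-group heterogeneity z-test,
algebraically identical to Cochran's Q with one degree of freedom. Power uses
the standard normal approximation for summary-data MR, where the effective
sample size is the outcome sample size times the instrument variance
explained (binary outcomes additionally inflated by the case-fraction
variance term).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .estimators import MrEstimate


@dataclass
class MetaResult:
    """Fixed-effect pooled estimate with heterogeneity statistics."""

    beta: float
    se: float
    pval: float
    q: float
    df: int
    p_het: float
    i2: float  # percentage in [0, 100]


@dataclass
class PowerResult:
    alpha: float
    power_target: float
    r2: float
    n: float
    case_fraction: Optional[float]
    min_detectable_beta: float
    min_detectable_or: float


def i_squared(q: float, df: int) -> float:
    """I^2 heterogeneity percentage: max(0, (Q - df)/Q) * 100."""
    if q <= 0:
        return 0.0
    return max(0.0, (q - df) / q) * 100.0


def meta_fixed(estimates: Sequence[MrEstimate]) -> MetaResult:
    """Inverse-variance fixed-effect pool of >= 2 estimates of the same effect."""
    if len(estimates) < 2:
        raise ValueError(f"meta_fixed needs >= 2 estimates, got {len(estimates)}")
    b = np.array([e.beta for e in estimates])
    w = np.array([1.0 / e.se ** 2 for e in estimates])
    beta = float(np.sum(w * b) / np.sum(w))
    se = math.sqrt(1.0 / np.sum(w))
    q = float(np.sum(w * (b - beta) ** 2))
    df = len(estimates) - 1
    p_het = float(stats.chi2.sf(q, df))
    z = beta / se
    pval = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return MetaResult(beta=beta, se=se, pval=pval, q=q, df=df, p_het=p_het,
                      i2=i_squared(q, df))


def sex_difference_test(est_men: MrEstimate, est_women: MrEstimate) -> float:
    """Two-sided p for a difference between sex-specific estimates.

    z = (b_m - b_w)/sqrt(se_m^2 + se_w^2); equivalent to a two-group
    Cochran Q heterogeneity test.
    """
    if est_men is None or est_women is None:
        raise ValueError("both sex-specific estimates are required")
    if est_men.se <= 0 or est_women.se <= 0:
        raise ValueError("sex-specific estimates must have se > 0")
    z = (est_men.beta - est_women.beta) / math.sqrt(est_men.se ** 2 + est_women.se ** 2)
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def classify_significance(
    pvals: dict[str, float], n_tests: int, alpha: float = 0.05
) -> dict[str, str]:
    """Bonferroni classification of per-outcome p-values.

    p < alpha/n_tests -> "significant"; alpha/n_tests <= p < alpha ->
    "suggestive"; otherwise "null".
    """
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    threshold = alpha / n_tests
    out = {}
    for key, p in pvals.items():
        if p < threshold:
            out[key] = "significant"
        elif p < alpha:
            out[key] = "suggestive"
        else:
            out[key] = "null"
    return out


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def min_detectable_effect(
    n: float,
    r2: float,
    case_fraction: Optional[float] = None,
    alpha: float = 0.05,
    power_target: float = 0.8,
) -> PowerResult:
    """Minimum detectable causal effect of a summary-data MR analysis.

    The causal-estimate standard error is approximated as
    1/sqrt(n * r2 * cf * (1 - cf)) for a binary outcome with case fraction
    cf (the cf term is dropped for quantitative outcomes). The minimum
    detectable effect at the target power is
    (z_{1-alpha/2} + z_{power}) * se.
    """
    if not (0 < r2 < 1):
        raise ValueError(f"r2 must lie in (0, 1), got {r2}")
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    if not (0 < alpha < 1) or not (0 < power_target < 1):
        raise ValueError("alpha and power_target must lie in (0, 1)")
    v = 1.0
    if case_fraction is not None:
        if not (0 < case_fraction < 1):
            raise ValueError(f"case_fraction must lie in (0, 1), got {case_fraction}")
        v = case_fraction * (1.0 - case_fraction)
    se = 1.0 / math.sqrt(n * r2 * v)
    mult = stats.norm.ppf(1 - alpha / 2) + stats.norm.ppf(power_target)
    beta_min = float(mult * se)
    return PowerResult(alpha=alpha, power_target=power_target, r2=r2, n=n,
                       case_fraction=case_fraction,
                       min_detectable_beta=beta_min,
                       min_detectable_or=math.exp(beta_min))
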