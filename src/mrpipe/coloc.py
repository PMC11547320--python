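"""Single-causal-variant Bayesian colocalization from summary statistics.

For two traits measured over the same genomic region, compares five
hypotheses: H0 (no association with either trait), H1/H2 (association with
one trait only), H3 (distinct causal variants for each trait) and H4 (one
shared causal variant). Per-SNP evidence is the Wakefield approximate Bayes
factor under a normal prior on the true effect; hypothesis likelihoods sum
single-causal-variant configurations weighted by per-SNP priors p1, p2, p12.
A high PP_H4 supports a shared causal variant (vertical pleiotropy for an MR
instrument); a high PP_H3 supports confounding by a distinct variant.

All sums are computed in log space with log-sum-exp for overflow safety at
large |z|.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import logsumexp

DEFAULT_PRIORS = (1e-4, 1e-4, 1e-5)  # (p1, p2, p12)
PRIOR_SD_QUANTITATIVE = 0.2
PRIOR_SD_BINARY = 0.15


@dataclass
class RegionStats:
    """Per-SNP summary statistics for one trait over a contiguous region."""

    trait: str
    trait_type: str  # "quantitative" | "binary"
    snps: pd.DataFrame  # columns rsid, beta, se
    n: float
    case_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.snps) < 1:
            raise ValueError("region must contain at least one SNP")
        if (self.snps["se"] <= 0).any():
            raise ValueError("all region SEs must be > 0")

    @property
    def prior_sd(self) -> float:
        return PRIOR_SD_BINARY if self.trait_type == "binary" else PRIOR_SD_QUANTITATIVE

    @classmethod
    def from_tsv(cls, path, trait: str, trait_type: str = "quantitative",
                 n: float = float("nan"), case_fraction: Optional[float] = None
                 ) -> "RegionStats":
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        return cls(trait=trait, trait_type=trait_type, snps=df[["rsid", "beta", "se"]],
                   n=n, case_fraction=case_fraction)


@dataclass
class ColocResult:
    """Posterior probabilities of the five colocalization hypotheses."""

    pp: dict[str, float]  # keys PP_H0..PP_H4
    priors: tuple[float, float, float]
    n_snps: int
    single_snp: bool = False

    def __post_init__(self) -> None:
        total = sum(self.pp.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"posteriors must sum to 1, got {total}")

    @property
    def pp_h4(self) -> float:
        return self.pp["PP_H4"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.pp])


def log_abf(beta: float, se: float, prior_sd: float) -> float:
    """Log Wakefield approximate Bayes factor for one SNP.

    With z = beta/se, V = se^2 and shrinkage r = prior_sd^2/(prior_sd^2 + V):
    log ABF = 0.5*(log(1-r) + r*z^2). Positive values favour a real effect.
    """
    if se <= 0:
        raise ValueError(f"se must be > 0, got {se}")
    if prior_sd <= 0:
        raise ValueError(f"prior_sd must be > 0, got {prior_sd}")
    z = beta / se
    v = se * se
    r = prior_sd ** 2 / (prior_sd ** 2 + v)
    return 0.5 * (math.log1p(-r) + r * z * z)


def _log_diff_exp(log_a: float, log_b: float) -> float:
    """log(exp(log_a) - exp(log_b)) for log_a >= log_b, safe near equality."""
    if log_b >= log_a:
        return -np.inf
    return log_a + math.log1p(-math.exp(log_b - log_a))


def colocalize(
    region1: RegionStats,
    region2: RegionStats,
    priors: tuple[float, float, float] = DEFAULT_PRIORS,
) -> ColocResult:
    """Posterior probabilities PP_H0..PP_H4 for two traits over one region.

    Regions are aligned on the intersection of their rsid lists (mismatches
    logged via the returned n_snps). Hypothesis likelihoods, up to a shared
    constant:

        H0 ∝ 1
        H1 ∝ p1 · Σ_i ABF1_i          H2 ∝ p2 · Σ_j ABF2_j
        H3 ∝ p1·p2 · Σ_{i≠j} ABF1_i·ABF2_j
        H4 ∝ p12 · Σ_i ABF1_i·ABF2_i
    """
    p1, p2, p12 = priors
    if min(p1, p2, p12) <= 0:
        raise ValueError("priors must be positive")
    df1 = region1.snps.set_index("rsid")
    df2 = region2.snps.set_index("rsid")
    common = [r for r in df1.index if r in set(df2.index)]
    if not common:
        raise ValueError("regions share no rsids")
    single = len(common) == 1

    l1 = np.array([log_abf(df1.at[r, "beta"], df1.at[r, "se"], region1.prior_sd)
                   for r in common])
    l2 = np.array([log_abf(df2.at[r, "beta"], df2.at[r, "se"], region2.prior_sd)
                   for r in common])

    log_sum1 = float(logsumexp(l1))
    log_sum2 = float(logsumexp(l2))
    log_sum12 = float(logsumexp(l1 + l2))

    log_h = np.empty(5)
    log_h[0] = 0.0
    log_h[1] = math.log(p1) + log_sum1
    log_h[2] = math.log(p2) + log_sum2
    # sum over i != j factorizes: (Σ ABF1)(Σ ABF2) - Σ ABF1·ABF2
    log_h[3] = math.log(p1) + math.log(p2) + _log_diff_exp(log_sum1 + log_sum2, log_sum12)
    log_h[4] = math.log(p12) + log_sum12

    log_post = log_h - logsumexp(log_h)
    post = np.exp(log_post)
    post /= post.sum()
    pp = {f"PP_H{i}": float(post[i]) for i in range(5)}
    return ColocResult(pp=pp, priors=(p1, p2, p12), n_snps=len(common),
                       single_snp=single)
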