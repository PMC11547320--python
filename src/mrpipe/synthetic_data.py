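"""Synthetic GWAS summary statistics and colocalization regions with known truth.

The MR generator draws per-SNP true exposure effects gamma_j on a
standardized-exposure scale, scaled so that the instruments jointly explain a
target fraction of exposure variance, then builds observed exposure and
outcome associations with the asymptotic sampling standard errors
se = 1/sqrt(2*maf*(1-maf)*n) (binary outcomes inflated by the case-fraction
variance term). Horizontal pleiotropy regimes (balanced, directional, or
correlated with instrument strength), weak instruments, outcome outliers and
harmonization hazards (palindromic allele pairs, swapped-allele records) can
all be injected, and the generating parameters are returned as a
:class:`SyntheticTruth` alongside the datasets.

The colocalization generator draws regional z-scores from a multivariate
normal with an AR(1) LD correlation structure and a configurable causal
configuration (shared, distinct, one-trait-only, or null).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field


import numpy as np
import pandas as pd
from scipy import stats

from .coloc import RegionStats
from .summary_stats import GwasSummary, SnpAssociation

# non-palindromic allele pairs cycled over generated SNPs
_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]
_PALINDROMIC_PAIRS = [("A", "T"), ("C", "G")]
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class SimConfig:
    """Generating parameters for one synthetic two-sample MR dataset.

    Defaults mirror the emulated study: nine instruments measured in an
    exposure GWAS of 121,577 individuals that jointly explain ~0.1% of the
    exposure variance (so each is strong, expected F > 10), with large
    binary-outcome GWAS.
    """

    k: int = 9
    n_exp: float = 121_577
    n_out: float = 500_000
    trait_type_out: str = "binary"
    case_fraction: float = 0.25
    true_beta: float = 0.0
    r2_total: float = 0.001
    pleiotropy_mode: str = "none"  # none | balanced | directional | inside_violating
    pleiotropy_sd: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_fraction: float = 1.0  # share of instruments carrying pleiotropy
    n_outliers: int = 0
    outlier_shift_sds: float = 0.0
    weak_fraction: float = 0.0
    inject_palindromic: int = 0
    inject_allele_swaps: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if not (0 < self.r2_total < 1):
            raise ValueError("r2_total must lie in (0, 1)")
        if not (0 <= self.weak_fraction <= 1):
            raise ValueError("weak_fraction must lie in [0, 1]")
        if not (0 <= self.pleiotropy_fraction <= 1):
            raise ValueError("pleiotropy_fraction must lie in [0, 1]")
        if self.pleiotropy_mode not in ("none", "balanced", "directional", "inside_violating"):
            raise ValueError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if self.trait_type_out not in ("quantitative", "binary"):
            raise ValueError(f"unknown trait_type_out {self.trait_type_out!r}")
        # each instrument needs expected F comfortably above the noise floor
        if self.r2_total * self.n_exp < self.k:
            raise ValueError(
                f"infeasible r2_total={self.r2_total} for k={self.k}, n_exp={self.n_exp}: "
                "expected chi-square per SNP below 1")


@dataclass
class SyntheticTruth:
    """The generating parameters recorded with every simulated dataset."""

    true_beta: float
    gamma: np.ndarray  # true per-SNP exposure effects
    alpha: np.ndarray  # true per-SNP pleiotropic outcome effects
    maf: np.ndarray
    seed: int
    outlier_rsids: list[str] = field(default_factory=list)
    weak_rsids: list[str] = field(default_factory=list)
    palindromic_rsids: list[str] = field(default_factory=list)
    swapped_rsids: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "true_beta": self.true_beta,
            "gamma": self.gamma.tolist(),
            "alpha": self.alpha.tolist(),
            "maf": self.maf.tolist(),
            "seed": self.seed,
            "outlier_rsids": self.outlier_rsids,
            "weak_rsids": self.weak_rsids,
            "palindromic_rsids": self.palindromic_rsids,
            "swapped_rsids": self.swapped_rsids,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(true_beta=d["true_beta"], gamma=np.array(d["gamma"]),
                   alpha=np.array(d["alpha"]), maf=np.array(d["maf"]),
                   seed=d["seed"], outlier_rsids=d["outlier_rsids"],
                   weak_rsids=d.get("weak_rsids", []),
                   palindromic_rsids=d["palindromic_rsids"],
                   swapped_rsids=d["swapped_rsids"])


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return np.clip(p, np.finfo(float).tiny, 1.0)


def generate_mr_dataset(config: SimConfig
                        ) -> tuple[GwasSummary, GwasSummary, SyntheticTruth]:
    """Generate (exposure GwasSummary, outcome GwasSummary, SyntheticTruth)."""
    rng = np.random.default_rng(config.seed)
    k = config.k
    maf = rng.uniform(0.05, 0.5, size=k)
    het = 2.0 * maf * (1.0 - maf)  # genotype variance under HWE

    gamma = rng.normal(0.0, 1.0, size=k)
    gamma *= math.sqrt(config.r2_total / float(np.sum(het * gamma ** 2)))

    se_exp = 1.0 / np.sqrt(het * config.n_exp)
    n_weak = int(round(config.weak_fraction * k))
    weak_idx = np.array([], dtype=int)
    if n_weak > 0:
        weak_idx = rng.choice(k, size=n_weak, replace=False)
        # down-scale so expected F = (gamma/se)^2 + 1 lands in ~3-8
        target_f = rng.uniform(3.0, 8.0, size=n_weak)
        gamma[weak_idx] = np.sign(gamma[weak_idx]) * np.sqrt(
            np.maximum(target_f - 1.0, 0.5)) * se_exp[weak_idx]

    beta_exp = rng.normal(gamma, se_exp)

    if config.pleiotropy_mode == "none":
        alpha = np.zeros(k)
    elif config.pleiotropy_mode == "balanced":
        alpha = rng.normal(0.0, config.pleiotropy_sd, size=k)
    elif config.pleiotropy_mode == "directional":
        # oriented relative to the exposure-increasing allele, so the bias
        # pushes every affected Wald ratio the same way
        alpha = np.sign(gamma) * rng.normal(config.pleiotropy_mean,
                                            config.pleiotropy_sd, size=k)
    else:  # inside_violating: pleiotropy correlated with instrument strength
        alpha = config.pleiotropy_mean * gamma + rng.normal(0.0, config.pleiotropy_sd, size=k)
    if config.pleiotropy_fraction < 1.0 and config.pleiotropy_mode != "none":
        n_pleio = int(round(config.pleiotropy_fraction * k))
        clean = rng.choice(k, size=k - n_pleio, replace=False)
        alpha[clean] = 0.0

    big_gamma = config.true_beta * gamma + alpha
    v = 1.0
    if config.trait_type_out == "binary":
        v = config.case_fraction * (1.0 - config.case_fraction)
    se_out = 1.0 / np.sqrt(het * config.n_out * v)
    beta_out = rng.normal(big_gamma, se_out)

    rsids = [f"rs{j + 1}" for j in range(k)]
    outlier_rsids: list[str] = []
    if config.n_outliers > 0:
        out_idx = rng.choice(k, size=min(config.n_outliers, k), replace=False)
        beta_out[out_idx] += config.outlier_shift_sds * se_out[out_idx]
        outlier_rsids = [rsids[i] for i in sorted(out_idx)]

    pairs = [_ALLELE_PAIRS[j % len(_ALLELE_PAIRS)] for j in range(k)]
    palindromic_rsids: list[str] = []
    for j in range(min(config.inject_palindromic, k)):
        idx = k - 1 - j  # perturb from the tail so low-index SNPs stay clean
        pairs[idx] = _PALINDROMIC_PAIRS[j % len(_PALINDROMIC_PAIRS)]
        palindromic_rsids.append(rsids[idx])

    p_exp = _two_sided_p(beta_exp, se_exp)
    p_out = _two_sided_p(beta_out, se_out)

    exp_records, out_records = [], []
    swapped_rsids: list[str] = []
    n_swaps = min(config.inject_allele_swaps, k)
    swap_idx = set(rng.choice(k, size=n_swaps, replace=False).tolist()) if n_swaps else set()
    for j in range(k):
        ea, oa = pairs[j]
        exp_records.append(SnpAssociation(
            rsid=rsids[j], chrom="1", pos=1000 * (j + 1),
            effect_allele=ea, other_allele=oa, eaf=float(maf[j]),
            beta=float(beta_exp[j]), se=float(se_exp[j]),
            pval=float(p_exp[j]), n=config.n_exp))
        o_ea, o_oa, o_beta, o_eaf = ea, oa, float(beta_out[j]), float(maf[j])
        if j in swap_idx:
            o_ea, o_oa = oa, ea
            o_beta, o_eaf = -o_beta, 1.0 - o_eaf
            swapped_rsids.append(rsids[j])
        out_records.append(SnpAssociation(
            rsid=rsids[j], chrom="1", pos=1000 * (j + 1),
            effect_allele=o_ea, other_allele=o_oa, eaf=o_eaf,
            beta=o_beta, se=float(se_out[j]),
            pval=float(p_out[j]), n=config.n_out,
            n_case=config.case_fraction * config.n_out
            if config.trait_type_out == "binary" else None))

    exposure = GwasSummary(trait="synthetic_exposure", trait_type="quantitative",
                           n=config.n_exp, records=exp_records)
    n_case = config.case_fraction * config.n_out if config.trait_type_out == "binary" else None
    outcome = GwasSummary(trait="synthetic_outcome", trait_type=config.trait_type_out,
                          n=config.n_out, records=out_records, n_case=n_case)
    truth = SyntheticTruth(true_beta=config.true_beta, gamma=gamma, alpha=alpha,
                           maf=maf, seed=config.seed, outlier_rsids=outlier_rsids,
                           weak_rsids=[rsids[i] for i in sorted(weak_idx)],
                           palindromic_rsids=palindromic_rsids,
                           swapped_rsids=swapped_rsids)
    return exposure, outcome, truth


def generate_coloc_region(
    m: int,
    rho: float,
    scenario: str,
    z_causal: float = 10.0,
    seed: int = 0,
    n: float = 100_000,
) -> tuple[RegionStats, RegionStats, dict]:
    """Generate two traits' regional summary stats with AR(1) LD.

    ``scenario`` is one of ``shared`` (one causal variant for both traits),
    ``distinct`` (two causal variants with pairwise r^2 < 0.01),
    ``trait1_only`` and ``null``. z-scores are drawn from
    MultivariateNormal(R @ lam, R) with R_ij = rho^|i-j| and lam carrying the
    non-centrality ``z_causal`` at the causal index.
    """
    if m < 2:
        raise ValueError("m must be >= 2")
    if not (0 <= rho < 1):
        raise ValueError("rho must lie in [0, 1)")
    if scenario not in ("shared", "distinct", "trait1_only", "null"):
        raise ValueError(f"unknown scenario {scenario!r}")
    rng = np.random.default_rng(seed)

    idx = np.arange(m)
    R = rho ** np.abs(idx[:, None] - idx[None, :])
    L = np.linalg.cholesky(R + 1e-10 * np.eye(m))

    c1 = m // 4
    if scenario == "distinct":
        c2 = 3 * m // 4
        if (rho ** abs(c2 - c1)) ** 2 >= 0.01:
            raise ValueError(
                f"distinct scenario infeasible: r2 between causal indexes "
                f"{(rho ** abs(c2 - c1)) ** 2:.3g} >= 0.01 at m={m}, rho={rho}")
    else:
        c2 = c1

    lam1 = np.zeros(m)
    lam2 = np.zeros(m)
    if scenario in ("shared", "trait1_only", "distinct"):
        lam1[c1] = z_causal
    if scenario == "shared":
        lam2[c1] = z_causal
    elif scenario == "distinct":
        lam2[c2] = z_causal

    z1 = R @ lam1 + L @ rng.standard_normal(m)
    z2 = R @ lam2 + L @ rng.standard_normal(m)

    maf = rng.uniform(0.05, 0.5, size=m)
    se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)
    rsids = [f"rs{j + 1}" for j in range(m)]
    df1 = pd.DataFrame({"rsid": rsids, "beta": z1 * se, "se": se})
    df2 = pd.DataFrame({"rsid": rsids, "beta": z2 * se, "se": se})
    r1 = RegionStats(trait="trait1", trait_type="quantitative", snps=df1, n=n)
    r2 = RegionStats(trait="trait2", trait_type="quantitative", snps=df2, n=n)
    truth = {"scenario": scenario, "causal_index_1": int(c1) if scenario != "null" else None,
             "causal_index_2": {"shared": int(c1), "distinct": int(c2)}.get(scenario),
             "z_causal": z_causal, "seed": seed}
    return r1, r2, truth
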