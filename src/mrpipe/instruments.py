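"""Instrument selection and quality control.

Candidates are SNPs associated with the exposure below a genome-wide
significance threshold (default p < 5e-8). Greedy LD clumping keeps the most
significant SNP of each correlated group (r-squared above the clumping
threshold, default 1e-3, to any retained index SNP discards a candidate).
Per-SNP instrument strength is the F-statistic (beta/se)^2, with F < 10
flagging a conventionally weak instrument; variance explained assumes a
standardized exposure, r2 = 2*eaf*(1-eaf)*beta^2.

Confounder screening is table-driven: an annotation table of (rsid, trait,
pval) rows stands in for live genotype-phenotype lookups; instruments
associated with an annotated trait below the screening threshold are flagged
but never removed here — removal is a pipeline-level sensitivity decision.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .summary_stats import GwasSummary, SnpAssociation

logger = logging.getLogger(__name__)

WEAK_F_THRESHOLD = 10.0


class EmptySelectionError(ValueError):
    """No candidate SNP passes the significance threshold."""


@dataclass
class LdMatrix:
    """Squared-correlation (r^2) matrix over an ordered rsid list."""

    rsids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        m = len(self.rsids)
        if self.r2.shape != (m, m):
            raise ValueError(f"r2 shape {self.r2.shape} does not match {m} rsids")
        if not np.allclose(self.r2, self.r2.T, atol=1e-8):
            raise ValueError("r2 matrix must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-8):
            raise ValueError("r2 diagonal must be 1")
        if self.r2.size and (self.r2.min() < -1e-12 or self.r2.max() > 1 + 1e-12):
            raise ValueError("r2 entries must lie in [0, 1]")
        self._pos = {r: i for i, r in enumerate(self.rsids)}

    def lookup(self, a: str, b: str) -> Optional[float]:
        """r^2 between two rsids, or None when either is not covered."""
        ia, ib = self._pos.get(a), self._pos.get(b)
        if ia is None or ib is None:
            return None
        return float(self.r2[ia, ib])

    @classmethod
    def identity(cls, rsids: Sequence[str]) -> "LdMatrix":
        return cls(list(rsids), np.eye(len(rsids)))

    @classmethod
    def from_tsv(cls, path) -> "LdMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError("LD matrix header row and column must list the same rsids")
        return cls([str(r) for r in df.index], df.to_numpy(dtype=float))

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.r2, index=self.rsids, columns=self.rsids).to_csv(path, sep="\t")


@dataclass
class InstrumentSet:
    """Retained instruments with per-SNP strength and confounder flags."""

    snps: list[SnpAssociation]
    f_stats: list[float]
    r2_per_snp: list[Optional[float]]
    confounder_flags: list[list[str]] = field(default_factory=list)
    unlinked_rsids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.confounder_flags:
            self.confounder_flags = [[] for _ in self.snps]
        if not (len(self.snps) == len(self.f_stats) == len(self.r2_per_snp)
                == len(self.confounder_flags)):
            raise ValueError("per-SNP vectors must align 1:1 with snps")

    @property
    def rsids(self) -> list[str]:
        return [s.rsid for s in self.snps]

    @property
    def r2_total(self) -> float:
        vals = [v for v in self.r2_per_snp if v is not None]
        return float(np.clip(sum(vals), 0.0, 1.0))

    @property
    def weak(self) -> list[bool]:
        return [f < WEAK_F_THRESHOLD for f in self.f_stats]

    @property
    def flagged_rsids(self) -> list[str]:
        return [s.rsid for s, fl in zip(self.snps, self.confounder_flags) if fl]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "rsid": self.rsids,
            "chrom": [s.chrom for s in self.snps],
            "pos": [s.pos for s in self.snps],
            "pval": [s.pval for s in self.snps],
            "f_stat": self.f_stats,
            "weak": self.weak,
            "r2": [np.nan if v is None else v for v in self.r2_per_snp],
            "confounder_flags": [",".join(f) for f in self.confounder_flags],
        })


def f_statistic(beta: float, se: float) -> float:
    """Per-SNP instrument strength, (beta/se)^2."""
    if se <= 0:
        raise ValueError(f"se must be > 0, got {se}")
    return (beta / se) ** 2


def variance_explained(snp: SnpAssociation) -> Optional[float]:
    """Exposure variance explained by one SNP: 2*eaf*(1-eaf)*beta^2.

    Assumes a standardized (unit-variance) exposure. Returns None when eaf is
    missing or degenerate; such SNPs are excluded from the set-level total with
    a logged warning.
    """
    if snp.eaf is None or not (0 < snp.eaf < 1):
        logger.warning("variance_explained: %s has missing/degenerate eaf; excluded from r2 total",
                       snp.rsid)
        return None
    return float(np.clip(2.0 * snp.eaf * (1.0 - snp.eaf) * snp.beta ** 2, 0.0, 1.0))


def _clump_sort_key(rec: SnpAssociation):
    # ties in p broken by (chrom, pos) ascending then rsid, for determinism
    return (rec.pval, rec.chrom, rec.pos, rec.rsid)


def select_instruments(
    gwas: GwasSummary,
    p_threshold: float = 5e-8,
    ld: Optional[LdMatrix] = None,
    r2_threshold: float = 1e-3,
) -> InstrumentSet:
    """Select significant, approximately independent instruments.

    Candidates have pval strictly below ``p_threshold``. Greedy clumping takes
    the smallest-p remaining candidate as an index SNP and discards candidates
    with r^2 > ``r2_threshold`` to any retained index. SNPs absent from the LD
    matrix are treated as unlinked and logged.
    """
    candidates = sorted((r for r in gwas.records if r.pval < p_threshold), key=_clump_sort_key)
    if not candidates:
        raise EmptySelectionError(
            f"no SNP in {gwas.trait!r} passes p < {p_threshold:g}"
        )
    if ld is None:
        ld = LdMatrix.identity([])

    retained: list[SnpAssociation] = []
    unlinked: list[str] = []
    for cand in candidates:
        conflict = False
        for idx_snp in retained:
            r2 = ld.lookup(cand.rsid, idx_snp.rsid)
            if r2 is None:
                continue
            if r2 > r2_threshold:
                conflict = True
                break
        if ld.lookup(cand.rsid, cand.rsid) is None:
            unlinked.append(cand.rsid)
        if not conflict:
            retained.append(cand)
    if unlinked:
        logger.warning("select_instruments: %d SNPs absent from the LD matrix, "
                       "treated as unlinked: %s", len(unlinked), ", ".join(unlinked))

    f_stats = [f_statistic(s.beta, s.se) for s in retained]
    r2_per = [variance_explained(s) for s in retained]
    return InstrumentSet(snps=retained, f_stats=f_stats, r2_per_snp=r2_per,
                         unlinked_rsids=unlinked)


def read_annotations(path) -> pd.DataFrame:
    """Long-format annotation table: columns rsid, trait, pval."""
    df = pd.read_csv(path, sep="\t")
    required = {"rsid", "trait", "pval"}
    if not required.issubset(df.columns):
        raise ValueError(f"annotation table needs columns {sorted(required)}, "
                         f"found {list(df.columns)}")
    return df


def screen_confounders(
    instruments: InstrumentSet,
    annotations: pd.DataFrame,
    p_threshold: float = 5e-8,
) -> InstrumentSet:
    """Flag instruments associated with annotated traits below ``p_threshold``.

    Flags are recorded per instrument; nothing is removed here. Missing
    annotation rows simply produce no flags.
    """
    ann = annotations[annotations["pval"] < p_threshold]
    by_rsid: dict[str, list[str]] = {}
    for row in ann.itertuples(index=False):
        by_rsid.setdefault(str(row.rsid), []).append(str(row.trait))
    flags = [sorted(set(by_rsid.get(s.rsid, []))) for s in instruments.snps]
    return dataclasses.replace(instruments, confounder_flags=flags)
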