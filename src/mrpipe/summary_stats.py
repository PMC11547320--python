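"""GWAS summary-statistics data model, I/O, and exposure/outcome harmonization.

The central objects are :class:`SnpAssociation` (one SNP's association with one
trait), :class:`GwasSummary` (a full summary-statistics dataset) and
:class:`HarmonizedData` (exposure/outcome effect pairs aligned to a shared
effect allele, with a drop log).

Harmonization follows the standard two-sample MR conventions: records are
matched by rsid; outcome effects are sign-flipped when the outcome's effect
allele is the exposure's other allele; strand-complemented records are
re-complemented before matching; palindromic SNPs (A/T, C/G) are dropped
unconditionally because strand alignment is ambiguous for them.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

DEFAULT_COLUMNS: Mapping[str, str] = {
    "rsid": "rsid",
    "chrom": "chr",
    "pos": "pos",
    "effect_allele": "ea",
    "other_allele": "oa",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pval": "pval",
    "n": "n",
}


class GwasIOError(IOError):
    """Raised when a summary-statistics file cannot be read."""


class GwasConfigError(ValueError):
    """Raised when the column map does not cover the required fields."""


class EmptyInputError(ValueError):
    """Raised when an operation receives zero usable records."""


@dataclass(frozen=True)
class SnpAssociation:
    """One SNP's summary association with one trait.

    ``beta`` is the effect per copy of ``effect_allele`` — per-SD units for
    quantitative traits, log-odds for binary traits. ``eaf`` may be missing
    (None); it is not needed once palindromic SNPs are removed.
    """

    rsid: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: Optional[float]
    beta: float
    se: float
    pval: float
    n: float
    n_case: Optional[float] = None

    def validate(self) -> None:
        if self.effect_allele not in VALID_ALLELES:
            raise ValueError(f"{self.rsid}: invalid effect allele {self.effect_allele!r}")
        if self.other_allele not in VALID_ALLELES:
            raise ValueError(f"{self.rsid}: invalid other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.rsid}: effect and other allele identical")
        if not (self.se > 0):
            raise ValueError(f"{self.rsid}: se must be > 0, got {self.se}")
        if not (0 < self.pval <= 1):
            raise ValueError(f"{self.rsid}: pval must lie in (0, 1], got {self.pval}")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise ValueError(f"{self.rsid}: eaf out of [0, 1]: {self.eaf}")
        if self.pos < 1:
            raise ValueError(f"{self.rsid}: pos must be >= 1, got {self.pos}")

    @property
    def is_palindromic(self) -> bool:
        return COMPLEMENT[self.effect_allele] == self.other_allele


@dataclass
class GwasSummary:
    """A summary-statistics dataset for one trait.

    rsids are unique within ``records``; for binary traits the betas are on the
    log-odds scale.
    """

    trait: str
    trait_type: str  # "quantitative" | "binary"
    n: float
    records: list[SnpAssociation]
    n_case: Optional[float] = None
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "binary"):
            raise ValueError(f"trait_type must be quantitative|binary, got {self.trait_type}")
        rsids = [r.rsid for r in self.records]
        if len(rsids) != len(set(rsids)):
            raise ValueError(f"{self.trait}: duplicate rsids in records")

    def __len__(self) -> int:
        return len(self.records)

    def get(self, rsid: str) -> Optional[SnpAssociation]:
        return self._index().get(rsid)

    def _index(self) -> dict[str, SnpAssociation]:
        idx = getattr(self, "_idx", None)
        if idx is None or len(idx) != len(self.records):
            idx = {r.rsid: r for r in self.records}
            object.__setattr__(self, "_idx", idx)
        return idx

    def to_frame(self) -> pd.DataFrame:
        rows = [dataclasses.asdict(r) for r in self.records]
        df = pd.DataFrame(
            rows,
            columns=["rsid", "chrom", "pos", "effect_allele", "other_allele",
                     "eaf", "beta", "se", "pval", "n", "n_case"],
        )
        return df


@dataclass
class HarmonizedData:
    """Exposure/outcome pairs on a common effect allele plus per-SNP drop reasons.

    ``snps`` columns: rsid, beta_exp, se_exp, beta_out, se_out, eaf_exp.
    ``dropped`` columns: rsid, reason with reason in
    {palindromic, allele_mismatch, missing_in_outcome, duplicate}.
    """

    exposure_trait: str
    outcome_trait: str
    snps: pd.DataFrame
    dropped: pd.DataFrame
    outcome_trait_type: str = "quantitative"
    exposure_trait_type: str = "quantitative"
    outcome_n: float = float("nan")
    outcome_case_fraction: Optional[float] = None

    @property
    def n_snp(self) -> int:
        return len(self.snps)

    @property
    def outcome_binary(self) -> bool:
        return self.outcome_trait_type == "binary"

    def subset(self, rsids: Sequence[str]) -> "HarmonizedData":
        keep = self.snps[self.snps["rsid"].isin(set(rsids))].reset_index(drop=True)
        return dataclasses.replace(self, snps=keep)

    def write(self, snp_path, drop_path=None) -> None:
        self.snps.to_csv(snp_path, sep="\t", index=False)
        if drop_path is not None:
            self.dropped.to_csv(drop_path, sep="\t", index=False)


def _coerce_float(value) -> Optional[float]:
    if value is None:
        return None
    try:
        f = float(value)
    except (TypeError, ValueError):
        return None
    if np.isnan(f):
        return None
    return f


def _sniff_sep(path) -> str:
    """Tab or comma, decided from the header line (gzip transparent)."""
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_gwas(
    path,
    column_map: Optional[Mapping[str, str]] = None,
    trait: str = "trait",
    trait_type: str = "quantitative",
    n: Optional[float] = None,
    n_case: Optional[float] = None,
) -> GwasSummary:
    """Read a tab- or comma-separated summary-statistics file.

    ``column_map`` maps SnpAssociation field names to column names in the file
    (defaults in :data:`DEFAULT_COLUMNS`). Rows violating the per-SNP
    invariants are dropped and counted in ``n_dropped``; alleles are
    upper-cased. Duplicate rsids keep the smallest-p record.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    try:
        sep = _sniff_sep(path)
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as exc:
        raise GwasIOError(f"cannot read summary statistics from {path}: {exc}") from exc

    required = ["rsid", "chrom", "pos", "effect_allele", "other_allele", "beta", "se", "pval"]
    for f in required:
        if cols[f] not in df.columns:
            raise GwasConfigError(
                f"column {cols[f]!r} (field {f!r}) absent from {path}; present: {list(df.columns)}"
            )
    has_eaf = cols["eaf"] in df.columns
    has_n = cols["n"] in df.columns

    records: list[SnpAssociation] = []
    n_dropped = 0
    for row in df.itertuples(index=False):
        row = row._asdict()
        try:
            rec = SnpAssociation(
                rsid=str(row[cols["rsid"]]),
                chrom=str(row[cols["chrom"]]),
                pos=int(row[cols["pos"]]),
                effect_allele=str(row[cols["effect_allele"]]).upper(),
                other_allele=str(row[cols["other_allele"]]).upper(),
                eaf=_coerce_float(row[cols["eaf"]]) if has_eaf else None,
                beta=float(row[cols["beta"]]),
                se=float(row[cols["se"]]),
                pval=float(row[cols["pval"]]),
                n=float(row[cols["n"]]) if has_n else float(n if n is not None else np.nan),
            )
            rec.validate()
        except (ValueError, TypeError, KeyError):
            n_dropped += 1
            continue
        records.append(rec)

    # duplicate rsids: keep the smallest-p record
    best: dict[str, SnpAssociation] = {}
    for rec in records:
        prev = best.get(rec.rsid)
        if prev is None or rec.pval < prev.pval:
            if prev is not None:
                n_dropped += 1
            best[rec.rsid] = rec
        else:
            n_dropped += 1
    records = list(best.values())

    if not records:
        raise EmptyInputError(f"no valid summary-statistics rows in {path}")
    total_n = n if n is not None else float(np.nanmax([r.n for r in records]))
    return GwasSummary(trait=trait, trait_type=trait_type, n=total_n,
                       records=records, n_case=n_case, n_dropped=n_dropped)


def write_gwas(gwas: GwasSummary, path) -> None:
    """Write a GwasSummary in the dialect read_gwas consumes (default columns)."""
    df = gwas.to_frame().rename(columns={
        "chrom": "chr", "effect_allele": "ea", "other_allele": "oa",
    })
    df = df.drop(columns=["n_case"])
    # %.17g round-trips IEEE doubles exactly
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def _dedupe(records: Sequence[SnpAssociation]) -> tuple[dict[str, SnpAssociation], list[str]]:
    best: dict[str, SnpAssociation] = {}
    dup: list[str] = []
    for rec in records:
        prev = best.get(rec.rsid)
        if prev is None:
            best[rec.rsid] = rec
        else:
            dup.append(rec.rsid)
            if rec.pval < prev.pval:
                best[rec.rsid] = rec
    return best, dup


def harmonize(
    exposure: GwasSummary,
    outcome: GwasSummary,
    instrument_rsids: Sequence[str],
) -> HarmonizedData:
    """Align instrument SNPs of ``exposure`` with ``outcome`` on a shared effect allele.

    For each instrument present in the outcome:

    * identical allele pairs — kept as-is;
    * swapped alleles (effect/other exchanged) — beta_out negated, eaf -> 1-eaf;
    * strand complement (possibly swapped) of a non-palindromic pair —
      complemented, then the swap rule applied;
    * palindromic pairs (A/T or C/G) — dropped, regardless of frequency;
    * anything else — dropped as allele_mismatch.

    Instruments absent from the outcome are dropped as missing_in_outcome.
    """
    if len(instrument_rsids) == 0:
        raise EmptyInputError("harmonize: empty instrument list")
    exp_idx, exp_dup = _dedupe(exposure.records)
    out_idx, out_dup = _dedupe(outcome.records)
    missing = [r for r in instrument_rsids if r not in exp_idx]
    if missing:
        raise ValueError(f"instruments not in exposure dataset: {missing}")

    kept_rows = []
    dropped_rows = [{"rsid": r, "reason": "duplicate"} for r in set(exp_dup + out_dup)
                    if r in set(instrument_rsids)]
    for rsid in instrument_rsids:
        e = exp_idx[rsid]
        o = out_idx.get(rsid)
        if o is None:
            dropped_rows.append({"rsid": rsid, "reason": "missing_in_outcome"})
            continue
        if e.is_palindromic:
            dropped_rows.append({"rsid": rsid, "reason": "palindromic"})
            continue
        ea, oa = e.effect_allele, e.other_allele
        pair = (o.effect_allele, o.other_allele)
        comp_pair = (COMPLEMENT[o.effect_allele], COMPLEMENT[o.other_allele])
        if pair == (ea, oa):
            beta_out, se_out = o.beta, o.se
        elif pair == (oa, ea):
            beta_out, se_out = -o.beta, o.se
        elif comp_pair == (ea, oa):
            beta_out, se_out = o.beta, o.se
        elif comp_pair == (oa, ea):
            beta_out, se_out = -o.beta, o.se
        else:
            dropped_rows.append({"rsid": rsid, "reason": "allele_mismatch"})
            continue
        kept_rows.append({
            "rsid": rsid,
            "beta_exp": e.beta, "se_exp": e.se,
            "beta_out": beta_out, "se_out": se_out,
            "eaf_exp": np.nan if e.eaf is None else e.eaf,
        })

    snps = pd.DataFrame(kept_rows, columns=["rsid", "beta_exp", "se_exp",
                                            "beta_out", "se_out", "eaf_exp"])
    dropped = pd.DataFrame(dropped_rows, columns=["rsid", "reason"])
    case_fraction = None
    if outcome.trait_type == "binary" and outcome.n_case and outcome.n:
        case_fraction = float(outcome.n_case) / float(outcome.n)
    return HarmonizedData(
        exposure_trait=exposure.trait,
        outcome_trait=outcome.trait,
        snps=snps,
        dropped=dropped,
        outcome_trait_type=outcome.trait_type,
        exposure_trait_type=exposure.trait_type,
        outcome_n=outcome.n,
        outcome_case_fraction=case_fraction,
    )
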