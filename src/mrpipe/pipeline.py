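"""Study orchestration: per-outcome MR with the full estimator suite,
confounder/colocalization-driven sensitivity sets, meta-analysis across
outcome datasets, sex-specific analyses, bidirectional MR and power.

The study is described either in memory (:class:`StudyInputs`, built from
`GwasSummary` objects — the natural route for simulation studies) or by a
YAML run configuration pointing at summary-statistics files
(:func:`load_study`). :func:`run_study` executes the same analysis chain
either way and emits a :class:`StudyReport` whose tables can be written as
TSVs plus a JSON manifest. Failure of one outcome is isolated: it is recorded
in the report and the remaining outcomes still run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coloc import DEFAULT_PRIORS, ColocResult, RegionStats, colocalize
from .estimators import (InsufficientInstrumentsError, MrEstimate, egger,
                         estimates_table, ivw, leave_one_out, mr_presso, pivw,
                         wald_ratio, weighted_median, weighted_mode, _finish)
from .instruments import (InstrumentSet, LdMatrix, read_annotations,
                          screen_confounders, select_instruments)
from .meta_power import (MetaResult, PowerResult, classify_significance,
                         meta_fixed, min_detectable_effect,
                         sex_difference_test)
from .summary_stats import GwasSummary, HarmonizedData, harmonize, read_gwas

logger = logging.getLogger(__name__)


@dataclass
class EstimatorSettings:
    boot_reps: int = 1000
    presso_sims: int = 1000
    presso_outlier_p: float = 0.05
    pivw_penalty: float = 1.0
    bandwidth_factor: float = 1.0
    seed: int = 0


@dataclass
class OutcomeSpec:
    """One outcome: one or two datasets, optional sex strata and coloc regions."""

    name: str
    datasets: list[GwasSummary]
    sex_datasets: dict[str, GwasSummary] = field(default_factory=dict)
    # rsid -> (exposure RegionStats, outcome RegionStats) for coloc screening
    coloc_regions: dict[str, tuple[RegionStats, RegionStats]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.datasets:
            raise ValueError(f"outcome {self.name!r} lists no datasets")


@dataclass
class StudyInputs:
    """A fully-resolved study: exposure, outcomes and analysis settings."""

    exposure: GwasSummary
    outcomes: list[OutcomeSpec]
    ld: Optional[LdMatrix] = None
    annotations: Optional[pd.DataFrame] = None
    p_threshold: float = 5e-8
    r2_threshold: float = 1e-3
    confounder_p: float = 5e-8
    outcome_assoc_p: float = 5e-8
    coloc_priors: tuple[float, float, float] = DEFAULT_PRIORS
    pp_h4_threshold: float = 0.8
    estimator: EstimatorSettings = field(default_factory=EstimatorSettings)
    n_tests: int = 15
    alpha: float = 0.05
    power_target: float = 0.8


@dataclass
class OutcomeReport:
    name: str
    estimates: pd.DataFrame  # all methods x instrument sets x strata
    heterogeneity: dict
    leave_one_out: dict[str, pd.DataFrame]
    meta: Optional[MetaResult]
    sex_difference_p: Optional[float]
    sensitivity_sets: dict[str, list[str]]
    sensitivity_exclusions: dict[str, list[dict]]
    coloc: dict[str, ColocResult]
    power: Optional[PowerResult]
    drop_logs: dict[str, pd.DataFrame]
    scatter: dict[str, pd.DataFrame] = field(default_factory=dict)
    error: Optional[str] = None


@dataclass
class StudyReport:
    instruments: pd.DataFrame
    outcomes: dict[str, OutcomeReport]
    significance: dict[str, str]
    manifest: dict
    reverse: dict[str, pd.DataFrame] = field(default_factory=dict)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.instruments.to_csv(out / "instruments.tsv", sep="\t", index=False)
        for name, rep in self.outcomes.items():
            if rep.error is not None:
                continue
            rep.estimates.to_csv(out / f"{name}_estimates.tsv", sep="\t", index=False)
            for label, loo in rep.leave_one_out.items():
                loo.to_csv(out / f"{name}_loo_{label}.tsv", sep="\t", index=False)
            for label, log in rep.drop_logs.items():
                log.to_csv(out / f"{name}_drops_{label}.tsv", sep="\t", index=False)
            for label, tab in rep.scatter.items():
                tab.to_csv(out / f"{name}_scatter_{label}.tsv", sep="\t", index=False)
        for name, tab in self.reverse.items():
            tab.to_csv(out / f"reverse_{name}_estimates.tsv", sep="\t", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=1, sort_keys=True, default=str)


def build_sensitivity_sets(
    instruments: InstrumentSet,
    coloc_results: dict[tuple[str, str], ColocResult],
    pp_h4_threshold: float,
    outcomes: Sequence[str],
    outcome_associated: Optional[dict[str, set]] = None,
) -> tuple[dict[str, list[str]], dict[str, list[dict]]]:
    """Per-outcome sensitivity instrument sets from confounder flags and coloc.

    The main set keeps every instrument. For each outcome, the sensitivity set
    excludes confounder-flagged instruments unless colocalization with that
    outcome supports a shared causal variant (PP_H4 >= threshold — read as
    vertical pleiotropy, so the instrument is retained). A flagged SNP that is
    also outcome-associated but lacks a coloc result is a hard error.
    """
    outcome_associated = outcome_associated or {}
    sets: dict[str, list[str]] = {"main": list(instruments.rsids)}
    exclusions: dict[str, list[dict]] = {"main": []}
    for outcome in outcomes:
        keep: list[str] = []
        excl: list[dict] = []
        assoc = outcome_associated.get(outcome, set())
        for snp, flags in zip(instruments.snps, instruments.confounder_flags):
            if not flags:
                keep.append(snp.rsid)
                continue
            res = coloc_results.get((snp.rsid, outcome))
            if res is None:
                if snp.rsid in assoc:
                    raise ValueError(
                        f"missing colocalization result for flagged, outcome-associated "
                        f"SNP {snp.rsid!r} with outcome {outcome!r}")
                excl.append({"rsid": snp.rsid, "reason":
                             f"confounder-flagged ({','.join(flags)}), no coloc support"})
                continue
            if res.pp_h4 >= pp_h4_threshold:
                keep.append(snp.rsid)
            else:
                excl.append({"rsid": snp.rsid, "reason":
                             f"confounder-flagged ({','.join(flags)}), "
                             f"PP_H4={res.pp_h4:.3f} < {pp_h4_threshold}"})
        sets[outcome] = keep
        exclusions[outcome] = excl
    return sets, exclusions


def _estimator_suite(data: HarmonizedData, settings: EstimatorSettings,
                     seed_offset: int = 0) -> list[MrEstimate]:
    """Run every applicable estimator; silently skip those lacking instruments."""
    ests: list[MrEstimate] = []
    seed = (settings.seed + seed_offset) % (2 ** 31)
    if data.n_snp == 1:
        row = data.snps.iloc[0]
        r, r_se = wald_ratio(row.beta_exp, row.se_exp, row.beta_out, row.se_out)
        ests.append(_finish("wald", r, r_se, 1, data.outcome_binary))
        return ests
    try:
        est, _ = ivw(data)
        ests.append(est)
    except InsufficientInstrumentsError:
        return ests
    try:
        ests.append(pivw(data, penalty=settings.pivw_penalty))
    except (InsufficientInstrumentsError, ValueError) as exc:
        logger.warning("pivw skipped: %s", exc)
    for fn in (
        lambda: egger(data)[0],
        lambda: weighted_median(data, settings.boot_reps, seed),
        lambda: weighted_mode(data, settings.bandwidth_factor, settings.boot_reps, seed + 1),
    ):
        try:
            ests.append(fn())
        except InsufficientInstrumentsError:
            pass
    try:
        raw, corrected, _ = mr_presso(data, settings.presso_sims,
                                      settings.presso_outlier_p, seed + 2)
        ests.extend([raw, corrected])
    except InsufficientInstrumentsError:
        pass
    return ests


def _outcome_assoc_rsids(datasets: Sequence[GwasSummary], rsids: Sequence[str],
                         p_threshold: float) -> set:
    assoc = set()
    for ds in datasets:
        for rsid in rsids:
            rec = ds.get(rsid)
            if rec is not None and rec.pval < p_threshold:
                assoc.add(rsid)
    return assoc


def _analyze_outcome(spec: OutcomeSpec, exposure: GwasSummary,
                     instruments: InstrumentSet, inputs: StudyInputs,
                     seed_offset: int) -> OutcomeReport:
    settings = inputs.estimator
    est_rows = []
    het: dict = {}
    loo_tables: dict[str, pd.DataFrame] = {}
    drop_logs: dict[str, pd.DataFrame] = {}

    # colocalization screening for confounder-flagged instruments
    coloc_results: dict[tuple[str, str], ColocResult] = {}
    coloc_out: dict[str, ColocResult] = {}
    for rsid, (reg_exp, reg_out) in spec.coloc_regions.items():
        res = colocalize(reg_exp, reg_out, inputs.coloc_priors)
        coloc_results[(rsid, spec.name)] = res
        coloc_out[rsid] = res

    assoc = {spec.name: _outcome_assoc_rsids(
        spec.datasets, instruments.flagged_rsids, inputs.outcome_assoc_p)}
    sets, exclusions = build_sensitivity_sets(
        instruments, coloc_results, inputs.pp_h4_threshold, [spec.name], assoc)
    set_labels = {"main": sets["main"], "sensitivity": sets[spec.name]}

    ivw_per_dataset: list[MrEstimate] = []
    scatter: dict[str, pd.DataFrame] = {}
    for d_i, ds in enumerate(spec.datasets):
        harmonized = harmonize(exposure, ds, instruments.rsids)
        drop_logs[ds.trait] = harmonized.dropped
        scatter[ds.trait] = harmonized.snps  # per-SNP plot data
        for label, rsids in set_labels.items():
            sub = harmonized.subset(rsids)
            if sub.n_snp == 0:
                continue
            ests = _estimator_suite(sub, settings, seed_offset + 10 * d_i)
            for e in ests:
                row = e.as_row()
                row.update({"dataset": ds.trait, "instrument_set": label,
                            "stratum": "all",
                            "extras": json.dumps(e.extras, default=str, sort_keys=True)})
                est_rows.append(row)
                if label == "main" and e.method == "ivw":
                    ivw_per_dataset.append(e)
                    het[ds.trait] = {"q": e.extras["q"], "df": e.n_snp - 1,
                                     "pval": e.extras["q_pval"]}
        try:
            loo_tables[ds.trait] = leave_one_out(harmonized)
        except InsufficientInstrumentsError:
            pass

    meta = meta_fixed(ivw_per_dataset) if len(ivw_per_dataset) >= 2 else None

    # sex-specific IVW (main instrument set) + sex-difference heterogeneity test
    sex_est: dict[str, MrEstimate] = {}
    for stratum, ds in spec.sex_datasets.items():
        harmonized = harmonize(exposure, ds, instruments.rsids)
        ests = _estimator_suite(harmonized, settings, seed_offset + 100)
        for e in ests:
            row = e.as_row()
            row.update({"dataset": ds.trait, "instrument_set": "main",
                        "stratum": stratum,
                        "extras": json.dumps(e.extras, default=str, sort_keys=True)})
            est_rows.append(row)
            if e.method == "ivw":
                sex_est[stratum] = e
    sex_p = None
    if {"men", "women"} <= set(sex_est):
        sex_p = sex_difference_test(sex_est["men"], sex_est["women"])

    n_total = sum(ds.n for ds in spec.datasets)
    case_fraction = None
    if spec.datasets[0].trait_type == "binary":
        n_cases = sum(ds.n_case or 0 for ds in spec.datasets)
        if n_cases > 0:
            case_fraction = n_cases / n_total
    r2 = instruments.r2_total
    power = None
    if 0 < r2 < 1:
        power = min_detectable_effect(n_total, r2, case_fraction,
                                      inputs.alpha, inputs.power_target)

    return OutcomeReport(
        name=spec.name,
        estimates=pd.DataFrame(est_rows),
        heterogeneity=het,
        leave_one_out=loo_tables,
        meta=meta,
        sex_difference_p=sex_p,
        sensitivity_sets=set_labels,
        sensitivity_exclusions={"main": exclusions["main"],
                                "sensitivity": exclusions[spec.name]},
        coloc=coloc_out,
        power=power,
        drop_logs=drop_logs,
        scatter=scatter,
    )


def run_study(inputs: StudyInputs, output_dir=None) -> StudyReport:
    """Execute the full study over every configured outcome.

    Deterministic given the seeds in ``inputs.estimator``; a hard error in one
    outcome aborts that outcome only. A run where every outcome fails raises.
    """
    instruments = select_instruments(inputs.exposure, inputs.p_threshold,
                                     inputs.ld, inputs.r2_threshold)
    if inputs.annotations is not None:
        instruments = screen_confounders(instruments, inputs.annotations,
                                         inputs.confounder_p)

    outcome_reports: dict[str, OutcomeReport] = {}
    headline_p: dict[str, float] = {}
    for i, spec in enumerate(sorted(inputs.outcomes, key=lambda s: s.name)):
        try:
            rep = _analyze_outcome(spec, inputs.exposure, instruments, inputs,
                                   seed_offset=1000 * (i + 1))
        except Exception as exc:  # noqa: BLE001 — failure isolation per outcome
            logger.error("outcome %s failed: %s", spec.name, exc)
            outcome_reports[spec.name] = OutcomeReport(
                name=spec.name, estimates=pd.DataFrame(), heterogeneity={},
                leave_one_out={}, meta=None, sex_difference_p=None,
                sensitivity_sets={}, sensitivity_exclusions={}, coloc={},
                power=None, drop_logs={}, scatter={}, error=str(exc))
            continue
        outcome_reports[spec.name] = rep
        if rep.meta is not None:
            headline_p[spec.name] = rep.meta.pval
        elif "method" in rep.estimates.columns:
            main_ivw = rep.estimates.query(
                "method == 'ivw' and instrument_set == 'main' and stratum == 'all'")
            if len(main_ivw):
                headline_p[spec.name] = float(main_ivw.iloc[0]["pval"])

    if all(rep.error is not None for rep in outcome_reports.values()):
        raise RuntimeError("every outcome failed; nothing to report")

    significance = classify_significance(headline_p, inputs.n_tests, inputs.alpha)
    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "seed": inputs.estimator.seed,
        "p_threshold": inputs.p_threshold,
        "r2_threshold": inputs.r2_threshold,
        "n_tests": inputs.n_tests,
        "alpha": inputs.alpha,
        "pp_h4_threshold": inputs.pp_h4_threshold,
        "instruments": instruments.rsids,
        "r2_total": instruments.r2_total,
        "significance": significance,
        "outcome_errors": {n: r.error for n, r in outcome_reports.items() if r.error},
        "meta": {n: dataclasses.asdict(r.meta) for n, r in outcome_reports.items()
                 if r.meta is not None},
        "sex_difference_p": {n: r.sex_difference_p for n, r in outcome_reports.items()
                             if r.sex_difference_p is not None},
        "power": {n: dataclasses.asdict(r.power) for n, r in outcome_reports.items()
                  if r.power is not None},
    }
    report = StudyReport(instruments=instruments.to_frame(),
                         outcomes=outcome_reports,
                         significance=significance, manifest=manifest)
    if output_dir is not None:
        report.write(output_dir)
    return report


def run_bidirectional(inputs: StudyInputs) -> dict[str, pd.DataFrame]:
    """Reverse-direction MR: each outcome's own instruments against the exposure.

    Instruments are selected from the outcome GWAS under the same thresholds
    and the estimation chain runs with the roles swapped. An outcome whose
    reverse selection is empty yields a single "not estimable" row instead of
    failing the run.
    """
    sections: dict[str, pd.DataFrame] = {}
    for i, spec in enumerate(sorted(inputs.outcomes, key=lambda s: s.name)):
        ds = spec.datasets[0]
        try:
            rev_instr = select_instruments(ds, inputs.p_threshold, inputs.ld,
                                           inputs.r2_threshold)
        except Exception as exc:  # empty selection or malformed data
            sections[spec.name] = pd.DataFrame(
                [{"method": "not_estimable", "note": str(exc)}])
            continue
        harmonized = harmonize(ds, inputs.exposure, rev_instr.rsids)
        if harmonized.n_snp == 0:
            sections[spec.name] = pd.DataFrame(
                [{"method": "not_estimable",
                  "note": "no reverse instruments survived harmonization"}])
            continue
        ests = _estimator_suite(harmonized, inputs.estimator,
                                seed_offset=77_000 + 1000 * i)
        tab = estimates_table(ests)
        tab.insert(0, "direction", "reverse")
        tab.insert(1, "instrument_source", spec.name)
        sections[spec.name] = tab
    return sections


# ---------------------------------------------------------------------------
# YAML run configuration


def load_study(config_path) -> StudyInputs:
    """Build StudyInputs from a YAML run configuration.

    Top-level keys mirror StudyInputs: ``exposure`` (file/trait/type/n,
    optional column_map), ``outcomes`` (list of name/trait_type/datasets,
    optional sex_files and coloc_regions), optional ``ld_matrix`` and
    ``annotations`` paths, instrument/coloc/estimator settings, ``n_tests``.
    Referenced paths are resolved relative to the config file.
    """
    path = Path(config_path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    base = path.parent

    def resolve(p):
        p = Path(p)
        return p if p.is_absolute() else base / p

    exp_cfg = cfg["exposure"]
    exposure = read_gwas(resolve(exp_cfg["file"]),
                         column_map=exp_cfg.get("column_map"),
                         trait=exp_cfg.get("trait", "exposure"),
                         trait_type=exp_cfg.get("trait_type", "quantitative"),
                         n=exp_cfg.get("n"))
    ld = LdMatrix.from_tsv(resolve(cfg["ld_matrix"])) if cfg.get("ld_matrix") else None
    ann = read_annotations(resolve(cfg["annotations"])) if cfg.get("annotations") else None

    outcomes = []
    for o in cfg["outcomes"]:
        datasets = []
        for d in o["datasets"]:
            datasets.append(read_gwas(
                resolve(d["file"]), column_map=d.get("column_map"),
                trait=d.get("trait", o["name"]),
                trait_type=o.get("trait_type", "binary"),
                n=d.get("n"), n_case=d.get("n_case")))
        sex_datasets = {}
        for stratum, d in (o.get("sex_files") or {}).items():
            sex_datasets[stratum] = read_gwas(
                resolve(d["file"]), column_map=d.get("column_map"),
                trait=f"{o['name']}_{stratum}",
                trait_type=o.get("trait_type", "binary"),
                n=d.get("n"), n_case=d.get("n_case"))
        regions = {}
        for rsid, r in (o.get("coloc_regions") or {}).items():
            regions[rsid] = (
                RegionStats.from_tsv(resolve(r["exposure"]), trait="exposure",
                                     trait_type=exp_cfg.get("trait_type", "quantitative")),
                RegionStats.from_tsv(resolve(r["outcome"]), trait=o["name"],
                                     trait_type=o.get("trait_type", "binary")),
            )
        outcomes.append(OutcomeSpec(name=o["name"], datasets=datasets,
                                    sex_datasets=sex_datasets,
                                    coloc_regions=regions))

    est_cfg = cfg.get("estimators", {})
    settings = EstimatorSettings(
        boot_reps=est_cfg.get("boot_reps", 1000),
        presso_sims=est_cfg.get("presso_sims", 1000),
        presso_outlier_p=est_cfg.get("presso_outlier_p", 0.05),
        pivw_penalty=est_cfg.get("pivw_penalty", 1.0),
        bandwidth_factor=est_cfg.get("bandwidth_factor", 1.0),
        seed=est_cfg.get("seed", 0),
    )
    coloc_cfg = cfg.get("coloc", {})
    priors = tuple(coloc_cfg.get("priors", DEFAULT_PRIORS))
    return StudyInputs(
        exposure=exposure, outcomes=outcomes, ld=ld, annotations=ann,
        p_threshold=cfg.get("p_threshold", 5e-8),
        r2_threshold=cfg.get("r2_threshold", 1e-3),
        confounder_p=cfg.get("confounder_p", 5e-8),
        outcome_assoc_p=cfg.get("outcome_assoc_p", 5e-8),
        coloc_priors=priors,
        pp_h4_threshold=coloc_cfg.get("pp_h4_threshold", 0.8),
        estimator=settings,
        n_tests=cfg.get("n_tests", 15),
        alpha=cfg.get("alpha", 0.05),
        power_target=cfg.get("power_target", 0.8),
    )
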