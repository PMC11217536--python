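"""End-to-end per-exposure analysis and the multi-exposure screen.

One exposure runs: p-value filter → LD clumping → instrument strength →
harmonization with the outcome → estimators (IVW primary; Egger, weighted
median, maximum likelihood as sensitivity analyses) → Cochran's Q →
Egger-intercept pleiotropy flag → MR-PRESSO.  The screen repeats this per
named catalog trait and collects one row per (exposure, method), flagging
exposures with IVW p below the significance threshold.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, MRScreenError
from .estimators import MREstimate, egger, ivw, max_likelihood, weighted_median
from .harmonize import HarmonizedSet, harmonization_report, harmonize_pair
from .instruments import (clump, filter_by_pvalue, filter_unnamed_taxa,
                          instrument_strength, trait_strength,
                          weak_instrument_filter)
from .io import (LDTable, SNPAssociation, read_ld_table, read_summary_stats,
                 read_trait_catalog, write_results_table)
from .sensitivity import (HeterogeneityResult, PlotData, PressoResult,
                          cochran_q, mr_presso, plot_data)

logger = logging.getLogger("mrscreen")

DEFAULT_METHODS = ("ivw", "egger", "weighted_median", "max_likelihood")


@dataclass
class PipelineConfig:
    """Analysis thresholds and options, defaulting to the study settings."""

    pvalue_threshold: float = 1e-5
    clump_r2: float = 0.001
    clump_kb: int = 10_000
    palindrome_policy: str = "drop"
    methods: tuple[str, ...] = DEFAULT_METHODS
    ivw_model: str = "auto"
    f_min: float = 10.0
    weak_instrument_action: str = "report"  # "report" | "filter"
    presso_n_simulations: int = 1000
    presso_significance: float = 0.05
    significance: float = 0.05
    multiple_testing: str = "none"  # "none" | "bonferroni" | "bh"
    weighted_median_n_boot: int = 1000
    seed: int = 42

    def __post_init__(self):
        if not 0.0 < self.pvalue_threshold <= 1.0:
            raise ConfigError(f"pvalue_threshold outside (0,1]: {self.pvalue_threshold}")
        if not 0.0 <= self.clump_r2 <= 1.0:
            raise ConfigError(f"clump_r2 outside [0,1]: {self.clump_r2}")
        if self.clump_kb <= 0:
            raise ConfigError(f"clump_kb must be > 0: {self.clump_kb}")
        if self.palindrome_policy != "drop":
            raise ConfigError("only palindrome_policy='drop' is supported")
        if self.multiple_testing not in ("none", "bonferroni", "bh"):
            raise ConfigError(f"unknown multiple_testing: {self.multiple_testing}")
        if self.weak_instrument_action not in ("report", "filter"):
            raise ConfigError(f"unknown weak_instrument_action: {self.weak_instrument_action}")
        unknown = set(self.methods) - set(DEFAULT_METHODS)
        if unknown:
            raise ConfigError(f"unknown method(s): {sorted(unknown)}")
        self.methods = tuple(self.methods)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class ExposureResult:
    """Everything computed for one exposure trait."""

    exposure: str
    status: str  # "ok" | "skipped"
    reason: str = ""
    n_snp_initial: int = 0
    n_snp_after_clump: int = 0
    n_snp_after_harmonize: int = 0
    estimates: list[MREstimate] = field(default_factory=list)
    method_errors: dict[str, str] = field(default_factory=dict)
    heterogeneity: HeterogeneityResult | None = None
    egger_intercept: MREstimate | None = None
    presso: PressoResult | None = None
    plots: PlotData | None = None
    harmonization: dict[str, int] = field(default_factory=dict)
    f_min_snp: float | None = None
    f_max_snp: float | None = None
    f_trait: float | None = None

    @property
    def ivw_estimate(self) -> MREstimate | None:
        return next((e for e in self.estimates if e.method.startswith("ivw")), None)


@dataclass
class ScreenResult:
    """Per-trait results of a multi-exposure screen."""

    results: list[ExposureResult]
    config: PipelineConfig

    def table(self) -> pd.DataFrame:
        """One row per (exposure, method), with diagnostics and stage counts."""
        rows = []
        for res in self.results:
            base = {
                "exposure": res.exposure,
                "status": res.status,
                "reason": res.reason,
                "n_snp_initial": res.n_snp_initial,
                "n_snp_after_clump": res.n_snp_after_clump,
                "n_snp_after_harmonize": res.n_snp_after_harmonize,
                "q_statistic": res.heterogeneity.q_statistic if res.heterogeneity else np.nan,
                "q_pvalue": res.heterogeneity.pvalue if res.heterogeneity else np.nan,
                "egger_intercept_p": res.egger_intercept.pvalue if res.egger_intercept else np.nan,
                "presso_global_p": res.presso.global_pvalue if res.presso else np.nan,
                "presso_n_outliers": len(res.presso.outlier_indices) if res.presso else np.nan,
            }
            ivw_est = res.ivw_estimate
            significant = bool(ivw_est and ivw_est.pvalue < self.config.significance)
            if not res.estimates:
                rows.append({**base, "method": "", "n_snp": np.nan, "beta": np.nan,
                             "se": np.nan, "or": np.nan, "ci_low": np.nan,
                             "ci_high": np.nan, "pvalue": np.nan,
                             "model_selected": "", "significant": significant})
            for est in res.estimates:
                rows.append({**base, "method": est.method, "n_snp": est.n_snp,
                             "beta": est.beta, "se": est.se, "or": est.or_value,
                             "ci_low": est.ci_low, "ci_high": est.ci_high,
                             "pvalue": est.pvalue,
                             "model_selected": est.model_selected or "",
                             "significant": significant})
        df = pd.DataFrame(rows)
        return _adjust_pvalues(df, self.config) if len(df) else df

    def significant_table(self) -> pd.DataFrame:
        """Rows for exposures whose (adjusted) IVW p is below the threshold —
        exactly a post-hoc filter of the full table, no hidden criteria."""
        table = self.table()
        if not len(table):
            return table
        return table[table["significant"]].reset_index(drop=True)


def _adjust_pvalues(df: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """Optional multiple-testing adjustment of the IVW screen p-values.

    Off by default; the study interpreted the screen without correction.
    """
    if config.multiple_testing == "none":
        return df
    from statsmodels.stats.multitest import multipletests

    mask = df["method"].astype(str).str.startswith("ivw") & df["pvalue"].notna()
    if not mask.any():
        return df
    method = {"bonferroni": "bonferroni", "bh": "fdr_bh"}[config.multiple_testing]
    reject, adjusted, _, _ = multipletests(
        df.loc[mask, "pvalue"], alpha=config.significance, method=method)
    df = df.copy()
    df["pvalue_adjusted"] = np.nan
    df.loc[mask, "pvalue_adjusted"] = adjusted
    # the significance flag follows the adjusted IVW p per exposure
    sig_by_exposure = dict(zip(df.loc[mask, "exposure"], reject))
    df["significant"] = df["exposure"].map(
        lambda e: bool(sig_by_exposure.get(e, False)))
    return df


def analyze_exposure(exposure: list[SNPAssociation], outcome: list[SNPAssociation],
                     ld: LDTable, config: PipelineConfig,
                     name: str = "exposure", outcome_name: str = "outcome"
                     ) -> ExposureResult:
    """Run the full single-exposure analysis on in-memory records."""
    result = ExposureResult(exposure=name, status="ok")

    selected = filter_by_pvalue(exposure, config.pvalue_threshold)
    result.n_snp_initial = len(selected)
    logger.info("%s: %d/%d SNPs pass p < %g", name, len(selected), len(exposure),
                config.pvalue_threshold)
    if not selected:
        result.status, result.reason = "skipped", "no instruments"
        return result

    clumped = clump(selected, ld, config.clump_r2, config.clump_kb)
    result.n_snp_after_clump = len(clumped)
    logger.info("%s: %d SNPs survive clumping", name, len(clumped))

    strengths = [instrument_strength(r, k=1) for r in clumped]
    result.f_min_snp = min(s.f_statistic for s in strengths)
    result.f_max_snp = max(s.f_statistic for s in strengths)
    result.f_trait = trait_strength(clumped).f_statistic
    if config.weak_instrument_action == "filter":
        strong_ids = {s.variant_id for s in weak_instrument_filter(strengths, config.f_min)}
        clumped = [r for r in clumped if r.variant_id in strong_ids]
        result.n_snp_after_clump = len(clumped)
        if not clumped:
            result.status, result.reason = "skipped", "no instruments with F > f_min"
            return result

    hset = harmonize_pair(clumped, outcome, exposure_name=name, outcome_name=outcome_name)
    result.n_snp_after_harmonize = hset.n_snp
    result.harmonization = harmonization_report(hset)
    logger.info("%s: %d SNPs after harmonization", name, hset.n_snp)
    if hset.n_snp == 0:
        result.status, result.reason = "skipped", "no instruments after harmonization"
        return result

    _run_estimators(hset, config, result)
    _run_diagnostics(hset, config, result)
    result.plots = plot_data(hset, result.estimates
                             + ([result.egger_intercept] if result.egger_intercept else []))
    for est in result.estimates:
        est.exposure = name
        est.outcome = outcome_name
    return result


def _run_estimators(hset: HarmonizedSet, config: PipelineConfig,
                    result: ExposureResult) -> None:
    # per-method failures degrade to an empty cell, not a failed run
    import warnings as _warnings

    for method in config.methods:
        try:
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                if method == "ivw":
                    result.estimates.append(ivw(hset, model=config.ivw_model))
                elif method == "egger":
                    slope, intercept = egger(hset)
                    result.estimates.append(slope)
                    result.egger_intercept = intercept
                elif method == "weighted_median":
                    result.estimates.append(weighted_median(
                        hset, n_boot=config.weighted_median_n_boot, seed=config.seed))
                elif method == "max_likelihood":
                    result.estimates.append(max_likelihood(hset))
        except MRScreenError as exc:
            result.method_errors[method] = str(exc)
            logger.info("%s: %s failed: %s", result.exposure, method, exc)


def _run_diagnostics(hset: HarmonizedSet, config: PipelineConfig,
                     result: ExposureResult) -> None:
    if hset.n_snp >= 2:
        result.heterogeneity = cochran_q(hset, significance=config.significance)
    if hset.n_snp >= 4:
        try:
            result.presso = mr_presso(
                hset, n_simulations=config.presso_n_simulations,
                significance=config.presso_significance, seed=config.seed,
                ivw_model=config.ivw_model)
        except MRScreenError as exc:
            result.method_errors["mr_presso"] = str(exc)


def run_single(exposure_path, outcome_path, ld_path, config: PipelineConfig,
               exposure_column_map: dict | None = None,
               outcome_column_map: dict | None = None,
               name: str | None = None) -> ExposureResult:
    """Read one exposure, the outcome and the LD table, then analyze."""
    exposure = read_summary_stats(exposure_path, exposure_column_map)
    outcome = read_summary_stats(outcome_path, outcome_column_map)
    ld = read_ld_table(ld_path) if ld_path is not None else LDTable()
    return analyze_exposure(exposure, outcome, ld, config,
                            name=name or Path(exposure_path).stem)


def run_screen(catalog_path, exposure_dir, outcome_path, ld_path,
               config: PipelineConfig,
               outcome_column_map: dict | None = None) -> ScreenResult:
    """Analyze every named catalog trait against one outcome.

    Exposure files are looked up as ``<exposure_dir>/<trait_id>.tsv``.
    Unnamed taxa are removed first; a missing exposure file or an empty
    instrument set yields a skip row with its reason, never a failed screen.
    """
    catalog = read_trait_catalog(catalog_path)
    named = filter_unnamed_taxa(catalog)
    logger.info("screen: %d/%d catalog traits have a specific name",
                len(named), len(catalog))
    if not named:
        logger.warning("screen: catalog is empty after removing unnamed taxa")
    outcome = read_summary_stats(outcome_path, outcome_column_map)
    ld = read_ld_table(ld_path) if ld_path is not None else LDTable()

    exposure_dir = Path(exposure_dir)
    results = []
    for trait in named:
        path = exposure_dir / f"{trait.trait_id}.tsv"
        if not path.exists():
            results.append(ExposureResult(
                exposure=trait.trait_name, status="skipped",
                reason=f"missing exposure file {path.name}"))
            logger.warning("screen: missing exposure file for %s", trait.trait_id)
            continue
        exposure = read_summary_stats(path)
        results.append(analyze_exposure(exposure, outcome, ld, config,
                                        name=trait.trait_name))
    return ScreenResult(results=results, config=config)


def _format_forest_row(est: MREstimate) -> dict:
    return {
        "exposure": est.exposure,
        "method": est.method,
        "n_snp": est.n_snp,
        "or_ci": f"{est.or_value:.2f} ({est.ci_low:.2f}-{est.ci_high:.2f})",
        "pvalue": f"{est.pvalue:.3g}",
    }


def report(result: ScreenResult, out_dir, plots: bool = False) -> dict[str, str]:
    """Write the screen outputs: full results TSV, significant subtable,
    forest table, per-exposure scatter/funnel data, and a run log with the
    config, seed and library versions.  Returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    table = result.table()
    table.to_csv(out_dir / "results.tsv", sep="\t", index=False, float_format="%.6g")
    paths["results"] = str(out_dir / "results.tsv")

    result.significant_table().to_csv(
        out_dir / "significant.tsv", sep="\t", index=False, float_format="%.6g")
    paths["significant"] = str(out_dir / "significant.tsv")

    estimates = [e for res in result.results for e in res.estimates]
    write_results_table(estimates, out_dir / "estimates.tsv")
    paths["estimates"] = str(out_dir / "estimates.tsv")

    forest = pd.DataFrame(
        [_format_forest_row(e) for e in estimates],
        columns=["exposure", "method", "n_snp", "or_ci", "pvalue"])
    forest.to_csv(out_dir / "forest.tsv", sep="\t", index=False)
    paths["forest"] = str(out_dir / "forest.tsv")

    plot_dir = out_dir / "plot_data"
    plot_dir.mkdir(exist_ok=True)
    for res in result.results:
        if res.plots is None:
            continue
        stem = res.exposure.replace("/", "_").replace(" ", "_")
        res.plots.scatter.to_csv(plot_dir / f"{stem}_scatter.tsv", sep="\t",
                                 index=False, float_format="%.6g")
        res.plots.funnel.to_csv(plot_dir / f"{stem}_funnel.tsv", sep="\t",
                                index=False, float_format="%.6g")
        if plots:
            from .sensitivity import render_plots
            render_plots(res.plots, str(plot_dir / stem))

    log = {
        "package_version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(result.config).items()},
        "seed": result.config.seed,
        "versions": _library_versions(),
        "n_exposures": len(result.results),
        "n_skipped": sum(r.status == "skipped" for r in result.results),
    }
    with open(out_dir / "run_log.json", "w", encoding="utf-8") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    paths["run_log"] = str(out_dir / "run_log.json")
    return paths


def _library_versions() -> dict[str, str]:
    import scipy
    return {"numpy": np.__version__, "scipy": scipy.__version__,
            "pandas": pd.__version__}
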