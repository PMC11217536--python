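"""Heterogeneity, pleiotropy and outlier diagnostics.

Cochran's Q tests whether the per-SNP Wald ratios are mutually consistent
(Q ~ chi-square(J−1) under homogeneity); significant heterogeneity switches
the IVW pooling from fixed to multiplicative random effects.  MR-PRESSO
(Pleiotropy RESidual Sum and Outlier) detects horizontal-pleiotropy
outliers by comparing each SNP's leave-one-out residual sum of squares to
its Monte-Carlo null, re-estimates after removing them, and tests whether
the removal distorts the estimate.  Scatter and funnel data back the visual
outlier/heterogeneity checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateCorrectionError, InsufficientInstrumentsError
from .estimators import MREstimate, _q_statistic, _ratio_weights, ivw, wald_ratio
from .harmonize import HarmonizedSet


@dataclass
class HeterogeneityResult:
    """Cochran's Q with its fixed/random model recommendation."""

    q_statistic: float
    df: int
    pvalue: float
    model_selected: str  # "fixed" | "random"


def cochran_q(hset: HarmonizedSet, significance: float = 0.05) -> HeterogeneityResult:
    """Cochran's Q = Σ w_j (θ̂_j − θ̂_IVW)², chi-square with J−1 df.

    ``model_selected`` is "random" exactly when p < ``significance``,
    mirroring the fixed→random IVW switch.
    """
    J = hset.n_snp
    if J < 2:
        raise InsufficientInstrumentsError(f"Cochran's Q needs >= 2 instruments, got {J}")
    ratios, weights = _ratio_weights(hset)
    pooled = float(np.sum(weights * ratios) / weights.sum())
    q = _q_statistic(ratios, weights, pooled)
    pvalue = float(stats.chi2.sf(q, J - 1))
    return HeterogeneityResult(
        q_statistic=q, df=J - 1, pvalue=max(pvalue, np.nextafter(0.0, 1.0)),
        model_selected="random" if pvalue < significance else "fixed")


@dataclass
class PressoResult:
    """MR-PRESSO global, outlier and distortion test results."""

    global_rss_observed: float
    global_pvalue: float
    outlier_indices: set[int]
    outlier_pvalues: np.ndarray
    distortion_pvalue: float | None
    estimate_raw: MREstimate
    estimate_corrected: MREstimate
    n_simulations: int
    seed: int


def _loo_ivw(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW estimates θ̂_(−j), vectorized over trailing axis j.

    Accepts 1-D (J,) or 2-D (m, J) effect arrays; sy broadcasts.
    """
    w = bx ** 2 / sy ** 2
    theta = by / bx
    sw = w.sum(axis=-1, keepdims=True)
    swt = (w * theta).sum(axis=-1, keepdims=True)
    return (swt - w * theta) / (sw - w)


def _rss_and_residuals(bx, by, sy):
    theta_loo = _loo_ivw(bx, by, sy)
    resid = (by - theta_loo * bx) ** 2 / sy ** 2
    return resid.sum(axis=-1), resid


def observed_rss(hset: HarmonizedSet) -> float:
    """Leave-one-out weighted residual sum of squares of the observed data."""
    rss, _ = _rss_and_residuals(hset.beta_exposure, hset.beta_outcome, hset.se_outcome)
    return float(rss)


def mr_presso(hset: HarmonizedSet, n_simulations: int = 1000,
              significance: float = 0.05, seed: int = 42,
              ivw_model: str = "auto", n_distortion: int = 1000) -> PressoResult:
    """MR-PRESSO: global heterogeneity, per-SNP outliers, distortion test.

    The observed statistic is RSS = Σ_j (β_Yj − θ̂_(−j) β_Xj)² / se_Yj²
    with θ̂_(−j) the leave-one-out IVW estimate (equivalently the
    IVW-weighted squared ratio deviation).  Its null distribution comes from
    ``n_simulations`` parametric draws β*_Xj ~ N(β_Xj, se_Xj²),
    β*_Yj ~ N(θ̂_(−j) β_Xj, se_Yj²).  Per-SNP outlier p-values are the
    Monte-Carlo tail probabilities of each observed residual, Bonferroni
    multiplied by J; SNPs below ``significance`` are flagged and the IVW
    estimate is recomputed without them.  The distortion p-value compares
    the raw-vs-corrected shift against shifts from removing random subsets
    of the same size.  All Monte-Carlo p-values use the add-one estimator
    (b+1)/(m+1).
    """
    J = hset.n_snp
    if J < 4:
        raise InsufficientInstrumentsError(f"MR-PRESSO needs >= 4 instruments, got {J}")
    if n_simulations < 100:
        raise ValueError(f"n_simulations must be >= 100, got {n_simulations}")
    rng = np.random.default_rng(seed)

    bx, sx = hset.beta_exposure, hset.se_exposure
    by, sy = hset.beta_outcome, hset.se_outcome
    rss_obs, resid_obs = _rss_and_residuals(bx, by, sy)
    theta_loo = _loo_ivw(bx, by, sy)

    m = n_simulations
    bx_sim = rng.normal(bx, sx, size=(m, J))
    by_sim = rng.normal(theta_loo * bx, sy, size=(m, J))
    rss_sim, resid_sim = _rss_and_residuals(bx_sim, by_sim, sy)

    global_pvalue = (int(np.sum(rss_sim >= rss_obs)) + 1) / (m + 1)
    tail = (resid_sim >= resid_obs).sum(axis=0)
    outlier_pvalues = np.minimum((tail + 1) / (m + 1) * J, 1.0)
    outliers = {int(j) for j in np.nonzero(outlier_pvalues < significance)[0]}

    estimate_raw = ivw(hset, model=ivw_model)
    if len(outliers) == J:
        raise DegenerateCorrectionError("every instrument flagged as an outlier")
    if outliers:
        keep = sorted(set(range(J)) - outliers)
        estimate_corrected = ivw(hset.subset(keep), model=ivw_model)
        distortion_pvalue = _distortion_test(
            hset, len(outliers), estimate_raw.beta, estimate_corrected.beta,
            rng, n_distortion, ivw_model)
    else:
        estimate_corrected = estimate_raw
        distortion_pvalue = None

    return PressoResult(
        global_rss_observed=float(rss_obs), global_pvalue=float(global_pvalue),
        outlier_indices=outliers, outlier_pvalues=outlier_pvalues,
        distortion_pvalue=distortion_pvalue,
        estimate_raw=estimate_raw, estimate_corrected=estimate_corrected,
        n_simulations=n_simulations, seed=seed)


def _distortion_test(hset, n_out, beta_raw, beta_corrected, rng, n_draws, ivw_model):
    J = hset.n_snp
    observed_shift = abs(beta_raw - beta_corrected)
    shifts = np.empty(n_draws)
    ratios, weights = _ratio_weights(hset)
    sw, swt = weights.sum(), float(np.sum(weights * ratios))
    for d in range(n_draws):
        drop = rng.choice(J, size=n_out, replace=False)
        w_drop = weights[drop].sum()
        beta_sub = (swt - float(np.sum(weights[drop] * ratios[drop]))) / (sw - w_drop)
        shifts[d] = abs(beta_raw - beta_sub)
    return (int(np.sum(shifts >= observed_shift)) + 1) / (n_draws + 1)


@dataclass
class PlotData:
    """Per-SNP tables behind the scatter and funnel diagnostic plots."""

    scatter: pd.DataFrame  # variant_id, beta_exposure, beta_outcome, se_exposure, se_outcome
    lines: pd.DataFrame    # method, slope, intercept
    funnel: pd.DataFrame   # variant_id, ratio, precision
    pooled: float | None = None


def plot_data(hset: HarmonizedSet, estimates: list[MREstimate]) -> PlotData:
    """Scatter (β_X vs β_Y with per-method fitted lines) and funnel data.

    Fitted lines pass through the origin for every method except the Egger
    slope, which is paired with its own intercept estimate.  The funnel
    plots each Wald ratio against its precision, with the pooled estimate
    (IVW where present, else the first method) as the vertical reference.
    """
    scatter = pd.DataFrame({
        "variant_id": hset.variant_ids,
        "beta_exposure": hset.beta_exposure,
        "beta_outcome": hset.beta_outcome,
        "se_exposure": hset.se_exposure,
        "se_outcome": hset.se_outcome,
    })
    egger_intercept = next((e.beta for e in estimates if e.method == "egger_intercept"), 0.0)
    lines = pd.DataFrame([
        {"method": e.method, "slope": e.beta,
         "intercept": egger_intercept if e.method == "egger_slope" else 0.0}
        for e in estimates if e.method not in ("egger_intercept",)
    ], columns=["method", "slope", "intercept"])

    if hset.n_snp:
        ratio_est = [wald_ratio(bx, sx, by, sy)
                     for bx, sx, by, sy in zip(hset.beta_exposure, hset.se_exposure,
                                               hset.beta_outcome, hset.se_outcome)]
        funnel = pd.DataFrame({
            "variant_id": hset.variant_ids,
            "ratio": [e.beta for e in ratio_est],
            "precision": [1.0 / e.se for e in ratio_est],
        })
    else:
        funnel = pd.DataFrame(columns=["variant_id", "ratio", "precision"])

    pooled = next((e.beta for e in estimates if e.method.startswith("ivw")),
                  estimates[0].beta if estimates else None)
    return PlotData(scatter=scatter, lines=lines, funnel=funnel, pooled=pooled)


def leave_one_out(hset: HarmonizedSet, model: str = "fixed") -> pd.DataFrame:
    """IVW estimate with each instrument removed in turn (optional extra)."""
    if hset.n_snp < 2:
        raise InsufficientInstrumentsError("leave-one-out needs >= 2 instruments")
    rows = []
    for j in range(hset.n_snp):
        keep = [i for i in range(hset.n_snp) if i != j]
        est = ivw(hset.subset(keep), model=model)
        rows.append({"excluded": hset.variant_ids[j], "beta": est.beta,
                     "se": est.se, "pvalue": est.pvalue})
    return pd.DataFrame(rows)


def render_plots(data: PlotData, out_prefix: str) -> list[str]:
    """Render basic scatter and funnel PNGs; returns the written paths."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = []
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(data.scatter["beta_exposure"], data.scatter["beta_outcome"],
                xerr=data.scatter["se_exposure"], yerr=data.scatter["se_outcome"],
                fmt="o", ms=3, lw=0.8, alpha=0.7)
    if len(data.scatter):
        xs = np.linspace(0, data.scatter["beta_exposure"].abs().max(), 50)
        for _, row in data.lines.iterrows():
            ax.plot(xs, row["intercept"] + row["slope"] * xs, label=row["method"], lw=1)
        ax.legend(fontsize=7)
    ax.set_xlabel("SNP effect on exposure")
    ax.set_ylabel("SNP effect on outcome")
    path = f"{out_prefix}_scatter.png"
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    paths.append(path)

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(data.funnel["ratio"], data.funnel["precision"], "o", ms=3, alpha=0.7)
    if data.pooled is not None:
        ax.axvline(data.pooled, color="k", lw=1, ls="--")
    ax.set_xlabel("Wald ratio")
    ax.set_ylabel("precision (1/SE)")
    path = f"{out_prefix}_funnel.png"
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    paths.append(path)
    return paths
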